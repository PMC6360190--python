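"""Readers and writers for every on-disk table the pipeline consumes or emits.

All files are TSV (tab-separated, UTF-8). Lines starting with ``#`` are
comments. Gzip compression is transparent (pandas dispatches on the ``.gz``
suffix). Floats are serialized with 6 significant digits. Readers validate
strictly and raise :class:`FormatError` / :class:`ValidationError` rather than
silently coercing malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "OrthogroupMap",
    "EdgeList",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_orthogroup_map",
    "write_orthogroup_map",
    "read_go_map",
    "write_go_map",
    "read_edges",
    "write_edges",
    "read_sif",
    "write_sif",
]

FLOAT_FMT = "%.6g"

METADATA_COLUMNS = ("species", "zt", "replicate", "dark")

VALID_UNITS = ("counts", "tpm", "normalized")


class FormatError(ValueError):
    """Malformed file structure (duplicates, ragged rows, bad headers)."""


class ValidationError(ValueError):
    """Well-formed file whose contents violate an invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns. Entries are
        nonnegative counts, TPM, or normalized counts according to ``unit``.
    metadata
        DataFrame indexed by sample ID with columns ``species`` (str), ``zt``
        (zeitgeber hours), ``replicate`` (str) and ``dark`` (bool). Must cover
        every sample in ``values``.
    lengths
        Optional per-gene transcript lengths in bp (positive), required for
        TPM computation.
    unit
        One of ``counts``, ``tpm``, ``normalized``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None
    lengths: pd.Series | None = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            g, s = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative value at (gene={idx[g]!r}, sample={cols[s]!r}): {vals[g, s]}"
            )
        if np.isnan(vals).any():
            g, s = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(f"missing value at (gene={idx[g]!r}, sample={cols[s]!r})")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(idx)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
                raise ValidationError(f"genes without length: {missing}")
            if (self.lengths <= 0).any():
                bad = self.lengths.index[self.lengths <= 0].tolist()[:5]
                raise ValidationError(f"non-positive lengths for genes: {bad}")
        if self.metadata is not None:
            missing = cols.difference(self.metadata.index)
            if len(missing):
                raise ValidationError(f"metadata missing samples: {missing.tolist()[:5]}")
            self.metadata = self.metadata.loc[cols]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zt(self) -> np.ndarray:
        """Zeitgeber time (hours) per sample, from metadata."""
        if self.metadata is None:
            raise ValidationError("no metadata attached")
        return self.metadata["zt"].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = pd.Index(gene_ids)
        lengths = self.lengths.loc[gene_ids] if self.lengths is not None else None
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.metadata, lengths, self.unit
        )

    def replace_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.metadata, self.lengths, unit)


@dataclass
class OrthogroupMap:
    """Transcript -> orthogroup assignment with transcript lengths.

    ``transcripts`` is indexed by transcript ID with columns ``orthogroup``
    and ``length`` (bp). ``bounds``, when present, is indexed by orthogroup
    with columns ``min_ref_length`` and ``max_ref_length`` — the shortest and
    longest homolog in the reference genomes the family was circumscribed
    against.
    """

    transcripts: pd.DataFrame
    bounds: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.transcripts.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"transcript mapped more than once: {dup[:5]}")
        if (self.transcripts["length"] <= 0).any():
            bad = self.transcripts.index[self.transcripts["length"] <= 0].tolist()
            raise ValidationError(f"non-positive transcript lengths: {bad[:5]}")
        if self.bounds is not None:
            b = self.bounds
            ok = (b["min_ref_length"] > 0) & (b["min_ref_length"] <= b["max_ref_length"])
            if not ok.all():
                bad = b.index[~ok].tolist()
                raise ValidationError(f"invalid reference bounds for orthogroups: {bad[:5]}")

    def orthogroup_of(self, transcript_ids) -> pd.Series:
        return self.transcripts["orthogroup"].reindex(transcript_ids)

    def members(self, orthogroup_id: str) -> list[str]:
        t = self.transcripts
        return t.index[t["orthogroup"] == orthogroup_id].tolist()


def _canonical_pairs(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    swap = a > b
    a2 = a.where(~swap, b)
    b2 = b.where(~swap, a)
    return a2, b2


@dataclass
class EdgeList:
    """Undirected weighted edges as a canonicalized table.

    Columns: ``node_a``, ``node_b`` (gene IDs, ``node_a < node_b``
    lexicographically), ``weight`` (MI in nats, >= 0), ``support`` (bootstrap
    count, integer).
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["node_a", "node_b", "weight", "support"]))

    def __post_init__(self) -> None:
        e = self.edges.reset_index(drop=True).copy()
        for col, default in (("weight", 1.0), ("support", 1)):
            if col not in e.columns:
                e[col] = default
        e["node_a"] = e["node_a"].astype(str)
        e["node_b"] = e["node_b"].astype(str)
        if (e["node_a"] == e["node_b"]).any():
            bad = e.loc[e["node_a"] == e["node_b"], "node_a"].tolist()
            raise ValidationError(f"self-edges not allowed: {bad[:5]}")
        e["node_a"], e["node_b"] = _canonical_pairs(e["node_a"], e["node_b"])
        if e.duplicated(subset=["node_a", "node_b"]).any():
            d = e.loc[e.duplicated(subset=["node_a", "node_b"]), ["node_a", "node_b"]]
            raise ValidationError(f"duplicate unordered pairs: {d.values.tolist()[:5]}")
        if (e["weight"].to_numpy() < 0).any():
            raise ValidationError("negative edge weight")
        e["weight"] = e["weight"].astype(float)
        e["support"] = e["support"].astype(int)
        self.edges = e[["node_a", "node_b", "weight", "support"]]

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> pd.Index:
        return pd.Index(
            pd.unique(np.concatenate([self.edges["node_a"], self.edges["node_b"]]))
            if len(self.edges) else [],
            name="node",
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse {path}: {exc}") from None


def read_counts(path, metadata=None, lengths=None, unit: str = "counts") -> ExpressionMatrix:
    """Read a gene x sample table (first column gene IDs, header sample IDs)."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene IDs in {path}: {dup[:5]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric column {col!r} in {path}")
    return ExpressionMatrix(df, metadata=metadata, lengths=lengths, unit=unit)


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0, dtype={"replicate": str})
    df.index = df.index.astype(str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} lacks columns {missing}")
    if df.index.duplicated().any():
        raise FormatError(f"duplicate sample IDs in metadata {path}")
    df["dark"] = df["dark"].astype(bool)
    df["zt"] = df["zt"].astype(float)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_orthogroup_map(path, bounds_path=None) -> OrthogroupMap:
    """Read transcript->orthogroup TSV (columns transcript, orthogroup, length).

    Optional reference bounds come either from ``bounds_path`` or from
    ``min_ref_length``/``max_ref_length`` columns in the main file.
    """
    df = _read_tsv(path)
    required = {"transcript", "orthogroup", "length"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} lacks columns {sorted(required - set(df.columns))}")
    df["transcript"] = df["transcript"].astype(str)
    tr = df.set_index("transcript")[["orthogroup", "length"]]
    bounds = None
    if {"min_ref_length", "max_ref_length"}.issubset(df.columns):
        bounds = (
            df.drop_duplicates("orthogroup")
            .set_index("orthogroup")[["min_ref_length", "max_ref_length"]]
        )
    if bounds_path is not None:
        b = _read_tsv(bounds_path)
        bounds = b.set_index("orthogroup")[["min_ref_length", "max_ref_length"]]
    return OrthogroupMap(tr, bounds)


def write_orthogroup_map(omap: OrthogroupMap, path) -> None:
    df = omap.transcripts.reset_index()
    df.columns = ["transcript", "orthogroup", "length"]
    if omap.bounds is not None:
        df = df.merge(omap.bounds, left_on="orthogroup", right_index=True, how="left")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_go_map(path) -> dict[str, set[str]]:
    """Read orthogroup -> GO annotation TSV (columns orthogroup, go_id)."""
    df = _read_tsv(path)
    if not {"orthogroup", "go_id"}.issubset(df.columns):
        raise FormatError(f"{path} lacks columns ['orthogroup', 'go_id']")
    out: dict[str, set[str]] = {}
    for og, go in zip(df["orthogroup"].astype(str), df["go_id"].astype(str)):
        out.setdefault(og, set()).add(go)
    return out


def write_go_map(go_map: dict[str, set[str]], path) -> None:
    rows = [(og, go) for og in sorted(go_map) for go in sorted(go_map[og])]
    pd.DataFrame(rows, columns=["orthogroup", "go_id"]).to_csv(path, sep="\t", index=False)


def read_edges(path) -> EdgeList:
    df = _read_tsv(path)
    if not {"node_a", "node_b"}.issubset(df.columns):
        raise FormatError(f"{path} lacks columns ['node_a', 'node_b']")
    return EdgeList(df)


def write_edges(edge_list: EdgeList, path) -> None:
    edge_list.edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


SIF_RELATION = "interacts"


def read_sif(path) -> EdgeList:
    """Read a SIF file of lines ``a interacts b``; weights default to 1.0."""
    rows = []
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3 or parts[1] != SIF_RELATION:
                raise FormatError(f"{path}:{ln}: expected 'a {SIF_RELATION} b'")
            a, rel, targets = parts[0], parts[1], parts[2:]
            for b in targets:
                rows.append((a, b))
    return EdgeList(pd.DataFrame(rows, columns=["node_a", "node_b"]))


def write_sif(edge_list: EdgeList, path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for a, b in zip(edge_list.edges["node_a"], edge_list.edges["node_b"]):
            fh.write(f"{a}\t{SIF_RELATION}\t{b}\n")
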