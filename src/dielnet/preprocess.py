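"""Expression and length filters plus count normalization.

The pipeline applies, in order: the orthogroup length filter (a transcript
must be no longer than the longest reference homolog of its family and at
least 50% of the shortest), the TPM expression filter (a gene whose TPM never
reaches the threshold in any sample is dropped), and median-of-ratios count
normalization for the downstream negative-binomial models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthogroupMap, ValidationError

__all__ = [
    "FilterReport",
    "tpm_from_counts",
    "filter_low_expression",
    "filter_by_orthogroup_length",
    "normalize_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping for sequentially applied gene filters."""

    n_input: int = 0
    n_removed_tpm: int = 0
    n_removed_length: int = 0
    n_retained: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input == self.n_retained + self.n_removed_tpm + self.n_removed_length

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, gid) for rule, ids in self.removed_ids.items() for gid in ids]
        return pd.DataFrame(rows, columns=["rule", "gene_id"])


def tpm_from_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts per kilobase million: length-normalized rates scaled so each
    sample column sums to 1e6.

    All-zero sample columns are left all-zero (with a logged warning).
    """
    if matrix.lengths is None:
        raise ValidationError("TPM requires transcript lengths")
    counts = matrix.values.to_numpy(dtype=float)
    kb = matrix.lengths.to_numpy(dtype=float) / 1000.0
    rate = counts / kb[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        bad = matrix.sample_ids[zero_cols].tolist()
        logger.warning("all-zero sample columns left as zero TPM: %s", bad)
        colsum[zero_cols] = 1.0
    tpm = rate / colsum[None, :] * 1e6
    values = pd.DataFrame(tpm, index=matrix.gene_ids, columns=matrix.sample_ids)
    return matrix.replace_values(values, unit="tpm")


def filter_low_expression(
    tpm: ExpressionMatrix, threshold: float = 2.0
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes whose TPM stays below ``threshold`` in every sample.

    A gene is retained iff max over samples TPM >= threshold (strict ``<``
    removal, so a gene that exactly reaches the threshold survives).
    """
    if threshold < 0:
        raise ValidationError("TPM threshold must be >= 0")
    if tpm.unit != "tpm":
        raise ValidationError(f"expected unit 'tpm', got {tpm.unit!r}")
    keep = tpm.values.max(axis=1) >= threshold
    removed = tpm.gene_ids[~keep].tolist()
    report = FilterReport(
        n_input=tpm.n_genes,
        n_removed_tpm=len(removed),
        n_retained=int(keep.sum()),
        removed_ids={"tpm": removed},
    )
    report.check()
    logger.info("TPM filter: %d removed, %d retained", len(removed), int(keep.sum()))
    return tpm.subset_genes(tpm.gene_ids[keep]), report


def filter_by_orthogroup_length(
    omap: OrthogroupMap, strict: bool = False
) -> tuple[set[str], FilterReport]:
    """Retain transcripts whose length lies in [0.5*min_ref, max_ref] of their
    orthogroup's reference-homolog bounds.

    Transcripts of an orthogroup lacking bounds are retained with a warning
    (``strict=True`` raises instead).
    """
    tr = omap.transcripts
    if omap.bounds is None:
        if strict:
            raise ValidationError("no reference bounds available")
        warnings.warn("orthogroup map has no reference bounds; all transcripts retained")
        report = FilterReport(n_input=len(tr), n_retained=len(tr), removed_ids={"length": []})
        return set(tr.index), report

    b = omap.bounds.reindex(tr["orthogroup"])
    has_bounds = ~b["min_ref_length"].isna().to_numpy()
    if not has_bounds.all():
        missing = sorted(set(tr["orthogroup"][~has_bounds]))
        if strict:
            raise ValidationError(f"orthogroups without reference bounds: {missing[:5]}")
        warnings.warn(
            f"{len(missing)} orthogroups lack reference bounds; their transcripts are retained"
        )
    length = tr["length"].to_numpy(dtype=float)
    lo = 0.5 * b["min_ref_length"].to_numpy(dtype=float)
    hi = b["max_ref_length"].to_numpy(dtype=float)
    ok = ~has_bounds | ((length >= lo) & (length <= hi))
    removed = tr.index[~ok].tolist()
    report = FilterReport(
        n_input=len(tr),
        n_removed_length=len(removed),
        n_retained=int(ok.sum()),
        removed_ids={"length": removed},
    )
    report.check()
    logger.info("length filter: %d removed, %d retained", len(removed), int(ok.sum()))
    return set(tr.index[ok]), report


def normalize_counts(
    matrix: ExpressionMatrix, method: str = "median_of_ratios"
) -> tuple[ExpressionMatrix, pd.Series]:
    """Library-size normalization of raw counts.

    ``median_of_ratios`` (default): per sample, the size factor is the median
    ratio of its counts to the geometric-mean pseudo-reference, computed over
    genes with all-positive counts, then rescaled so the factors have
    geometric mean 1. Falls back to total-count scaling (with a warning) when
    no gene has all-positive counts.
    """
    if matrix.unit != "counts":
        raise ValidationError(f"expected unit 'counts', got {matrix.unit!r}")
    counts = matrix.values.to_numpy(dtype=float)
    if method not in ("median_of_ratios", "total_count"):
        raise ValidationError(f"unknown normalization method {method!r}")

    factors = None
    if method == "median_of_ratios":
        allpos = (counts > 0).all(axis=1)
        if allpos.any():
            logc = np.log(counts[allpos])
            ref = logc.mean(axis=1)  # log geometric mean per gene
            ratios = logc - ref[:, None]
            factors = np.exp(np.median(ratios, axis=0))
        else:
            warnings.warn(
                "no gene with all-positive counts; falling back to total-count scaling"
            )
            method = "total_count"
    if method == "total_count":
        tot = counts.sum(axis=0)
        if (tot == 0).any():
            raise ValidationError("sample with zero total count cannot be normalized")
        factors = tot

    factors = np.asarray(factors, dtype=float)
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    normalized = counts / factors[None, :]
    values = pd.DataFrame(normalized, index=matrix.gene_ids, columns=matrix.sample_ids)
    sf = pd.Series(factors, index=matrix.sample_ids, name="size_factor")
    return matrix.replace_values(values, unit="normalized"), sf
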