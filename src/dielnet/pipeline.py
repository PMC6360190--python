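"""End-to-end pipeline: simulate -> preprocess -> timecourse -> cluster ->
network -> cross-species comparison -> diffusion -> enrichment.

Every stage writes its tables under the configured output directory and
records row counts, seeds and paths in a JSON manifest. Stage seeds are
spawned deterministically from the global seed, so rerunning a config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, compare, io, network, preprocess, simulate, timecourse
from .io import ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for every stage plus paths and the global seed."""

    outdir: str = "dielnet_run"
    seed: int = 0
    # synthetic data (None -> read inputs from counts/metadata paths instead)
    synth: simulate.SynthConfig | None = None
    counts_paths: dict | None = None      # species -> counts TSV
    metadata_paths: dict | None = None    # species -> metadata TSV
    orthogroup_path: str | None = None
    go_path: str | None = None
    # preprocess
    tpm_threshold: float = 2.0
    length_rule: bool = True
    normalization: str = "median_of_ratios"
    # timecourse
    max_degree: int = 4
    fdr: float = 0.05
    alpha_enter: float = 0.05
    dfbetas_threshold: float | str = 2.0
    # clustering
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 12)
    m: float | str = "auto"
    restarts: int = 5
    # network
    n_boot: int = 100
    mi_pvalue: float = 1e-8
    n_null: int = 100_000
    dpi_tolerance: float = 0.0
    consensus_alpha: float = 0.05
    # comparison
    outlier_rule: str = "tukey"
    outlier_multiplier: float = 1.5
    diffusion_fraction: float = 0.10
    diffusion_time: float = 0.1
    seed_gene: str | None = None  # default: the most-connected gene of species A
    enrichment: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = simulate.SynthConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["synth"].items()
            })
        if "k_range" in d and d["k_range"] is not None:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)


def demo_config(seed: int = 0, outdir: str = "dielnet_demo") -> PipelineConfig:
    """Desk-scale demo: 2 species x 500 genes, 25 bootstraps."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        synth=simulate.SynthConfig(n_genes=500, seed=seed),
        n_boot=25,
        n_null=20_000,
    )


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config.to_dict(), default=str)),
                      "stages": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # ---- stage 1: inputs -------------------------------------------------
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        matrices, omap, go_map, truth = simulate.generate_dataset(synth_cfg)
        paths = {}
        for s, m in matrices.items():
            cpath = out / f"{s}_counts.tsv"
            mpath = out / f"{s}_metadata.tsv"
            io.write_counts(m, cpath)
            io.write_metadata(m.metadata, mpath)
            paths[s] = {"counts": str(cpath), "metadata": str(mpath)}
        io.write_orthogroup_map(omap, out / "orthogroups.tsv")
        io.write_go_map(go_map, out / "go_map.tsv")
        pd.Series(sorted(truth.time_structured_genes)).to_csv(
            out / "truth_structured_genes.tsv", sep="\t", index=False, header=["gene_id"])
        pd.Series(sorted(truth.diff_connected_orthogroups)).to_csv(
            out / "truth_diff_connected.tsv", sep="\t", index=False, header=["orthogroup"])
        record("simulate", seed=config.seed, outputs=paths,
               n_genes={s: m.n_genes for s, m in matrices.items()})
    else:
        if not (config.counts_paths and config.metadata_paths and config.orthogroup_path):
            raise ValidationError("either synth config or input paths are required")
        omap = io.read_orthogroup_map(config.orthogroup_path)
        go_map = io.read_go_map(config.go_path) if config.go_path else None
        matrices = {}
        for s, cpath in config.counts_paths.items():
            meta = io.read_metadata(config.metadata_paths[s])
            m = io.read_counts(cpath, metadata=meta)
            lengths = omap.transcripts["length"].reindex(m.gene_ids)
            matrices[s] = io.ExpressionMatrix(m.values, meta, lengths, "counts")
        truth = None
        record("inputs", species=sorted(matrices))
    if config.enrichment and go_map is None:
        raise ValidationError("enrichment enabled but no GO map provided")

    species = sorted(matrices)

    # ---- stage 2: preprocess --------------------------------------------
    normalized: dict[str, io.ExpressionMatrix] = {}
    for s in species:
        m = matrices[s]
        if config.length_rule:
            kept, rep_len = preprocess.filter_by_orthogroup_length(
                io.OrthogroupMap(omap.transcripts.loc[omap.transcripts.index.isin(m.gene_ids)],
                                 omap.bounds))
            m = m.subset_genes([g for g in m.gene_ids if g in kept])
        tpm = preprocess.tpm_from_counts(m)
        tpm_f, rep_tpm = preprocess.filter_low_expression(tpm, config.tpm_threshold)
        m = m.subset_genes(tpm_f.gene_ids)
        norm, sf = preprocess.normalize_counts(m, config.normalization)
        normalized[s] = norm
        npath = out / f"{s}_normalized.tsv"
        io.write_counts(norm, npath)
        rep = pd.concat([rep_tpm.to_frame()] + ([rep_len.to_frame()] if config.length_rule else []))
        rep.to_csv(out / f"{s}_filter_report.tsv", sep="\t", index=False)
        record(f"preprocess_{s}", n_input=matrices[s].n_genes,
               n_retained=norm.n_genes, output=str(npath))

    # ---- stage 3: timecourse --------------------------------------------
    significant: dict[str, set] = {}
    for s in species:
        det = timecourse.TimeCourseDetector(
            max_degree=config.max_degree, fdr=config.fdr,
            alpha_enter=config.alpha_enter,
            dfbetas_threshold=config.dfbetas_threshold,
        ).fit(normalized[s])
        significant[s] = det.significant_
        rpath = out / f"{s}_timecourse.tsv"
        det.results_.to_csv(rpath, sep="\t", float_format="%.6g")
        record(f"timecourse_{s}", n_tested=normalized[s].n_genes,
               n_significant=len(det.significant_), output=str(rpath))

    # ---- stage 4: clustering --------------------------------------------
    cluster_assign: dict[str, pd.Series] = {}
    for s in species:
        genes = sorted(significant[s])
        if len(genes) < 3:
            logger.warning("%s: too few significant genes to cluster", s)
            cluster_assign[s] = pd.Series(dtype=int)
            continue
        profiles = clustering.zscore_profiles(normalized[s].values.loc[genes])
        m_val = (clustering.estimate_fuzzifier(*profiles.shape)
                 if config.m == "auto" else float(config.m))
        seed_c = _stage_seed(config.seed, 4)
        if config.k == "auto":
            lo, hi = config.k_range
            hi = min(hi, len(profiles) - 1)
            k_val, curve = clustering.select_k(
                profiles, m_val, range(lo, hi + 1), seed=seed_c, n_init=config.restarts)
            curve.to_csv(out / f"{s}_k_curve.tsv", sep="\t")
        else:
            k_val = int(config.k)
        result = clustering.fuzzy_cmeans(
            profiles, k_val, m_val, seed=seed_c, n_init=config.restarts)
        clustering.label_bias(result, simulate.dark_mask(normalized[s].metadata))
        cluster_assign[s] = result.hard_assignment
        result.membership.to_csv(out / f"{s}_membership.tsv", sep="\t", float_format="%.6g")
        result.median_profile.to_csv(out / f"{s}_cluster_medians.tsv", sep="\t",
                                     float_format="%.6g")
        result.bias_label.to_csv(out / f"{s}_cluster_labels.tsv", sep="\t")
        record(f"cluster_{s}", k=k_val, m=round(m_val, 4), seed=seed_c,
               n_night=int((result.bias_label == "night").sum()))

    # ---- stage 5: network -------------------------------------------------
    networks: dict[str, network.GeneNetwork] = {}
    for s in species:
        genes = sorted(significant[s])
        seed_n = _stage_seed(config.seed, 50 + species.index(s))
        net = network.bootstrap_consensus(
            normalized[s].subset_genes(genes),
            n_boot=config.n_boot, p_value=config.mi_pvalue,
            dpi_tolerance=config.dpi_tolerance,
            consensus_alpha=config.consensus_alpha,
            seed=seed_n, n_null=config.n_null,
        )
        net.set_node_attributes(
            orthogroup=omap.orthogroup_of(net.nodes.index),
            cluster=cluster_assign[s],
        )
        networks[s] = net
        epath = out / f"{s}_edges.tsv"
        io.write_edges(net.edges, epath)
        io.write_sif(net.edges, out / f"{s}_edges.sif")
        net.nodes.to_csv(out / f"{s}_nodes.tsv", sep="\t")
        stats = network.network_stats(net)
        record(f"network_{s}", seed=seed_n, n_nodes=stats["n_nodes"],
               n_edges=stats["n_edges"],
               mean_degree=round(stats["mean_degree"], 3), output=str(epath))

    # ---- stage 6: cross-species comparison -------------------------------
    s_a, s_b = species[0], species[1] if len(species) > 1 else species[0]
    conn = {s: compare.orthogroup_connectivity(networks[s], omap) for s in species}
    comparison = compare.connectivity_zdiff(conn[s_a], conn[s_b], s_a, s_b)
    compare.flag_outliers(comparison, config.outlier_multiplier, config.outlier_rule)
    cpath = out / "connectivity_comparison.tsv"
    comparison.table.to_csv(cpath, sep="\t", float_format="%.6g")
    outliers = set(comparison.table.index[comparison.table["outlier"]])
    record("compare", n_shared=len(comparison.table), n_outliers=len(outliers),
           output=str(cpath))

    # ---- stage 7: diffusion + enrichment ----------------------------------
    universe = set(conn[s_a].index) | set(conn[s_b].index)
    seed_gene = config.seed_gene
    if seed_gene is None:
        deg_a = networks[s_a].degree()
        seed_gene = deg_a.sort_index().sort_values(ascending=False, kind="stable").index[0]
    focal_og = omap.orthogroup_of([seed_gene]).iloc[0]
    subnets = {}
    for s in species:
        net = networks[s]
        og_nodes = net.nodes.index[net.nodes["orthogroup"] == focal_og]
        if not len(og_nodes):
            logger.warning("%s: focal orthogroup %s absent from network", s, focal_og)
            continue
        deg = net.degree()
        focal = deg.loc[og_nodes].sort_index().sort_values(ascending=False, kind="stable").index[0]
        diff = compare.diffusion_subnetwork(
            net, focal, fraction=config.diffusion_fraction, time=config.diffusion_time)
        subnets[s] = diff
        dpath = out / f"{s}_diffusion.tsv"
        pd.DataFrame({"heat": diff.heat, "rank": diff.rank,
                      "selected": diff.heat.index.isin(list(diff.subnetwork_nodes))}
                     ).to_csv(dpath, sep="\t", float_format="%.6g")
        io.write_sif(diff.subnetwork_edges, out / f"{s}_diffusion.sif")
        record(f"diffuse_{s}", seed_gene=str(focal),
               n_subnetwork=len(diff.subnetwork_nodes), output=str(dpath))

    if len(subnets) == 2:
        ov = compare.subnetwork_overlap(
            subnets[s_a].subnetwork_nodes, subnets[s_b].subnetwork_nodes, omap, universe)
        record("overlap", shared=len(ov["shared"]),
               n_a=len(ov["orthogroups_a"]), n_b=len(ov["orthogroups_b"]),
               p=float(ov["p"]))

    if config.enrichment and go_map is not None:
        enr = compare.go_enrichment(outliers & universe, go_map, universe)
        epath = out / "outlier_go_enrichment.tsv"
        enr.to_csv(epath, sep="\t", float_format="%.6g")
        n_hits = int((enr["p_bh"] < 0.05).sum())
        record("enrich", n_terms=len(enr), n_significant=n_hits, output=str(epath))
        for s, diff in subnets.items():
            ogs = set(omap.orthogroup_of(sorted(diff.subnetwork_nodes)).dropna())
            enr_s = compare.go_enrichment(ogs & universe, go_map, universe)
            enr_s.to_csv(out / f"{s}_diffusion_go.tsv", sep="\t", float_format="%.6g")

    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete; manifest at %s", mpath)
    return manifest
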