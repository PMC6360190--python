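"""Two-species diel RNA-seq simulator with known ground truth.

Emulates the study design the package targets: two species sampled every 4 h
across a 12:12 photoperiod with 4 replicates per time point (24 samples per
species), negative-binomially distributed counts, a subset of genes with
smooth diel profiles, latent co-expression modules, planted differential
connectivity between species at the orthogroup level, and GO labels with
planted enrichment.

Model per gene g, sample j (species s):

    log mu_gj = a_g + b * cos(2*pi*(t_j - phi_g)/24) * [g structured]
                + lambda * F_{m(g)}(t_j) * [g in module m]
                + log(L_j)
    y_gj ~ NB(mean = exp(log mu_gj), size = theta)

where ``a_g`` is a baseline log-expression, ``phi_g`` a diel phase shared by
the orthogroup across species, ``F_m(t)`` a per-module smooth diel curve (a
random mix of the 24 h fundamental and its second harmonic, standardized to
unit variance over the samples and shared across species, as orthologous
pathway programs are), and ``L_j`` a log-normal library-size factor.

Co-expression modules are phase-synchronous: every orthogroup of a module
shares the module's diel phase (with small jitter), as genes of a common
diel-regulated pathway do. Ordinary module members carry additional private
log-normal noise. A differentially connected orthogroup acts as its module's
regulator in species A: it carries the module signal without private noise, so
its links to every member are the strongest edges of the module and survive
the data-processing-inequality pruning (the regulator-target topology DPI is
designed to retain), giving it a high network degree. In species B the same
orthogroup is a singleton with a private phase and no latent factor — its
expected degree collapses between species, while ordinary members stay
balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthogroupMap, ValidationError

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "dark_mask"]

SPECIES = ("speciesA", "speciesB")


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-species diel experiment.

    Defaults give 500 genes per species sampled at ZT 0,4,8,12,16,20 with 4
    replicates (24 samples per species), 40% time-structured genes, NB
    dispersion theta=10, 5 phase-synchronous modules of 8 orthogroups each,
    and 10% of module orthogroups planted as differentially connected.
    """

    n_genes: int = 500
    n_timepoints: int = 6
    replicate_count: int = 4
    period_hours: float = 24.0
    lights_on: float = 0.0
    lights_off: float = 12.0
    frac_time_structured: float = 0.4
    amplitude_logscale: float = 1.0
    dispersion: float = 10.0
    libsize_sigma: float = 0.1
    baseline_logmean: float = float(np.log(150.0))
    baseline_logsd: float = 0.5
    n_modules: int = 5
    module_size: int = 8          # orthogroups per module
    module_loading: float = 2.0   # module-curve loading (log scale)
    biological_noise: float = 0.6  # private log-noise sd (all genes except hubs)
    phase_jitter_hours: float = 0.5
    frac_diff_connected_orthogroups: float = 0.1  # fraction of module orthogroups
    copies_per_orthogroup_range: tuple[int, int] = (1, 3)
    n_go_terms: int = 50
    go_terms_per_orthogroup: tuple[int, int] = (1, 3)
    n_enriched_go_terms: int = 3
    go_enrichment_odds: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("NB dispersion theta must be > 0")
        for name in ("frac_time_structured", "frac_diff_connected_orthogroups"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.amplitude_logscale < 0 or self.libsize_sigma < 0:
            raise ValidationError("amplitude_logscale and libsize_sigma must be >= 0")
        lo, hi = self.copies_per_orthogroup_range
        if not (1 <= lo <= hi):
            raise ValidationError("copies_per_orthogroup_range must satisfy 1 <= lo <= hi")
        # every orthogroup contributes at least one gene, so modules cannot
        # require more genes than exist
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError(
                f"module_size x n_modules = {self.n_modules * self.module_size} "
                f"exceeds n_genes = {self.n_genes}"
            )

    @property
    def samples_per_species(self) -> int:
        return self.n_timepoints * self.replicate_count

    def zt_grid(self) -> np.ndarray:
        step = self.period_hours / self.n_timepoints
        return np.arange(self.n_timepoints) * step

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    time_structured_genes: set[str] = field(default_factory=set)
    gene_phase: dict[str, float] = field(default_factory=dict)
    gene_module: dict[str, dict[str, int]] = field(default_factory=dict)  # species -> gene -> module
    diff_connected_orthogroups: set[str] = field(default_factory=set)
    module_orthogroups: dict[int, list[str]] = field(default_factory=dict)
    enriched_go_terms: set[str] = field(default_factory=set)


def dark_mask(metadata: pd.DataFrame, lights_on: float = 0.0, lights_off: float = 12.0) -> np.ndarray:
    """Boolean dark flag per sample: dark iff ZT in [lights_off, 24).

    ZT (zeitgeber time) is hours since lights-on; the boundary ZT=lights_off
    belongs to the dark phase (half-open convention).
    """
    zt = np.asarray(metadata["zt"], dtype=float)
    if (zt < 0).any() or (zt >= 24).any():
        raise ValidationError("ZT values must lie in [0, 24)")
    return (zt >= lights_off) & (zt < 24.0)


def _build_orthogroups(cfg: SynthConfig, rng: np.random.Generator):
    """Assign orthogroups with per-species copy numbers summing to n_genes each."""
    lo, hi = cfg.copies_per_orthogroup_range
    per_species: dict[str, list[tuple[str, int]]] = {s: [] for s in SPECIES}
    orthogroups: list[str] = []
    totals = {s: 0 for s in SPECIES}
    i = 0
    while min(totals.values()) < cfg.n_genes:
        og = f"OG{i:05d}"
        orthogroups.append(og)
        for s in SPECIES:
            c = int(rng.integers(lo, hi + 1))
            c = min(c, cfg.n_genes - totals[s])  # trim the tail exactly
            if c > 0:
                per_species[s].append((og, c))
                totals[s] += c
        i += 1
    return orthogroups, per_species


def _gene_table(cfg, rng):
    """Gene IDs per species with their orthogroup, module, phase, baseline."""
    orthogroups, per_species = _build_orthogroups(cfg, rng)

    # modules over orthogroups present in both species
    common = [og for og in orthogroups
              if any(o == og for o, _ in per_species[SPECIES[0]])
              and any(o == og for o, _ in per_species[SPECIES[1]])]
    need = cfg.n_modules * cfg.module_size
    if len(common) < need:
        raise ValidationError(
            f"only {len(common)} orthogroups shared by both species; "
            f"modules need {need}"
        )
    chosen = rng.choice(len(common), size=need, replace=False)
    module_of_og: dict[str, int] = {}
    module_ogs: dict[int, list[str]] = {m: [] for m in range(cfg.n_modules)}
    for k, ci in enumerate(chosen):
        m = k // cfg.module_size
        og = common[ci]
        module_of_og[og] = m
        module_ogs[m].append(og)

    # planted orthogroups are module hubs, so at most one per module
    n_diff = min(int(round(cfg.frac_diff_connected_orthogroups * need)), cfg.n_modules)
    diff_modules = rng.choice(cfg.n_modules, size=n_diff, replace=False) if n_diff else []
    diff_ogs = set()
    hub_of_module: dict[int, str] = {}
    for m_id in diff_modules:
        ogs = module_ogs[m_id]
        hub = ogs[int(rng.integers(len(ogs)))]
        diff_ogs.add(hub)
        hub_of_module[m_id] = hub

    module_phase = rng.uniform(0.0, cfg.period_hours, size=cfg.n_modules)
    og_phase: dict[str, float] = {}
    for og in orthogroups:
        if og in module_of_og:
            jit = rng.normal(0.0, cfg.phase_jitter_hours)
            og_phase[og] = (module_phase[module_of_og[og]] + jit) % cfg.period_hours
        else:
            og_phase[og] = rng.uniform(0.0, cfg.period_hours)
    # a diff-connected orthogroup gets a private phase in species B
    diff_phase_b = {og: rng.uniform(0.0, cfg.period_hours) for og in sorted(diff_ogs)}

    tables = {}
    for s in SPECIES:
        rows = []
        for og, copies in per_species[s]:
            in_module = og in module_of_og
            detached = s == SPECIES[1] and og in diff_ogs
            is_hub = (in_module and not detached
                      and hub_of_module.get(module_of_og[og]) == og)
            for c in range(copies):
                gid = f"{s}_{og}_c{c}"
                rows.append({
                    "gene_id": gid,
                    "orthogroup": og,
                    "module": -1 if (not in_module or detached) else module_of_og[og],
                    "is_hub": is_hub,
                    "phase": diff_phase_b[og] if detached else og_phase[og],
                    "baseline": rng.normal(cfg.baseline_logmean, cfg.baseline_logsd),
                    "length": float(rng.integers(300, 3000)),
                })
        tables[s] = pd.DataFrame(rows).set_index("gene_id")
    return tables, module_ogs, diff_ogs


def _pick_structured(cfg, rng, table: pd.DataFrame) -> pd.Index:
    """Exactly round(frac * n_genes) genes, module genes first."""
    target = int(round(cfg.frac_time_structured * len(table)))
    module_genes = table.index[table["module"] >= 0]
    rest = table.index.difference(module_genes)
    if target <= len(module_genes):
        pick = rng.choice(len(module_genes), size=target, replace=False)
        return module_genes[np.sort(pick)]
    extra = target - len(module_genes)
    pick = rng.choice(len(rest), size=extra, replace=False)
    return module_genes.append(rest[np.sort(pick)])


def generate_dataset(config: SynthConfig):
    """Simulate the two-species diel experiment.

    Returns
    -------
    matrices : dict[str, ExpressionMatrix]
        Count matrix (with lengths and metadata) per species.
    omap : OrthogroupMap
        Transcript -> orthogroup map over both species' transcripts, with
        per-orthogroup reference length bounds.
    go_map : dict[str, set[str]]
        Orthogroup -> GO term labels.
    truth : GroundTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tables, module_ogs, diff_ogs = _gene_table(cfg, rng)

    zt_grid = cfg.zt_grid()
    zt = np.repeat(zt_grid, cfg.replicate_count)
    reps = np.tile(np.arange(cfg.replicate_count), cfg.n_timepoints)

    truth = GroundTruth(
        diff_connected_orthogroups=set(diff_ogs),
        module_orthogroups=module_ogs,
    )
    # per-module smooth diel curve, shared across species: random mix of the
    # fundamental and second harmonic, standardized over the samples
    w = 2 * np.pi / cfg.period_hours
    amp1 = rng.uniform(0.5, 1.0, size=cfg.n_modules)
    amp2 = rng.uniform(0.5, 1.0, size=cfg.n_modules)
    ph1 = rng.uniform(0.0, cfg.period_hours, size=cfg.n_modules)
    ph2 = rng.uniform(0.0, cfg.period_hours, size=cfg.n_modules)
    matrices: dict[str, ExpressionMatrix] = {}
    for s in SPECIES:
        table = tables[s]
        structured = _pick_structured(cfg, rng, table)
        truth.time_structured_genes |= set(structured)
        truth.gene_module[s] = {
            g: int(m) for g, m in table["module"].items() if m >= 0
        }
        for g in structured:
            truth.gene_phase[g] = float(table.at[g, "phase"])

        is_structured = table.index.isin(structured)
        phase = table["phase"].to_numpy()
        baseline = table["baseline"].to_numpy()
        module = table["module"].to_numpy()

        libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=zt.size))
        factors = (
            amp1[:, None] * np.cos(w * (zt[None, :] - ph1[:, None]))
            + amp2[:, None] * np.cos(2 * w * (zt[None, :] - ph2[:, None]))
        )
        if cfg.n_modules:
            factors = factors - factors.mean(axis=1, keepdims=True)
            sd = factors.std(axis=1, keepdims=True)
            factors = factors / np.where(sd > 0, sd, 1.0)

        diel = cfg.amplitude_logscale * np.cos(
            2 * np.pi * (zt[None, :] - phase[:, None]) / cfg.period_hours
        )
        in_mod = module >= 0
        # module genes follow the module curve instead of their own cosine
        logmu = baseline[:, None] + np.where(
            (is_structured & ~in_mod)[:, None], diel, 0.0)
        if in_mod.any():
            logmu[in_mod] += cfg.module_loading * factors[module[in_mod]]
        noisy = ~table["is_hub"].to_numpy()
        if noisy.any() and cfg.biological_noise > 0:
            logmu[noisy] += cfg.biological_noise * rng.normal(
                size=(int(noisy.sum()), zt.size))
        mean = np.exp(logmu) * libsize[None, :]
        theta = cfg.dispersion
        counts = rng.negative_binomial(theta, theta / (theta + mean))

        sample_ids = [f"{s}_ZT{int(z):02d}_r{r}" for z, r in zip(zt, reps)]
        meta = pd.DataFrame(
            {
                "species": s,
                "zt": zt,
                "replicate": [str(r) for r in reps],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        meta["dark"] = dark_mask(meta, cfg.lights_on, cfg.lights_off)
        values = pd.DataFrame(counts, index=table.index, columns=sample_ids)
        matrices[s] = ExpressionMatrix(
            values, metadata=meta, lengths=table["length"].rename("length"),
            unit="counts",
        )

    omap = _orthogroup_map(tables, rng)
    go_map, enriched = _go_labels(cfg, rng, tables, diff_ogs)
    truth.enriched_go_terms = enriched
    return matrices, omap, go_map, truth


def _orthogroup_map(tables, rng) -> OrthogroupMap:
    tr = pd.concat(
        [t[["orthogroup", "length"]] for t in tables.values()]
    )
    tr.index.name = "transcript"
    # reference bounds wide enough to retain simulated lengths by default
    by_og = tr.groupby("orthogroup")["length"]
    bounds = pd.DataFrame(
        {
            "min_ref_length": by_og.min() * rng.uniform(0.8, 1.0, size=by_og.ngroups),
            "max_ref_length": by_og.max() * rng.uniform(1.0, 1.3, size=by_og.ngroups),
        }
    )
    return OrthogroupMap(tr, bounds)


def _go_labels(cfg, rng, tables, diff_ogs):
    all_ogs = sorted(
        set().union(*(set(t["orthogroup"]) for t in tables.values()))
    )
    terms = [f"GO:{i:07d}" for i in range(cfg.n_go_terms)]
    n_enriched = min(cfg.n_enriched_go_terms, cfg.n_go_terms)
    enriched = set(terms[:n_enriched])
    background = terms[n_enriched:]
    lo, hi = cfg.go_terms_per_orthogroup
    # base probability for an enriched term on a background orthogroup; on a
    # diff-connected orthogroup the odds are go_enrichment_odds times larger
    p0 = 0.08
    odds0 = p0 / (1 - p0)
    p1 = (odds0 * cfg.go_enrichment_odds) / (1 + odds0 * cfg.go_enrichment_odds)
    go_map: dict[str, set[str]] = {}
    for og in all_ogs:
        labels = set()
        p = p1 if og in diff_ogs else p0
        for t in sorted(enriched):
            if rng.uniform() < p:
                labels.add(t)
        k = int(rng.integers(lo, hi + 1))
        if background:
            picks = rng.choice(len(background), size=min(k, len(background)), replace=False)
            labels |= {background[i] for i in picks}
        go_map[og] = labels
    return go_map, enriched
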