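"""Cross-species network comparison: orthogroup connectivity, Z-score
differences with Tukey-fence outlier calling, heat-diffusion subnetworks
around focal genes, and hypergeometric overlap / GO enrichment tests.

Connectivity of an orthogroup in one species is the mean degree of its
transcripts in that species' consensus network. Per species, connectivities
over the orthogroups shared by both networks are standardized to Z-scores and
subtracted; orthogroups whose Z-score difference falls outside the Tukey
fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR by default) are the differential-
connectivity outliers. Focal subnetworks spread unit heat from a seed gene by
the Laplacian heat kernel exp(-L t) on the unweighted consensus topology and
keep the hottest 10% of nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import EdgeList, OrthogroupMap, ValidationError
from .network import GeneNetwork

__all__ = [
    "ConnectivityComparison",
    "DiffusionResult",
    "orthogroup_connectivity",
    "connectivity_zdiff",
    "iqr_outliers",
    "diffuse",
    "diffusion_subnetwork",
    "hypergeom_test",
    "go_enrichment",
    "subnetwork_overlap",
]


def orthogroup_connectivity(
    network: GeneNetwork,
    omap: OrthogroupMap,
    ignore_unmapped: bool = False,
) -> pd.Series:
    """Mean node degree per orthogroup, over its nodes present in the network.

    Orthogroups with no node in the network are absent from the result.
    Unmapped nodes raise unless ``ignore_unmapped``.
    """
    deg = network.degree()
    og = omap.orthogroup_of(deg.index)
    unmapped = og.isna()
    if unmapped.any():
        bad = deg.index[unmapped].tolist()
        if not ignore_unmapped:
            raise ValidationError(f"network nodes without orthogroup: {bad[:5]}")
        warnings.warn(f"{len(bad)} unmapped nodes dropped from connectivity table")
        deg, og = deg[~unmapped], og[~unmapped]
    out = deg.groupby(og.to_numpy()).mean()
    out.index.name = "orthogroup"
    return out.rename("mean_degree")


@dataclass
class ConnectivityComparison:
    """Per-orthogroup connectivity Z-score difference between two species."""

    table: pd.DataFrame  # mean_degree_a/b, z_a, z_b, z_diff, outlier, direction
    species_a: str = "speciesA"
    species_b: str = "speciesB"


def connectivity_zdiff(
    table_a: pd.Series,
    table_b: pd.Series,
    species_a: str = "speciesA",
    species_b: str = "speciesB",
    include: str = "union",
) -> ConnectivityComparison:
    """Z-score each species' orthogroup connectivity and subtract:
    z_diff = z_b - z_a.

    ``include="union"`` (default) scores every orthogroup present in either
    network, entering mean degree 0 for the species where it has no edges — an
    orthogroup connected in one species only is the starkest form of
    differential connectivity. ``include="shared"`` restricts to orthogroups
    present in both networks.
    """
    if include == "union":
        idx = table_a.index.union(table_b.index)
    elif include == "shared":
        idx = table_a.index.intersection(table_b.index)
    else:
        raise ValidationError(f"unknown include mode {include!r}")
    if len(idx) < 3:
        raise ValidationError(f"only {len(idx)} comparable orthogroups; need >= 3")
    a = table_a.reindex(idx, fill_value=0.0).astype(float)
    b = table_b.reindex(idx, fill_value=0.0).astype(float)
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    if sa == 0 or sb == 0:
        raise ValidationError("degenerate network: zero connectivity variance")
    z_a = (a - a.mean()) / sa
    z_b = (b - b.mean()) / sb
    z_diff = z_b - z_a
    table = pd.DataFrame(
        {
            "mean_degree_a": a,
            "mean_degree_b": b,
            "z_a": z_a,
            "z_b": z_b,
            "z_diff": z_diff,
        }
    )
    table["outlier"] = False
    table["direction"] = np.where(
        z_diff > 0, f"higher_in_{species_b}", f"higher_in_{species_a}"
    )
    return ConnectivityComparison(table, species_a, species_b)


def iqr_outliers(
    z_diffs: pd.Series,
    multiplier: float = 1.5,
    rule: str = "tukey",
) -> set:
    """Outliers of a Z-difference vector.

    ``tukey`` (default): outside Q1 - multiplier*IQR or Q3 + multiplier*IQR,
    quartiles by linear interpolation (type 7). ``absolute``: |z| >
    multiplier * IQR. A zero IQR flags every non-median value, with a warning.
    """
    z = z_diffs.astype(float)
    if len(z) < 4:
        raise ValidationError("need at least 4 values for quartile fences")
    q1, q3 = np.quantile(z.to_numpy(), [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("IQR is zero; flagging every non-median value")
        med = float(np.median(z))
        return set(z.index[z != med])
    if rule == "tukey":
        out = (z > q3 + multiplier * iqr) | (z < q1 - multiplier * iqr)
    elif rule == "absolute":
        out = z.abs() > multiplier * iqr
    else:
        raise ValidationError(f"unknown outlier rule {rule!r}")
    return set(z.index[out])


def flag_outliers(
    comparison: ConnectivityComparison,
    multiplier: float = 1.5,
    rule: str = "tukey",
) -> ConnectivityComparison:
    out = iqr_outliers(comparison.table["z_diff"], multiplier, rule)
    comparison.table["outlier"] = comparison.table.index.isin(list(out))
    return comparison


# ---------------------------------------------------------------------------
# heat diffusion


def _laplacian(network: GeneNetwork) -> tuple[np.ndarray, pd.Index]:
    nodes = network.nodes.index
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    e = network.edges.edges
    ia = e["node_a"].map(pos).to_numpy()
    ib = e["node_b"].map(pos).to_numpy()
    A[ia, ib] = 1.0
    A[ib, ia] = 1.0
    L = np.diag(A.sum(axis=1)) - A
    return L, nodes


def diffuse(network: GeneNetwork, seed_node: str, time: float = 0.1) -> pd.Series:
    """Heat vector exp(-L t) e_seed on the unweighted consensus topology.

    The unnormalized Laplacian has zero row sums, so total heat is conserved
    at 1. Computed by symmetric eigendecomposition.
    """
    if time < 0:
        raise ValidationError("diffusion time must be >= 0")
    L, nodes = _laplacian(network)
    if seed_node not in set(nodes):
        raise ValidationError(f"seed node {seed_node!r} not in network")
    i0 = list(nodes).index(seed_node)
    if L[i0, i0] == 0:
        warnings.warn("isolated seed node: all heat stays on the seed")
    vals, vecs = np.linalg.eigh(L)
    h0 = np.zeros(len(nodes))
    h0[i0] = 1.0
    heat = vecs @ (np.exp(-vals * time) * (vecs.T @ h0))
    heat = np.maximum(heat, 0.0)
    return pd.Series(heat, index=nodes, name="heat")


@dataclass
class DiffusionResult:
    """Focal subnetwork of the hottest nodes around a seed gene."""

    seed_node: str
    heat: pd.Series
    rank: pd.Series
    subnetwork_nodes: set
    subnetwork_edges: EdgeList
    diffusion_time: float


def diffusion_subnetwork(
    network: GeneNetwork,
    seed_node: str,
    fraction: float = 0.10,
    time: float = 0.1,
) -> DiffusionResult:
    """Top ceil(fraction * n_nodes) nodes by heat (seed always included; heat
    ties broken lexicographically by node ID) plus their induced edges."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    heat = diffuse(network, seed_node, time)
    n_keep = int(np.ceil(fraction * network.n_nodes))
    order = pd.DataFrame({"heat": heat.to_numpy()}, index=heat.index)
    order = order.rename_axis("node").reset_index()
    order = order.sort_values(["heat", "node"], ascending=[False, True])
    rank = pd.Series(np.arange(1, len(order) + 1),
                     index=pd.Index(order["node"]), name="rank")
    selected = set(order["node"].iloc[:n_keep])
    selected.add(seed_node)
    e = network.edges.edges
    keep = e["node_a"].isin(selected) & e["node_b"].isin(selected)
    sub_edges = EdgeList(e.loc[keep].reset_index(drop=True))
    return DiffusionResult(
        seed_node=seed_node,
        heat=heat,
        rank=rank.reindex(heat.index),
        subnetwork_nodes=selected,
        subnetwork_edges=sub_edges,
        diffusion_time=time,
    )


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_test(k: int, K: int, n: int, N: int, alternative: str = "over") -> float:
    """Exact hypergeometric tail probability.

    ``k`` observed overlap, ``K`` size of set 1, ``n`` size of set 2 (draws),
    ``N`` universe size. ``over``: P(X >= k); ``under``: P(X <= k).
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise ValidationError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    xs = np.arange(0, min(K, n) + 1)
    pmf = hypergeom.pmf(xs, N, K, n)
    if alternative == "over":
        return float(pmf[xs >= k].sum())
    if alternative == "under":
        return float(pmf[xs <= k].sum())
    raise ValidationError(f"unknown alternative {alternative!r}")


def go_enrichment(
    target,
    go_map: dict[str, set[str]],
    universe,
    alternative: str = "over",
) -> pd.DataFrame:
    """One hypergeometric test per GO term present in the universe, BH-corrected.

    ``target`` and ``universe`` are orthogroup (or gene) ID collections with
    ``target`` a subset of ``universe``. Terms with zero overlap are still
    tested (p = 1 under over-representation unless the term covers nothing).
    """
    target = set(target)
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not target <= universe:
        raise ValidationError("target must be a subset of the universe")
    term_members: dict[str, set] = {}
    for og in universe:
        for term in go_map.get(og, ()):
            term_members.setdefault(term, set()).add(og)
    N, n = len(universe), len(target)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & target)
        p = hypergeom_test(k, K, n, N, alternative)
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        _, padj, _, _ = multipletests(df["p"], method="fdr_bh")
        df["p_bh"] = padj
    else:
        df["p_bh"] = []
    return df.set_index("term")


def subnetwork_overlap(
    sub_a: set,
    sub_b: set,
    omap: OrthogroupMap,
    universe: set,
    alternative: str = "under",
) -> dict:
    """Orthogroup content overlap of two focal subnetworks.

    Node sets are mapped to orthogroup sets; the overlap is tested against the
    hypergeometric null on the given orthogroup universe (under-enrichment by
    default, as when asking whether two subnetworks share fewer families than
    chance).
    """
    og_a = set(omap.orthogroup_of(sorted(sub_a)).dropna())
    og_b = set(omap.orthogroup_of(sorted(sub_b)).dropna())
    if not (og_a <= universe and og_b <= universe):
        raise ValidationError("subnetwork orthogroups must map into the universe")
    shared = og_a & og_b
    p = hypergeom_test(
        len(shared), len(og_a), len(og_b), len(universe), alternative=alternative
    )
    return {
        "orthogroups_a": og_a,
        "orthogroups_b": og_b,
        "shared": shared,
        "p": p,
    }
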