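"""Fuzzy c-means clustering of diel expression profiles.

Time-structured genes are standardized to Z-score profiles and clustered with
fuzzy c-means using the data-driven fuzzifier of Schwammle & Jensen (2010),
m(D, N) = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134),
where N is the number of genes and D the number of samples. The cluster count
k is chosen at the elbow of the within-group variance curve (the curve is
monotone decreasing in k, so its literal minimum is uninformative; the elbow
is the point of maximum distance to the chord joining the curve's endpoints).
Each cluster gets a median Z-score profile and a day/night bias label from the
dark-sample mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "estimate_fuzzifier",
    "zscore_profiles",
    "FuzzyCMeans",
    "fuzzy_cmeans",
    "select_k",
    "label_bias",
    "ClusterResult",
]


def estimate_fuzzifier(n_genes: int, n_samples: int) -> float:
    """Data-dimension fuzzifier estimate (always > 1)."""
    if n_genes < 2 or n_samples < 2:
        raise ValidationError("need at least 2 genes and 2 samples")
    N = float(n_genes)
    D = float(n_samples)
    return (
        1.0
        + (1418.0 / N + 22.05) * D ** -2
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


def zscore_profiles(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance genes are excluded with a warning.
    """
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 samples to standardize")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant genes excluded from Z-scoring"
        )
    keep = ~flat
    z = (arr[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=values.index[keep], columns=values.columns)


@dataclass
class ClusterResult:
    """Fuzzy clustering outcome on Z-score profiles."""

    membership: pd.DataFrame      # gene x k, rows sum to 1
    centers: pd.DataFrame         # k x sample
    hard_assignment: pd.Series    # argmax cluster per gene
    median_profile: pd.DataFrame  # k x sample, median Z-score of members
    bias_label: pd.Series | None  # "day" | "night" per cluster
    m: float
    k: int
    objective: float


def _kmeanspp_init(X, k, rng):
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[c] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[c]) ** 2, axis=1))
    return centers


class FuzzyCMeans:
    """Fuzzy c-means with seeded k-means++ initialization.

    Standard alternating updates: membership
    u_ic ∝ (1 / ||x_i − v_c||^2)^(1/(m−1)) normalized over clusters, centers
    v_c = Σ_i u_ic^m x_i / Σ_i u_ic^m, iterated until the largest center shift
    falls below ``tol``. Deterministic given ``random_state``; the best of
    ``n_init`` restarts (by final objective Σ u^m ||x − v||^2) is kept.

    Attributes after ``fit``: ``cluster_centers_``, ``membership_``,
    ``labels_``, ``objective_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 6, m: float = 1.09, tol: float = 1e-6,
                 max_iter: int = 500, n_init: int = 5, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_clusters", "m", "tol", "max_iter", "n_init", "random_state")}

    def set_params(self, **params) -> "FuzzyCMeans":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _memberships(self, X, centers):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        # log-domain for numerical stability as m -> 1+ (exponent blows up)
        logu = -np.log(d2) / (self.m - 1.0)
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        return u / u.sum(axis=1, keepdims=True)

    def _objective(self, X, u, centers):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return float(np.sum(u ** self.m * d2))

    def _single_run(self, X, rng):
        k = self.n_clusters
        centers = _kmeanspp_init(X, k, rng)
        prev_obj = np.inf
        for it in range(self.max_iter):
            u = self._memberships(X, centers)
            um = u ** self.m
            denom = um.sum(axis=0)
            empty = denom < 1e-12
            if empty.any():
                warnings.warn("empty effective cluster re-seeded")
                for c in np.where(empty)[0]:
                    centers[c] = X[rng.integers(X.shape[0])]
                u = self._memberships(X, centers)
                um = u ** self.m
                denom = um.sum(axis=0)
            new_centers = (um.T @ X) / denom[:, None]
            obj = self._objective(X, u, new_centers)
            # the FCM objective is non-increasing across alternating updates
            assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), \
                "fuzzy c-means objective increased"
            shift = np.max(np.abs(new_centers - centers))
            centers = new_centers
            prev_obj = obj
            if shift < self.tol:
                break
        u = self._memberships(X, centers)
        return centers, u, self._objective(X, u, centers), it + 1

    def fit(self, X, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if self.n_clusters < 2:
            raise ValidationError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValidationError("fuzzifier m must be > 1")
        if self.n_clusters > X.shape[0]:
            raise ValidationError(
                f"n_clusters = {self.n_clusters} exceeds n_genes = {X.shape[0]}"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers, u, obj, n_iter = self._single_run(X, rng)
            if best is None or obj < best[2]:
                best = (centers, u, obj, n_iter)
        self.cluster_centers_, self.membership_, self.objective_, self.n_iter_ = best
        self.labels_ = np.argmax(self.membership_, axis=1)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.argmax(self._memberships(X, self.cluster_centers_), axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    m: float,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 5,
) -> ClusterResult:
    """Cluster Z-score profiles; returns memberships, centers, medians."""
    model = FuzzyCMeans(
        n_clusters=k, m=m, tol=tol, max_iter=max_iter,
        n_init=n_init, random_state=seed,
    ).fit(profiles.to_numpy(dtype=float))
    membership = pd.DataFrame(
        model.membership_, index=profiles.index,
        columns=[f"cluster{c}" for c in range(k)],
    )
    centers = pd.DataFrame(
        model.cluster_centers_, columns=profiles.columns,
        index=membership.columns,
    )
    hard = pd.Series(model.labels_, index=profiles.index, name="cluster")
    med = np.full((k, profiles.shape[1]), np.nan)
    arr = profiles.to_numpy(dtype=float)
    for c in range(k):
        members = model.labels_ == c
        if members.any():
            med[c] = np.median(arr[members], axis=0)
        else:
            med[c] = model.cluster_centers_[c]
    median_profile = pd.DataFrame(med, columns=profiles.columns, index=membership.columns)
    return ClusterResult(
        membership=membership, centers=centers, hard_assignment=hard,
        median_profile=median_profile, bias_label=None,
        m=m, k=k, objective=model.objective_,
    )


def within_group_variance(profiles: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """W(k) = sum_i ||x_i - v_hard(i)||^2."""
    return float(np.sum((profiles - centers[labels]) ** 2))


def select_k(
    profiles: pd.DataFrame,
    m: float,
    k_range=range(2, 13),
    seed: int = 0,
    n_init: int = 5,
) -> tuple[int, pd.Series]:
    """Pick k at the elbow of the within-group variance curve.

    The elbow is the k whose point on the W(k) curve lies farthest from the
    chord joining (k_min, W(k_min)) and (k_max, W(k_max)). A single-element
    k_range is returned as-is.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValidationError("empty k_range")
    X = profiles.to_numpy(dtype=float)
    W = []
    for k in ks:
        model = FuzzyCMeans(n_clusters=k, m=m, n_init=n_init, random_state=seed).fit(X)
        W.append(within_group_variance(X, model.labels_, model.cluster_centers_))
    curve = pd.Series(W, index=pd.Index(ks, name="k"), name="within_group_variance")
    if len(ks) == 1:
        return ks[0], curve
    # max distance to chord, on a normalized scale so k and W are comparable
    x = (np.asarray(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    w = np.asarray(W)
    span = w[0] - w[-1]
    y = (w - w[-1]) / span if span > 0 else np.zeros_like(w)
    chord = 1.0 - x  # line from (0, 1) to (1, 0)
    best = int(np.argmax(chord - y))  # farthest below the chord
    return ks[best], curve


def label_bias(result: ClusterResult, dark: np.ndarray) -> pd.Series:
    """Label each cluster day or night by its median profile.

    Night iff the mean of the cluster's median Z-profile over dark samples
    exceeds its mean over light samples; exact ties go to day with a warning.
    """
    dark = np.asarray(dark, dtype=bool)
    if dark.size != result.median_profile.shape[1]:
        raise ValidationError("dark mask must cover every sample")
    if dark.all() or (~dark).all():
        raise ValidationError("dark mask needs both light and dark samples")
    med = result.median_profile.to_numpy(dtype=float)
    dark_mean = med[:, dark].mean(axis=1)
    light_mean = med[:, ~dark].mean(axis=1)
    labels = np.where(dark_mean > light_mean, "night", "day")
    if (dark_mean == light_mean).any():
        warnings.warn("tied day/night means labeled 'day'")
    out = pd.Series(labels, index=result.median_profile.index, name="bias_label")
    result.bias_label = out
    return out
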