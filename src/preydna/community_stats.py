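"""Whole-diet comparisons on presence/absence data.

Presence/absence Bray-Curtis (= Sorensen) dissimilarity, one-way
PERMANOVA, multivariate dispersion homogeneity, sample-based rarefaction
(both the randomized accumulation ensemble and its hypergeometric closed
form), and the assemblage randomization test that compares group-specific
accumulation curves to the pooled curve via between-curve areas.

All stochastic routines take a seed (or Generator) and are bit-reproducible;
permutation p-values use the add-one estimator and never report 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_model import PresenceMatrix, PreyDnaError

__all__ = [
    "DistanceMatrix", "PermTestResult", "AccumulationEnsemble",
    "bray_curtis_presence", "pairwise_distances", "mean_dissimilarity",
    "permanova", "dispersion_homogeneity", "accumulation_ensemble",
    "rarefaction_expected", "assemblage_ecotest",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among specimens with group labels."""

    values: pd.DataFrame
    groups: "pd.Series[str]"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise PreyDnaError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise PreyDnaError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise PreyDnaError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise PreyDnaError("distances must be non-negative")
        missing = [s for s in self.values.index if s not in self.groups.index]
        if missing:
            raise PreyDnaError(f"specimens without group label: {missing}")

    @property
    def specimens(self) -> list[str]:
        return list(self.values.index)

    def group_labels(self) -> np.ndarray:
        return self.groups.loc[self.specimens].to_numpy()


@dataclass
class PermTestResult:
    statistic: float
    effect_size: float | None
    p: float
    n_permutations: int
    seed: int | None
    df: tuple[int, int] | None = None
    p_parametric: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise PreyDnaError("permutation p must lie in (0, 1]")


@dataclass
class AccumulationEnsemble:
    """Cumulative richness over R random sample orderings of one group."""

    curves: np.ndarray       # shape (R, n_samples)
    mean_curve: np.ndarray   # shape (n_samples,)
    group: str | None
    R: int

    def __post_init__(self) -> None:
        if (np.diff(self.curves, axis=1) < 0).any():
            raise PreyDnaError("accumulation curves must be non-decreasing")


def bray_curtis_presence(a, b) -> float:
    """(A + B - 2J)/(A + B) on binary vectors: A, B are per-diet richness,
    J the shared richness.  Undefined (error) when both diets are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise PreyDnaError("vectors must have equal length")
    A, B = int(a.sum()), int(b.sum())
    if A + B == 0:
        raise PreyDnaError("dissimilarity undefined for two empty diets")
    J = int((a & b).sum())
    return (A + B - 2 * J) / (A + B)


def pairwise_distances(pm: PresenceMatrix) -> DistanceMatrix:
    """All pairwise presence/absence Bray-Curtis distances among specimens."""
    X = pm.values.to_numpy(dtype=np.int64).T  # specimens x taxa
    richness = X.sum(axis=1)
    if (richness == 0).any():
        raise PreyDnaError("presence matrix contains empty specimens")
    J = X @ X.T
    denom = richness[:, None] + richness[None, :]
    d = (denom - 2 * J) / denom
    np.fill_diagonal(d, 0.0)
    sex = pm.sex.loc[pm.specimens].astype(str)
    return DistanceMatrix(
        values=pd.DataFrame(d, index=pm.specimens, columns=pm.specimens),
        groups=sex,
    )


def _bca_interval(theta: float, boots: np.ndarray, jack: np.ndarray,
                  alpha: float) -> tuple[float, float]:
    # shared BCa arithmetic: z0 from bootstrap, acceleration from jackknife
    B = boots.size
    prop = np.clip(np.mean(boots < theta), 1 / (B + 1), 1 - 1 / (B + 1))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    denom = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = float(((jm - jack) ** 3).sum() / denom) if denom > 0 else 0.0
    z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [a1, a2])
    return float(lo), float(hi)


def mean_dissimilarity(
    D: DistanceMatrix,
    B: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Mean of the upper triangle with a BCa bootstrap CI.

    The resampling unit is the specimen, not the pair: each bootstrap
    replicate draws specimens with replacement and averages the distances
    among the resampled set (duplicates contribute zero distances).
    """
    d = D.values.to_numpy(dtype=float)
    n = d.shape[0]
    if n < 2:
        raise PreyDnaError("need at least two specimens")
    iu = np.triu_indices(n, k=1)
    theta = float(d[iu].mean())
    if np.ptp(d[iu]) == 0:
        return theta, (theta, theta)
    rng = np.random.default_rng(rng)

    def stat(idx: np.ndarray) -> float:
        sub = d[np.ix_(idx, idx)]
        m = idx.size
        return float(sub[np.triu_indices(m, k=1)].mean())

    boots = np.array(
        [stat(rng.integers(0, n, size=n)) for _ in range(B)], dtype=float
    )
    jack = np.array(
        [stat(np.delete(np.arange(n), i)) for i in range(n)], dtype=float
    )
    return theta, _bca_interval(theta, boots, jack, alpha)


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise PreyDnaError("need at least two groups")
    small = uniq[counts < min_size]
    if small.size:
        raise PreyDnaError(
            f"groups smaller than {min_size}: {small.tolist()}"
        )


def _ss_within(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    ssw = 0.0
    for idx in idx_groups:
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(
    D: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermTestResult:
    """One-way PERMANOVA from the squared-distance decomposition.

    F = (SS_between/(g-1)) / (SS_within/(n-g)); p from free permutation of
    the group labels with the add-one estimator; R^2 = SS_between/SS_total.
    """
    labels = D.group_labels()
    _check_groups(labels)
    d2 = D.values.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    g = len(np.unique(labels))
    ss_total = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, _group_indices(labels))
    ssb = ss_total - ssw
    f_obs = (ssb / (g - 1)) / (ssw / (n - g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssw_p = _ss_within(d2, _group_indices(perm))
        f_p = ((ss_total - ssw_p) / (g - 1)) / (ssw_p / (n - g))
        if f_p >= f_obs:
            count += 1
    return PermTestResult(
        statistic=float(f_obs),
        effect_size=float(ssb / ss_total),
        p=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        df=(g - 1, n - g),
    )


def _pcoa_axes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of a (possibly non-Euclidean) distance
    matrix, split into real (positive-eigenvalue) and imaginary
    (negative-eigenvalue) coordinate blocks."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ a @ centering
    vals, vecs = np.linalg.eigh((gower + gower.T) / 2.0)
    tol = max(abs(vals).max(), 1.0) * 1e-10
    pos = vals > tol
    neg = vals < -tol
    real_axes = vecs[:, pos] * np.sqrt(vals[pos])
    imag_axes = vecs[:, neg] * np.sqrt(-vals[neg])
    return real_axes, imag_axes


def _centroid_distances(real_axes: np.ndarray, imag_axes: np.ndarray,
                        labels: np.ndarray) -> np.ndarray:
    out = np.empty(len(labels))
    for idx in _group_indices(labels):
        cr = real_axes[idx].mean(axis=0)
        ci = imag_axes[idx].mean(axis=0) if imag_axes.size else None
        d2 = ((real_axes[idx] - cr) ** 2).sum(axis=1)
        if ci is not None:
            # imaginary-axis contribution is subtracted, floored at 0
            d2 = d2 - ((imag_axes[idx] - ci) ** 2).sum(axis=1)
        out[idx] = np.sqrt(np.maximum(d2, 0.0))
    return out


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ssb = ssw = 0.0
    for idx in _group_indices(labels):
        gm = values[idx].mean()
        ssb += idx.size * (gm - grand) ** 2
        ssw += ((values[idx] - gm) ** 2).sum()
    g = len(np.unique(labels))
    n = values.size
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (g - 1)) / (ssw / (n - g))


def dispersion_homogeneity(
    D: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Homogeneity of multivariate dispersions: one-way F on distances to
    group centroids in principal-coordinate space.

    Negative-eigenvalue axes (expected: presence/absence Bray-Curtis is
    non-Euclidean) contribute negatively to the squared distance, floored
    at 0.  Both the parametric F p-value and the label-permutation p-value
    are reported.
    """
    labels = D.group_labels()
    _check_groups(labels)
    real_axes, imag_axes = _pcoa_axes(D.values.to_numpy(dtype=float))
    dists = _centroid_distances(real_axes, imag_axes, labels)
    f_obs = _anova_f(dists, labels)
    g = len(np.unique(labels))
    n = len(labels)
    p_param = float(stats.f.sf(f_obs, g - 1, n - g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_p = _anova_f(_centroid_distances(real_axes, imag_axes, perm), perm)
        if f_p >= f_obs:
            count += 1
    return PermTestResult(
        statistic=float(f_obs),
        effect_size=None,
        p=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        df=(g - 1, n - g),
        p_parametric=p_param,
    )


def _binary_matrix(pm: PresenceMatrix, group: str | None) -> np.ndarray:
    cols = pm.specimens
    if group is not None:
        sex = pm.sex.loc[cols]
        cols = [c for c in cols if sex[c] == group]
        if not cols:
            raise PreyDnaError(f"no specimens in group {group!r}")
    return pm.values[cols].to_numpy(dtype=bool)


def accumulation_ensemble(
    pm: PresenceMatrix,
    group: str | None = None,
    R: int = 1000,
    seed: int | None = None,
) -> AccumulationEnsemble:
    """Cumulative richness across samples for R uniformly random orderings."""
    X = _binary_matrix(pm, group)
    n = X.shape[1]
    rng = np.random.default_rng(seed)
    curves = np.empty((R, n), dtype=np.int64)
    for r in range(R):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(X[:, order], axis=1)
        curves[r] = seen.sum(axis=0)
    return AccumulationEnsemble(
        curves=curves,
        mean_curve=curves.mean(axis=0),
        group=group,
        R=R,
    )


def _log_comb(a: np.ndarray, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _expected_curve(incidence: np.ndarray, n: int,
                    m: np.ndarray) -> np.ndarray:
    """E[S(m)] = sum_i 1 - C(n - n_i, m)/C(n, m) (sample-based rarefaction)."""
    m = np.asarray(m)
    out = np.empty(m.shape, dtype=float)
    log_cn = _log_comb(np.array([n]), m)  # log C(n, m), per m
    for j, mj in np.ndenumerate(m):
        ok = (n - incidence) >= mj
        terms = np.zeros(incidence.shape)
        if ok.any():
            terms[ok] = np.exp(
                _log_comb(n - incidence[ok], mj) - log_cn[j]
            )
        out[j] = float((1.0 - terms).sum())
    return out


def rarefaction_expected(pm: PresenceMatrix | np.ndarray, m):
    """Closed-form expected richness after drawing m of the n samples
    without replacement (the mean of the accumulation ensemble)."""
    X = (pm.values.to_numpy(dtype=bool) if isinstance(pm, PresenceMatrix)
         else np.asarray(pm).astype(bool))
    n = X.shape[1]
    scalar = np.isscalar(m)
    m_arr = np.atleast_1d(np.asarray(m, dtype=int))
    if (m_arr < 0).any() or (m_arr > n).any():
        raise PreyDnaError(f"m must lie in [0, {n}]")
    incidence = X.sum(axis=1)
    out = _expected_curve(incidence, n, m_arr)
    return float(out[0]) if scalar else out


def assemblage_ecotest(
    pm: PresenceMatrix,
    iterations: int = 200,
    seed: int | None = None,
) -> PermTestResult:
    """Randomization test of whether group diets draw on one assemblage.

    Statistic: sum over groups of the absolute area between the group's
    expected accumulation curve and the pooled curve, both from the
    rarefaction closed form, evaluated at m = 1..n_group.  Null: specimens
    reassigned to groups of the same sizes.
    """
    labels = pm.sex.loc[pm.specimens].to_numpy()
    _check_groups(labels)
    X = pm.values.to_numpy(dtype=bool)
    n = X.shape[1]
    pooled_inc = X.sum(axis=1)
    max_m = int(max(idx.size for idx in _group_indices(labels)))
    pooled_curve = _expected_curve(pooled_inc, n, np.arange(1, max_m + 1))

    def area(lbls: np.ndarray) -> float:
        z = 0.0
        for idx in _group_indices(lbls):
            ng = idx.size
            inc = X[:, idx].sum(axis=1)
            curve = _expected_curve(inc, ng, np.arange(1, ng + 1))
            z += float(np.abs(curve - pooled_curve[:ng]).sum())
        return z

    z_obs = area(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(iterations):
        if area(rng.permutation(labels)) >= z_obs:
            count += 1
    return PermTestResult(
        statistic=float(z_obs),
        effect_size=None,
        p=(count + 1) / (iterations + 1),
        n_permutations=iterations,
        seed=seed,
    )
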