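"""Per-taxon diet description and sex comparison.

Prevalences with exact Clopper-Pearson intervals, two-sided Fisher tests
with Holm-Bonferroni control, order-level prevalence with informal CI
overlap, per-sample richness with a tie-corrected Mann-Whitney test, and
BCa bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PresenceMatrix, PreyDnaError, TaxonomyTable

__all__ = [
    "clopper_pearson", "fisher_exact_2x2", "holm_bonferroni",
    "PrevalenceRecord", "prevalence_table", "order_prevalence",
    "orders_from_taxonomy", "richness_per_sample", "mann_whitney",
    "bca_bootstrap_ci", "format_proportion",
]


def clopper_pearson(k: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (Beta quantiles).

    lo is exactly 0 when k = 0 and hi exactly 1 when k = n.  Values are
    returned at full precision; rounding happens only at report time.
    """
    if not 0 <= k <= n or n < 1:
        raise PreyDnaError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise PreyDnaError("alpha must be in (0, 1)")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def format_proportion(x: float, decimals: int = 3) -> str:
    """Round to ``decimals`` places and trim trailing zeros
    ('0.49', not '0.490')."""
    s = f"{round(x, decimals):.{decimals}f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


# Relative slack when comparing hypergeometric point probabilities, so the
# minimum-likelihood rule is robust to floating-point noise at ties.
_FISHER_TOL = 1.0 + 1e-7


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, minimum-likelihood rule.

    Sums the hypergeometric probabilities (margins fixed) of every table
    whose point probability does not exceed that of the observed table.
    A zero margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise PreyDnaError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise PreyDnaError("table entries must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise PreyDnaError("table entries must be non-negative")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1, c2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("2x2 table has a zero margin; p = 1", stacklevel=2)
        return 1.0
    n = r1 + r2
    k_obs = int(t[0, 0])
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(k_obs, n, r1, c1)
    p = float(pmf[pmf <= p_obs * _FISHER_TOL].sum())
    return min(p, 1.0)


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment; monotone, capped at 1, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise PreyDnaError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        val = min(1.0, (m - i) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj.tolist()


@dataclass
class PrevalenceRecord:
    """One taxon's (or order's) prevalence summary and sex comparison."""

    taxon: str
    k_overall: int
    n_overall: int
    k_female: int
    n_female: int
    k_male: int
    n_male: int
    prevalence: dict[str, float]
    ci: dict[str, tuple[float, float]]
    fisher_p: float | None = None
    holm_p: float | None = None
    order: str | None = None

    def __post_init__(self) -> None:
        for k, n in ((self.k_overall, self.n_overall),
                     (self.k_female, self.n_female),
                     (self.k_male, self.n_male)):
            if k > n:
                raise PreyDnaError(f"k={k} exceeds n={n}")


def _sex_detection_counts(pm: PresenceMatrix) -> pd.DataFrame:
    sex = pm.sex.loc[pm.specimens]
    f_cols = sex.index[sex == "female"]
    m_cols = sex.index[sex == "male"]
    return pd.DataFrame({
        "k_female": pm.values[list(f_cols)].sum(axis=1),
        "k_male": pm.values[list(m_cols)].sum(axis=1),
    })


def prevalence_table(
    pm: PresenceMatrix,
    denominators: tuple[int, int, int] | None = None,
    top: int | None = None,
    alpha: float = 0.05,
    orders: Mapping[str, str] | None = None,
) -> list[PrevalenceRecord]:
    """Per-taxon prevalence records, highest overall prevalence first.

    ``denominators`` are (n_overall, n_female, n_male); the default is the
    analyzed-sample count (specimens with >= 1 detection, i.e. the columns
    of the presence matrix).  A study may instead supply the collected
    counts when that is the convention of its summary tables.

    If ``top`` is given, Fisher tests are run for the ``top`` most
    prevalent taxa and Holm-adjusted within that family.
    """
    counts = _sex_detection_counts(pm)
    sex = pm.sex.loc[pm.specimens]
    nf_obs = int((sex == "female").sum())
    nm_obs = int((sex == "male").sum())
    if denominators is None:
        n_all, nf, nm = nf_obs + nm_obs, nf_obs, nm_obs
    else:
        n_all, nf, nm = denominators
        if nf < nf_obs or nm < nm_obs:
            raise PreyDnaError(
                "denominators smaller than observed group sizes"
            )
    records: list[PrevalenceRecord] = []
    for taxon in pm.taxa:
        kf = int(counts.at[taxon, "k_female"])
        km = int(counts.at[taxon, "k_male"])
        k = kf + km
        records.append(PrevalenceRecord(
            taxon=taxon,
            k_overall=k, n_overall=n_all,
            k_female=kf, n_female=nf,
            k_male=km, n_male=nm,
            prevalence={"overall": k / n_all, "female": kf / nf,
                        "male": km / nm},
            ci={"overall": clopper_pearson(k, n_all, alpha),
                "female": clopper_pearson(kf, nf, alpha),
                "male": clopper_pearson(km, nm, alpha)},
            order=None if orders is None else orders.get(taxon),
        ))
    records.sort(key=lambda r: (-r.prevalence["overall"], r.taxon))
    if top is not None:
        tested = records[:top]
        ps = []
        for r in tested:
            r.fisher_p = fisher_exact_2x2(
                [[r.k_female, r.n_female - r.k_female],
                 [r.k_male, r.n_male - r.k_male]]
            )
            ps.append(r.fisher_p)
        for r, hp in zip(tested, holm_bonferroni(ps)):
            r.holm_p = hp
    return records


def records_to_frame(records: Sequence[PrevalenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"taxon": r.taxon, "order": r.order}
        for g in ("overall", "female", "male"):
            row[f"k_{g}"] = getattr(r, f"k_{g}")
            row[f"n_{g}"] = getattr(r, f"n_{g}")
            row[f"prevalence_{g}"] = format_proportion(r.prevalence[g])
            lo, hi = r.ci[g]
            row[f"ci_{g}"] = (f"{format_proportion(lo)}-"
                              f"{format_proportion(hi)}")
        row["fisher_p"] = r.fisher_p
        row["holm_p"] = r.holm_p
        rows.append(row)
    return pd.DataFrame(rows)


def orders_from_taxonomy(taxon_keys: Sequence[str],
                         tax: TaxonomyTable) -> dict[str, str]:
    """Map resolved-taxon row keys ('rank:label') to order labels by
    looking up any ASV carrying that label at that rank."""
    out: dict[str, str] = {}
    t = tax.table
    for key in taxon_keys:
        rank, _, label = key.partition(":")
        if rank == "order":
            out[key] = label
            continue
        hits = t.index[t[f"{rank}_label"] == label]
        if len(hits):
            out[key] = str(t.at[hits[0], "order_label"])
    return out


def order_prevalence(
    pm: PresenceMatrix,
    orders: Mapping[str, str],
    denominators: tuple[int, int, int] | None = None,
    alpha: float = 0.05,
) -> tuple[list[PrevalenceRecord], pd.DataFrame]:
    """Aggregate presence to taxonomic orders and flag CI overlap.

    A specimen counts once per order however many member taxa are present.
    Returns the per-order records plus a long DataFrame with one row per
    (order pair, group) and a boolean ``ci_overlap`` column — the informal
    comparison rule.
    """
    missing = [t for t in pm.taxa if t not in orders]
    if missing:
        raise PreyDnaError(f"taxa without an order label: {missing}")
    order_index = sorted(set(orders[t] for t in pm.taxa))
    collapsed = pd.DataFrame(
        np.zeros((len(order_index), len(pm.specimens)), dtype="int8"),
        index=order_index, columns=pm.specimens,
    )
    for t in pm.taxa:
        collapsed.loc[orders[t]] |= pm.values.loc[t]
    agg = PresenceMatrix(values=collapsed, sex=pm.sex)
    records = prevalence_table(agg, denominators=denominators, alpha=alpha)
    rows = []
    by_name = {r.taxon: r for r in records}
    names = [r.taxon for r in records]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for g in ("overall", "female", "male"):
                lo1, hi1 = by_name[a].ci[g]
                lo2, hi2 = by_name[b].ci[g]
                rows.append({
                    "order_a": a, "order_b": b, "group": g,
                    "ci_overlap": not (hi1 < lo2 or hi2 < lo1),
                })
    return records, pd.DataFrame(rows)


def richness_per_sample(pm: PresenceMatrix) -> "pd.Series[int]":
    """Number of detected taxa per specimen (column sums)."""
    return pm.values.sum(axis=0).astype(int)


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U via the tie-corrected normal approximation
    (no continuity correction).  Returns (U, Z, p) with U for the first
    sample.  Exact enumeration is deliberately left to tests."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise PreyDnaError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return u1, float(z), min(p, 1.0)


def bca_bootstrap_ci(
    values,
    statistic: Callable[[np.ndarray], float] = np.mean,
    B: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    z0 comes from the fraction of bootstrap replicates below the observed
    statistic; the acceleration a from jackknife skewness.  Constant input
    returns a zero-width interval at the constant.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise PreyDnaError("need at least two values")
    if B < 1:
        raise PreyDnaError("B must be positive")
    if np.ptp(v) == 0:
        c = float(statistic(v))
        return c, c
    rng = np.random.default_rng(rng)
    n = v.size
    theta = float(statistic(v))
    idx = rng.integers(0, n, size=(B, n))
    boots = np.array([statistic(v[row]) for row in idx], dtype=float)
    prop = np.clip(np.mean(boots < theta), 1 / (B + 1), 1 - 1 / (B + 1))
    z0 = stats.norm.ppf(prop)
    jack = np.array(
        [statistic(np.delete(v, i)) for i in range(n)], dtype=float
    )
    jm = jack.mean()
    denom = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = float(((jm - jack) ** 3).sum() / denom) if denom > 0 else 0.0
    z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [a1, a2])
    return float(lo), float(hi)
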