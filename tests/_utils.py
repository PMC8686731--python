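"""Shared helpers for the test suite (imported by test modules)."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from preydna.data_model import PresenceMatrix, Role, SampleMeta, Sex


def make_pm(arr, sexes, taxa=None, columns=None) -> PresenceMatrix:
    """Build a PresenceMatrix from a binary array and per-column sexes."""
    arr = np.asarray(arr, dtype="int8")
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    columns = columns or [f"s{i}" for i in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=taxa, columns=columns)
    sex = pd.Series(list(sexes), index=columns, dtype=object)
    return PresenceMatrix(values=values, sex=sex)


def make_meta(sample_roles, primer_set="Leray", replicate=1):
    """sample_roles: list of (sample_id, role, sex) strings."""
    return [
        SampleMeta(sample_id=s, role=Role(r), sex=Sex(x),
                   primer_set=primer_set, replicate=replicate)
        for s, r, x in sample_roles
    ]


def fisher_oracle(table) -> float:
    """Exact-rational enumeration of the two-sided Fisher p
    (minimum-likelihood rule); independent of the implementation."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
           for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def mann_whitney_exact_p(x, y) -> float:
    """Exact permutation enumeration of the two-sided Mann-Whitney p
    (deviation of U from its mean)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dev = abs(u_obs - mu)
    hits = total = 0
    for c in combinations(range(len(pooled)), n1):
        u = ranks[list(c)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mu) >= dev - 1e-9
        total += 1
    return hits / total


def anova_f_on_coords(X, labels) -> float:
    """Classical one-way (M)ANOVA F summed over coordinates; the algebraic
    oracle for PERMANOVA on Euclidean distances."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for g in groups:
        sub = X[labels == g]
        ssb += len(sub) * ((sub.mean(axis=0) - grand) ** 2).sum()
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    n, g = len(X), len(groups)
    return (ssb / (g - 1)) / (ssw / (n - g))
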