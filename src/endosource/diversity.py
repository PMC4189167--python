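"""Sørensen similarity and small-sample rank-sum comparison.

Communities are presence sets of (dye, integer size) categories derived
from the >=2-trial presence rule.  Sørensen's index QS = 2c/(S1+S2)
where S1, S2 are the community sizes and c the number of shared
categories.  Group contrasts (e.g. same-tissue-across-genotypes vs
cross-tissue-within-genotype QS values) use a Mann-Whitney rank-sum
test, exact by enumeration for small combined sample sizes.
"""
from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import SampleProfile


def presence_set(profile: SampleProfile | Iterable, dyes=None) -> frozenset:
    """Presence set of a profile (or pass any iterable of categories through)."""
    if isinstance(profile, SampleProfile):
        return profile.present_set(dyes=dyes)
    return frozenset(profile)


def sorensen(a: Iterable, b: Iterable) -> float:
    """Sørensen similarity QS = 2c / (S1 + S2) between two presence sets.

    Symmetric, in [0, 1].  Undefined (raises) when both sets are empty.
    """
    sa, sb = frozenset(a), frozenset(b)
    if not sa and not sb:
        raise ValueError("Sørensen similarity is undefined for two empty communities")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def jaccard(a: Iterable, b: Iterable) -> float:
    """Optional Jaccard helper: |A∩B| / |A∪B|."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa and not sb:
        raise ValueError("Jaccard similarity is undefined for two empty communities")
    return len(sa & sb) / len(sa | sb)


def pairwise_qs(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Symmetric QS matrix over labelled presence sets.

    Rows/columns follow the mapping's key order.  Pairs involving an
    empty set get NaN (and a warning); the diagonal is 1 for non-empty
    sets.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least two profiles")
    frozen = {k: frozenset(v) for k, v in sets.items()}
    empties = [k for k, v in frozen.items() if not v]
    if empties:
        warnings.warn(f"empty profile(s) {empties}: QS undefined, rows flagged NaN",
                      stacklevel=2)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, ki in enumerate(labels):
        for kj in labels[i:]:
            if not frozen[ki] or not frozen[kj]:
                continue  # flagged NaN
            mat.loc[ki, kj] = mat.loc[kj, ki] = sorensen(frozen[ki], frozen[kj])
    return mat


class RankSumResult(NamedTuple):
    statistic: float  # Mann-Whitney U for the first group
    pvalue: float
    method: str  # "exact" | "asymptotic"


def rank_sum_test(
    group_x: Iterable[float], group_y: Iterable[float], exact_max_n: int = 20
) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test.

    For combined sample size <= ``exact_max_n`` the p-value is exact,
    by full enumeration of rank assignments on the midranks (which
    handles ties as a permutation test on U); above that the normal
    approximation with tie correction is used.  If every value in both
    groups is identical the test is degenerate and p = 1 is returned
    with a warning.
    """
    x = np.asarray(list(group_x), dtype=float)
    y = np.asarray(list(group_y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs at least one value")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if np.all(combined == combined[0]):
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return RankSumResult(statistic=u1, pvalue=1.0, method="degenerate")

    n = n1 + n2
    if n <= exact_max_n:
        center = n1 * n2 / 2.0
        obs_dev = abs(u1 - center)
        total = math.comb(n, n1)
        hits = 0
        base = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n), n1):
            u = ranks[list(idx)].sum() - base
            if abs(u - center) >= obs_dev - 1e-12:
                hits += 1
        return RankSumResult(statistic=u1, pvalue=hits / total, method="exact")

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                         method="asymptotic")
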