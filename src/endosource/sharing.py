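"""Significance of TRFLP peak sharing between two samples.

Sample A shows ``a`` peaks, sample B shows ``b`` peaks, ``c`` of A's
peaks are shared with B, all drawn from a global pool of N possible
(dye, size) categories (N = 314 by default, the empirically observed
universe the defaults target).  Three routes to a null probability are
provided side by side:

* :func:`sharing_probability` — the closed-form screening statistic
      P(b, c) = (1/N)^c × [b!/(b−c)!] × a
  implemented verbatim.  It is an upper-bound style approximation and
  can exceed 1 (always does at c = 0, where it degenerates to ``a``);
  a warning is emitted in that case.  The assumption that each peak
  size may hide several microbial strains does not change the value
  (it scales pool size and sharing odds together), so the
  strains-per-peak figure is carried as documentation only.
* :func:`hypergeometric_sharing` — the exact null: if B's b categories
  were drawn uniformly without replacement from the pool, the number
  shared with A's fixed a categories is Hypergeometric(N, a, b); the
  upper tail P(X >= c) is returned.
* :func:`mc_sharing` — a seeded Monte-Carlo estimate of the same tail
  (plus the exact-c point mass), as an independent simulation oracle.
"""
from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np
from scipy import stats

#: default category pool size
POOL_SIZE = 314
#: documentation-only: assumed microbial strains per peak size
STRAINS_PER_PEAK = 10


def _validate(a: int, b: int, c: int, N: int) -> None:
    if N < 1:
        raise ValueError("pool size N must be >= 1")
    if a < 0 or b < 0 or c < 0:
        raise ValueError("a, b, c must be non-negative")
    if a > N or b > N:
        raise ValueError(f"a={a} and b={b} must not exceed the pool size N={N}")
    if c > min(a, b):
        raise ValueError(f"c={c} exceeds min(a, b)={min(a, b)}")


def sharing_probability(a: int, b: int, c: int, N: int = POOL_SIZE) -> float:
    """The closed-form sharing statistic P(b,c) = (1/N)^c [b!/(b-c)!] a.

    Implemented exactly as stated; values above 1 (guaranteed at c = 0)
    trigger a warning, since the formula is a screening approximation
    rather than a calibrated probability there.
    """
    _validate(a, b, c, N)
    p = (1.0 / N) ** c * math.perm(b, c) * a
    if p > 1.0:
        warnings.warn(
            f"P(b,c)={p:.4g} exceeds 1 for (a={a}, b={b}, c={c}, N={N}); "
            "the formula is an upper-bound approximation, degenerate at small c",
            stacklevel=2,
        )
    return p


def hypergeometric_sharing(a: int, b: int, c: int, N: int = POOL_SIZE) -> float:
    """Exact null tail P(X >= c), X ~ Hypergeometric(N, a, b)."""
    _validate(a, b, c, N)
    return float(stats.hypergeom.sf(c - 1, N, a, b))


class McSharing(NamedTuple):
    p_ge: float  # empirical P(shared >= c)
    se: float  # binomial standard error of p_ge
    p_eq: float  # empirical P(shared == c)
    reps: int


def mc_sharing(
    a: int, b: int, c: int, N: int = POOL_SIZE,
    reps: int = 100_000, rng_seed: int = 0,
) -> McSharing:
    """Monte-Carlo estimate of the sharing null.

    Each rep draws a uniform b-subset of the pool and counts overlap
    with a fixed a-subset; returns the >=c tail with its standard error
    and the exact-c fraction.  Reproducible given ``rng_seed``.
    """
    _validate(a, b, c, N)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ge = eq = 0
    chunk = max(1, min(reps, 20_000))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        # first b positions of a random permutation = uniform b-subset;
        # overlap with the fixed subset {0..a-1} is the count of small indices
        u = rng.random((m, N))
        subset = np.argpartition(u, b - 1, axis=1)[:, :b] if b > 0 else np.empty((m, 0), int)
        shared = (subset < a).sum(axis=1)
        ge += int((shared >= c).sum())
        eq += int((shared == c).sum())
        done += m
    p_ge = ge / reps
    se = math.sqrt(max(p_ge * (1.0 - p_ge), 1e-300) / reps)
    return McSharing(p_ge=p_ge, se=se, p_eq=eq / reps, reps=reps)
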