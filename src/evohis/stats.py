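"""Statistical validation harness: Wilcoxon signed-rank and one-sample t-test.

Both tests are two-sided.  The signed-rank test uses the exact null
distribution (enumerated by subset-sum dynamic programming over midranks,
so tied differences are handled) for n <= 25 nonzero differences, and the
normal approximation with tie correction otherwise.
Implemented directly (using only scipy's t/normal distributions) so the
test suite can cross-check against scipy's own routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateTestError

__all__ = [
    "TestOutcome",
    "wilcoxon_signed_rank",
    "one_sample_t_test",
    "repeated_runs",
]

EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class TestOutcome:
    p_value: float
    reject_null: bool
    alpha: float
    statistic: float
    ci_lower: float = math.nan
    ci_upper: float = math.nan


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic W+.

    Enumerates the 2^n equiprobable sign assignments via subset-sum DP.
    Ranks are doubled so that midranks (.5 values) become integers.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, alpha: float = 0.05) -> TestOutcome:
    """Paired two-sided Wilcoxon signed-rank test on x - y.

    Zero differences are dropped before ranking.  If every difference is
    zero the outcome is degenerate (p = 1, no rejection).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestOutcome(p_value=1.0, reject_null=False, alpha=alpha, statistic=0.0)
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")

    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_THRESHOLD:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return TestOutcome(p_value=1.0, reject_null=False, alpha=alpha, statistic=w_plus)
        z = (w_plus - mean) / math.sqrt(var)
        p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return TestOutcome(p_value=p, reject_null=p < alpha, alpha=alpha, statistic=w_plus)


def one_sample_t_test(x, m: float, alpha: float = 0.05) -> TestOutcome:
    """Two-sided one-sample Student's t-test of mean(x) = m.

    Returns the (1 - alpha) confidence interval for the mean as ci bounds.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of length >= 2")
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateTestError("zero sample variance: t statistic undefined")
    se = s / math.sqrt(n)
    t_stat = (x.mean() - m) / se
    df = n - 1
    p = float(min(1.0, 2.0 * _sps.t.sf(abs(t_stat), df)))
    t_crit = float(_sps.t.ppf(1.0 - alpha / 2.0, df))
    return TestOutcome(
        p_value=p,
        reject_null=p < alpha,
        alpha=alpha,
        statistic=float(t_stat),
        ci_lower=float(x.mean() - t_crit * se),
        ci_upper=float(x.mean() + t_crit * se),
    )


def repeated_runs(runner, n_runs: int = 20, base_seed: int = 0) -> np.ndarray:
    """Run a seeded experiment repeatedly; rows are (PAC, SEY, SPY) triples.

    Seeds are ``base_seed .. base_seed + n_runs - 1``.
    """
    rows = [np.asarray(runner(seed), dtype=float) for seed in range(base_seed, base_seed + n_runs)]
    out = np.vstack(rows)
    if out.shape != (n_runs, 3):
        raise ValueError(f"runner must yield 3-vectors; got matrix of shape {out.shape}")
    return out
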