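"""Shared statistical primitives.

The paired t-test lives here so that the community-enrichment and host
differential-expression stages share one code path (and one oracle in the
test suite). The designs in question are tiny — two trap/leaf pairs per
species — so degenerate difference vectors (zero variance) are a real
occurrence and are handled explicitly instead of propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class PairedTResult:
    """Outcome of a paired t-test on trap/leaf (or season) differences.

    ``degenerate`` is set when the differences have zero variance, where the
    classical statistic is undefined: all-zero differences yield p = 1
    (no evidence of change), while constant nonzero differences are reported
    as p = 0 with the flag raised so downstream consumers can treat the
    value with caution.
    """

    t: float
    p: float
    n: int
    df: int
    degenerate: bool = False
    low_power: bool = False


def paired_t_test(x, y) -> PairedTResult:
    """Classical paired t-test on differences ``x - y``.

    Parameters
    ----------
    x, y : array-like
        Paired observations (e.g. trap and leaf abundances over sample
        pairs). Must have equal length >= 2.

    Returns
    -------
    PairedTResult
        Two-sided p from the t distribution with ``n - 1`` degrees of
        freedom; ``low_power`` flags n < 3 (one degree of freedom, as in
        two-pairs-per-species designs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t_test requires two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    low_power = n < 3
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, n=n, df=n - 1,
                                 degenerate=True, low_power=low_power)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(t=t, p=0.0, n=n, df=n - 1,
                             degenerate=True, low_power=low_power)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(_sps.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), p=min(p, 1.0), n=n, df=n - 1,
                         low_power=low_power)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero at .5, the convention of the published
    composition tables (bankers' rounding would disagree on e.g. 0.125)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 2) -> float:
    """100 * count / total, rounded half-up to ``decimals``."""
    if total <= 0:
        raise ValueError("percent requires a positive total")
    return round_half_up(100.0 * count / total, decimals)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg q-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
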