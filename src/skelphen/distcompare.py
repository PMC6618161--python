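"""Two-sample Kolmogorov-Smirnov comparison on the percent scale.

The D statistic is reported as ``100 x sup |ECDF1 - ECDF2|`` and compared
against analytic critical values ``100 x c(alpha) x sqrt((n1+n2)/(n1 n2))``
with tabulated coefficients c = 1.36 / 1.63 / 1.95 for alpha = 0.05 / 0.01 /
0.001.  At n1 = n2 = 1024 these give the thresholds 6.01, 7.20 and 8.62.

Ties are handled by evaluating ECDF gaps at all pooled unique values, so
the statistic is exact for discrete and binned data alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KSResult",
    "ALPHA_COEFFICIENTS",
    "ks_two_sample_percent",
    "ks_histogram_percent",
    "ks_critical_percent",
]

#: Tabulated large-sample coefficients; only these reproduce the printed
#: 1024-pixel thresholds at two decimals (the exact asymptotic
#: sqrt(-ln(alpha/2)/2) does not).
ALPHA_COEFFICIENTS = {0.05: 1.36, 0.01: 1.63, 0.001: 1.95}


@dataclass(frozen=True)
class KSResult:
    """Percent-scale KS statistic with crossed significance levels."""

    d_percent: float
    n1: int
    n2: int
    critical_percent: dict[float, float]
    crossed_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.d_percent <= 100 + 1e-9:
            raise ValueError("d_percent must lie in [0, 100]")


def ks_critical_percent(alpha: float, n1: int, n2: int) -> float:
    """Analytic percent-scale critical value of D at level alpha.

    D_crit = 100 x c(alpha) x sqrt((n1 + n2) / (n1 * n2)).
    """
    if alpha not in ALPHA_COEFFICIENTS:
        supported = sorted(ALPHA_COEFFICIENTS)
        raise ValueError(f"unsupported alpha {alpha}; supported levels: {supported}")
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    c = ALPHA_COEFFICIENTS[alpha]
    return 100.0 * c * float(np.sqrt((n1 + n2) / (n1 * n2)))


def _crossed(d_percent: float, n1: int, n2: int) -> tuple[dict[float, float], tuple[float, ...]]:
    crit = {a: ks_critical_percent(a, n1, n2) for a in sorted(ALPHA_COEFFICIENTS, reverse=True)}
    crossed = tuple(a for a, c in crit.items() if d_percent > c)
    return crit, crossed


def ks_two_sample_percent(sample1: Sequence[float], sample2: Sequence[float]) -> KSResult:
    """Exact two-sample KS statistic on the percent scale.

    ECDF gaps are evaluated at every pooled unique value (right-continuous
    ECDFs), which handles ties exactly.
    """
    a = np.sort(np.asarray(sample1, dtype=float))
    b = np.sort(np.asarray(sample2, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    grid = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = 100.0 * float(np.max(np.abs(cdf_a - cdf_b)))
    crit, crossed = _crossed(d, a.size, b.size)
    return KSResult(d_percent=d, n1=int(a.size), n2=int(b.size),
                    critical_percent=crit, crossed_levels=crossed)


def ks_histogram_percent(hist1, hist2) -> KSResult:
    """KS statistic between two histograms sharing bin edges.

    D is the maximum absolute difference of cumulative relative
    frequencies over the bin edges; the pixel counts of the histograms
    provide n1 and n2 for critical values.
    """
    e1 = np.asarray(hist1.edges, dtype=float)
    e2 = np.asarray(hist2.edges, dtype=float)
    if e1.shape != e2.shape or not np.allclose(e1, e2, rtol=0, atol=1e-12):
        raise ValueError("histograms must share identical bin edges")
    f1 = np.asarray(hist1.frequencies, dtype=float)
    f2 = np.asarray(hist2.frequencies, dtype=float)
    if np.count_nonzero(f1) < 1 or np.count_nonzero(f2) < 1:
        raise ValueError("each histogram needs at least one non-empty bin")
    d = 100.0 * float(np.max(np.abs(np.cumsum(f1) - np.cumsum(f2))))
    d = min(d, 100.0)
    n1, n2 = int(hist1.n_pixels), int(hist2.n_pixels)
    crit, crossed = _crossed(d, n1, n2)
    return KSResult(d_percent=d, n1=n1, n2=n2, critical_percent=crit, crossed_levels=crossed)
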