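"""Paired solution-vs-laser comparison statistics.

With only ten teeth per metric the comparison is non-parametric: a Wilcoxon
signed-rank test on paired per-tooth metrics (median, min, max, amplitude,
endmember values), group means +/- sample SD, and a Pearson correlation
between the per-tooth amplitude difference and the laser amplitude (the
signature of sampling-volume signal damping: the larger the laser amplitude,
the more the strip sample under-reads it).

The signed-rank convention is fixed and documented because printed Z values
depend on it: zero differences are dropped (Wilcoxon's original rule), tied
absolute differences take midranks with the tie-corrected normal variance,
and no continuity correction is applied.  Differences are oriented
``solution - laser`` so a negative Z means the laser metric is larger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedMetric:
    """One tooth's metric under both methods; difference = solution - laser."""

    tooth_key: tuple[str, str]
    value_solution: float
    value_laser: float

    @property
    def difference(self) -> float:
        return self.value_solution - self.value_laser


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome (normal approximation)."""

    n_nonzero: int
    w_plus: float
    w_minus: float
    z: float
    p_two_sided: float


def wilcoxon_signed_rank(
    pairs: Sequence[PairedMetric] | Sequence[float],
    continuity_correction: bool = False,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Accepts either ``PairedMetric`` records or raw differences
    (solution - laser).  Zeros are dropped; midranks handle ties;
    ``Z = (W+ - m(m+1)/4) / sqrt(Var)`` with the tie-corrected variance
    ``m(m+1)(2m+1)/24 - sum(t^3 - t)/48``.  ``continuity_correction``
    subtracts 0.5 from ``|W+ - mean|`` before standardizing (off by default;
    the default convention is the one that reproduces midrank hand
    computation exactly).
    """
    if len(pairs) and isinstance(pairs[0], PairedMetric):
        d = np.array([p.difference for p in pairs], dtype=float)
    else:
        d = np.asarray(pairs, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mean = m * (m + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float(
        ((counts.astype(float) ** 3 - counts).sum()) / 48.0
    )
    if var <= 0:
        raise ValueError("zero variance in signed ranks")
    dev = w_plus - mean
    if continuity_correction and dev != 0:
        dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    z = dev / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(
        n_nonzero=m, w_plus=w_plus, w_minus=w_minus, z=float(z),
        p_two_sided=float(min(p, 1.0)),
    )


def group_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1))


def amplitude_damping_regression(
    laser_amplitudes: Sequence[float],
    amplitude_differences: Sequence[float],
) -> tuple[float, float, float]:
    """Pearson correlation of amplitude difference against laser amplitude.

    Returns ``(r, r_squared, p_two_sided)``.  A strong positive correlation
    indicates damping proportional to signal size: teeth with larger laser
    amplitude lose more of it in the strip-sampled profile.
    """
    x = np.asarray(laser_amplitudes, dtype=float)
    y = np.asarray(amplitude_differences, dtype=float)
    if x.size != y.size:
        raise ValueError("input lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)
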