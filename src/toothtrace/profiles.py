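"""Intra-tooth 87Sr/86Sr profiles: containers, smoothing, summaries, endmembers.

A profile is an ordered series of (distance from the enamel-root junction,
ratio) pairs for one tooth and one method.  Enamel grows from the crown cusp
toward the root, so position along the crown is a time axis: the occlusal
surface (OS) is the oldest enamel, the enamel-root junction (ERJ) the
youngest.  The season each terminus records depends on the tooth: in the M2
the OS forms in late summer/autumn and the ERJ in winter; the M3 is the
reverse.

Laser profiles (one cycle every ~21 um) are noisy at the single-cycle level
and are smoothed with a 20-point centred running mean before summary
statistics; strip (solution) profiles have ~6-8 samples and are used raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .constants import BIOLOGICAL_RATIO_RANGE

Tooth = Literal["M2", "M3"]
Method = Literal["solution", "laser", "ideal"]
Season = Literal["summer", "winter"]

#: Season recorded at each crown terminus, by tooth.
TERMINUS_SEASONS: dict[str, dict[str, Season]] = {
    "M2": {"OS": "summer", "ERJ": "winter"},
    "M3": {"OS": "winter", "ERJ": "summer"},
}


@dataclass(frozen=True)
class ToothProfile:
    """One tooth/method profile, ordered by distance from the ERJ (mm)."""

    individual_id: str
    tooth: Tooth
    method: Method
    distances: np.ndarray
    ratios: np.ndarray
    crown_height: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "ratios", r)
        if self.tooth not in TERMINUS_SEASONS:
            raise ValueError(f"unknown tooth label {self.tooth!r}")
        if self.method not in ("solution", "laser", "ideal"):
            raise ValueError(f"unknown method {self.method!r}")
        if d.size != r.size:
            raise ValueError("distances and ratios differ in length")
        if d.size < 2:
            raise ValueError("a profile needs at least two samples")
        if np.any(d < 0):
            raise ValueError("distances from the ERJ must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        lo, hi = BIOLOGICAL_RATIO_RANGE
        if np.any((r <= lo) | (r >= hi)):
            raise ValueError(f"ratios outside plausible range ({lo}, {hi})")

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class SmoothedProfile:
    """Centred running mean (+/- running SD) of a profile."""

    window: int
    positions: np.ndarray
    running_mean: np.ndarray
    running_sd: np.ndarray


@dataclass(frozen=True)
class ProfileSummary:
    """Median / min / max / amplitude of one profile (amplitude = max - min)."""

    median: float
    min: float
    max: float
    amplitude: float

    def rounded(self, ndigits: int = 4) -> "ProfileSummary":
        """Reporting precision: 4 decimals, amplitude re-derived after rounding."""
        mn, mx = round(self.min, ndigits), round(self.max, ndigits)
        return ProfileSummary(
            median=round(self.median, ndigits), min=mn, max=mx,
            amplitude=round(mx - mn, ndigits),
        )


@dataclass(frozen=True)
class EndmemberPair:
    """Seasonal endmembers of one profile: values at the OS and ERJ termini."""

    os_value: float
    erj_value: float
    os_season: Season
    erj_season: Season

    @property
    def amplitude(self) -> float:
        return abs(self.os_value - self.erj_value)

    def value_for(self, season: Season) -> float:
        if season == self.os_season:
            return self.os_value
        if season == self.erj_season:
            return self.erj_value
        raise ValueError(f"unknown season {season!r}")


def smooth_profile(profile: ToothProfile, window: int = 20) -> SmoothedProfile:
    """Centred running mean and SD with a window of ``window`` points.

    At the profile edges the centred span is truncated to the points
    available, which is never fewer than ``ceil(window / 2)``; the output has
    the same length as the input.
    """
    n = len(profile)
    if window < 2:
        raise ValueError("window must be at least 2")
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    min_periods = (window + 1) // 2
    roll = pd.Series(profile.ratios).rolling(
        window, center=True, min_periods=min_periods
    )
    means = roll.mean().to_numpy()
    sds = roll.std(ddof=1).to_numpy()
    return SmoothedProfile(
        window=window, positions=profile.distances.copy(),
        running_mean=means, running_sd=sds,
    )


def summarize(values: Iterable[float]) -> ProfileSummary:
    """Median, min, max and amplitude of a series of ratios.

    For laser profiles pass the smoothed running mean; for solution profiles
    the raw strip values.  Order-invariant.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty series")
    mn, mx = float(arr.min()), float(arr.max())
    return ProfileSummary(
        median=float(np.median(arr)), min=mn, max=mx, amplitude=mx - mn
    )


def summarize_profile(profile: ToothProfile, window: int = 20) -> ProfileSummary:
    """Summary statistics on the method-appropriate series.

    Laser profiles are smoothed with ``window`` first (single cycles are too
    noisy to define extrema); solution strips are summarized raw.
    """
    if profile.method == "laser":
        return summarize(smooth_profile(profile, window).running_mean)
    return summarize(profile.ratios)


def extract_endmembers(profile: ToothProfile, window: int = 20) -> EndmemberPair:
    """Seasonal endmembers: the samples closest to the OS and the ERJ.

    Solution endmembers are the first and last strip values.  Laser
    endmembers are the mean of the ``window`` raw cycles nearest each
    terminus (the running-average value evaluated at the terminus).  Season
    labels follow tooth identity: M2 OS = summer, ERJ = winter; M3 reversed.
    """
    seasons = TERMINUS_SEASONS[profile.tooth]
    r = profile.ratios
    if profile.method == "laser":
        if window > len(profile):
            raise ValueError(f"window {window} exceeds profile length {len(profile)}")
        erj_value = float(r[:window].mean())   # distances start at the ERJ
        os_value = float(r[-window:].mean())
    else:
        erj_value = float(r[0])
        os_value = float(r[-1])
    return EndmemberPair(
        os_value=os_value, erj_value=erj_value,
        os_season=seasons["OS"], erj_season=seasons["ERJ"],
    )


# ---------------------------------------------------------------------------
# long-format CSV I/O

PROFILE_COLUMNS = [
    "individual_id", "tooth", "method", "distance_from_erj_mm", "sr87_86",
]


def read_profiles(path: str | Path) -> list[ToothProfile]:
    """Read profiles from long-format CSV, one row per sample."""
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    out = []
    for (ind, tooth, method), grp in df.groupby(
        ["individual_id", "tooth", "method"], sort=False
    ):
        grp = grp.sort_values("distance_from_erj_mm")
        out.append(
            ToothProfile(
                individual_id=str(ind), tooth=tooth, method=method,
                distances=grp["distance_from_erj_mm"].to_numpy(),
                ratios=grp["sr87_86"].to_numpy(),
            )
        )
    return out


def write_profiles(profiles: Iterable[ToothProfile], path: str | Path) -> None:
    """Write profiles as long-format CSV."""
    frames = [
        pd.DataFrame(
            {
                "individual_id": p.individual_id,
                "tooth": p.tooth,
                "method": p.method,
                "distance_from_erj_mm": p.distances,
                "sr87_86": p.ratios,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
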