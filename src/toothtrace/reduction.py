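"""Reduction of raw LA-MC-ICP-MS beam intensities to corrected 87Sr/86Sr.

A laser line scan yields, every ~21 um, a cycle of beam intensities (V) at
nominal masses 84-88, plus gas-blank cycles measured with the laser off.  The
reduction sequence is:

1. gas-blank subtraction (removes the Kr contribution riding on masses 84/86),
2. isobaric Rb correction of the mass-87 beam using the natural 87Rb/85Rb
   abundance and the Sr mass-bias factor,
3. exponential-law mass-bias normalization of 87Sr/86Sr (and 84Sr/86Sr for
   QC) to the canonical 88Sr/86Sr.

The exponential law is written ``R_true = R_meas * (m_a / m_b) ** beta`` with
``beta`` solved from the measured 88Sr/86Sr; the same ``beta`` corrects every
other Sr ratio and (applied with opposite sign when predicting a *measured*
quantity) the Rb interference.  Solution data are normalized to the session
SRM987 by an additive offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import BIOLOGICAL_RATIO_RANGE, DEFAULT_CONSTANTS, ReductionConstants

MASS_NAMES = (84, 85, 86, 87, 88)


@dataclass(frozen=True)
class RawCycle:
    """One laser-scan measurement cycle before correction.

    ``position`` is um along the scan from the occlusal surface; ``beams``
    maps nominal mass (84, 85, 86, 87, 88) to intensity in volts;
    ``is_blank`` marks gas-blank cycles (laser off).
    """

    position: float
    beams: dict[int, float]
    is_blank: bool = False

    def __post_init__(self) -> None:
        missing = set(MASS_NAMES) - set(self.beams)
        if missing:
            raise ValueError(f"cycle missing beams at masses {sorted(missing)}")
        for mass, v in self.beams.items():
            if v < 0:
                raise ValueError(f"negative beam intensity {v} at mass {mass}")


@dataclass(frozen=True)
class ReducedCycle:
    """One corrected cycle: position (um), corrected ratios, bias factor, QC."""

    position: float
    ratio_87_86: float
    ratio_84_86: float
    beta: float
    qc_pass: bool


def subtract_gas_blank(
    cycles: Sequence[RawCycle], blanks: Sequence[RawCycle]
) -> tuple[list[RawCycle], int]:
    """Subtract the mean gas-blank beam at each mass from every sample cycle.

    Returns the corrected cycles and the number of beam values clipped to
    zero (a negative post-subtraction intensity is physically meaningless).

    Raises
    ------
    ValueError
        If no blank cycles are supplied or the mass sets differ.
    """
    if not blanks:
        raise ValueError("at least one gas-blank cycle is required")
    mass_set = set(cycles[0].beams) if cycles else set(MASS_NAMES)
    for b in blanks:
        if set(b.beams) != mass_set:
            raise ValueError("blank and sample cycles measure different mass sets")
    mean_blank = {
        m: float(np.mean([b.beams[m] for b in blanks])) for m in mass_set
    }
    out: list[RawCycle] = []
    n_clipped = 0
    for c in cycles:
        beams = {}
        for m in mass_set:
            v = c.beams[m] - mean_blank[m]
            if v < 0:
                v = 0.0
                n_clipped += 1
            beams[m] = v
        out.append(replace(c, beams=beams))
    return out, n_clipped


def mass_bias_beta(
    measured_88_86: float, constants: ReductionConstants = DEFAULT_CONSTANTS
) -> float:
    """Exponential-law mass-bias factor from the measured 88Sr/86Sr.

    Solves ``canonical = measured * (m88/m86)**beta``.
    """
    if measured_88_86 <= 0:
        raise ValueError("measured 88Sr/86Sr must be strictly positive")
    m = constants.atomic_masses
    return math.log(constants.canonical_88_86 / measured_88_86) / math.log(
        m["Sr88"] / m["Sr86"]
    )


def correct_rb(
    beam_85: float,
    beam_87: float,
    beta: float,
    constants: ReductionConstants = DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Strip the isobaric 87Rb contribution from the mass-87 beam.

    The *measured* 87Rb beam is predicted from the measured 85Rb beam via the
    natural 87Rb/85Rb abundance carried through the instrumental mass bias:
    since ``R_true = R_meas * (m87/m85)**beta``, the measured interference is
    ``beam_85 * rho * (m87Rb/m85Rb)**(-beta)``.

    Returns the corrected beam and a flag that is True when the subtraction
    would have gone negative (the beam is clipped to zero in that case).
    """
    if beam_85 < 0:
        raise ValueError("beam_85 must be non-negative")
    m = constants.atomic_masses
    rb87 = beam_85 * constants.natural_87rb_85rb * (m["Rb87"] / m["Rb85"]) ** (-beta)
    corrected = beam_87 - rb87
    if corrected < 0:
        return 0.0, True
    return corrected, False


def reduce_cycle(
    cycle: RawCycle,
    constants: ReductionConstants = DEFAULT_CONSTANTS,
    qc_tolerance: float | None = None,
) -> ReducedCycle:
    """Reduce one blank-subtracted cycle to corrected ratios with QC.

    Applies the Rb correction then the exponential-law normalization of
    87Sr/86Sr and 84Sr/86Sr to the canonical 88Sr/86Sr.  The QC flag requires
    the corrected 84Sr/86Sr to sit within ``qc_tolerance`` of the invariant
    value and the 87Sr/86Sr to be biologically plausible.
    """
    if qc_tolerance is None:
        qc_tolerance = constants.qc_tolerance
    b = cycle.beams
    if b[86] <= 0:
        raise ValueError("beam at mass 86 must be strictly positive")
    beta = mass_bias_beta(b[88] / b[86], constants)
    m = constants.atomic_masses
    beam_87_sr, clipped = correct_rb(b[85], b[87], beta, constants)
    r87 = (beam_87_sr / b[86]) * (m["Sr87"] / m["Sr86"]) ** beta
    r84 = (b[84] / b[86]) * (m["Sr84"] / m["Sr86"]) ** beta
    lo, hi = BIOLOGICAL_RATIO_RANGE
    qc = (
        not clipped
        and abs(r84 - constants.invariant_84_86) <= qc_tolerance
        and lo < r87 < hi
    )
    return ReducedCycle(
        position=cycle.position, ratio_87_86=r87, ratio_84_86=r84,
        beta=beta, qc_pass=qc,
    )


def reduce_scan(
    cycles: Sequence[RawCycle],
    constants: ReductionConstants = DEFAULT_CONSTANTS,
    qc_tolerance: float | None = None,
) -> list[ReducedCycle]:
    """Full reduction of a scan: blank subtraction then per-cycle correction.

    ``cycles`` mixes sample and blank cycles (``is_blank`` distinguishes
    them, mirroring the raw-scan CSV schema).
    """
    blanks = [c for c in cycles if c.is_blank]
    samples = [c for c in cycles if not c.is_blank]
    positions = [c.position for c in samples]
    if any(b >= a for b, a in zip(positions, positions[1:])):
        raise ValueError("sample positions must be strictly increasing")
    subtracted, _ = subtract_gas_blank(samples, blanks)
    return [reduce_cycle(c, constants, qc_tolerance) for c in subtracted]


def normalize_to_reference(
    ratio: float,
    session_reference_measured: float,
    constants: ReductionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Additive session normalization against the measured SRM987.

    Returns ``ratio + (accepted - measured)``; e.g. a session SRM987 of
    0.710260 against the accepted 0.710240 shifts every sample by -0.00002.
    """
    lo, hi = BIOLOGICAL_RATIO_RANGE
    for name, v in (("ratio", ratio),
                    ("session_reference_measured", session_reference_measured)):
        if not lo < v < hi:
            raise ValueError(f"{name}={v} outside plausible range {lo}-{hi}")
    return ratio + (constants.srm987_accepted - session_reference_measured)


# ---------------------------------------------------------------------------
# forward simulation (the independent oracle for round-trip testing)

def simulate_cycle(
    true_87_86: float,
    beta: float,
    position: float = 0.0,
    beam_86: float = 2.0,
    rb85_beam: float = 0.0,
    blank: dict[int, float] | None = None,
    true_84_86: float | None = None,
    constants: ReductionConstants = DEFAULT_CONSTANTS,
) -> RawCycle:
    """Forward-simulate the measured beams for a known true composition.

    Inverts the reduction model exactly: true Sr ratios are biased by
    ``(m_a/m_b)**(-beta)``, the Rb interference is added onto mass 87 with
    the Rb mass pair, and an optional blank spectrum is added on top.  Used
    to verify that reduction recovers the construction values.
    """
    m = constants.atomic_masses
    if true_84_86 is None:
        true_84_86 = constants.invariant_84_86
    beams = {
        86: beam_86,
        88: beam_86 * constants.canonical_88_86 * (m["Sr88"] / m["Sr86"]) ** (-beta),
        87: beam_86 * true_87_86 * (m["Sr87"] / m["Sr86"]) ** (-beta),
        84: beam_86 * true_84_86 * (m["Sr84"] / m["Sr86"]) ** (-beta),
        85: rb85_beam,
    }
    beams[87] += rb85_beam * constants.natural_87rb_85rb * (
        m["Rb87"] / m["Rb85"]
    ) ** (-beta)
    if blank:
        for mass, v in blank.items():
            beams[mass] = beams.get(mass, 0.0) + v
    return RawCycle(position=position, beams=beams)


# ---------------------------------------------------------------------------
# text I/O

RAW_COLUMNS = ["position_um", "i84", "i85", "i86", "i87", "i88", "is_blank"]


def read_raw_scan(path: str | Path) -> list[RawCycle]:
    """Read one scan's raw cycles from CSV (columns ``position_um, i84..i88,
    is_blank``)."""
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw scan CSV missing columns {sorted(missing)}")
    return [
        RawCycle(
            position=float(r.position_um),
            beams={84: r.i84, 85: r.i85, 86: r.i86, 87: r.i87, 88: r.i88},
            is_blank=bool(r.is_blank),
        )
        for r in df.itertuples()
    ]


def write_reduced(cycles: Iterable[ReducedCycle], path: str | Path) -> None:
    """Write reduced cycles as CSV (``position_um, sr87_86, sr84_86, qc_pass``)."""
    cycles = list(cycles)
    pd.DataFrame(
        {
            "position_um": [c.position for c in cycles],
            "sr87_86": [c.ratio_87_86 for c in cycles],
            "sr84_86": [c.ratio_84_86 for c in cycles],
            "qc_pass": [c.qc_pass for c in cycles],
        }
    ).to_csv(path, index=False)
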