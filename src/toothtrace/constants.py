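"""Physical constants for Sr isotope data reduction.

The canonical ``88Sr/86Sr`` used for internal mass-bias normalization and the
invariant ``84Sr/86Sr`` quality-control ratio are the values conventionally
used for bioapatite Sr work; atomic masses are CODATA/AME values to >= 7
significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ReductionConstants:
    """Constants entering LA-MC-ICP-MS and solution Sr data reduction.

    Attributes
    ----------
    canonical_88_86
        Canonical ``88Sr/86Sr`` the exponential mass-bias law normalizes to.
    invariant_84_86
        Invariant ``84Sr/86Sr`` used as a per-cycle quality-control check.
    natural_87rb_85rb
        Natural ``87Rb/85Rb`` abundance ratio used to strip the isobaric
        ``87Rb`` interference from the mass-87 beam.
    atomic_masses
        Isotope masses (u) keyed by ``"Sr84" ... "Rb87"``.
    srm987_accepted
        Accepted ``87Sr/86Sr`` of NIST SRM987, the reference used for the
        additive session normalization of solution data.
    seawater_check
        Modern-seawater ``87Sr/86Sr`` used as an accuracy check on marine
        in-house standards.
    qc_tolerance
        Default half-width of the acceptance band ``|84Sr/86Sr - invariant|``
        for the per-cycle QC flag (about 3x the typical cycle SD).
    """

    canonical_88_86: float = 8.375209
    invariant_84_86: float = 0.0565
    natural_87rb_85rb: float = 0.38571
    atomic_masses: dict[str, float] = field(
        default_factory=lambda: {
            "Sr84": 83.9134191,
            "Sr86": 85.9092606,
            "Sr87": 86.9088775,
            "Sr88": 87.9056125,
            "Rb85": 84.9117897,
            "Rb87": 86.9091805,
        }
    )
    srm987_accepted: float = 0.710240
    seawater_check: float = 0.7092
    qc_tolerance: float = 0.012

    def __post_init__(self) -> None:
        for name in ("canonical_88_86", "invariant_84_86", "natural_87rb_85rb",
                     "srm987_accepted", "seawater_check", "qc_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for key, mass in self.atomic_masses.items():
            if mass <= 0:
                raise ValueError(f"atomic mass {key} must be strictly positive")


#: Plausible biological ``87Sr/86Sr`` window; ratios outside it fail QC.
BIOLOGICAL_RATIO_RANGE: tuple[float, float] = (0.69, 0.75)

DEFAULT_CONSTANTS = ReductionConstants()
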