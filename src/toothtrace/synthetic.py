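"""Synthetic isoscape, migratory trajectory, and enamel forward model.

A download-free test bed emulating the study system: a northern summer
range and a southern winter range of low-to-intermediate bioavailable
87Sr/86Sr separated by a high-ratio mountain band, an annual migratory cycle
crossing that band, and the chain of attenuating transfers between daily
intake and the measured enamel profile:

    daily location -> intake ratio -> blood (exponential pool with a bone
    baseline) -> enamel (secretion front + maturation kernel) -> sampled
    profile (1.5 mm strips vs ~21 um laser cycles, each with its own
    averaging support and measurement noise).

Day 0 is calving (~1 June); a month is taken as 30 days.  Default secretion
windows are M2 = days 105-270 (3.5-9 months) and M3 = days 290-480 (~9.5-16
months; the nominal window runs to <18 months but observed profiles carry a
single seasonal transition, consistent with a shorter effective window).
Every stochastic step draws from a caller-supplied seed, so a dataset is
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .assign import RangePolygon, write_ranges
from .profiles import ToothProfile, write_profiles
from .raster import Isoscape, write_isoscape

ZONES = ("winter_south", "mountain_band", "summer_north")


@dataclass(frozen=True)
class SyntheticIsoscapeSpec:
    """Parameters of the synthetic isoscape grid.

    Zone mean ratios default to 0.7095 (winter south), 0.7135 (mountain
    band) and 0.7115 (summer north): low values in the seasonal ranges, the
    highest values in the band separating them.  ``noise_sd`` and
    ``correlation_length`` (cells) control the spatially correlated noise
    added to the zone means; ``error_sd`` is the per-cell error surface.
    """

    nrows: int = 40
    ncols: int = 30
    summer_rows: int = 16
    mountain_rows: int = 8
    winter_rows: int = 16
    zone_means: dict[str, float] = field(
        default_factory=lambda: {
            "winter_south": 0.7095,
            "mountain_band": 0.7135,
            "summer_north": 0.7115,
        }
    )
    noise_sd: float = 0.00025
    correlation_length: float = 3.0
    error_sd: float = 0.0005
    cell_size: float = 1.0
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        if self.summer_rows + self.mountain_rows + self.winter_rows != self.nrows:
            raise ValueError("zone row counts do not partition the grid")
        if set(self.zone_means) != set(ZONES):
            raise ValueError(f"zone_means must cover exactly {ZONES}")
        for z, m in self.zone_means.items():
            if not 0.69 < m < 0.75:
                raise ValueError(f"zone mean {z}={m} outside plausible range")

    def zone_row_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open row ranges per zone (row 0 = north)."""
        s, m = self.summer_rows, self.mountain_rows
        return {
            "summer_north": (0, s),
            "mountain_band": (s, s + m),
            "winter_south": (s + m, self.nrows),
        }


@dataclass
class SyntheticWorld:
    """A generated isoscape plus its seasonal range polygons and zone masks."""

    isoscape: Isoscape
    ranges: dict[str, RangePolygon]
    zone_masks: dict[str, np.ndarray]
    spec: SyntheticIsoscapeSpec


def generate_isoscape(
    spec: SyntheticIsoscapeSpec, seed: int | None = None
) -> SyntheticWorld:
    """Zone-mean surface plus spatially correlated noise, with range polygons.

    Noise is white Gaussian smoothed to ``correlation_length`` cells and
    rescaled to ``noise_sd``; with ``noise_sd == 0`` every cell equals its
    zone mean.  The summer range polygon is the northern zone's rectangle,
    the winter polygon the southern one.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    bounds = spec.zone_row_bounds()
    mean = np.empty((spec.nrows, spec.ncols))
    masks: dict[str, np.ndarray] = {}
    for zone, (r0, r1) in bounds.items():
        mask = np.zeros((spec.nrows, spec.ncols), dtype=bool)
        mask[r0:r1, :] = True
        masks[zone] = mask
        mean[r0:r1, :] = spec.zone_means[zone]
    if spec.noise_sd > 0:
        white = rng.standard_normal(mean.shape)
        smooth = gaussian_filter(white, sigma=spec.correlation_length, mode="reflect")
        smooth *= spec.noise_sd / smooth.std()
        mean = mean + smooth
    iso = Isoscape(
        mean=mean,
        error_sd=np.full(mean.shape, spec.error_sd),
        xll=spec.xll, yll=spec.yll, cell_size=spec.cell_size,
        crs="synthetic",
    )
    cs = spec.cell_size
    y_top = spec.yll + spec.nrows * cs
    ranges = {
        "summer": RangePolygon(
            "summer",
            box(spec.xll, y_top - spec.summer_rows * cs,
                spec.xll + spec.ncols * cs, y_top),
        ),
        "winter": RangePolygon(
            "winter",
            box(spec.xll, spec.yll,
                spec.xll + spec.ncols * cs, spec.yll + spec.winter_rows * cs),
        ),
    }
    return SyntheticWorld(isoscape=iso, ranges=ranges, zone_masks=masks, spec=spec)


# ---------------------------------------------------------------------------
# movement

@dataclass(frozen=True)
class MovementSchedule:
    """Day-indexed zone occupancy plus the within-zone daily step SD (cells)."""

    zones: tuple[str, ...]
    step_sd: float = 0.5

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("schedule covers no days")
        unknown = set(self.zones) - set(ZONES)
        if unknown:
            raise ValueError(f"unknown zones in schedule: {sorted(unknown)}")

    @property
    def n_days(self) -> int:
        return len(self.zones)

    @property
    def sedentary(self) -> bool:
        return len(set(self.zones)) == 1

    @classmethod
    def migratory(
        cls,
        n_days: int = 620,
        autumn: tuple[int, int] = (165, 195),
        spring: tuple[int, int] = (320, 350),
        second_autumn: tuple[int, int] = (470, 500),
        step_sd: float = 0.5,
    ) -> "MovementSchedule":
        """Annual cycle: summer from calving, autumn crossing to the winter
        range, spring crossing back, and a second autumn crossing."""
        zones = []
        for day in range(n_days):
            if autumn[0] <= day < autumn[1] or spring[0] <= day < spring[1] or (
                second_autumn[0] <= day < second_autumn[1]
            ):
                zones.append("mountain_band")
            elif day < autumn[0] or spring[1] <= day < second_autumn[0]:
                zones.append("summer_north")
            else:
                zones.append("winter_south")
        return cls(zones=tuple(zones), step_sd=step_sd)

    @classmethod
    def sedentary_in(
        cls, zone: str = "winter_south", n_days: int = 620, step_sd: float = 0.5
    ) -> "MovementSchedule":
        return cls(zones=(zone,) * n_days, step_sd=step_sd)


def _segments(zones: tuple[str, ...]) -> list[tuple[int, int, str]]:
    """Contiguous (start, stop, zone) runs of a schedule."""
    runs = []
    start = 0
    for i in range(1, len(zones) + 1):
        if i == len(zones) or zones[i] != zones[start]:
            runs.append((start, i, zones[start]))
            start = i
    return runs


def simulate_trajectory(
    schedule: MovementSchedule,
    world: SyntheticWorld,
    seed: int | None = None,
) -> pd.DataFrame:
    """Daily positions and intake ratios under a movement schedule.

    Within a residence zone the animal random-walks (mean-reverting, step SD
    ``schedule.step_sd`` cells) around a home centre drawn once per zone;
    during a mountain-band crossing the centre sweeps linearly across the
    band between the neighbouring homes.  Intake each day is the isoscape
    mean of the occupied cell.

    Returns a frame with columns ``day, row, col, zone, intake_ratio``.
    """
    rng = np.random.default_rng(seed)
    spec = world.spec
    bounds = spec.zone_row_bounds()
    homes: dict[str, tuple[float, float]] = {}
    for zone in ZONES:
        r0, r1 = bounds[zone]
        homes[zone] = (
            rng.uniform(r0 + 1.0, r1 - 1.0),
            rng.uniform(1.0, spec.ncols - 1.0),
        )
    runs = _segments(schedule.zones)
    target_rows = np.empty(schedule.n_days)
    target_cols = np.empty(schedule.n_days)
    for k, (start, stop, zone) in enumerate(runs):
        if zone == "mountain_band" and 0 < k < len(runs) - 1:
            prev_home = homes[runs[k - 1][2]]
            next_home = homes[runs[k + 1][2]]
            frac = np.linspace(0.0, 1.0, stop - start)
            r0, r1 = bounds["mountain_band"]
            going_south = next_home[0] > prev_home[0]
            edge_in, edge_out = (r0 + 0.5, r1 - 0.5) if going_south else (
                r1 - 0.5, r0 + 0.5
            )
            target_rows[start:stop] = edge_in + frac * (edge_out - edge_in)
            target_cols[start:stop] = prev_home[1] + frac * (
                next_home[1] - prev_home[1]
            )
        else:
            target_rows[start:stop] = homes[zone][0]
            target_cols[start:stop] = homes[zone][1]
    rows = np.empty(schedule.n_days)
    cols = np.empty(schedule.n_days)
    fr = fc = 0.0
    phi = 0.85  # day-to-day persistence of the wander around the target
    for day in range(schedule.n_days):
        fr = phi * fr + rng.normal(0.0, schedule.step_sd)
        fc = phi * fc + rng.normal(0.0, schedule.step_sd)
        r0, r1 = bounds[schedule.zones[day]]
        rows[day] = np.clip(target_rows[day] + fr, r0 + 1e-6, r1 - 1e-6)
        cols[day] = np.clip(target_cols[day] + fc, 1e-6, spec.ncols - 1e-6)
    intake = world.isoscape.mean[
        rows.astype(int), cols.astype(int)
    ]
    return pd.DataFrame(
        {
            "day": np.arange(schedule.n_days),
            "row": rows,
            "col": cols,
            "zone": list(schedule.zones),
            "intake_ratio": intake,
        }
    )


# ---------------------------------------------------------------------------
# physiology: blood pool and enamel mineralization

@dataclass(frozen=True)
class EnamelModel:
    """Forward model linking daily blood 87Sr/86Sr to the enamel profile.

    The secretion front moves linearly from the occlusal surface
    (``secretion_start``, oldest enamel) to the enamel-root junction
    (``secretion_end``); enamel at a position then matures over ``t_mat``
    days, incorporating a fraction ``f_fast`` uniformly over the first
    ``d_fast`` days and the remainder along an exponentially decaying tail.
    Blood is an exponential moving average of intake (half-life
    ``blood_half_life`` days) mixed with a constant bone-remodelling
    baseline of weight ``w_bone`` (``bone_ratio`` None = long-run mean
    intake).
    """

    tooth: str
    secretion_start: int
    secretion_end: int
    crown_length: float = 9.0
    blood_half_life: float = 15.0
    w_bone: float = 0.2
    bone_ratio: float | None = None
    f_fast: float = 0.6
    d_fast: int = 7
    t_mat: int = 60

    def __post_init__(self) -> None:
        if self.secretion_end <= self.secretion_start:
            raise ValueError("secretion window must have positive length")
        if not 0 <= self.w_bone < 1:
            raise ValueError("w_bone must be in [0, 1)")
        if not 0 < self.f_fast <= 1 or self.d_fast < 1 or self.t_mat <= self.d_fast:
            raise ValueError("invalid maturation kernel parameters")

    @classmethod
    def for_tooth(cls, tooth: str, **kwargs) -> "EnamelModel":
        windows = {"M2": (105, 270), "M3": (290, 480)}
        if tooth not in windows:
            raise ValueError(f"unknown tooth {tooth!r}")
        start, end = windows[tooth]
        return cls(tooth=tooth, secretion_start=start, secretion_end=end, **kwargs)

    def kernel(self) -> np.ndarray:
        """Maturation weights over day offsets 0..t_mat-1 (sum exactly 1)."""
        w = np.zeros(self.t_mat)
        w[: self.d_fast] = self.f_fast / self.d_fast
        tail = np.arange(self.d_fast, self.t_mat, dtype=float)
        scale = (self.t_mat - self.d_fast) / 3.0
        tw = np.exp(-(tail - self.d_fast) / scale)
        w[self.d_fast :] = (1.0 - self.f_fast) * tw / tw.sum()
        return w


def blood_series(intake: np.ndarray, model: EnamelModel) -> np.ndarray:
    """Daily blood ratio: EMA of intake mixed with the bone baseline.

    ``blood = (1 - w_bone) * ema + w_bone * bone_ratio`` where the EMA has
    half-life ``blood_half_life`` days and is initialized at the first
    intake value.  After a step change the EMA covers half the step on the
    ``blood_half_life``-th day following the step.
    """
    intake = np.asarray(intake, dtype=float)
    alpha = 1.0 - 2.0 ** (-1.0 / model.blood_half_life)
    ema = np.empty_like(intake)
    level = intake[0]
    for t, x in enumerate(intake):
        level = alpha * x + (1.0 - alpha) * level
        ema[t] = level
    bone = model.bone_ratio if model.bone_ratio is not None else float(intake.mean())
    return (1.0 - model.w_bone) * ema + model.w_bone * bone


def enamel_profile(
    blood: np.ndarray,
    model: EnamelModel,
    spacing: float = 0.01,
    individual_id: str = "ideal",
) -> ToothProfile:
    """Ideal (continuous) enamel profile from the daily blood series.

    Position ``x`` mm from the ERJ maps linearly to secretion day
    ``t(x) = secretion_end - (x / crown_length) * window``; the enamel value
    is the maturation-kernel average of blood over ``[t(x), t(x) + t_mat)``.
    Amplitude can never exceed the blood amplitude (weights sum to 1).
    """
    blood = np.asarray(blood, dtype=float)
    if model.secretion_end + model.t_mat > blood.size:
        raise ValueError(
            "blood series does not cover the secretion window plus maturation"
        )
    if model.secretion_start < 0:
        raise ValueError("secretion window starts before the blood series")
    x = np.arange(0.0, model.crown_length + spacing / 2, spacing)
    window = model.secretion_end - model.secretion_start
    t_x = model.secretion_end - (x / model.crown_length) * window
    k = model.kernel()
    days = t_x[:, None] + np.arange(model.t_mat)[None, :]
    vals = np.interp(days.ravel(), np.arange(blood.size), blood).reshape(days.shape)
    enamel = vals @ k
    return ToothProfile(
        individual_id=individual_id, tooth=model.tooth, method="ideal",
        distances=x, ratios=enamel, crown_height=model.crown_length,
    )


# ---------------------------------------------------------------------------
# sampling operators

@dataclass(frozen=True)
class SamplingOperator:
    """Strip (solution) or laser sampling of an ideal enamel profile.

    Strips are ``strip_width`` mm wide through the full enamel thickness;
    depth averaging widens the effective along-axis support by
    ``depth_factor``.  Laser cycles are spaced ``laser_spacing`` mm with a
    near-point surface kernel.  ``noise_sd`` is the per-measurement noise
    (defaults: 3e-5 for strips, 1e-4 for laser cycles).
    """

    kind: str
    strip_width: float = 1.5
    depth_factor: float = 1.5
    laser_spacing: float = 0.021
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("strip", "laser"):
            raise ValueError(f"unknown sampling kind {self.kind!r}")

    @property
    def sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return 3e-5 if self.kind == "strip" else 1e-4


def sample_profile(
    ideal: ToothProfile,
    operator: SamplingOperator,
    seed: int | None = None,
) -> ToothProfile:
    """Apply a sampling operator (with measurement noise) to an ideal profile."""
    rng = np.random.default_rng(seed)
    crown = float(ideal.distances[-1])
    if operator.kind == "strip":
        n = int(crown // operator.strip_width)
        if n < 1:
            raise ValueError("crown shorter than one strip")
        centers = (np.arange(n) + 0.5) * operator.strip_width
        half = operator.strip_width * operator.depth_factor / 2.0
        vals = np.empty(n)
        for i, c in enumerate(centers):
            sel = (ideal.distances >= c - half) & (ideal.distances <= c + half)
            vals[i] = ideal.ratios[sel].mean()
        vals = vals + rng.normal(0.0, operator.sd, n)
        return ToothProfile(
            individual_id=ideal.individual_id, tooth=ideal.tooth,
            method="solution", distances=centers, ratios=vals,
            crown_height=ideal.crown_height,
        )
    xs = np.arange(0.0, crown, operator.laser_spacing)
    vals = np.interp(xs, ideal.distances, ideal.ratios)
    vals = vals + rng.normal(0.0, operator.sd, xs.size)
    return ToothProfile(
        individual_id=ideal.individual_id, tooth=ideal.tooth,
        method="laser", distances=xs, ratios=vals,
        crown_height=ideal.crown_height,
    )


# ---------------------------------------------------------------------------
# end-to-end dataset

def simulate_individual(
    world: SyntheticWorld,
    schedule: MovementSchedule,
    seed: int,
    individual_id: str,
    models: dict[str, EnamelModel] | None = None,
    strip: SamplingOperator | None = None,
    laser: SamplingOperator | None = None,
) -> dict:
    """Simulate one individual: trajectory, blood, and per-tooth profiles.

    Returns ``{"trajectory": frame, "blood": array, "teeth": {tooth:
    {"ideal"|"solution"|"laser": ToothProfile}}}``.
    """
    if models is None:
        models = {t: EnamelModel.for_tooth(t) for t in ("M2", "M3")}
    strip = strip or SamplingOperator("strip")
    laser = laser or SamplingOperator("laser")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    traj_seed, *tooth_seeds = ss.spawn(1 + 2 * len(models))
    traj = simulate_trajectory(schedule, world, seed=traj_seed)
    out: dict = {"trajectory": traj, "teeth": {}}
    intake = traj["intake_ratio"].to_numpy()
    for i, (tooth, model) in enumerate(sorted(models.items())):
        blood = blood_series(intake, model)
        ideal = enamel_profile(blood, model, individual_id=individual_id)
        out["teeth"][tooth] = {
            "ideal": ideal,
            "solution": sample_profile(ideal, strip, seed=tooth_seeds[2 * i]),
            "laser": sample_profile(ideal, laser, seed=tooth_seeds[2 * i + 1]),
        }
        out.setdefault("blood", {})[tooth] = blood
    return out


def make_dataset(
    out_dir: str | Path,
    n_individuals: int = 5,
    n_sedentary: int = 1,
    seed: int = 0,
    spec: SyntheticIsoscapeSpec | None = None,
) -> dict[str, Path]:
    """Write an end-to-end synthetic dataset to ``out_dir``.

    Emits ``profiles.csv`` (solution + laser, both teeth, all individuals),
    ``isoscape_mean.asc`` / ``isoscape_sd.asc``, ``ranges.geojson`` and
    ``truth.csv`` (daily ground-truth locations and intake).  Sedentary
    individuals (the last ``n_sedentary``) stay in the winter range.
    Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticIsoscapeSpec()
    ss = np.random.SeedSequence(seed)
    iso_seed, *ind_seeds = ss.spawn(1 + n_individuals)
    world = generate_isoscape(spec, seed=iso_seed)
    profiles = []
    truth_frames = []
    for i in range(n_individuals):
        sedentary = i >= n_individuals - n_sedentary
        ind_id = f"SIM-{i + 1:03d}{'S' if sedentary else 'M'}"
        schedule = (
            MovementSchedule.sedentary_in()
            if sedentary
            else MovementSchedule.migratory()
        )
        sim = simulate_individual(world, schedule, ind_seeds[i], ind_id)
        for tooth_data in sim["teeth"].values():
            profiles.extend([tooth_data["solution"], tooth_data["laser"]])
        tf = sim["trajectory"].copy()
        tf.insert(0, "individual_id", ind_id)
        tf["sedentary"] = sedentary
        truth_frames.append(tf)
    paths = {
        "profiles": out_dir / "profiles.csv",
        "isoscape_mean": out_dir / "isoscape_mean.asc",
        "isoscape_sd": out_dir / "isoscape_sd.asc",
        "ranges": out_dir / "ranges.geojson",
        "truth": out_dir / "truth.csv",
    }
    write_profiles(profiles, paths["profiles"])
    write_isoscape(world.isoscape, paths["isoscape_mean"], paths["isoscape_sd"])
    write_ranges(list(world.ranges.values()), paths["ranges"])
    pd.concat(truth_frames, ignore_index=True).to_csv(paths["truth"], index=False)
    return paths
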