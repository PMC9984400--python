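# toothtrace

Analysis of sequential ⁸⁷Sr/⁸⁶Sr measurements from ungulate tooth enamel to
infer seasonal movements — for isotope ecologists, archaeologists and
palaeoecologists working with intra-tooth transects from migratory animals.

Tooth enamel mineralizes incrementally from the crown cusp to the
enamel–root junction and never remodels, so a transect of ⁸⁷Sr/⁸⁶Sr
measurements along the growth axis is a time series of where an animal fed
during its first years. `toothtrace` covers the full chain from raw
measurements to geographic inference:

* **reduction** — LA-MC-ICP-MS cycle reduction: gas-blank (Kr) subtraction,
  ⁸⁷Rb isobaric correction via the natural ⁸⁷Rb/⁸⁵Rb, exponential-law mass
  bias normalization to ⁸⁸Sr/⁸⁶Sr = 8.375209, ⁸⁴Sr/⁸⁶Sr quality control,
  and SRM987 session normalization for solution data;
* **profiles** — intra-tooth profile containers, 20-point running
  mean/SD smoothing, median/min/max/amplitude summaries, and seasonal
  endmember extraction (M2: occlusal = late summer/autumn, cervical =
  winter; M3 reversed);
* **compare** — paired Wilcoxon signed-rank tests (zeros dropped, midranks,
  tie-corrected variance `m(m+1)(2m+1)/24 − Σ(t³−t)/48`, no continuity
  correction), group means ± SD, and the damping regression of amplitude
  difference on laser amplitude;
* **assign** — Bayesian geographic assignment against a gridded isoscape:
  per-cell likelihood `N(r; μ_i, √(σ_i² + s²))`, flat prior, posterior
  rescaled to 1; top-20% assignment regions, region overlap, and seasonal
  odds ratios `P(summer range) / P(winter range)` with optional bootstrap
  CIs — exposed as a `SrAssignmentModel.fit() → SrAssignmentResults`
  pair with a `summary()` table;
* **synthetic** — a forward model (three-zone isoscape, migratory random
  walk, blood pool with bone baseline, enamel maturation kernel, strip vs
  laser sampling operators) generating fully ground-truthed datasets.

File formats are plain text throughout: CSV for cycles/profiles/tables,
ESRI ASCII grids for rasters, GeoJSON for range polygons.

## Worked example

Ten teeth (M2 + M3 of five migratory caribou) were measured with both strip
sampling and laser ablation; the per-tooth summary tables ship with the
package. Is the laser signal less damped?

```python
from toothtrace.datasets import profile_summaries
from toothtrace.compare import wilcoxon_signed_rank, group_mean_sd

t = profile_summaries()
res = wilcoxon_signed_rank((t.sol_amplitude - t.las_amplitude).to_numpy())
print(f"laser amplitude mean = {group_mean_sd(t.las_amplitude)[0]:.4f}")
print(f"solution amplitude mean = {group_mean_sd(t.sol_amplitude)[0]:.4f}")
print(f"Wilcoxon: n_nonzero={res.n_nonzero}, W+={res.w_plus}, "
      f"Z={res.z:.2f}, p={res.p_two_sided:.4f}")
```

```
laser amplitude mean = 0.0019
solution amplitude mean = 0.0009
Wilcoxon: n_nonzero=9, W+=0.0, Z=-2.67, p=0.0076
```

Laser profiles carry roughly twice the seasonal amplitude of the strip
profiles of the same teeth (Z = −2.67: in nine of ten teeth with unequal
amplitudes the laser amplitude is larger) — the strip's larger sampling
volume averages away part of the seasonal signal.

Simulate a migratory individual and assign its winter endmember:

```python
from toothtrace.synthetic import (SyntheticIsoscapeSpec, generate_isoscape,
                                  MovementSchedule, simulate_individual)
from toothtrace.profiles import extract_endmembers
from toothtrace.assign import SrAssignmentModel

world = generate_isoscape(SyntheticIsoscapeSpec(), seed=1)
sim = simulate_individual(world, MovementSchedule.migratory(), 0, "demo")
em = extract_endmembers(sim["teeth"]["M2"]["laser"])
print(f"M2 laser endmembers: OS={em.os_value:.4f} ({em.os_season}), "
      f"ERJ={em.erj_value:.4f} ({em.erj_season})")

model = SrAssignmentModel(world.isoscape, summer=world.ranges["summer"],
                          winter=world.ranges["winter"], analytical_sd=1e-4)
fit = model.fit(em.value_for("winter"), q=0.20, n_boot=500, seed=42)
print(fit.summary().to_string(index=False))
```

```
M2 laser endmembers: OS=0.7111 (summer), ERJ=0.7100 (winter)
 sample_ratio  analytical_sd   q  region_cells  max_posterior  odds_ratio   ci_low  ci_high assigned_range
     0.709953         0.0001 0.2           240       0.003597    0.066852 0.057855 0.077659         winter
```

The winter-formed endmember of the simulated tooth assigns to the winter
range with odds ≈ 0.07 (posterior mass 15× higher in the winter range than
the summer range), and the bootstrap CI stays well below 1.

A command-line interface mirrors the library
(`toothtrace reduce | profile-stats | compare | assign | simulate | run`);
`toothtrace run --config run.yaml` executes the whole pipeline and writes a
manifest with every parameter and seed used.

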