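# Methods

`toothtrace` analyses sequential strontium-isotope measurements from ungulate
tooth enamel to infer seasonal movements between geographically distinct
ranges, and provides a forward model of the whole measurement chain so that
every analysis stage can be exercised on data with known ground truth.

## Scientific setting

Bioavailable ⁸⁷Sr/⁸⁶Sr varies across a landscape with the age and chemistry
of the underlying lithology and passes essentially unfractionated from soil
through diet into skeletal tissue. Tooth enamel mineralizes incrementally
from the crown cusp (occlusal surface, OS) toward the enamel–root junction
(ERJ) and never remodels, so a transect of measurements along the growth
axis is a time series of early-life residence. In a migratory ungulate
whose summer and winter ranges differ in bioavailable ⁸⁷Sr/⁸⁶Sr, the
intra-tooth profile records the seasonal round trip; the two crown termini
("endmembers") anchor the two seasons. In the second molar the occlusal
end forms in late summer/autumn and the cervical end in winter; the third
molar, forming later, is oriented the opposite way.

Two sampling strategies are compared throughout. Strip (solution) sampling
cuts ~1.5 mm bands through the full enamel thickness, dissolves them, and
measures purified Sr; laser ablation (LA-MC-ICP-MS) reads a ~21 µm-pitch
transect in situ. Both see a signal already attenuated by physiology
(blood-pool mixing, bone-remodelling baseline, protracted enamel
maturation); the strip's much larger averaging volume attenuates it
further. The package quantifies that differential damping and carries the
endmembers into a probabilistic geographic assignment.

## Laser data reduction

Raw cycles carry beam intensities at masses 84–88. The reduction sequence
is: (1) gas-blank subtraction — the mean blank spectrum (Kr contribution)
is removed, with negatives clipped to zero and counted; (2) isobaric
correction of mass 87 for ⁸⁷Rb using the natural ⁸⁷Rb/⁸⁵Rb = 0.38571 and
the Sr mass-bias factor; (3) exponential-law normalization to
⁸⁸Sr/⁸⁶Sr = 8.375209.

The exponential law is written `R_true = R_meas · (m_a/m_b)^β`, with β
solved from the measured ⁸⁸Sr/⁸⁶Sr. Note the sign convention: because β is
defined on the *true-from-measured* direction, the *measured* Rb
interference predicted from the measured ⁸⁵Rb beam carries
`(m87Rb/m85Rb)^(−β)`. Under this single convention, forward-simulating
beams from any (true ratio, β, Rb level, blank level) and reducing recovers
the truth to machine precision; the test suite verifies ≤1e-8 relative
error over a parameter grid spanning β ∈ [−2, 2] and Rb beams up to 2 mV.

Quality control follows the invariant ⁸⁴Sr/⁸⁶Sr = 0.0565: a cycle passes
when its corrected ⁸⁴Sr/⁸⁶Sr is within a configurable tolerance (default
0.012, ≈3× a typical per-cycle SD of 0.004) and its ⁸⁷Sr/⁸⁶Sr is
biologically plausible (0.69–0.75). Solution data are normalized to the
session SRM987 by an additive offset (`accepted − measured`, accepted
0.710240).

## Profiles, smoothing, endmembers

Profiles are ordered by distance from the ERJ in mm. Laser transects are
smoothed with a 20-point centred running mean (and running SD) before
summary statistics; at the edges the centred span truncates to the
available points, never fewer than half the window. Summaries are median,
min, max and amplitude (= max − min), computed on the smoothed series for
laser profiles and on the raw strip values for solution profiles (the
choice for laser data is a documented assumption: plotted profiles are the
running average, and single cycles are too noisy to define extrema).
Values are reported at 4 decimals; computation keeps full precision.

Endmembers are the samples closest to each terminus: for strips, the first
and last strip values; for laser transects, the mean of the 20 raw cycles
nearest each terminus (the running-average value evaluated at the end
point). Season labels are fixed by tooth identity as above.

## Comparison statistics

Solution and laser metrics are compared per tooth with the Wilcoxon
signed-rank test under one fixed convention: differences oriented
solution − laser, zero differences dropped, midranks for tied absolute
differences, tie-corrected variance
`m(m+1)(2m+1)/24 − Σ(t³−t)/48`, no continuity correction, two-sided normal
p. This convention reproduces the published Z = −2.67 (profile amplitudes)
and Z = −2.2 (endmember amplitudes) exactly from the bundled ten-teeth
tables; a continuity-correction switch exists (and is what the exact
sign-flip enumeration test uses, since the corrected p tracks the discrete
permutation distribution better) but no claim is made to reproduce the
published minima/maxima statistics, which appear to follow a different
convention. Group summaries are means ± sample SD (n−1). The damping
signature is the Pearson correlation between per-tooth amplitude
difference (laser − solution) and laser amplitude; on the bundled tables
R² = 0.81.

## Bayesian geographic assignment

For a sample ratio `r` with analytical SD `s`, each valid isoscape cell
with mean μ_i and error SD σ_i gets likelihood `N(r; μ_i, √(σ_i²+s²))`.
With a flat prior over valid cells, the posterior is the likelihood
rescaled to sum to 1. Likelihoods are evaluated in the log domain and
normalized by max-subtraction, so samples tens of SDs from every cell
still produce a proper surface.

The assignment region is the top 20% (configurable q) of study-area cells
by posterior probability, selected by cell count (`⌈q·N⌉`), with cells tied
exactly at the threshold all included; the grid is treated as equal-area (a
documented simplification). Overlap between two regions is
`|A∩B|/|A| × 100` with the first region as denominator — symmetric in the
nominal tie-free case. Seasonal inference uses the odds ratio: summed
posterior over cells whose centres fall in the summer-range polygon divided
by that of the winter range; a centre covered by both polygons counts
toward the first (summer). Odds ratio > 1 reads "summer range". An
optional nonparametric bootstrap over cells gives a percentile 95% CI; a CI
spanning 1 is reported NS. The bootstrap is this package's own uncertainty
device, not a re-implementation of any published CI.

Rasters are exchanged as ESRI ASCII grids (mean and error surfaces in
separate files) and range polygons as GeoJSON; both are plain text and
GIS-portable.

## Synthetic forward model

The generator emulates the study system at the level needed to test the
pipeline, not to mimic Alaska. Its defaults are the package's fixed study
conditions.

**Isoscape.** A 40×30 grid split into three latitudinal zones: summer
range in the north (mean 0.7115), mountain band (0.7135, the highest
values), winter range in the south (0.7095). Spatially correlated noise
(Gaussian, SD 2.5e-4, correlation length 3 cells) is added to the zone
means; the per-cell error surface is a constant 5e-4. The noise SD keeps
within-range heterogeneity small relative to the ~2e-3 between-range
contrast — the regime a seasonal-assignment experiment targets; the
generated field stays inside the observed bioavailable extremes
(0.7062–0.7271). Summer/winter range polygons are the zone rectangles.

**Movement.** Day 0 is calving (~1 June; months are 30 days). Migratory
schedules occupy the summer range from birth, cross the mountain band on
days 165–195 (autumn), winter until the spring crossing (days 320–350),
summer again, and start a second autumn crossing on day 470. Within a
zone the animal performs a mean-reverting random walk (step SD 0.5 cells)
around a home centre drawn once per zone; during crossings the centre
sweeps linearly across the band. Sedentary animals stay in the winter
range throughout. Daily intake is the isoscape mean at the occupied cell.

**Physiology.** Blood is an exponential moving average of intake
(half-life 15 d) mixed with a constant bone-remodelling baseline (weight
0.2, default value = long-run mean intake). Enamel at position x maps
linearly to a secretion day (M2: days 105–270; M3: days 290–480 over a
9 mm crown) and then averages blood over the following 60 days with a
maturation kernel: 60% of the mineral deposited uniformly over the first
7 days, the rest along an exponential tail. The M3 window is shorter than
the nominal "9 to <18 months" because observed third-molar profiles carry
a single seasonal transition, consistent with a contracted effective
recording window. All kernel parameters are configurable; none is claimed
as the true *Rangifer* value — mineralization timing in this genus is not
quantitatively characterised.

Two consequences of this model shaped the defaults. First, the maturation
kernel delays and smears the recorded signal by ~10–25 days, so migration
windows are placed late enough that the mountain-band excursion stays
interior to the crown for both sampling supports. Second, amplitude
ordering between sampling modes is only resolvable where a crown terminus
sits on a transient rather than a long plateau; since individual teeth can
be plateau-limited, replicate-level comparisons use the mean endmember
amplitude over an individual's two teeth.

**Sampling.** The strip operator takes non-overlapping 1.5 mm boxcar means
(six strips on a 9 mm crown) with the effective along-axis support widened
by a depth-averaging factor of 1.5 (deeper enamel matures later, so a
full-thickness strip integrates a longer maturation span); measurement
noise SD 3e-5. The laser operator reads every 21 µm with a near-point
kernel and per-cycle noise SD 1e-4 (a 20-cycle running mean then has
SE ≈ 2e-5, of the order of a good in-run external reproducibility).

**What the generator does not emulate.** Real 2-D enamel geometry, wear of
the occlusal surface, variable crown heights, diet-dependent Sr
concentration weighting, anthropogenic isoscape distortion, and
individual variation in migration timing. Passing tests therefore show
that the pipeline's logic is correct under a faithful signal-chain
abstraction — not that the specific Alaskan assignments are reproduced;
those depend on an external isoscape raster and are out of scope.

## Numerical choices and degenerate inputs

* Posterior surfaces must sum to 1 within 1e-9; this is asserted on
  construction.
* Ties at the top-fraction threshold are all included (a uniform surface
  selects every cell); the threshold used is recorded.
* Zero-difference Wilcoxon inputs raise rather than silently degenerate;
  fewer than 3 pairs, empty profiles, windows longer than profiles,
  crowns shorter than one strip, and blank-free scans are all errors.
* Gas-blank subtraction clips negative beams to zero and reports the
  count; Rb over-correction clips and flags the cycle as QC-failed.
* Sub-seeds for individuals and per-tooth noise derive deterministically
  from one `SeedSequence`, so datasets are byte-reproducible per seed.

## Problem sizes

Stochastic checks use 100 migratory and 20 sedentary individuals for the
damping ordering, 50 individuals (200 endmember assignments) for
seasonal-range recovery, and a 75-point parameter grid for the reduction
round trip; these sizes give the binomial head-room the properties are
stated with while keeping a full run in seconds.

## Known limitations

* The top-fraction region is counted in cells, not geodesic area.
* The overlap denominator convention matters when threshold ties inflate
  one region.
* The bootstrap CI treats cells as exchangeable and ignores spatial
  autocorrelation of the posterior.
* The forward model's linear secretion front and single-exponential
  maturation tail are first-order abstractions; published maturation
  geometries are more complex and species-specific.
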