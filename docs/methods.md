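# Methods

`nlbench` is a ground-truth benchmark for EEG source localization: it
simulates dipolar brain activity with known positions, projects it to the
scalp through an analytic head model, embeds it in resting-EEG-like
noise, localizes it with four inverse solvers written from scratch, and
scores every solver against the known truth. This note records the
models, the parameter choices that matter, and the places where the
design was genuinely open.

## Forward model

The head is a concentric three-shell spherical conductor — brain, skull,
scalp — with default radii 80 / 85 / 92 mm and conductivities 0.33 /
0.0042 / 0.33 S/m (the classical ~1:80 skull-to-tissue ratio). For each
Legendre order `n` the radial transfer coefficient of the shell stack is
obtained by solving the five interface conditions (potential and radial
current continuity at both internal boundaries, zero current through the
scalp) with radii normalized by the scalp radius so that powers up to
`n = 200` stay in floating-point range. A radial unit dipole at
eccentricity `b` produces the scalp potential

    V(theta) = 1/(4 pi sigma_1 R^2) * sum_n  n t_n (b/R)^(n-1) P_n(cos theta),

truncated when the largest term falls below 1e-10 of the accumulated
scale (reached near n ≈ 100 for the deepest grid voxels; failure to
converge raises). With equal conductivities `t_n = (2n+1)/n`, the
homogeneous-sphere closed form, which the test suite uses as an
independent oracle. Columns are average-referenced, matching the
recording convention the solvers assume. Units: mm, nA·m, microvolt.

The spherical substitution (rather than a template-anatomy boundary
element model) keeps the package self-contained; it preserves what the
benchmark actually measures — depth, SNR and correlation phenomenology —
but absolute localization errors on real anatomy will differ.

Sensors come from a named standard montage (`biosemi64` by default,
resolved through the layouts bundled with `mne`), a user TSV
(`label, x, y, z` in mm), or a procedural quasi-uniform cap
(`synthetic<N>`); every electrode is projected radially onto the scalp
sphere. The source grid is a Cartesian lattice (default 5 mm) clipped to
90% of the brain radius, with radial orientations and a left/right split
at x = 0 (x = 0 assigned left).

## Synthetic signals

* **Steady-state oscillation**: `q(t) = sin(2 pi 40 t + phi) + eps`,
  `eps ~ N(0, sigma^2)` with `sigma = 0` by default (noise enters through
  the baseline instead; `sigma` is overridable).
* **Transient (ERP-like) response**: a mixture of Gaussian pulses,
  default a negative pulse (amplitude −1, center 110 ms, width 20 ms, an
  N100-like deflection) and a positive pulse (+0.6, 400 ms, 40 ms). The
  exact mixture parameters are not pinned down by any published value,
  so they are configurable rather than asserted.

Dipole configurations: `single` (left auditory-cortex seed, (−60, −28, 6)
mm), `two_point` (plus right seed (64, −24, 6)), `distributed` (up to 100
grid dipoles within 12 mm of each seed; on the 5 mm lattice an interior
ball holds ~57, and near the grid boundary the ball is truncated). All
members of a distributed cluster share the seed waveform — intra-cluster
jitter is not simulated, since nothing pins its magnitude down.
Left-hemisphere sources always carry zero lag; right-hemisphere sources
carry the requested phase lag (sinusoids) or time lag (pulses).

## Baseline noise

Real resting EEG is emulated with 500 grid dipoles drawn uniformly over
the source volume, each carrying `1/f^alpha` Gaussian noise
(`alpha = 1`) with a narrowband alpha-band excess (Gaussian bump at
10 Hz, width 1.5 Hz, power gain 3), forward-projected through the same
lead field. Each epoch draws fresh noise; everything is deterministic
under the seed. What this surrogate does *not* emulate: spatial
clustering of resting-state generators, non-stationarity, ocular/muscle
artifacts, and sensor noise. Passing benchmarks on this noise therefore
demonstrate solver correctness and relative method behavior, not
performance on recorded EEG.

By default the task epochs reuse the same baseline noise realization
(task = baseline + scaled signal), mirroring a design in which simulated
signals are added onto one acquired baseline recording;
`independent_noise=True` draws fresh task noise.

## Signal level

Two level controls:

* **SNR in dB** (transient arm): `SNR = 10 log10(mean_u <v_u^2>/eta_u^2)`
  with `eta_u^2` the per-sensor baseline variance. Scaling the source by
  `k` adds `20 log10 k`, so the target (19, 22, 25, 28 or 31 dB; 25 dB
  treated as physiological) is met in closed form to < 0.01 dB.
* **40 Hz power ratio** (steady-state arm): the sinusoid is scaled so its
  sensor-averaged 40 Hz periodogram power is `ratio` times a
  physiological reference, with ratios 0.5–1.5. The reference is 10× the
  baseline's own 40 Hz power: an auditory steady-state response stands
  roughly an order of magnitude above the resting spectrum at its driving
  frequency, so ratio 1.0 is a realistic oscillation, not an arbitrary
  amplitude. This choice matters: tying ratio 1.0 to the 25 dB broadband
  SNR instead would put the single 40 Hz bin ~1e7× above the noise floor,
  making bilateral sources perfectly coherent at the analysis frequency
  and collapsing the beamformers by source cancellation at every lag.

## Inverse solvers

All four are scalar (fixed radial orientation) solvers, matching the
simulation's radial dipoles.

* **LCMV**: `w = l' C^-1 / (l' C^-1 l)` on the task covariance; per-voxel
  value `w C_task w' − w C_baseline w'`. Unit gain `w·l = 1` holds at
  every valid voxel; voxels with non-positive `l' C^-1 l` are flagged
  invalid and excluded downstream.
* **DICS**: the same construction on the complex cross-spectral density
  at 40 Hz (multitaper, 2 Slepian tapers, time-bandwidth 1.5,
  demodulation at exactly 40 Hz), taking real parts of the quadratic
  forms. On a real-valued matrix DICS reduces to LCMV identically.
* **eLORETA**: the standard fixed-point iteration
  `w_i <- sqrt(l_i' M l_i)`, `M = pinv(L W^-1 L' + a s H)` with `H` the
  average-reference centering matrix (`a = 0` default; tolerance 1e-6 on
  the relative weight change, max 100 iterations, non-convergence
  raises). The filter row is `l_i' M / w_i`; Cauchy–Schwarz in the
  M-metric then gives the exact zero-localization-error property for
  noise-free point sources, which the tests assert directly. Weights are
  data-independent and cached per lead field.
* **MNE**: `q = R L' (L R L' + lambda^2 C)^-1 v` with `R = I` (no depth
  weighting) and `lambda = 0` by default, computed via pseudo-inverse;
  the per-voxel value is the mean squared current density over the
  analysis window. Unweighted minimum norm has the textbook radial bias:
  its amplitude peak for a deep point source sits several mm superficial
  of the truth (exactness holds only on the outermost source shell), and
  the benchmark reports this honestly rather than adding depth weighting.

### Numerical rank and regularization

Zero regularization on average-referenced data means every inversion runs
through a truncated-eigenvalue pseudo-inverse. Two tolerances are used,
and the distinction is load-bearing:

* deterministic lead-field grams (eLORETA, MNE): eigenvalues below
  **1e-10** of the maximum are discarded — essentially only the
  average-reference null direction;
* estimated covariance/CSD matrices (LCMV, DICS): eigenvalues below
  **1e-6** of the maximum are discarded. A CSD estimated from 30 epochs ×
  2 tapers has rank 60 in 63 average-referenced dimensions, and its
  smallest retained sample eigenvalues sit around 1e-8 of the maximum —
  pure sampling noise. Inverting them produces filters with norms in the
  thousands and occasional sign-flipped contrasts; the looser cutoff is a
  rank-aware truncation of estimated statistics, which is the reason a
  pseudo-inverse is prescribed in the first place.

Diagonal loading (`reg` as a fraction of the mean sensor power) is
available but off by default.

### Task-baseline contrast

The `contrast_power` operation implements both conventions: absolute
difference for beamformers and relative change
`(task − baseline)/baseline` for the current-density methods, as an
empirical analysis without ground truth would use. The simulation
benchmark, however, scores the **power-difference** map for all four
methods. The reason is a property of synthetic baselines: the argmax of
the relative contrast is independent of signal strength and locks onto
the spatial structure of the synthetic noise floor in the denominator,
displacing eLORETA/MNE peaks by 10–20 mm even at the highest SNR, while
the same estimates' difference maps peak at the true voxel. The
`contrast="relative"` switch restores the ratio form.

## Evaluation

Per estimate: z-score voxel values within each hemisphere (population
SD); keep voxels at or above the 99.99th percentile of their hemisphere's
z values (the hemisphere maximum always survives; the threshold is
configurable — an alternative convention of "top 0.05%" maps to
percentile 99.95); k-means-cluster the surviving locations per
hemisphere, selecting k in {1..5} by silhouette with fixed-seed restarts
(k = 1 when the best silhouette is below 0.6) — a reproducible surrogate
for visual cluster counting; identify the cluster whose centroid is
nearest each true seed.

Metrics: localization error = distance from the nearest cluster's peak-z
voxel to the seed (summed over seed hemispheres for bilateral truths;
per-seed values are also kept); focal width = mean member-to-peak
distance (headline) and the raw sum; FP% = significant voxels outside
the nearest cluster(s) over all significant voxels (pooled globally
across seed hemispheres); hit rate = nearest-cluster members within
15 mm of their seed. Only hemispheres containing a true seed enter the
totals — thresholding always promotes each hemisphere's maximum, so a
source-free hemisphere would otherwise contribute a guaranteed spurious
cluster and force FP% ≥ 50% for single-dipole runs.

## Benchmark sweeps and problem sizes

Sweeps use 30 task + 30 baseline epochs per dataset at 1 kHz — 5 s epochs
for the steady-state arm (band-passed 5–48 Hz before the CSD), 1 s for
the transient arm (the ±25 ms analysis window is centered on the
global-field-power peak of the evoked response). The frequency sweep
crosses power ratios × phase lags {0, π/2, π, 3π/2}; the time sweep
crosses SNRs × time lags {0, 15, 30, 45} ms; the depth sweep moves the
distributed clusters 0–20 mm inward along x in 1 mm steps at the
physiological level with zero lag (right-hemisphere track x = 60 → 40 at
y = −24, z = 6, mirroring the left track's printed endpoints). Default
5 replicates per cell with per-cell seeds derived from the master seed;
results are byte-identical under a fixed master seed. `scripts/
acceptance.py` uses 5 replicates for the single-dipole sweep, 1 for the
SNR × lag design and 3 for the depth sweep, sizes chosen to keep the full
recomputation in the tens of minutes on one core.

## Known limitations

* Fully phase-locked bilateral sinusoids are perfectly coherent at the
  analysis frequency at *every* fixed phase lag, so the beamformers
  suffer correlated-source cancellation in the two-point and distributed
  40 Hz conditions (errors of many cm while eLORETA stays within ~1 cm).
  A control with incoherent bilateral sources confirms DICS localizes
  both to the grid floor, isolating coherence as the cause. Depth-sweep
  results for DICS (which runs phase-locked) inherit this variability.
* The spherical head and surrogate noise bound external validity, as
  above.
* Unweighted MNE's superficial bias is reported, not corrected.
* k-selection by silhouette at threshold 0.6 is conservative for weakly
  separated clusters; with the extreme 99.99th-percentile threshold,
  significant sets are small and usually form a single cluster per
  hemisphere.
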