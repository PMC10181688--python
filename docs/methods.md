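# Methods

This note records the modelling assumptions, default parameters, numerical
choices and known limitations of `nirsconn`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal chain

**Optical density.** ΔOD_k(t) = −ln(I_k(t)/Ī_k) with Ī_k the channel's
temporal mean. Natural logarithm throughout. Mean-referencing makes the
conversion invariant to source power and detector gain, at the cost of
absorbing any DC concentration component — irrelevant for connectivity,
which operates on band-passed fluctuations.

**Modified Beer–Lambert law.** Per source–detector pair, the two-wavelength
system ΔOD_λ = (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR)·d·DPF_λ is solved exactly at
every sample. Defaults (overridable via `MbllConfig`):

| parameter | default | unit | note |
|---|---|---|---|
| ε(760 nm) HbO / HbR | 1.4866 / 3.8437 | mM⁻¹cm⁻¹ | standard CW-fNIRS table |
| ε(850 nm) HbO / HbR | 2.5264 / 1.7986 | mM⁻¹cm⁻¹ | |
| DPF | 6.0 | — | both wavelengths |
| d | from probe coordinates | cm assumed | output then in µM |

Coordinates are taken from the file as-is; only the source–detector
distance and relative cluster geometry matter, so no unit conversion is
attempted. The forward model (`mbll_forward`) is the exact inverse and is
used by the simulator and the round-trip tests (max relative error
~1e-15).

**Band-pass filter.** Linear-phase FIR, order 71 (72 symmetric taps),
windowed-sinc design with a Hamming window, band 0.010–0.400 Hz at
fs = 10.2 Hz, applied forward–backward (`filtfilt`, reflection padding), so
the net phase response is identically zero. Zero-phase application is the
single most consequential preprocessing choice: a one-directional FIR pass
would delay every channel by 35.5 samples (~3.5 s) and corrupt every lagged
regression. With 72 taps the achievable transition width (~0.47 Hz) is far
wider than the 0.01 Hz lower edge, so the low-frequency roll-off is gentle
while the upper stopband is deep (≈92 dB single-pass at 2 Hz, measured by
the acceptance script). Whether filtering happens before or after MBLL is
switchable (`filter_domain`); both orders commute in exact arithmetic
because MBLL is linear and time-invariant, and the default filters the
hemoglobin series.

**Filtering vs. lag-1 inference.** Band-passing to ≤0.4 Hz at a 10.2 Hz
sampling rate concentrates nearly all signal energy far below Nyquist, so
successive samples become extremely correlated regardless of the underlying
dynamics. The test suite measures the consequence: fitting a VAR(1) to
band-passed VAR(1) data drives the coefficient matrix toward the identity,
and the Wald test for condition deltas rejects true-zero deltas at a rate
far above the nominal α (≈0.6–0.8 at α=0.05 in the measured configuration)
because the residuals are strongly colored. This is a property of the
method as published, not of this implementation; the parameter-recovery and
calibration validations therefore run at the region level (on the
generative model the estimator actually assumes), and the filtered-path
behaviour is asserted by its own test so the distortion stays visible.
Users who need calibrated lag-domain inference on filtered data should
either widen the band, decimate to match the band, or use spectral
(coherence-based) estimators — all outside this package's scope.

## Low-rank projection

Channels are clustered once per montage by their 3D midpoint coordinates:
Euclidean K-means, `n_init=10` random restarts under one seed, best inertia
kept, bit-reproducible given the seed. Default M = 6 clusters, matching
three regions of interest (motoric, somatosensory, temporal) per
hemisphere; exposed as `--clusters`. Each cluster is summarised by its
per-sample median (mid-pair average for even sizes). The mean summary is
provided for comparison. The robustness contract — corrupting fewer than
half a cluster's channels leaves the median within the clean members'
spread, while the mean shifts by (corrupted/size)·offset exactly — is
property-tested. One quantified caveat: with one systematically one-sided
outlier among five channels the median becomes the upper-middle order
statistic of the four clean channels, which inflates its noise-floor error
by a scale-free factor ≈1.2 (still ~1% of the signal SD in the default
configuration, versus a 20-SD bias for the mean). ROI labels, when a
channel→ROI table is supplied, are assigned per cluster by channel
majority, ties toward the earliest-seen ROI.

## Condition-driven VAR

One design matrix stacks all runs: a baseline lag block active everywhere
plus one delta block per non-baseline condition, active only for that
condition's rows (indicators are constant within a run; lagged predictors
never straddle runs). The design is saturated, so the joint OLS baseline
block equals a VAR fit on baseline data alone, exactly (tested), and K=0
reduces to an ordinary VAR(1) identical to `statsmodels`' estimate
(tested to 1e-8).

- VAR order p defaults to 1. Higher p is supported; for long-lag models a
  frequency-domain estimator (partially directed coherence) is the better
  tool and is deliberately not provided.
- Residual covariance uses the n−q degrees-of-freedom correction;
  coefficient covariance is the Kronecker form Σ_ε ⊗ (XᵀX)⁻¹ (the
  per-equation and joint forms coincide for a shared design).
- z = estimate/SE referred to the standard normal; two-sided p-values. Zero
  SEs yield NaN p-values plus a warning, never a silent 0/1.
- No multiple-testing correction by default; Benjamini–Hochberg step-up
  behind `correction="bh"` (cross-checked against an independent
  implementation in the tests).
- Rank-deficient designs (a condition with no data, a constant channel)
  raise a `SingularDesignError` naming the collinear columns. Fewer than
  10·q observations per equation triggers a small-sample warning.
- The companion spectral radius of Φ̂₀ and of each Φ̂₀+Φ̂_k is reported with
  every fit; ≥1 warns of non-stationarity.

**Epoching.** By default only task blocks are fitted: each run is cut at
its event markers, blocks truncated to the shortest, and either averaged
across trials (`per_trial=False`, the default, mirroring estimation on the
trial-mean signal) or stacked as separate runs (`per_trial=True`). Trial
averaging of four 22 s blocks at 10.2 Hz leaves ~223 observations — enough
for M=6, q=30 without a warning, but small; the per-trial mode quadruples
the sample at the cost of averaging away no noise. Initial/final and
inter-block rests are excluded unless `include_rest=True`.

## Connectivity maps

One map per condition: the baseline map thresholds Φ̂₀, condition maps
threshold the deltas Φ̂_k — matching the model's parameterisation, where
per-condition inference exists only for the deltas. `absolute=True` renders
Φ̂₀+Φ̂_k edge weights instead (same delta p-values). Self-loops are kept but
separable from cross-region edges. Hemisphere tags come from the sign of
the centroid's x coordinate (configurable axis; exact zero → "midline",
counted separately in the inter/intra summary). Exports: CSV edge list,
GraphML with weight/z/p attributes, JSON, and an optional scatter-plus-
arrows quick-look figure (no interpolated topography).

## Synthetic experiments

The generator emulates the structure of a footwear/walking block design:

- **Coefficients** (`make_ground_truth`): baseline self-coupling 0.3 on the
  diagonal; a `sparsity` fraction (default 0.2) of off-diagonal entries at
  ±`effect_size` (default 0.4); per-condition deltas of the same count
  placed preferentially on entries the baseline leaves free; everything
  rescaled until every condition's companion spectral radius is < 0.95.
- **Paradigm** (`ParadigmSpec`): 17 s initial/final rests, 22 s task
  blocks, 10 s inter-block rests, 4 trials, fs 10.2 Hz → 152 s, 1550
  samples per run; one run per condition, 5 conditions by default.
- **Task gating**: VAR dynamics are multiplied by a block envelope (boxcar
  default, or a peak-normalised canonical double-gamma HRF convolution);
  rests carry low-amplitude white noise. The gating is a generator choice —
  real data's generative process is unknown — and is configurable.
- **Channel layer**: each region spawns 5 channels jittered around an
  anchor on a 10 cm sphere (jitter SD = min anchor distance / 20, so
  K-means recovers the partition by construction), carrying the regional
  signal (scaled to 1 µM) plus independent Gaussian noise (SD 0.1 µM);
  HbR = −0.3·HbO plus noise; optional outlier channels receive a constant
  offset. The forward Beer–Lambert model then produces two-wavelength
  intensities, so the simulator's files exercise the identical code path as
  real SNIRF recordings.
- **Innovations**: Gaussian by default; unit-variance Student-t
  (configurable df) to stress the median-vs-mean comparison.
- All generators are pure functions of their seeds; SNIRF output is
  byte-identical across reruns.

What the simulator does *not* emulate: physiological nuisance rhythms
(Mayer waves, cardiac, respiration), motion artifacts, scalp/short-channel
contamination, or inter-subject variability. Passing the validation suite
therefore demonstrates correctness of the estimator under its own model
assumptions — not robustness to every failure mode of real walking data.

## Validation problem sizes

The packaged validation runs at sizes chosen to make the statistical
properties measurable while keeping the whole suite quick on a single CPU:
coefficient recovery over 20 replicates at T ∈ {200, 1000, 5000} per
condition; null calibration over 500 replicates at T = 1000 (type-I error
of the 144 delta coefficients within [0.03, 0.07] at α = 0.05);
bidirectional-pair recovery over 100 replicates at T = 5000; oracle
comparisons on ten M = 3 instances. The acceptance script uses the same
conditions with 10/200/50 replicates respectively and reports every
measured quantity.

## Known limitations

- Wald inference assumes white innovations; it is calibrated at the region
  level and demonstrably anti-conservative after heavy band-passing (see
  above).
- Trial-averaged estimation treats the average as one realisation of the
  VAR; condition-level inference inherits whatever non-stationarity
  survives averaging.
- The median projection's breakdown point is ⌈n/2⌉ corrupted channels per
  cluster; the generator warns when a requested outlier layout reaches it.
- No group-level statistics: maps are per subject/montage, as in the
  motivating experiment.
- SNIRF support covers continuous-wave amplitude data only.
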