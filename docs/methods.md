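# Methods

## Preprocessing

Recordings enter as samples × channels arrays at 250 Hz (1000 Hz input is
FIR-decimated with anti-alias filtering). Cap recordings are reduced to the
canonical 52-channel analysis set: the 60-channel cap is the reference
numbering; the four ocular channels (61–64) and any channels beyond the
reference set are dropped first, then the eight outermost channels
(1, 17, 23, 29, 32, 43, 47, 55), which are the most artifact-prone. The
canonical channel order is the ascending cap numbering, independent of input
order, so matrices are comparable across subjects. Re-restricting an
already-restricted recording raises an error rather than passing through:
silent idempotence would hide double-processing in a mis-wired pipeline.

The continuous recording is band-passed 1–47 Hz and average-referenced
(instantaneous across-channel mean removed). Per-band filtering for the
phase lag index is applied to the **continuous** recording, before epoching,
so filter edge transients never contaminate the 2-s analysis windows. All
filters are order-4 Butterworth band-passes applied forward–backward
(`sosfiltfilt`): zero phase distortion is a hard requirement for phase-based
connectivity, and the squared magnitude response comfortably meets the
pass/stop behaviour the test suite asserts (in-band tones retained ≥ 0.95 at
band centre, tones at twice the upper edge attenuated below 0.10).

Epochs are consecutive, non-overlapping 2-s windows `[kL, (k+1)L)` from the
start of the recording; the first 15 are kept (≥ 30 s of signal), and a
recording too short for 15 epochs is rejected as insufficient clean signal.
Artifact detection is out of scope; `segment_epochs` accepts an external
boolean epoch mask so cleaned data from other toolchains can be used.

## Connectivity

**MSC.** Welch cross-spectra use 1-s Hann segments with 50% overlap — on a
2-s epoch: three averaged periodograms and a 1 Hz frequency grid, the finest
grid that still averages at least three segments. Band values are means of
MSC(f) over bins in the half-open interval [low, high), so adjacent bands
never share a bin. The estimator is biased upward for small segment counts
(E[MSC] ≈ 1/K under independence, ≈ 1/3 at the default K = 3); the segment
count is recorded on every matrix and the bias is verified by simulation in
the tests. A single segment makes MSC identically 1 and is refused. MSC is
computed from the broadband epoch (it is already frequency-resolved); band
filtering is only needed for the PLI.

**PLI.** Instantaneous phases are angles of the analytic (Hilbert) signal of
the band-filtered epoch; phase differences are wrapped differences of
wrapped phases, re-wrapped to (−π, π]. The three-valued sign is used, so
sign(0) = 0 and identical channels score exactly 0. No edge trimming is
applied: 2-s epochs leave no budget for it, and the tests allow a 0.02
tolerance on the analytic-signal edge effect when asserting the perfect-
locking limit.

## Minimum spanning tree

Kruskal's algorithm on edge weights 1 − PLI; minimising total weight keeps
the strongest couplings. Ties are broken by (weight, smaller node index,
larger node index), making construction fully deterministic. Metrics follow
the definitions in the README table; two conventions deserve note:

- **Betweenness** is normalised by the (N−1)(N−2)/2 unordered pairs
  excluding the node itself, which gives the star hub exactly 1.
- **Tree hierarchy** uses the leaf *number* L in the numerator,
  Th = L/(2·m·B_max). Only this convention reaches the documented star limit
  of 0.5 (L = m, B_max = 1); with the leaf fraction the star value would
  collapse toward 1/(2N).

Degree correlation is the Pearson correlation over the 2m ordered
edge-endpoint degree pairs (standard assortativity); it is reported as NaN
when a marginal has zero variance (e.g. a 2-node tree). Construction is
tested against exhaustive spanning-tree enumeration (N ≤ 7) and every metric
against an independent path-enumeration oracle (N ≤ 20).

## Statistics

Epoch features are averaged within subject × timepoint × band; a group with
missing epochs is an error, not a silent partial mean. Group contrasts use a
linear mixed model with a subject random intercept — repeated measures from
subjects seen at both timepoints are not independent — and fixed effects for
timepoint, sex and their interaction under sum-to-zero coding, so each main
effect is averaged over the other factor and subjects observed at a single
timepoint are handled by the likelihood. Each single-df effect is reported
as the squared Wald z (an F statistic on one numerator df) with its
normal-theory p-value. A Gaussian response with identity link was chosen
because all features are continuous and bounded. Responses with zero
variance (possible in small montages: every 4-node tree has Th = 0.5
exactly) are rejected as degenerate and skipped by the pipeline with a
warning.

FDR adjustment is Benjamini–Hochberg step-up, applied within each
feature × effect family across the six bands (six tests per family).
Outcome associations use Spearman's ρ with a 1000-resample percentile
bootstrap over subjects (x, y resampled together, listwise deletion of
missing pairs, ≥ 5 complete pairs required); a correlation is significant
when the 95% CI excludes zero. The correlational analyses are deliberately
not multiplicity-adjusted: they are exploratory, and type-II errors are the
greater risk there.

## Synthetic cohorts

Channel model: x_c(t) = coupling·cos(2πft + φ₀ − lag_c) + noise_sd·ε_c(t),
ε white Gaussian per channel, carrier 10 Hz by default, per-recording random
start phase φ₀, distinct per-channel lags spread over (0, π). Under this
model the connectivity estimators have analytic limits (PLI = 1 at any
constant nonzero lag with no noise; PLI and MSC increase monotonically with
the coupling-to-noise ratio), which the tests exploit.

Channel 0 is a **hub**: a full-amplitude driver with small sensor noise
(hub_noise_sd = 0.1), while peripheral channels mix the driver at the
subject's coupling strength against unit-scale noise (noise_sd = 0.7).
Hub–peripheral pairs therefore carry systematically stronger true coupling
than peripheral–peripheral pairs. At low coupling the PLI contrast is buried
in estimation noise and the MST is close to a random tree; as coupling
rises the hub edges dominate and the tree crystallises star-ward. This is
the mechanism by which a coupling increment at the second timepoint
reproduces the developmental direction pattern (Mean MSC/PLI, Lf, Th, κ up;
diameter, eccentricity, Bc down) without any feature being wired to the
group label.

Cohort defaults: 132 subjects at T6, 61 at T12, 47 seen at both; 16
channels, 32 s at 250 Hz per recording; subject latent coupling trait
N(0, 0.1²) shared across timepoints; group means 0.35 (T6) and 0.55 (T12);
sex offset 0. Outcome scores are linear in the subject's true mean coupling
(RC = 75 + 40·c̄ + N(0, 6²); RLC intercept 30 lower) with follow-up missing
completely at random at rate 0.48, independent of everything. The effect
sizes are free parameters of the generator — documented choices, not
estimates of any real population. What the generator does **not** emulate:
volume conduction, 1/f background spectra, artifacts (blinks, movement),
non-stationarity, or realistic scalp topography; passing tests therefore
validate the estimators and statistics, not robustness to real-world EEG
noise sources.

## Problem sizes and numerical choices

Simulation-based tests use scaled designs chosen to give stable Monte-Carlo
estimates: mixed-model power and type-I use 60-subject cohorts with
4-channel, 30-s recordings (100 alternative and 200 null replicates);
bootstrap coverage uses 100 runs at n = 30; Monte-Carlo checks of estimator
behaviour use 100–200 seeds. The direction-pattern check runs the full
pipeline on a 15-subject cohort with the default 16-channel montage and a
strong coupling contrast (0.12 vs 0.80, trait SD 0.03).

Randomness is handled with one master seed per run; per-subject and
per-timepoint substreams are derived deterministically from it, so cohorts
are reproducible under subsetting, and a pipeline rerun with the same
config and seed writes byte-identical tables.

Known limitations: Wald z² tests are asymptotic (no small-sample df
correction; type-I was verified ≈ 0.03–0.05 at n = 60 by simulation);
MixedLM variance components can sit on the boundary for near-null data, in
which case the model degenerates gracefully toward OLS-like inference; the
MSC small-sample bias floor (≈ 1/3 at default Welch settings) is inherent to
3-segment epochs and is documented in the run manifest rather than
subtracted.
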