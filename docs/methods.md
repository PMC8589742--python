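# Methods

This note documents the models implemented in `qmrn`, the defaults of the
synthetic-phantom generator, and the numerical and design choices that were
genuinely open.

## Signal models and estimation

**T2 relaxometry.** The multi-spin-echo signal of a voxel population is
modelled as mono-exponential with a constant offset,

    S(TE) = PSD · exp(−TE / T2) + offset .

Estimation follows ROI-mean-first practice: the arithmetic mean over the
ROI voxels is formed per echo *before* any fitting (averaging denoises the
decay curve; fitting voxelwise and averaging afterwards is a different,
noisier estimator, and a regression test locks the implemented order). The
analysis is restricted to the *even echoes* — echoes whose TE is an even
multiple of the 10 ms base spacing, i.e. TE = 20, 40, …, 120 ms under the
default protocol — because odd echoes of a multi-echo train are
contaminated by stimulated-echo pathways; an even-index rule is available
for non-uniform protocols. The offset absorbs slowly decaying signal
contributions and the Rician noise floor of magnitude images, which is why
it is kept as a free parameter rather than fixed at zero.

The fit is trust-region-reflective nonlinear least squares
(`scipy.optimize.least_squares`, analytic Jacobian, `x_scale="jac"`,
tolerances 1e-12) with bounds PSD > 0, offset ≥ 0 and T2 ∈ (1, 1000) ms
(parameters of `fit_t2_decay`, so unit conversions can scale them).
Initialisation is log-linear: a provisional offset of half the minimum
signal is subtracted and `log(S − offset₀)` is regressed on TE.
Non-convergence is flagged, never silent; per-nerve aggregation can either
fail or drop bad slices (≥ 4 surviving slices required).

Slice-wise estimates on the six central slices of the stack are averaged
unweighted; the six-central-slice window is also how stacks with different
slice counts (reference 41, multi-echo 13, MT 18) are aligned when masks
are transferred between grids — the programmatic counterpart of acquiring
all sequences over the same anatomical region at identical slice
positions.

**Normalized PSD.** PSD is semi-quantitative (it scales with receiver
gain), so the nerve value is divided by the PSD of adjacent muscle,
estimated by the identical six-slice procedure on the muscle ROI.

**MTR.** `MTR = 100 · (S0_mean − S1_mean) / S0_mean` per slice — ROI means
first, then the ratio — followed by the unweighted six-slice mean. Gain
invariance is exact by construction. No co-registration between the two
volumes is applied (the acquisition is assumed at identical slice
positions); negative MTR values, possible under noise, are reported as-is
with a warning because clipping would bias the reliability statistics.

**CSA.** Voxel count × in-plane pixel area of the reference-grid mask,
averaged over the six central reference slices. With a square FOV and
anisotropic matrix (e.g. 512 × 333 over 160 mm), pixel area is
(FOV/rows)·(FOV/cols).

**Mask transfer.** Nearest-neighbour resampling in physical coordinates
(grids must share the FOV). This deliberately admits partial-volume voxels
at the nerve boundary — there is no analogue of a human reader's manual
correction — so end-to-end image-based estimates carry a small
resolution-dependent bias (T2 pulled toward muscle, PSD toward the
brighter muscle amplitude) that noiseless operation-level tests, which use
matched masks, do not show.

## Reliability statistics

For an n × k table (targets × raters) the two-way crossed ANOVA without
replication gives mean squares MSR (rows), MSC (columns), MSE (error),
computed in centred form. The single-measurement absolute-agreement ICC is

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)) .

The interreader design (rows = subject × scan pairs, columns = readers) is
reported under a two-way *random*-effects reading, the test–retest design
(rows = subjects, columns = scans, one table per reader) under a two-way
*mixed*-effects reading; the point estimate and the exact F-based
confidence interval (McGraw–Wong, Satterthwaite degrees of freedom) are
identical — only the model tag differs. Pooling all scans into the
interreader table (63 rows for 21 × 3) matches reporting a single
interreader ICC per biomarker.

SEM: the *agreement* flavour `√((MSC − MSE)/n + MSE)` (default; includes
rater variance, with a negative rater-variance estimate truncated at zero
and logged) or the *consistency* flavour `√MSE`; the flavour is recorded
in every output. MDD = SEM · 1.96 · √2, with 1.96 kept as a literal
constant at the 95% level so that published MDDs reproduce exactly from
published SEMs. ICC classes: < 0.5 poor, [0.5, 0.75) moderate,
[0.75, 0.9) good, ≥ 0.9 excellent (boundary values to the upper class).

Bland–Altman: bias = mean difference; limits of agreement
bias ± 1.96 · SD. In repeated-measures mode the SD is corrected for
multiple difference pairs per subject by a one-way ANOVA on the
differences: Var(single difference) = between-subject component
(MSB − MSW)/m₀ (truncated at zero) plus MSW. Both modes are exposed
(`ba_mode`); neither is asserted to be "the" canonical choice as the
distinction matters only when subjects contribute unequal information.

## The synthetic phantom

**What it emulates.** A small hyperintense nerve (filled disc of the true
CSA, ~18 mm²; the anatomy of a real nerve cross-section is irrelevant to
ROI-mean statistics) in a muscle background that fills the rest of the
FOV; mono-exponential echo decay with offset; MT saturation contrast;
Rician noise (two Gaussian channels in quadrature — the identity at
σ = 0); subject/scan variance entering through the true biomarker values;
reader variance entering exclusively through stochastic toggling of
ROI-boundary voxels (readers segment independently on identical images).

**What it does not emulate.** k-space acquisition, B1 inhomogeneity,
motion or distortion artifacts, geometric repositioning between scans,
multi-compartment or stimulated-echo (EPG) decay, anatomical nerve shape,
or correlated segmentation errors between readers. Passing tests therefore
demonstrate correctness of the estimation and reliability machinery under
the stated generative model, not robustness to those physical effects.

**Calibration of defaults.** Grand means and total SDs reproduce a
healthy-volunteer sciatic-nerve cohort (MTR 26.75 ± 3.5 %, T2
64.54 ± 8.2 ms, PSD 340.93 ± 78.8, normalized PSD 0.71 ± 0.09, CSA
18.1 ± 4.5 mm²). The residual SD of each biomarker is set to its published
test–retest SEM (1.7 %, 2.66 ms, 20.1, 0.03; CSA: 1.0 mm², a plausible
value as no SEM is published for CSA), the scan and reader SDs default to
zero (the published interreader and test–retest SEMs are nearly equal, so
neither component is separately identifiable), and the subject SD makes up
the remainder: sd_subject = √(sd_total² − sd_residual²). The implied
theoretical ICCs are 0.76 (MTR), 0.90 (T2), 0.94 (PSD), 0.89 (normalized
PSD) — consistent with the published 0.75–0.94 range. The published
values themselves are not exactly self-consistent (total SD, ICC and SEM
over-determine the decomposition), so exact reproduction of every printed
ICC is not attainable from any single set of components.

Muscle tissue parameters are unpublished calibration choices: T2 = 30 ms
(typical skeletal muscle at 3 T) and muscle PSD = 340.93/0.71, which
centres the normalized-PSD ratio at 0.71. MT-pair signal levels (S0 220
a.u. nerve / 300 a.u. muscle, muscle MTR 40 %) are plausible constants;
only ratios enter the MTR. The constant decay offset defaults to 12 a.u.

**Geometry defaults** mirror a 3-T protocol: 160 × 160 mm FOV; reference
512 × 333 / 41 slices / 3.5 mm; multi-echo 192 × 169 / 13 / 3.5 mm with
TE = 10…120 ms; MT pair 128 × 128 / 18 / 4 mm. Default image noise
σ = 5 a.u. (SNR ≈ 60 at the first nerve echo) and boundary-flip
probability 0.15 per reader.

**Determinism.** One master seed; every draw comes from a
`SeedSequence(seed, spawn_key=(namespace, subject, scan, …))` substream,
so identical configurations are bit-reproducible and enlarging the cohort
never changes earlier subjects' draws. Out-of-range truth draws (e.g.
T2 ≤ 0 under extreme components) are redrawn and logged.

## Problem sizes used in validation

The test suite exercises image operations on reduced geometries
(96 × 96 / 192 × 192 matrices, 8–9 slices) that preserve the physical FOV
and near-protocol pixel sizes, and validates the reliability stage on the
full 21 × 3 × 2 design at the measurement level: 500 random tables against
a brute-force double-loop ANOVA/ICC oracle (1e-10 relative agreement),
2000-replicate Monte-Carlo recovery of theoretical ICCs in
{0.5, 0.75, 0.81, 0.9, 0.94} (mean within 0.03; empirical 95%-CI coverage
within [0.92, 0.975]), and 20 calibrated cohort replicates (pooled
descriptive means within 2 SE of a single cohort's grand mean; estimated
SEMs within 25% of the configured residual SDs). The acceptance script
additionally runs the image-based pipeline at the full acquisition
geometry for all 21 × 3 image sets.

## Known limitations

* Image-based estimates inherit a partial-volume bias from
  nearest-neighbour mask transfer (see above); the measurement-level
  simulator is the calibrated reference for reliability properties.
* The ICC confidence interval is exact only under normality and a
  balanced, complete design; incomplete rows are removed listwise.
* PSD in the phantom is an arbitrary-unit amplitude; cross-scanner
  comparability is explicitly out of scope (that is what normalized PSD
  is for).
* DICOM support is read-only convenience (EchoTime extraction);
  NIfTI + JSON sidecar is the canonical interchange format.
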