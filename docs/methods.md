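# Methods

This note documents the models, numerical choices and open design decisions
behind `fusednet`, and what the synthetic study does and does not establish
about real recordings.

## Synthetic study design

The generator (`fusednet.synthdata`) emulates a simultaneous EEG-fMRI
emotion-regulation experiment: 15 subjects, three conditions
(`neutral-watch`, `negative-watch`, `negative-reappraisal`), 30 trials per
condition, EEG epochs from −0.2 to 1.5 s at 250 Hz (426 samples), BOLD at
TR = 2 s over 200 volumes. Defaults not fixed by that design were chosen
once at field-typical values: sensor SNR 3, condition amplitude scales
1.0 / 1.5 / 1.1 (negative images evoke the largest response, reappraisal
partially downregulates it), BOLD effect size β = 2 against unit noise,
10% trial-to-trial feature jitter.

**Head model.** Sensors are Fibonacci-sphere sampled on the unit sphere,
sources on a concentric sphere of radius 0.8; the gain is
`G[i,j] = exp(−ang(i,j)²/(2·0.4²))` (angular distance in radians). This toy
geometry is analytic, full row rank, and preserves the ill-posedness
(`s > m`) the solvers must handle, but it is not a boundary-element head
model: its topographies are broader and more symmetric than real ones, so
absolute localization errors here do not transfer to real anatomy.

**Sources.** Active dipoles carry Gaussian-windowed sinusoids
`amp·exp(−(t−latency)²/(2·width²))·sin(2πft+φ)`; the default truth places
one dipole per analysis window (alpha at 116 ms, a gamma pair at 504 ms
with a constant π/2 phase lag, a theta dipole at 1220 ms). Inactive
dipoles carry pink noise at 1% of the peak active amplitude — enough to
keep windowed source covariances non-singular, small enough not to mask
the signals.

**Sensor noise** is drawn from `σ²(0.9·I + 0.1·𝟙𝟙ᵀ/m)`: deliberately
non-diagonal (a rank-one common-mode term) so that noise-covariance
estimation is non-trivially exercised. σ² is set from the requested SNR as
a power ratio; the realized ratio is within 5% for epochs of ≥ 400 samples.
With identically zero sources the ratio is undefined and unit variance is
used.

**BOLD.** Voxels near the active dipoles (3 each, scattered by 0.2× the
source spacing; configurable via `voxel_jitter`) follow the HRF-convolved,
feature-weighted onset train scaled by β; all other voxels are pure noise.

**Seeding.** Every stochastic quantity derives from
`SeedSequence((master_seed, subject_index))`, so studies are bit-identical
under a fixed seed and adding subjects never reshuffles earlier ones.

What passing tests show: the pipeline's mathematics (solvers, phase
estimation, statistics, graph measures) is correct and calibrated under its
own assumptions. What they do not show: robustness to real artifacts
(gradient, ballistocardiogram, EMG), realistic head-model error, or
physiological (non-sinusoidal, non-stationary) coupling.

## Preprocessing

Common-average re-referencing, zero-phase FIR band-pass, and baseline
correction over [−200, 0] ms. Filtering is forward-backward (zero phase)
because the downstream phase-lag analysis must not be corrupted by filter
delay. FIR length is 3 carrier cycles of the low band edge (`3·fs/lo`),
capped at a third of the record and forced odd; at 250 Hz this gives
alpha-band gain within 5% at band centre while attenuating out-of-band
tones by > 40 dB. A high-pass edge below half a cycle per record (such as
0.01 Hz on a 1.7 s epoch) is unrealizable at that record length; the filter
then degrades to a low-pass and the high-pass role is carried by baseline
correction. The five analysis bands are delta 1–3, theta 3–8, alpha 8–13,
beta 13–30, gamma 30–40 Hz; adjacent bands share their printed edge
frequency.

When the pipeline re-references the data it applies the same centering
projector to the lead-field rows, keeping the forward model consistent with
the referenced data.

## fMRI prior

The EEG-informed regressor is the feature-weighted onset stick train
convolved with a canonical double-gamma HRF (response peak 6 s, undershoot
16 s, ratio 1/6, 32 s support, peak-normalized), resampled at the TR and
mean-centered (an explicit intercept absorbs the baseline; centering
removes the β/baseline scale ambiguity). Per-voxel OLS gives t = β̂/SE;
the voxel threshold is one-sided p < 0.001 uncorrected (the threshold is a
free choice here; it is configurable). Active voxels are mapped to dipoles
within a radius of 2× the source spacing — this guarantees coverage of the
generating dipoles but necessarily includes their immediate neighbours, so
the recovered activation set is a superset of the truth at defaults; exact
set recovery requires the high-precision regime (radius 0.5× spacing,
p < 10⁻⁶, small voxel jitter), which the tests exercise separately. The
prior diagonal is 1 inside the activation set and 0.1 outside.

## Inverse solvers

The estimator `Ĵ = R Gᵀ(G R Gᵀ + λ²C)⁻¹Y` is evaluated through a Cholesky
factorization of the m×m sensor-space matrix (never an explicit inverse);
for small systems it matches the directly evaluated formula to relative
error < 1e-8. The printed estimator is scale-inconsistent between R and C
unless a regularization scale is fixed; we use the standard
`λ² = tr(GRGᵀ)/(tr(C)·snr²)` with snr = 3 by default, and `lam2=1`
reproduces the literal unscaled formula. The sensor noise covariance is
the pooled pre-stimulus baseline sample covariance with 5% diagonal
loading (absolute fallback when the baseline is identically zero, keeping
it positive definite).

FWMNE windows default to the three fixed analysis spans with half-open
sample indexing; window priors are per-dipole temporal variances of the
full-epoch fMNE estimate, rescaled to max 1 and floored at 1% (flooring
prevents singular priors for silent dipoles; an all-constant window
degrades to uniform weights). Dipoles are scalar (fixed orientation) —
one lead-field column each.

## ROI extraction and PLI

The 68 Desikan-Killiany cortical labels are bundled as a static list; the
toy sphere is partitioned into 68 contiguous angular patches (34 per
hemisphere by the sign of one coordinate, sizes within a hemisphere
differing by at most one). ROI series are plain means of member dipoles.
Plain averaging can cancel opposite-signed dipoles within a label; the
hazard is documented and `abs_mean` / `first_pc` aggregations are provided,
but sign-flip alignment is deliberately not applied by default.

Instantaneous phase comes from the frequency-domain analytic signal;
constant series have undefined phase and are rejected (trials containing
one are dropped from the PLI average with a logged warning). Before sign
averaging, 5% of samples are discarded at each record edge (Hilbert edge
effects). The sign of a wrapped phase difference below 1e-9 rad counts as
zero, which makes the self-PLI exactly 0 in floating point. PLI is
computed per trial for all 2278 ROI pairs and averaged arithmetically
across trials.

Two null-level facts matter for interpretation. For M independent phase
differences, `E|mean sign|= √(2/(πM))` (≈ 0.025 at M = 1000); but phases
from the analytic signal of noise are serially correlated, so the
empirical null of the full Hilbert path is higher (≈ 0.032 at M = 1000 for
white noise, and higher still after narrow-band filtering, scaling with the
number of independent phase samples ≈ 2·bandwidth·duration). Narrow bands
on short epochs therefore have an elevated PLI floor. Separately, source
leakage (the broad toy topographies mixing a lagged pair into many ROIs)
produces genuinely lagged mixtures at many pairs; PLI suppresses zero-lag
leakage only, so supra-threshold edge counts on simulated data should be
read with this in mind.

By default the PLI is computed on band-filtered full-epoch source series,
where "full-epoch" means FWMNE with a single window spanning the whole
epoch (an fMNE pass followed by one fused re-estimate);
`connectivity_scope: windows` instead concatenates the three analysis
windows. Either choice is defensible; neither is claimed canonical.

## Network analysis

Binarization keeps edges with PLI ≥ threshold. The default threshold is
the fixed value 0.30; `threshold: auto` scans a 0.01-step grid from the
top and returns the largest value whose binarized group-mean graph has
mean degree > 2 ln K and small-world σ > 1, failing with a per-threshold
diagnostics table when no value qualifies (as happens on degenerate
all-equal input, where every admissible graph is complete and σ = 1).

Edge-wise condition differences use a two-sided paired t-test
(df = n_subjects − 1) with Benjamini-Hochberg FDR at q = 0.05 across all
2278 edges; zero-variance edges record p = 1 and are flagged. Two-sided
testing and BH (rather than BY) are the conventional choices where the
direction and dependence handling are not otherwise specified. The final
edge set is the intersection of the threshold-binarized and FDR-significant
edges; `threshold_only` and `significance_only` are available because the
composition of the two rules is genuinely open.

Betweenness is unnormalized shortest-path betweenness over unordered node
pairs (Brandes' algorithm via networkx; verified in tests against
exhaustive path enumeration); pairs in different components contribute
zero. Density is `2M/(K(K−1))` exactly. The small-world index is
`σ = (C/C_rand)/(L/L_rand)` with C the mean local clustering coefficient,
L the mean shortest path over connected pairs on the largest component,
and the null given by 20 degree-preserving edge-rewired surrogates (10·M
seeded swap attempts each). A complete graph is its own null (σ = 1
exactly); graphs with fewer edges than nodes cannot be rewired and raise an
explicit error, which the pipeline records as a summary note rather than a
failure.

## Pipeline and reproducibility

All interchange is TSV/JSON so every stage is independently runnable and
testable; NumPy containers are used only for the bulky raw study arrays.
One master seed governs all stochastic stages through the documented
derivation. The manifest records the config hash, seed, package version
and SHA-256 of every output file; wall-clock timestamps go to `run.log`,
which is excluded from the reproducibility identity, so identical
config + seed yields byte-identical manifests and outputs.

Problem sizes: the default study (15 subjects, 3 × 30 trials, 16 sensors,
200 dipoles, 426-sample epochs, five bands) runs end to end in a few
minutes on one CPU; tests use smaller geometries (64–100 dipoles, 3–4
subjects) where the property under test does not require the full design.

## Known limitations

- The spherical Gaussian-topography lead field has no anatomical validity;
  parcel assignments are geometric patches, not cortical regions.
- MR-environment artifact correction (gradient, ballistocardiogram), ICA
  cleaning and fMRI spatial preprocessing are out of scope; inputs are
  assumed artifact-free.
- The per-trial EEG feature feeding the BOLD regressor is a free input
  (the simulator uses the condition amplitude scale with jitter); no claim
  is made about which feature a real analysis should use.
- PLI on short, narrow-band epochs has an elevated null floor, and source
  leakage produces lagged mixtures PLI does not remove (see above).
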