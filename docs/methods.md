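# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of `fluxwin`, module by module.

## Spectral-flux stimuli (`stimgen`)

**Generative model.** A stimulus is a sum of `n_components = 20`
sinusoids with frequencies drawn uniformly without replacement from a
pool of 101 log-spaced frequencies on [246, 4435] Hz (constant successive
ratio; endpoints exact). Frequencies are re-drawn per exemplar. The
per-frame dB amplitude of each component follows an independent
stationary Gaussian AR(1) process,

    a[k+1] = mu + r1 (a[k] − mu) + sqrt(1 − r1²) · sigma · eps,

with marginal mean `mean_db = 65`, SD `sd_db = 10`, and lag-1
autocorrelation `r1`. This is the minimal process with the stated
marginals for which the across-component Pearson correlation between
frames n apart equals `r1**n` in expectation. Nothing about the AR
choice is fitted; it is the modeling assumption that closes the gap
between "frames correlate at r1" and an explicit sampler.

**Window duration.** `win = frame_dur · ln(r_min)/ln(r1)` with
`r_min = 0.2`, `frame_dur = 20 ms`, clamped below at one frame so the
fully decorrelated condition (`r1 = 0`) reports a 20-ms window rather
than 0. `r1 ≥ 1` is rejected (unbounded window).

**Rendering.** Frame amplitudes are converted as `10^(dB/20)` with unit
reference — the reference is immaterial because waveforms are
peak-normalized after summation. Envelopes are piecewise-linear
interpolations of the frame amplitudes on the *linear* scale
(interpolating dB would give exponential-in-time segments), anchored at
frame centres and held at the edges. Carrier phases are uniform random,
frozen per exemplar. Onset/offset ramps are linear, default 20 ms
(configurable; 50 ms is a common presentation-side choice). WAV output
is 16-bit PCM at 44.1 kHz.

**Correlation estimator.** Recovering per-frame component amplitudes
from the audio by frame-wise DFT fails here for two physical reasons:
(i) pool frequencies can lie < 10 Hz apart, far below the ~50-Hz
resolution of a 20-ms window, so neighbouring components are not
separable within any single frame; (ii) the piecewise-linear envelope
makes a frame-length window read a [1, 6, 1]/8 moving average of the
frame amplitudes, which biases the lag-1 correlation upward (≈ +0.32 at
nominal 0), and inverting that kernel on magnitude estimates amplifies
error on quiet frames catastrophically on the dB scale. The estimator
therefore projects the whole waveform onto its known generative basis:
carriers `sin(2π f_j t + θ_j)` (frequencies and phases stored with the
stimulus) scaled by piecewise-linear envelopes with one unknown
amplitude per (component, frame-anchor). Each inter-anchor segment
involves only its two flanking anchors, so the normal equations are
block-tridiagonal and solved exactly as a symmetric banded system;
closely spaced components are separated by their full-duration carrier
coherence. The Pearson formula is then applied unchanged to the
recovered dB frame spectra, excluding one edge frame per side. The
round trip |measured − generating| is < 0.003 per exemplar, well inside
the ±0.03 mean / ±0.05 per-lag verification bands used by the tests.
The estimator is a *verification* of rendered audio, not a blind
analyzer of arbitrary recordings.

**Tonotopy stimuli.** Random-phase spectral shaping (unit magnitudes
with uniform phases inside the pass-band, inverse real FFT), multiplied
by `(1 + d·sin(2π·10·t))/(1 + d)` with `d = 0.9`. Modulation depth is
verified by Hilbert demodulation followed by projection onto the 10-Hz
sinusoid; narrowband envelope ripple leaves a ~0.02 noise floor on that
estimate.

## Session design (`design`)

"Five stimulus volumes for every three silence volumes" is implemented
as a strict block structure: each consecutive aligned block of eight
volumes holds 5 stimulus + 3 silence, shuffled within block, so the
ratio holds at every scale and baseline is interleaved. The five levels
appear exactly equally often per session; the level sequence forbids
immediate repeats (a greedy scheduler drains any level once it holds
half the remaining slots, otherwise samples proportionally). Exemplars
cycle through each level's 45-exemplar pool, so adjacent stimulus trials
never share an exemplar — the strictest reading of the "different sound
on adjacent trials" rule. Stimulus onset is
`acq_onset − (stim_dur − ta)` so the 1.35-s acquisition covers the final
1.35 s of the 6-s trial. Whether the original sequences interspersed
silences singly or in runs is unreported; within-block shuffling allows
runs of up to 6 silences across a block boundary.

## BOLD phantom (`bold_sim`)

The phantom is a deliberately simple two-hemisphere superior-temporal
ribbon on a 48×48×8 grid of 1.2-mm voxels: 15 fields per hemisphere
(A1, R, RT; CM, RM, RTM; CL, ML, AL, RTL; CPB, RPB; Tpt, RTp, STGr)
painted as mirror-symmetric rectangles. Two-voxel gaps separate ribbon
columns (and the flat-tuned association fields from core along the
postero-anterior axis) so that 3-mm smoothing cannot mix tuning across
tier boundaries — the phantom's purpose is recoverable programmed
physiology, not partial-volume realism.

**Programmed tuning** (percent signal change over the five conditions
ordered shortest → longest window): core `2.0 − 0.25·i`, belt
`1.5 − 0.125·i` (half slope), parabelt 0.4 flat, association 0.3 flat;
silence response zero. True effect sizes in the source experiments are
only shown graphically, so these are free parameters chosen once as
realistic auditory %SC values at high field; the acceptance properties
are phrased as pattern recovery (ordering and significance tiers), not
as numeric reproduction.

**Sampling model.** Because sparse sampling acquires one volume per
trial at a near-plateau hemodynamic delay, each volume is one
independent sample: expected intensity
`baseline · (1 + tuning/100 · h)` with scalar HRF factor `h = 1` by
default. The canonical double-gamma is implemented (`canonical_hrf`,
`hrf_factor_at`) for studying non-plateau timing; note the human-typical
double-gamma convolved with a 6-s boxcar reaches its plateau after the
stimulus ends, so `h < 1` at the actual acquisition time — using
`h = 1` treats the macaque response as having plateaued, following the
design logic of the experiment. Noise is AR(1) across volumes with
coefficient 0.1 (volumes are 10 s apart) at 1% of baseline, plus
per-session cosine drift (periods 240 s and 480 s, 1% amplitude, random
phase) that gives the 120-s high-pass something real to remove.
Background voxels carry baseline plus white noise. Tonotopy mode drives
each voxel by `2.0 · 0.5^|band − best_band|` %SC; the best-band map
descends from band 3 to band 1 at the A1/R border (y = 24) and rises
again — exactly one reversal. Simulation is bit-reproducible from
(phantom, design, seed).

**What the phantom does not emulate:** anatomy and registration, motion,
physiological (cardiac/respiratory) noise structure, spatial noise
correlations, voxel-wise tuning heterogeneity within an ROI, and
hemispheric asymmetries. Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated, not that it is robust to
every artifact of real acquisitions.

## GLM (`glm`)

Smoothing uses a per-volume 3D Gaussian with
`sigma = FWHM / (2·sqrt(2·ln 2))` in voxel units (nearest-edge
padding); FWHM 0 is the identity. The design matrix holds one indicator
column per condition scaled by the HRF factor (silence is the implicit
baseline), a discrete-cosine drift basis per session with
`floor(2·T/cutoff)` components (periods > 120 s; DC excluded), one
intercept per session, and optional motion columns (accepted, never
simulated). High-pass filtering via nuisance regressors (rather than
pre-filtering) keeps the degrees of freedom accounting exact in one OLS
pass. Global scaling divides each session by its mean in-mask intensity
and multiplies by 100, so betas read as percent of the session grand
mean and are invariant to per-session gain.

Fitting is ordinary least squares via the pseudoinverse;
`df = n_volumes − rank(X)`. t-contrasts use
`t = c'b / sqrt(sigma² · c'(X'X)⁻¹c)`; zero-variance voxels yield NaN
and are excluded from maps; identically zero contrasts return 0.
Thresholding is one-sided at t > 3.1 (≈ P < 0.001 at these df) — the
source analyses report directional contrasts at that threshold, and
whether they were one- or two-sided is not stated; one-sided is the
implemented reading. Calibration is verified against the nominal
exceedance rate and a KS test against Student's t, and the OLS/t path is
cross-checked against nilearn's GLM as an independent oracle in the
test suite.

## Derived maps (`maps`)

Best-frequency maps take the per-voxel argmax of band betas inside the
sound-responsive mask; ties break to the lowest band index (deterministic)
and are counted and logged. Reversal counting profiles the mean band
along the gradient axis and counts slope sign changes.

The linear negative parametric contrast uses weights (2, 1, 0, −1, −2);
an exponentially decaying alternative `exp(−decay·rank)`, mean-centred,
is provided for the standard robustness check (at `decay → 0` it
vanishes after centring).

Small-volume cluster correction replaces random-field theory with a
permutation max-cluster-size null: clusters form at t > 3.1 under
6-connectivity (the most conservative standard neighbourhood) inside the
small volume; condition labels are permuted among stimulus volumes
within session (exact under the null of no condition differences, since
silence volumes and nuisance structure are untouched); corrected
`p = (1 + #{perm max ≥ observed})/(n_perm + 1)`. With spatially smooth
data the null cluster sizes are well spread and the family-wise error
rate calibrates to ≈ 0.05; on spatially *independent* noise cluster
sizes are almost always 0 or 1 and the test becomes strongly
conservative through discreteness — a property of all cluster-extent
inference, which is why the calibration test uses smoothed null data,
matching the pipeline's own smoothing. The original cluster-extent
thresholds are unreported, so calibration (FWER ≈ nominal) and power on
the programmed effect are the testable properties.

## ROI analysis (`roi`)

Per (ROI, hemisphere): voxels are `ROI ∩ sound_mask`; the reported
contrast estimate is the mean of voxel-wise contrast values; t and p
come from a GLM refit on the spatially averaged time series of those
voxels (the MarsBaR convention), not from averaging voxel t-values.
Hemispheres are separate inference units; significance is Bonferroni
`p < alpha/n` with `alpha = 0.05`, `n = 30`. Empty intersections are
flagged and excluded from inference. Group summaries average the ROI
contrast across hemispheres of all subjects (hemisphere-equal by
default; `weight="animal"` averages within subject first — the original
reporting does not state which) and count significant hemispheres.

## Problem sizes

Defaults were chosen to keep a laptop-scale workflow: 48×48×8 phantom
grids, 360-volume sessions, 20-replicate recovery studies, 50 exemplars
per condition for stimulus verification, and 200 replicates × 200
permutations for the error-rate calibration (run on 16×16×4 grids with
120-volume designs). All are parameters, not constants.
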