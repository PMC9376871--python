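"""Spectral-flux and tonotopy stimulus synthesis.

A spectral-flux stimulus is a bank of fixed-frequency sinusoids whose
frame-wise dB amplitude spectra evolve with a controlled Pearson
correlation ``r1`` between adjoining 20-ms frames.  High ``r1`` means low
spectral flux (the spectrum changes slowly); ``r1 = 0`` means maximal flux
(independent frames).  The adjacent-frame correlation implies an analysis
"time window": the span over which the inter-frame correlation decays to a
floor ``r_min``, since the correlation at a lag of ``n`` frames is
``r1**n``.

This module synthesizes such stimuli, computes the implied window
durations, verifies the realized spectrotemporal correlation of rendered
audio, and builds amplitude-modulated narrowband noise for tonotopic
mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.linalg import solveh_banded
from scipy.signal import hilbert

from .errors import ConsistencyError, InsufficientDataError, ParameterError

__all__ = [
    "FluxSpec",
    "FramedSpectrum",
    "Stimulus",
    "TonotopySpec",
    "FLUX_LEVELS",
    "window_duration",
    "build_frequency_pool",
    "sample_amplitude_trajectories",
    "synthesize_waveform",
    "make_stimulus",
    "measure_spectrotemporal_correlation",
    "measure_am_depth",
    "generate_tonotopy_stimulus",
    "generate_corpus",
    "write_wav",
]

#: The five adjacent-frame correlation levels of the main experiment,
#: ordered from high flux (r1 = 0, shortest window) to low flux.
FLUX_LEVELS = (0.0, 0.3, 0.6, 0.8, 0.9)


@dataclass(frozen=True)
class FluxSpec:
    """Full parameterization of one spectral-flux condition.

    Parameters
    ----------
    r1 : float
        Target Pearson correlation between the dB amplitude spectra of
        adjoining frames, in ``[0, 1)``.
    r_min : float
        Terminal correlation defining the analysis window (default 0.2).
    frame_dur : float
        Frame duration in ms (default 20).
    n_components : int
        Number of sinusoids per stimulus (default 20).
    pool_size : int
        Number of candidate frequencies (default 101).
    f_lo, f_hi : float
        Pool bounds in Hz (defaults 246 and 4435).
    mean_db, sd_db : float
        Marginal mean and SD of the frame amplitude spectra in dB
        (defaults 65 and 10).
    duration_s : float
        Stimulus length in seconds (default 6).
    sample_rate : int
        Audio sample rate in Hz (default 44100).
    ramp_ms : float
        Linear onset/offset ramp in ms (default 20).
    """

    r1: float = 0.0
    r_min: float = 0.2
    frame_dur: float = 20.0
    n_components: int = 20
    pool_size: int = 101
    f_lo: float = 246.0
    f_hi: float = 4435.0
    mean_db: float = 65.0
    sd_db: float = 10.0
    duration_s: float = 6.0
    sample_rate: int = 44100
    ramp_ms: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r1 < 1.0:
            raise ParameterError(
                f"r1 must lie in [0, 1); got {self.r1} (r1 = 1 implies an "
                "unbounded analysis window)"
            )
        if not 0.0 < self.r_min < 1.0:
            raise ParameterError(f"r_min must lie in (0, 1); got {self.r_min}")
        if self.frame_dur <= 0:
            raise ParameterError("frame_dur must be positive")
        if self.n_components > self.pool_size:
            raise ParameterError("n_components cannot exceed pool_size")
        if not self.f_lo < self.f_hi:
            raise ParameterError("f_lo must be below f_hi")
        n_frames = self.duration_s * 1000.0 / self.frame_dur
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ParameterError(
                "duration_s must be an integer multiple of frame_dur"
            )

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * 1000.0 / self.frame_dur)

    @property
    def samples_per_frame(self) -> int:
        return round(self.sample_rate * self.frame_dur / 1000.0)

    @property
    def window_ms(self) -> float:
        """Implied analysis-window duration for this condition."""
        return window_duration(self.r1, self.r_min, self.frame_dur)


@dataclass
class FramedSpectrum:
    """Per-frame, per-component dB amplitudes with their frequencies."""

    freqs: np.ndarray  # (n_components,) Hz
    amps_db: np.ndarray  # (n_components, n_frames) dB
    frame_dur: float  # ms

    @property
    def n_frames(self) -> int:
        return self.amps_db.shape[1]

    def lag_correlation(self, lag: int = 1) -> float:
        """Mean across-component Pearson correlation between frames ``lag`` apart.

        This is the direct, audio-free evaluation of the spectrotemporal
        correlation on the generating amplitude matrix; the synthesized
        waveform should round-trip to the same value.
        """
        return _mean_lag_correlation(self.amps_db, lag)


@dataclass
class Stimulus:
    """A rendered spectral-flux exemplar with its generating parameters.

    ``phases`` holds the per-component carrier phases frozen at synthesis;
    the correlation estimator uses them (together with the frequencies) to
    project the audio onto its known carrier structure.
    """

    waveform: np.ndarray
    framed: FramedSpectrum
    spec: FluxSpec
    seed: int
    phases: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class TonotopySpec:
    """Amplitude-modulated narrowband-noise stimulus for tonotopic mapping."""

    band_lo: float
    band_hi: float
    am_rate: float = 10.0
    am_depth: float = 0.9
    duration_s: float = 6.0
    sample_rate: int = 44100
    ramp_ms: float = 20.0

    def __post_init__(self) -> None:
        if not self.band_lo < self.band_hi:
            raise ParameterError("band_lo must be below band_hi")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ParameterError("am_depth must lie in [0, 1]")
        if self.band_hi > self.sample_rate / 2:
            raise ParameterError("pass-band exceeds the Nyquist frequency")


#: Standard tonotopy pass-bands in Hz, low to high.
TONOTOPY_BANDS = ((500.0, 1000.0), (2000.0, 4000.0), (8000.0, 16000.0))


def window_duration(r1: float, r_min: float = 0.2, frame_dur: float = 20.0) -> float:
    """Analysis-window duration in ms implied by an adjacent-frame correlation.

    The correlation at a lag of ``n`` frames is ``r1**n``, so the window over
    which the correlation decays to ``r_min`` spans
    ``frame_dur * ln(r_min)/ln(r1)`` ms.  The result is clamped below at one
    frame: at ``r1 = 0`` the spectrum decorrelates within a single frame.
    Strictly increasing in ``r1`` on (0, 1) and decreasing in ``r_min``.
    """
    if r1 >= 1.0:
        raise ParameterError("r1 >= 1 implies an unbounded window")
    if r1 < 0.0:
        raise ParameterError("r1 must be non-negative")
    if not 0.0 < r_min < 1.0:
        raise ParameterError("r_min must lie in (0, 1)")
    if frame_dur <= 0:
        raise ParameterError("frame_dur must be positive")
    if r1 == 0.0:
        return frame_dur
    return max(frame_dur, frame_dur * math.log(r_min) / math.log(r1))


def build_frequency_pool(f_lo: float, f_hi: float, count: int) -> np.ndarray:
    """``count`` log-spaced frequencies from ``f_lo`` to ``f_hi`` inclusive."""
    if count < 2:
        raise ParameterError("pool needs at least 2 frequencies")
    if f_lo <= 0:
        raise ParameterError("f_lo must be positive")
    if not f_lo < f_hi:
        raise ParameterError("f_lo must be below f_hi")
    return np.geomspace(f_lo, f_hi, count)


def sample_amplitude_trajectories(
    spec: FluxSpec, seed: int | np.random.Generator
) -> FramedSpectrum:
    """Draw component frequencies and AR(1) dB amplitude trajectories.

    Each of the ``n_components`` frequencies (drawn uniformly without
    replacement from the log-spaced pool) receives an independent
    stationary Gaussian AR(1) trajectory on the dB scale::

        a[k+1] = mu + r1 * (a[k] - mu) + sqrt(1 - r1**2) * sigma * eps

    with marginal mean ``mean_db`` and SD ``sd_db``.  The expected Pearson
    correlation across components between frames ``n`` apart is then
    exactly ``r1**n``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = build_frequency_pool(spec.f_lo, spec.f_hi, spec.pool_size)
    freqs = np.sort(rng.choice(pool, size=spec.n_components, replace=False))

    mu, sigma, rho = spec.mean_db, spec.sd_db, spec.r1
    n_frames = spec.n_frames
    amps = np.empty((spec.n_components, n_frames))
    amps[:, 0] = mu + sigma * rng.standard_normal(spec.n_components)
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    for k in range(1, n_frames):
        amps[:, k] = (
            mu
            + rho * (amps[:, k - 1] - mu)
            + innov_sd * rng.standard_normal(spec.n_components)
        )
    return FramedSpectrum(freqs=freqs, amps_db=amps, frame_dur=spec.frame_dur)


def _frame_anchor_times(spec: FluxSpec) -> np.ndarray:
    """Envelope anchor instants: centres of the non-overlapping frames, s."""
    fd = spec.frame_dur / 1000.0
    return (np.arange(spec.n_frames) + 0.5) * fd


def synthesize_waveform(
    framed: FramedSpectrum, spec: FluxSpec, seed: int | np.random.Generator
) -> Stimulus:
    """Render a framed spectrum to audio.

    Component envelopes are piecewise-linear interpolations (anchored at
    frame centres, held at the edges) of the per-frame amplitudes converted
    from dB to linear scale; each component keeps a random phase frozen per
    exemplar.  Onset/offset are shaped by linear ramps and the summed
    waveform is peak-normalized.
    """
    if framed.n_frames != spec.n_frames:
        raise ConsistencyError(
            f"framed spectrum has {framed.n_frames} frames, spec implies {spec.n_frames}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1

    n_samples = round(spec.duration_s * spec.sample_rate)
    t = np.arange(n_samples) / spec.sample_rate
    anchors = _frame_anchor_times(spec)
    amps_lin = 10.0 ** (framed.amps_db / 20.0)

    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(framed.freqs))
    x = np.zeros(n_samples)
    for j, (f, ph) in enumerate(zip(framed.freqs, phases)):
        env = np.interp(t, anchors, amps_lin[j])
        x += env * np.sin(2.0 * np.pi * f * t + ph)

    x *= _linear_ramp(n_samples, spec.sample_rate, spec.ramp_ms)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return Stimulus(
        waveform=x, framed=framed, spec=spec, seed=int(seed_val), phases=phases
    )


def make_stimulus(spec: FluxSpec, seed: int) -> Stimulus:
    """Sample trajectories and render audio with a single seed."""
    rng = np.random.default_rng(seed)
    framed = sample_amplitude_trajectories(spec, rng)
    stim = synthesize_waveform(framed, spec, rng)
    stim.seed = int(seed)
    return stim


def _linear_ramp(n_samples: int, sample_rate: int, ramp_ms: float) -> np.ndarray:
    gate = np.ones(n_samples)
    n_ramp = round(sample_rate * ramp_ms / 1000.0)
    if n_ramp > 0:
        r = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        gate[:n_ramp] = r
        gate[-n_ramp:] = r[::-1]
    return gate


def _mean_lag_correlation(amps_db: np.ndarray, lag: int) -> float:
    """Mean Pearson correlation across components between frames ``lag`` apart."""
    n_frames = amps_db.shape[1]
    if n_frames - lag < 1:
        raise InsufficientDataError("not enough frames for requested lag")
    a = amps_db[:, : n_frames - lag]
    b = amps_db[:, lag:]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=0) / denom
    return float(np.nanmean(r))


@dataclass
class CorrelationEstimate:
    """Measured spectrotemporal correlation of a rendered stimulus."""

    r1: float
    lags: np.ndarray
    lag_corr: np.ndarray
    amps_db: np.ndarray  # recovered per-frame dB amplitudes (components x frames)


def recover_frame_amplitudes(stim: Stimulus) -> np.ndarray:
    """Recover per-frame linear component amplitudes from rendered audio.

    A frame-length DFT cannot do this: pool frequencies can sit < 10 Hz
    apart, unresolvable in any 20-ms window, and the piecewise-linear
    interpolation makes each frame window read a moving average of the
    frame amplitudes.  Instead the audio is projected onto its known
    generative structure: carriers ``sin(2*pi*f_j*t + theta_j)`` (stored
    frequencies and phases) scaled by piecewise-linear envelopes anchored
    at the frame centres, with the onset/offset ramp included.  The anchor
    amplitudes are the unknowns of a least-squares problem whose normal
    matrix is block-tridiagonal (each inter-anchor segment involves only
    its two flanking anchors), solved as a symmetric banded system.
    Closely spaced components are separated by their full-duration carrier
    coherence rather than within one frame.
    """
    spec = stim.spec
    if stim.phases.size != len(stim.framed.freqs):
        raise ConsistencyError("stimulus does not carry its carrier phases")
    fs = spec.sample_rate
    spf = spec.samples_per_frame
    K = spec.n_frames
    m = len(stim.framed.freqs)
    x = stim.waveform
    n_samples = len(x)
    t = np.arange(n_samples) / fs

    carriers = np.sin(
        2.0 * np.pi * np.outer(t, stim.framed.freqs) + stim.phases
    ) * _linear_ramp(n_samples, fs, spec.ramp_ms)[:, None]

    # Inter-anchor segments: segment k spans [anchor_k, anchor_{k+1}), each
    # spf samples, where the envelope is a_(k)*(1-u) + a_(k+1)*u.
    half = spf // 2
    n_int = (K - 1) * spf
    u = ((np.arange(n_int) % spf) / spf).reshape(K - 1, spf, 1)
    seg_c = carriers[half : half + n_int].reshape(K - 1, spf, m)
    design = np.concatenate([(1.0 - u) * seg_c, u * seg_c], axis=2)
    y_seg = x[half : half + n_int].reshape(K - 1, spf)

    dT = design.transpose(0, 2, 1)
    gram = dT @ design
    rvec = (dT @ y_seg[:, :, None])[:, :, 0]

    block_diag = np.zeros((K, m, m))
    block_off = np.zeros((K - 1, m, m))
    rhs = np.zeros((K, m))
    block_diag[:-1] += gram[:, :m, :m]
    block_diag[1:] += gram[:, m:, m:]
    block_off += gram[:, :m, m:]
    rhs[:-1] += rvec[:, :m]
    rhs[1:] += rvec[:, m:]
    # held-envelope stubs before the first and after the last anchor
    c_pre, c_post = carriers[:half], carriers[half + n_int :]
    block_diag[0] += c_pre.T @ c_pre
    rhs[0] += c_pre.T @ x[:half]
    block_diag[-1] += c_post.T @ c_post
    rhs[-1] += c_post.T @ x[half + n_int :]

    # assemble symmetric banded (upper) storage, bandwidth 2m - 1
    nb = 2 * m - 1
    ab = np.zeros((nb + 1, K * m))
    for a in range(m):
        for b in range(m):
            if b >= a:
                ab[nb + a - b, b::m] += block_diag[:, a, b]
            ab[nb - m + a - b, m + b :: m] += block_off[:, a, b]
    sol = solveh_banded(ab, rhs.ravel())
    return np.clip(sol.reshape(K, m).T, 1e-12, None)


def measure_spectrotemporal_correlation(
    stim: Stimulus, max_lag: int = 5, n_edge_exclude: int = 1
) -> CorrelationEstimate:
    """Estimate ``r1`` (and the lag-``n`` correlation curve) from the audio.

    Per-frame dB amplitudes at the known component frequencies are
    recovered by :func:`recover_frame_amplitudes`, edge frames are
    discarded, and the Pearson correlation across components is averaged
    over all frame pairs at each lag (``lag_corr[n-1]`` should track
    ``r1**n``).
    """
    n_frames = stim.spec.n_frames
    if n_frames - 2 * n_edge_exclude < 3:
        raise InsufficientDataError("fewer than 3 analyzable frames")

    amps_db = 20.0 * np.log10(recover_frame_amplitudes(stim))
    core = amps_db[:, n_edge_exclude : n_frames - n_edge_exclude]
    lags = np.arange(1, max_lag + 1)
    lag_corr = np.array([_mean_lag_correlation(core, int(n)) for n in lags])
    return CorrelationEstimate(
        r1=float(lag_corr[0]), lags=lags, lag_corr=lag_corr, amps_db=amps_db
    )


def generate_tonotopy_stimulus(
    tspec: TonotopySpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Band-limited random-phase noise with a sinusoidal AM envelope.

    The carrier is synthesized by spectral shaping: unit magnitudes with
    uniform random phases inside ``[band_lo, band_hi]``, zero outside, then
    an inverse real FFT.  The envelope ``(1 + depth*sin(2*pi*rate*t))``
    (normalized to unit peak) imposes the stated modulation depth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = round(tspec.duration_s * tspec.sample_rate)
    freqs = np.fft.rfftfreq(n, d=1.0 / tspec.sample_rate)
    in_band = (freqs >= tspec.band_lo) & (freqs <= tspec.band_hi)
    spectrum = np.zeros(len(freqs), dtype=complex)
    spectrum[in_band] = np.exp(2j * np.pi * rng.uniform(size=in_band.sum()))
    x = np.fft.irfft(spectrum, n=n)

    t = np.arange(n) / tspec.sample_rate
    env = (1.0 + tspec.am_depth * np.sin(2.0 * np.pi * tspec.am_rate * t)) / (
        1.0 + tspec.am_depth
    )
    x *= env
    x *= _linear_ramp(n, tspec.sample_rate, tspec.ramp_ms)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return x


def measure_am_depth(
    waveform: np.ndarray, sample_rate: int, am_rate: float, trim_s: float = 0.25
) -> float:
    """Modulation index of a sinusoidal AM envelope by Hilbert demodulation."""
    env = np.abs(hilbert(waveform))
    n_trim = round(trim_s * sample_rate)
    env = env[n_trim:-n_trim]
    t = np.arange(len(env)) / sample_rate
    proj = np.mean(env * np.exp(-2j * np.pi * am_rate * t))
    return float(2.0 * np.abs(proj) / np.mean(env))


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a normalized waveform as 16-bit PCM WAV."""
    data = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, sample_rate, (data * 32767.0).astype(np.int16))


def generate_corpus(
    template: FluxSpec | None = None,
    levels: tuple[float, ...] = FLUX_LEVELS,
    n_per_level: int = 45,
    seed: int = 0,
    out_dir=None,
    measure: bool = True,
) -> tuple[list[Stimulus], pd.DataFrame]:
    """Generate the full stimulus corpus and its manifest.

    With the defaults (5 levels x 45 exemplars) this reproduces the study's
    225-exemplar corpus.  Every exemplar gets a distinct child seed derived
    from ``seed``; the manifest records seed, level, nominal and (optionally)
    measured ``r1``, and the implied window duration.  If ``out_dir`` is
    given, 16-bit WAV files and a ``manifest.csv`` are written there.
    """
    if template is None:
        template = FluxSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(levels) * n_per_level
    ) % (2**31)
    if len(np.unique(child_seeds)) != len(child_seeds):
        raise ParameterError("duplicate exemplar seeds; choose another corpus seed")

    stimuli: list[Stimulus] = []
    rows = []
    idx = 0
    for level_i, r1 in enumerate(levels, start=1):
        spec = replace(template, r1=r1)
        for _ in range(n_per_level):
            s = int(child_seeds[idx])
            stim = make_stimulus(spec, s)
            measured = (
                measure_spectrotemporal_correlation(stim).r1 if measure else np.nan
            )
            fname = f"flux_L{level_i}_r{r1:.1f}_{idx:04d}.wav"
            if out_dir is not None:
                write_wav(f"{out_dir}/{fname}", stim.waveform, spec.sample_rate)
            rows.append(
                {
                    "exemplar_id": idx,
                    "level": level_i,
                    "nominal_r1": r1,
                    "measured_r1": measured,
                    "window_ms": spec.window_ms,
                    "seed": s,
                    "path": fname if out_dir is not None else "",
                }
            )
            stimuli.append(stim)
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(f"{out_dir}/manifest.csv", index=False)
    return stimuli, manifest
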