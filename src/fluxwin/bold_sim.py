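"""Synthetic BOLD generator: a parcellated auditory-cortex phantom.

The phantom is a simplified two-hemisphere superior-temporal-plane ribbon,
not an anatomically registered brain: ROI-level analysis needs labels and
programmed tuning, not anatomy.  Fifteen auditory fields per hemisphere
(core A1/R/RT, medial belt CM/RM/RTM, lateral belt CL/ML/AL/RTL, parabelt
CPB/RPB, association Tpt/RTp/STGr) are painted as contiguous rectangular
patches, mirror-symmetric across hemispheres.

Programmed physiology follows the study's headline pattern: core responses
decrease linearly across the five flux conditions ordered by window
duration (strong preference for short windows), belt decreases with half
the slope, parabelt and association respond weakly and flat.  A mirrored
high-low-high tonotopic gradient runs along the postero-anterior axis with
its single low-frequency reversal at the A1/R border.  Sampling under the
sparse design adds slow cosine drift and AR(1) Gaussian noise; each volume
is one independent sample of the near-plateau response scaled by an HRF
attenuation factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import nibabel as nib

from .design import SessionDesign
from .errors import ConsistencyError, GeometryError

__all__ = [
    "Phantom",
    "BoldDataset",
    "ROI_NAMES",
    "ROI_TIERS",
    "make_phantom",
    "simulate_session",
    "simulate_tonotopy_session",
]

#: The fifteen auditory fields of each hemisphere.
ROI_NAMES = (
    "A1", "R", "RT",
    "CM", "RM", "RTM",
    "CL", "ML", "AL", "RTL",
    "CPB", "RPB",
    "Tpt", "RTp", "STGr",
)

ROI_TIERS = {
    "A1": "core", "R": "core", "RT": "core",
    "CM": "belt", "RM": "belt", "RTM": "belt",
    "CL": "belt", "ML": "belt", "AL": "belt", "RTL": "belt",
    "CPB": "parabelt", "RPB": "parabelt",
    "Tpt": "association", "RTp": "association", "STGr": "association",
}


@dataclass
class Phantom:
    """Voxel grid with ROI labels, tuning curves, tonotopy and noise model."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    roi_labels: np.ndarray  # int, 0 = background, 1..15 = ROI_NAMES index+1
    hemisphere: np.ndarray  # -1 background, 0 left, 1 right
    tuning: dict[str, np.ndarray]  # ROI name -> %SC per condition (short->long)
    best_band: np.ndarray  # 0 background, 1..n_bands
    baseline: float
    noise_sd: float  # percent of baseline
    ar_coef: float
    drift_amp: float  # percent of baseline
    tono_amp: float = 2.0  # %SC at the preferred band
    tono_falloff: float = 0.5  # response ratio per band of distance

    @property
    def mask(self) -> np.ndarray:
        return self.roi_labels > 0

    def roi_mask(self, name: str, hemi: int | None = None) -> np.ndarray:
        idx = ROI_NAMES.index(name) + 1
        m = self.roi_labels == idx
        if hemi is not None:
            m &= self.hemisphere == hemi
        return m

    def labels_nifti(self) -> nib.Nifti1Image:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return nib.Nifti1Image(self.roi_labels.astype(np.int16), aff)


@dataclass
class BoldDataset:
    """4D BOLD intensities sampled under a sparse design."""

    volumes: np.ndarray  # (X, Y, Z, T)
    design: SessionDesign
    mask: np.ndarray
    voxel_size_mm: float = 1.2
    truth: Phantom | None = None

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[-1]

    def to_nifti(self) -> nib.Nifti1Image:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return nib.Nifti1Image(self.volumes.astype(np.float32), aff)


def _paint(labels: np.ndarray, region: tuple, value: int) -> None:
    xs, ys, zs = region
    block = labels[xs, ys, zs]
    if np.any(block != 0):
        raise GeometryError(f"ROI {value} overlaps an existing region")
    labels[xs, ys, zs] = value


def _band_profile(ny: int, y: np.ndarray, n_bands: int, reversal_y: float,
                  span: float) -> np.ndarray:
    """High-low-high band index along the postero-anterior axis.

    Descends from the highest band to band 1 at ``reversal_y`` (the A1/R
    border) then ascends back: exactly one frequency reversal.
    """
    d = np.abs(y - reversal_y) / span  # 0 at border -> low frequency
    band = 1 + np.minimum(np.floor(d * n_bands), n_bands - 1)
    return band.astype(int)


def make_phantom(
    grid_shape: tuple[int, int, int] = (48, 48, 8),
    voxel_size_mm: float = 1.2,
    core_amp: float = 2.0,
    core_slope: float = 0.25,
    belt_amp: float = 1.5,
    belt_slope: float = 0.125,
    parabelt_amp: float = 0.4,
    assoc_amp: float = 0.3,
    n_conditions: int = 5,
    n_bands: int = 3,
    baseline: float = 1000.0,
    noise_sd: float = 1.0,
    ar_coef: float = 0.1,
    drift_amp: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Build the default two-hemisphere phantom.

    Tuning is %-signal-change per condition with conditions ordered from
    shortest to longest analysis window; ``core_amp`` is the core response
    to the shortest-window condition and ``core_slope`` the per-condition
    decrement (belt: half slope by default; parabelt/association: flat).
    """
    nx, ny, nz = grid_shape
    if nx < 44 or ny < 46 or nz < 4:
        raise GeometryError("grid too small for the STP ribbon layout")
    labels = np.zeros(grid_shape, dtype=np.int16)
    hemi = np.full(grid_shape, -1, dtype=np.int8)

    zs = slice(2, min(nz - 1, 6))
    # local-x columns of the left hemisphere ribbon, with 2-voxel gaps so
    # that 3-mm smoothing cannot mix tuning across tier boundaries
    med = slice(2, 6)
    core = slice(8, 12)
    lat = slice(14, 18)
    outer = slice(20, 24)
    regions = {
        # core column, posterior -> anterior (gaps flank the flat-tuned
        # association fields Tpt and RTp)
        "Tpt": (core, slice(4, 10)),
        "A1": (core, slice(12, 24)),
        "R": (core, slice(24, 34)),
        "RT": (core, slice(34, 38)),
        "RTp": (core, slice(40, 44)),
        # medial belt
        "CM": (med, slice(12, 24)),
        "RM": (med, slice(24, 34)),
        "RTM": (med, slice(34, 40)),
        # lateral belt
        "CL": (lat, slice(12, 20)),
        "ML": (lat, slice(20, 28)),
        "AL": (lat, slice(28, 34)),
        "RTL": (lat, slice(34, 40)),
        # parabelt + rostral association
        "CPB": (outer, slice(8, 22)),
        "RPB": (outer, slice(22, 34)),
        "STGr": (outer, slice(36, 44)),
    }
    for name, (xs, ys) in regions.items():
        _paint(labels, (xs, ys, zs), ROI_NAMES.index(name) + 1)
    # mirror into the right hemisphere
    left = labels.copy()
    labels += left[::-1, :, :]
    hemi[left > 0] = 0
    hemi[(left == 0) & (labels > 0)] = 1

    # mirrored high-low-high tonotopic gradient, reversal at the A1/R border
    y = np.arange(ny, dtype=float)
    band_y = _band_profile(ny, y, n_bands, reversal_y=24.0, span=13.0)
    best_band = np.zeros(grid_shape, dtype=np.int16)
    best_band[labels > 0] = np.broadcast_to(
        band_y[None, :, None], grid_shape
    )[labels > 0]

    conds = np.arange(n_conditions, dtype=float)
    tuning: dict[str, np.ndarray] = {}
    for name in ROI_NAMES:
        tier = ROI_TIERS[name]
        if tier == "core":
            amps = core_amp - core_slope * conds
        elif tier == "belt":
            amps = belt_amp - belt_slope * conds
        elif tier == "parabelt":
            amps = np.full(n_conditions, parabelt_amp)
        else:
            amps = np.full(n_conditions, assoc_amp)
        if np.any(amps < 0):
            raise GeometryError("tuning amplitudes must stay non-negative")
        tuning[name] = amps

    return Phantom(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        roi_labels=labels,
        hemisphere=hemi,
        tuning=tuning,
        best_band=best_band,
        baseline=baseline,
        noise_sd=noise_sd,
        ar_coef=ar_coef,
        drift_amp=drift_amp,
    )


def _condition_pct_map(phantom: Phantom, n_conditions: int) -> np.ndarray:
    """(n_voxels_in_mask, n_conditions) programmed %SC for flux conditions."""
    mask = phantom.mask
    lab = phantom.roi_labels[mask]
    n_prog = len(next(iter(phantom.tuning.values())))
    if n_conditions > n_prog:
        raise ConsistencyError(
            f"design has {n_conditions} conditions but phantom tuning "
            f"covers {n_prog}"
        )
    out = np.zeros((mask.sum(), n_conditions))
    for name in ROI_NAMES:
        sel = lab == ROI_NAMES.index(name) + 1
        out[sel] = phantom.tuning[name][:n_conditions]
    return out


def _tono_pct_map(phantom: Phantom, n_bands: int) -> np.ndarray:
    """(n_voxels_in_mask, n_bands) %SC response for tonotopy bands."""
    best = phantom.best_band[phantom.mask]
    bands = np.arange(1, n_bands + 1)
    return phantom.tono_amp * phantom.tono_falloff ** np.abs(
        bands[None, :] - best[:, None]
    )


def _sample_noise_and_drift(
    phantom: Phantom, design: SessionDesign, rng: np.random.Generator,
    n_vox: int,
) -> np.ndarray:
    """AR(1) noise plus per-session slow cosine drift, in intensity units."""
    n_t = design.n_volumes
    sd = phantom.noise_sd / 100.0 * phantom.baseline
    noise = np.empty((n_vox, n_t), dtype=np.float64)
    rho = phantom.ar_coef
    noise[:, 0] = sd * rng.standard_normal(n_vox)
    innov = np.sqrt(1.0 - rho * rho) * sd
    for t in range(1, n_t):
        noise[:, t] = rho * noise[:, t - 1] + innov * rng.standard_normal(n_vox)

    drift = np.zeros(n_t)
    amp = phantom.drift_amp / 100.0 * phantom.baseline
    sess = design.trials["session"].to_numpy()
    tsec = design.trials["acq_onset_s"].to_numpy()
    for s in np.unique(sess):
        m = sess == s
        for period in (240.0, 480.0):  # slower than the 120-s cutoff
            phase = rng.uniform(0, 2 * np.pi)
            drift[m] += amp * np.cos(2 * np.pi * tsec[m] / period + phase)
    return noise + drift[None, :]


def _simulate(
    phantom: Phantom,
    design: SessionDesign,
    pct: np.ndarray,  # (n_vox_in_mask, n_conditions)
    seed: int,
    hrf_factor: float,
) -> BoldDataset:
    levels = design.trials["level"].to_numpy()
    n_cond = pct.shape[1]
    if levels.max() > n_cond:
        raise ConsistencyError(
            f"design has {levels.max()} levels but phantom tuning covers {n_cond}"
        )
    rng = np.random.default_rng(seed)
    mask = phantom.mask
    n_vox = int(mask.sum())

    gain = np.ones((n_vox, design.n_volumes))
    stim = levels > 0
    gain[:, stim] += pct[:, levels[stim] - 1] / 100.0 * hrf_factor
    signal = phantom.baseline * gain
    signal += _sample_noise_and_drift(phantom, design, rng, n_vox)

    vols = np.full(phantom.grid_shape + (design.n_volumes,),
                   phantom.baseline, dtype=np.float64)
    # background gets plain white noise so global scaling stays benign
    bg_sd = phantom.noise_sd / 100.0 * phantom.baseline
    n_bg = int((~mask).sum())
    vols[~mask] += bg_sd * rng.standard_normal((n_bg, design.n_volumes))
    vols[mask] = signal
    return BoldDataset(
        volumes=vols,
        design=design,
        mask=mask.copy(),
        voxel_size_mm=phantom.voxel_size_mm,
        truth=phantom,
    )


def simulate_session(
    phantom: Phantom,
    design: SessionDesign,
    seed: int = 0,
    hrf_factor: float = 1.0,
) -> BoldDataset:
    """Sample flux-experiment BOLD volumes from the phantom.

    Expected intensity of a stimulus volume is
    ``baseline * (1 + tuning[roi, condition]/100 * hrf_factor)``; silence
    volumes carry baseline plus noise only.  Bit-reproducible from
    (phantom, design, seed).
    """
    pct = _condition_pct_map(phantom, design.n_levels)
    return _simulate(phantom, design, pct, seed, hrf_factor)


def simulate_tonotopy_session(
    phantom: Phantom,
    design: SessionDesign,
    seed: int = 0,
    hrf_factor: float = 1.0,
) -> BoldDataset:
    """Sample tonotopy-experiment volumes (conditions are frequency bands).

    Voxel response to band ``b`` is ``tono_amp * tono_falloff**|b - best|``
    %SC, maximal at the voxel's programmed best band.
    """
    pct = _tono_pct_map(phantom, design.n_levels)
    return _simulate(phantom, design, pct, seed, hrf_factor)
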