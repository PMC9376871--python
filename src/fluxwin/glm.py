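"""Mass-univariate GLM for sparse-sampling BOLD data.

Smoothing, design-matrix construction (condition indicators scaled by an
HRF attenuation factor, discrete-cosine drift regressors implementing the
high-pass filter, per-session intercepts), session-wise global scaling to
a grand mean of 100, voxel-wise ordinary least squares, and t-contrasts.

Because the sparse design acquires one volume per trial at a near-plateau
hemodynamic delay, HRF convolution reduces to a scalar attenuation factor
per volume (1.0 at plateau).  The canonical double-gamma response is still
available (:func:`canonical_hrf`, :func:`hrf_factor_at`) so non-plateau
acquisition timing can be studied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gammaln
from scipy import stats

from .bold_sim import BoldDataset
from .design import SessionDesign
from .errors import DesignError, ParameterError

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "ContrastSpec",
    "canonical_hrf",
    "hrf_factor_at",
    "smooth_volumes",
    "build_design_matrix",
    "global_scale",
    "fit_glm",
    "t_contrast",
    "threshold_map",
    "T_DEFAULT",
]

#: Default one-sided threshold, t > 3.1 (P < 0.001 at the session df).
T_DEFAULT = 3.1


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str]
    condition_columns: list[int]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class GlmResult:
    betas: np.ndarray  # (..., n_regressors)
    sigma2: np.ndarray  # (...)
    df: int
    design: DesignMatrix

    def condition_betas(self) -> np.ndarray:
        return self.betas[..., self.design.condition_columns]


@dataclass
class ContrastSpec:
    """Per-condition contrast weights; parametric contrasts sum to zero."""

    weights: np.ndarray
    name: str = ""
    parametric: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.parametric and abs(self.weights.sum()) > 1e-9:
            raise ParameterError(
                f"parametric contrast {self.name!r} must sum to zero"
            )


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response.

    Peak ~5 s, undershoot ~15 s, undershoot ratio 1/6; unit peak.  ``t``
    in seconds.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x, shape, scale):
        return np.exp(
            (shape - 1) * np.log(x) - x / scale
            - shape * np.log(scale) - gammaln(shape)
        )

    h = gpdf(tp, 6.0, 1.0) - gpdf(tp, 16.0, 1.0) / 6.0
    out[pos] = h
    peak = out.max()
    return out / peak if peak > 0 else out


def hrf_factor_at(
    acq_delay_s: float, stim_dur_s: float = 6.0, dt: float = 0.1
) -> float:
    """Response level at ``acq_delay_s`` after onset of a boxcar stimulus.

    The boxcar of ``stim_dur_s`` convolved with the canonical HRF,
    normalized to its plateau (maximum), evaluated at the acquisition
    time.  With 6-s stimuli sampled 4.65 s after onset this is close
    to 1, matching the plateau logic of the sparse design.
    """
    t = np.arange(0, max(acq_delay_s, stim_dur_s) + 32.0, dt)
    box = (t < stim_dur_s).astype(float)
    resp = np.convolve(box, canonical_hrf(t))[: len(t)] * dt
    resp /= resp.max()
    return float(np.interp(acq_delay_s, t, resp))


def smooth_volumes(data: BoldDataset, fwhm_mm: float) -> BoldDataset:
    """Per-volume 3D Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ParameterError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return data
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / data.voxel_size_mm
    out = np.empty_like(data.volumes)
    for t in range(data.n_volumes):
        gaussian_filter(data.volumes[..., t], sigma_vox, output=out[..., t],
                        mode="nearest")
    return BoldDataset(
        volumes=out, design=data.design, mask=data.mask,
        voxel_size_mm=data.voxel_size_mm, truth=data.truth,
    )


def _dct_drift_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: cosines with periods > cutoff.

    Standard construction: component k has period 2*T/k, so the count of
    retained components is floor(2*T/cutoff) (DC excluded; the session
    intercept covers it).
    """
    t_total = n * tr_s
    n_comp = int(np.floor(2.0 * t_total / cutoff_s))
    t = np.arange(n)
    basis = np.empty((n, n_comp))
    for k in range(1, n_comp + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n) * np.cos(
            np.pi * k * (2 * t + 1) / (2 * n)
        )
    return basis


def build_design_matrix(
    design: SessionDesign,
    hp_cutoff_s: float = 120.0,
    hrf_factor: float = 1.0,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Condition indicators + DCT drift + per-session intercepts.

    One column per flux condition (silence is the implicit baseline) with
    entries ``hrf_factor`` at that condition's volumes; per session, a
    discrete-cosine drift basis spanning periods longer than
    ``hp_cutoff_s``; one intercept per session.  Optional motion nuisance
    columns are appended unchanged.
    """
    levels = design.trials["level"].to_numpy()
    sessions = design.trials["session"].to_numpy()
    n = len(levels)
    n_cond = design.n_levels

    cond_cols = np.zeros((n, n_cond))
    for lv in range(1, n_cond + 1):
        cond_cols[levels == lv, lv - 1] = hrf_factor
    if not np.any(cond_cols):
        raise DesignError("design contains no stimulus volumes")

    cols = [cond_cols]
    labels = [f"level{lv}" for lv in range(1, n_cond + 1)]
    uniq = np.unique(sessions)
    for s in uniq:
        m = sessions == s
        drift = _dct_drift_basis(int(m.sum()), design.tr_s, hp_cutoff_s)
        block = np.zeros((n, drift.shape[1]))
        block[m] = drift
        cols.append(block)
        labels += [f"drift_s{s}_{k}" for k in range(drift.shape[1])]
    for s in uniq:
        icol = (sessions == s).astype(float)[:, None]
        cols.append(icol)
        labels.append(f"intercept_s{s}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n:
            motion = motion.T
        cols.append(motion)
        labels += [f"motion_{k}" for k in range(motion.shape[1])]

    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return DesignMatrix(
        matrix=X, labels=labels, condition_columns=list(range(n_cond))
    )


def global_scale(data: BoldDataset, target: float = 100.0) -> BoldDataset:
    """Scale each session so its mean in-mask intensity equals ``target``.

    Removes session-to-session gain differences; after scaling, betas are
    in percent of the session grand mean.
    """
    sessions = data.design.trials["session"].to_numpy()
    vols = data.volumes.astype(np.float64).copy()
    inmask = vols[data.mask]
    for s in np.unique(sessions):
        m = sessions == s
        g = inmask[:, m].mean()
        if not g > 0:
            raise ParameterError("nonpositive session global mean")
        vols[..., m] *= target / g
    return BoldDataset(
        volumes=vols, design=data.design, mask=data.mask,
        voxel_size_mm=data.voxel_size_mm, truth=data.truth,
    )


def fit_glm(data: BoldDataset | np.ndarray, X: DesignMatrix) -> GlmResult:
    """Voxel-wise ordinary least squares.

    ``data`` may be a :class:`BoldDataset` (fits every in-mask voxel) or a
    plain ``(n_series, n_volumes)`` array.  ``betas = pinv(X) y``;
    ``sigma2 = RSS / df`` with ``df = n_volumes - rank(X)``.
    """
    if isinstance(data, BoldDataset):
        y = data.volumes[data.mask]  # (n_vox, T)
    else:
        y = np.atleast_2d(np.asarray(data, dtype=float))
    mat = X.matrix
    if y.shape[1] != mat.shape[0]:
        raise DesignError("time dimension of data and design differ")
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        raise DesignError("design matrix is rank deficient")
    pinv = np.linalg.pinv(mat)
    betas = y @ pinv.T
    resid = y - betas @ mat.T
    df = mat.shape[0] - rank
    sigma2 = (resid**2).sum(axis=1) / df
    return GlmResult(betas=betas, sigma2=sigma2, df=df, design=X)


def t_contrast(glm: GlmResult, c: ContrastSpec | np.ndarray) -> np.ndarray:
    """t-statistic per series: ``c'b / sqrt(sigma2 * c'(X'X)^-1 c)``.

    Condition-length weight vectors are padded with zeros over nuisance
    columns.  Zero-variance series yield NaN (flagged, excluded from maps).
    """
    w = c.weights if isinstance(c, ContrastSpec) else np.asarray(c, float)
    mat = glm.design.matrix
    full = np.zeros(mat.shape[1])
    if w.shape[0] == mat.shape[1]:
        full[:] = w
    elif w.shape[0] == len(glm.design.condition_columns):
        full[glm.design.condition_columns] = w
    else:
        raise ParameterError("contrast weights not conformable with design")
    xtx_inv = np.linalg.inv(mat.T @ mat)
    var_unit = float(full @ xtx_inv @ full)
    eff = glm.betas @ full
    if var_unit == 0.0:  # identically zero contrast
        return np.zeros_like(eff)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = eff / np.sqrt(glm.sigma2 * var_unit)
    t[glm.sigma2 <= 0] = np.nan
    return t


def t_to_p(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """One-sided upper-tail p-value of a Student-t statistic."""
    return stats.t.sf(t, df)


def threshold_map(tmap: np.ndarray, t_thresh: float = T_DEFAULT) -> np.ndarray:
    """One-sided suprathreshold mask ``t > t_thresh`` (NaN excluded)."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(tmap, nan=-np.inf) > t_thresh
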