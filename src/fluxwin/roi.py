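"""ROI-level contrast averaging, corrected inference, and group summaries.

Following the MarsBaR convention, the ROI statistic is computed by
refitting the GLM on the spatially averaged time series of the ROI's
sound-responsive voxels (not by averaging voxel t-values); the ROI
contrast estimate reported alongside is the mean of the voxel-wise
contrast values over the same voxels.  Hemispheres are separate inference
units, and ROI-level significance is Bonferroni-corrected over the ROI
family (n = 30: fifteen fields in each of two hemispheres).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bold_sim import BoldDataset, Phantom, ROI_NAMES, ROI_TIERS
from .errors import ConsistencyError
from .glm import ContrastSpec, DesignMatrix, fit_glm, t_contrast, t_to_p
from .maps import LINEAR_NEGATIVE_WEIGHTS

__all__ = [
    "sound_contrast_weights",
    "roi_contrast_table",
    "roi_significance",
    "group_summary",
]

HEMI_NAMES = {0: "L", 1: "R"}


def sound_contrast_weights(n_conditions: int = 5) -> ContrastSpec:
    """All-stimuli-vs-silence contrast: the mean of the condition betas."""
    return ContrastSpec(
        np.full(n_conditions, 1.0 / n_conditions),
        name="sound_vs_silence",
        parametric=False,
    )


def roi_contrast_table(
    data: BoldDataset,
    X: DesignMatrix,
    phantom: Phantom,
    sound_mask: np.ndarray,
    subject: str = "sim",
    param_weights: np.ndarray = LINEAR_NEGATIVE_WEIGHTS,
) -> pd.DataFrame:
    """Per-(ROI, hemisphere) contrast estimates and averaged-series tests.

    For each ROI and hemisphere the voxels in ``ROI & sound_mask`` are
    selected; the voxel-wise sound and parametric contrast estimates are
    averaged over them, and t/p for both contrasts come from a GLM refit
    on the spatially averaged time series.  Empty intersections yield a
    flagged row with ``n_voxels = 0`` that is excluded from inference.
    """
    if phantom.roi_labels.shape != data.volumes.shape[:3]:
        raise ConsistencyError("ROI labels are not aligned with the data grid")
    n_cond = X.matrix[:, X.condition_columns].shape[1]
    sound_c = sound_contrast_weights(n_cond)
    param_c = ContrastSpec(param_weights, name="parametric")

    glm_vox = fit_glm(data, X)
    cond_betas = glm_vox.condition_betas()  # (n_vox_in_mask, n_cond)
    vox_sound = cond_betas @ sound_c.weights
    vox_param = cond_betas @ param_c.weights
    mask_idx = np.zeros(phantom.grid_shape, dtype=int)
    mask_idx[data.mask] = np.arange(int(data.mask.sum()))

    rows = []
    for roi in ROI_NAMES:
        for hemi in (0, 1):
            sel3d = phantom.roi_mask(roi, hemi) & sound_mask & data.mask
            n_vox = int(sel3d.sum())
            row = {
                "subject": subject,
                "hemisphere": HEMI_NAMES[hemi],
                "roi": roi,
                "tier": ROI_TIERS[roi],
                "n_voxels": n_vox,
                "empty": n_vox == 0,
            }
            if n_vox == 0:
                row.update(
                    mean_sound=np.nan, mean_param=np.nan,
                    t_sound=np.nan, p_sound=np.nan,
                    t_param=np.nan, p_param=np.nan,
                )
            else:
                idx = mask_idx[sel3d]
                avg_series = data.volumes[sel3d].mean(axis=0)
                glm_roi = fit_glm(avg_series[None, :], X)
                t_s = float(t_contrast(glm_roi, sound_c)[0])
                t_p = float(t_contrast(glm_roi, param_c)[0])
                row.update(
                    mean_sound=float(vox_sound[idx].mean()),
                    mean_param=float(vox_param[idx].mean()),
                    t_sound=t_s,
                    p_sound=float(t_to_p(t_s, glm_roi.df)),
                    t_param=t_p,
                    p_param=float(t_to_p(t_p, glm_roi.df)),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def roi_significance(
    table: pd.DataFrame, alpha: float = 0.05, n_rois: int = 30
) -> pd.DataFrame:
    """Bonferroni-corrected significance flags at ``p < alpha / n_rois``."""
    out = table.copy()
    thresh = alpha / n_rois
    out["sig_sound"] = (out["p_sound"] < thresh) & ~out["empty"]
    out["sig_param"] = (out["p_param"] < thresh) & ~out["empty"]
    return out


def group_summary(
    tables: list[pd.DataFrame], weight: str = "hemisphere"
) -> pd.DataFrame:
    """Per-ROI group mean contrast and count of significant hemispheres.

    ``weight='hemisphere'`` (default) averages every hemisphere of every
    subject equally; ``weight='animal'`` first averages hemispheres within
    subject.  ROIs missing from some tables are kept via union with
    missing-value handling.
    """
    if not tables:
        raise ConsistencyError("need at least one ROI table")
    allt = pd.concat(tables, ignore_index=True)
    if "sig_param" not in allt.columns:
        allt = roi_significance(allt)
    valid = allt[~allt["empty"]]
    if weight == "animal":
        per_subj = valid.groupby(["roi", "subject"], sort=False)[
            ["mean_param", "mean_sound"]
        ].mean().reset_index()
        means = per_subj.groupby("roi", sort=False)[
            ["mean_param", "mean_sound"]
        ].mean()
    elif weight == "hemisphere":
        means = valid.groupby("roi", sort=False)[
            ["mean_param", "mean_sound"]
        ].mean()
    else:
        raise ValueError("weight must be 'hemisphere' or 'animal'")
    counts = valid.groupby("roi", sort=False)["sig_param"].sum().astype(int)
    out = means.join(counts.rename("n_hemis_significant"), how="outer")
    out["tier"] = [ROI_TIERS.get(r, "") for r in out.index]
    return out.reset_index()
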