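"""Full analysis on one simulated subject: phantom -> GLM -> ROI table.

The phantom programs the study's headline physiology: core fields respond
more strongly to short analysis windows (high spectral flux), belt fields
with half the gradient, parabelt weakly and flat.  The pipeline smooths
(3 mm FWHM), scales each session to a grand mean of 100, fits the GLM,
masks sound-responsive voxels (t > 3.1), and summarizes the linear
negative parametric contrast (weights 2, 1, 0, -1, -2; positive = prefers
shorter windows) per ROI with Bonferroni correction over 30 ROIs.
"""

import numpy as np

import fluxwin as fw

design = fw.generate_session_design(360, 5, seed=1)
phantom = fw.make_phantom()
data = fw.simulate_session(phantom, design, seed=2)
data = fw.global_scale(fw.smooth_volumes(data, fwhm_mm=3.0))

X = fw.build_design_matrix(design, hp_cutoff_s=120.0)
glm = fw.fit_glm(data, X)

t_sound = fw.t_contrast(glm, fw.sound_contrast_weights())
sound_mask = fw.embed(t_sound, data.mask, fill=-np.inf) > fw.T_DEFAULT
print(f"sound-responsive voxels (t > {fw.T_DEFAULT}):", int(sound_mask.sum()))

table = fw.roi_significance(
    fw.roi_contrast_table(data, X, phantom, sound_mask, subject="sim1")
)
cols = ["roi", "hemisphere", "tier", "n_voxels", "mean_param", "t_param",
        "sig_param"]
show = table[table.roi.isin(["A1", "CM", "AL", "RPB"])]
print("\nparametric contrast by ROI (positive = short-window preference):")
print(show[cols].to_string(index=False, float_format="%.3f"))

print("\nexpected pattern: strong significant contrast in core (A1), "
      "weaker in belt (CM, AL), null in parabelt (RPB).")
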