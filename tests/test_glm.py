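"""GLM machinery: smoothing, design construction, scaling, OLS, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fluxwin as fw
from fluxwin.design import SessionDesign
from fluxwin.errors import DesignError, ParameterError
from fluxwin.glm import _dct_drift_basis


def _noise_dataset(shape, design, seed, mask=None):
    rng = np.random.default_rng(seed)
    vols = rng.standard_normal(shape + (design.n_volumes,)) + 100.0
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return fw.BoldDataset(volumes=vols, design=design, mask=mask)


class TestSmoothing:
    def test_zero_fwhm_identity(self, session_design):
        ds = _noise_dataset((6, 6, 4), session_design, 0)
        assert fw.smooth_volumes(ds, 0.0) is ds

    def test_impulse_matches_analytic_gaussian(self, session_design):
        d = fw.generate_session_design(8, 5, seed=0)
        vols = np.zeros((21, 21, 21, 8))
        vols[10, 10, 10, :] = 1.0
        ds = fw.BoldDataset(volumes=vols, design=d,
                            mask=np.ones((21, 21, 21), bool),
                            voxel_size_mm=1.2)
        sm = fw.smooth_volumes(ds, 3.0).volumes[..., 0]
        sigma = 3.0 / (2 * np.sqrt(2 * np.log(2))) / 1.2
        offs = np.arange(21) - 10
        g1 = np.exp(-(offs**2) / (2 * sigma**2))
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        assert np.allclose(sm, expected, atol=1e-4)

    def test_constant_volume_preserved(self, session_design):
        d = fw.generate_session_design(8, 5, seed=0)
        vols = np.full((10, 10, 6, 8), 7.0)
        ds = fw.BoldDataset(volumes=vols, design=d,
                            mask=np.ones((10, 10, 6), bool))
        sm = fw.smooth_volumes(ds, 3.0)
        assert np.allclose(sm.volumes, 7.0)


class TestDesignMatrix:
    def test_condition_columns_have_45_entries(self, session_design):
        X = fw.build_design_matrix(session_design)
        cond = X.matrix[:, X.condition_columns]
        assert cond.shape == (360, 5)
        assert np.all((cond > 0).sum(axis=0) == 45)

    def test_dct_column_count(self):
        """floor(2 T / cutoff) drift columns per session."""
        basis = _dct_drift_basis(360, 10.0, 120.0)
        assert basis.shape[1] == int(np.floor(2 * 3600 / 120))

    def test_highpass_removes_slow_cosine(self):
        """A cosine slower than the cutoff is captured by the drift basis."""
        d = fw.generate_session_design(360, 5, seed=1)
        X = fw.build_design_matrix(d, hp_cutoff_s=120.0)
        t = d.trials.acq_onset_s.to_numpy()
        slow = np.cos(2 * np.pi * t / 300.0 + 0.7)
        glm = fw.fit_glm(slow[None, :], X)
        resid_var = glm.sigma2[0] * glm.df / len(t)
        assert resid_var < 0.01 * slow.var()

    def test_silence_only_design_rejected(self):
        d = fw.generate_session_design(16, 5, seed=0)
        trials = d.trials.copy()
        trials["level"] = 0
        silent = SessionDesign(trials=trials, n_levels=5)
        with pytest.raises(DesignError):
            fw.build_design_matrix(silent)

    def test_per_session_intercepts(self):
        multi = fw.concatenate_sessions(
            [fw.generate_session_design(80, 5, seed=s) for s in range(3)]
        )
        X = fw.build_design_matrix(multi)
        assert sum(lb.startswith("intercept") for lb in X.labels) == 3

    def test_motion_columns_appended(self, session_design):
        rng = np.random.default_rng(0)
        X = fw.build_design_matrix(session_design,
                                   motion=rng.standard_normal((360, 6)))
        assert sum(lb.startswith("motion") for lb in X.labels) == 6


class TestGlobalScaling:
    def test_constant_data_scales_to_target(self):
        d = fw.generate_session_design(16, 5, seed=0)
        vols = np.full((4, 4, 2, 16), 137.0)
        ds = fw.BoldDataset(volumes=vols, design=d,
                            mask=np.ones((4, 4, 2), bool))
        assert np.allclose(fw.global_scale(ds).volumes, 100.0)

    def test_session_gain_invariance(self):
        multi = fw.concatenate_sessions(
            [fw.generate_session_design(40, 5, seed=s) for s in range(2)]
        )
        rng = np.random.default_rng(3)
        base = rng.standard_normal((5, 5, 2, 80)) + 200.0
        gain = np.where(multi.trials.session.to_numpy() == 0, 1.0, 3.7)
        ds = fw.BoldDataset(volumes=base * gain, design=multi,
                            mask=np.ones((5, 5, 2), bool))
        scaled = fw.global_scale(ds)
        sess = multi.trials.session.to_numpy()
        m0 = scaled.volumes[..., sess == 0].mean()
        m1 = scaled.volumes[..., sess == 1].mean()
        assert m0 == pytest.approx(100.0) and m1 == pytest.approx(100.0)

    def test_betas_invariant_to_global_gain(self, quiet_phantom):
        d = fw.generate_session_design(80, 5, seed=4)
        X = fw.build_design_matrix(d)
        ds = fw.simulate_session(quiet_phantom, d, seed=5)
        b1 = fw.fit_glm(fw.global_scale(ds), X).betas
        ds2 = fw.BoldDataset(volumes=ds.volumes * 13.5, design=d,
                             mask=ds.mask, truth=ds.truth)
        b2 = fw.fit_glm(fw.global_scale(ds2), X).betas
        assert np.allclose(b1, b2, atol=1e-9)


class TestOls:
    def test_matches_hand_solved_normal_equations(self):
        """Betas equal the closed-form (X'X)^-1 X'y on a tiny system."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([[1.0, 2.1, 2.9, 4.2]])
        dm = fw.DesignMatrix(matrix=X, labels=["i", "s"], condition_columns=[1])
        glm = fw.fit_glm(y, dm)
        expected = np.linalg.solve(X.T @ X, X.T @ y[0])
        assert np.allclose(glm.betas[0], expected)
        assert glm.df == 2

    def test_residuals_orthogonal_to_design(self, session_design):
        X = fw.build_design_matrix(session_design)
        rng = np.random.default_rng(1)
        y = rng.standard_normal((50, 360))
        glm = fw.fit_glm(y, X)
        resid = y - glm.betas @ X.matrix.T
        assert np.max(np.abs(resid @ X.matrix)) < 1e-8

    def test_row_permutation_invariance(self, session_design):
        X = fw.build_design_matrix(session_design)
        rng = np.random.default_rng(2)
        y = rng.standard_normal((10, 360))
        perm = rng.permutation(360)
        Xp = fw.DesignMatrix(matrix=X.matrix[perm], labels=X.labels,
                             condition_columns=X.condition_columns)
        b1 = fw.fit_glm(y, X).betas
        b2 = fw.fit_glm(y[:, perm], Xp).betas
        assert np.allclose(b1, b2)

    def test_matches_nilearn_oracle(self, session_design):
        """Betas and t-values agree with an independent GLM implementation."""
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        X = fw.build_design_matrix(session_design)
        rng = np.random.default_rng(7)
        y = rng.standard_normal((30, 360)) + 100.0
        glm = fw.fit_glm(y, X)
        labels, results = nilearn_glm.run_glm(y.T, X.matrix, noise_model="ols")
        assert len(np.unique(labels)) == 1  # one OLS model for all voxels
        ref_betas = results[labels[0]].theta  # (n_regressors, n_voxels)
        assert np.allclose(glm.betas.T, ref_betas, atol=1e-8)
        from nilearn.glm import compute_contrast

        w = np.zeros(X.matrix.shape[1])
        w[X.condition_columns] = fw.LINEAR_NEGATIVE_WEIGHTS
        ref_t = compute_contrast(labels, results, w, stat_type="t").stat()
        ours = fw.t_contrast(glm, fw.LINEAR_NEGATIVE_WEIGHTS)
        assert np.allclose(ours, ref_t, atol=1e-6)


class TestTContrast:
    def test_null_exceedance_near_nominal(self, session_design):
        X = fw.build_design_matrix(session_design)
        rng = np.random.default_rng(11)
        y = rng.standard_normal((20000, 360))
        glm = fw.fit_glm(y, X)
        t = fw.t_contrast(glm, fw.LINEAR_NEGATIVE_WEIGHTS)
        frac = (t > 3.1).mean()
        p = stats.t.sf(3.1, glm.df)
        # 4-sigma binomial band around the nominal rate
        tol = 4 * np.sqrt(p * (1 - p) / len(t))
        assert abs(frac - p) < tol

    def test_zero_weights_give_zero_t(self, session_design):
        X = fw.build_design_matrix(session_design)
        y = np.random.default_rng(0).standard_normal((5, 360))
        glm = fw.fit_glm(y, X)
        t = fw.t_contrast(glm, np.zeros(5))
        assert np.allclose(t, 0.0)

    def test_zero_variance_flagged_nan(self, session_design):
        X = fw.build_design_matrix(session_design)
        y = np.zeros((1, 360))
        glm = fw.fit_glm(y, X)
        t = fw.t_contrast(glm, fw.LINEAR_NEGATIVE_WEIGHTS)
        assert np.isnan(t[0])

    def test_nonconformable_weights(self, session_design):
        X = fw.build_design_matrix(session_design)
        glm = fw.fit_glm(np.zeros((1, 360)), X)
        with pytest.raises(ParameterError):
            fw.t_contrast(glm, np.ones(4))


class TestThresholdAndHrf:
    def test_threshold_edges(self):
        tmap = np.zeros(10)
        assert fw.threshold_map(tmap, 3.1).sum() == 0
        assert fw.threshold_map(tmap, -np.inf).sum() == 10

    def test_hrf_shape(self):
        t = np.arange(0, 32, 0.1)
        h = fw.canonical_hrf(t)
        assert h.max() == pytest.approx(1.0)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=1.0)
        assert h[(t > 10) & (t < 20)].min() < 0  # undershoot

    def test_boxcar_response_rises_to_plateau(self):
        """The boxcar response rises monotonically toward its plateau."""
        f3, f6, f9 = (fw.hrf_factor_at(x) for x in (3.0, 6.0, 9.0))
        assert 0.0 < f3 < f6 < f9
        assert f9 > 0.9  # near the plateau of the 6-s boxcar response
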