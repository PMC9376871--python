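import numpy as np
import pytest

import fluxwin as fw


@pytest.fixture(scope="session")
def short_spec():
    """A 2-s flux spec: 100 frames, enough for correlation estimation."""
    return fw.FluxSpec(r1=0.8, duration_s=2.0)


@pytest.fixture(scope="session")
def session_design():
    return fw.generate_session_design(360, 5, seed=11)


@pytest.fixture(scope="session")
def phantom():
    return fw.make_phantom()


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free, drift-free phantom for exact-recovery checks."""
    return fw.make_phantom(noise_sd=0.0, drift_amp=0.0)


@pytest.fixture(scope="session")
def fitted_pipeline(phantom, session_design):
    """Simulate -> smooth -> scale -> fit, shared across ROI/map tests."""
    ds = fw.simulate_session(phantom, session_design, seed=21)
    ds = fw.global_scale(fw.smooth_volumes(ds, 3.0))
    X = fw.build_design_matrix(session_design)
    glm = fw.fit_glm(ds, X)
    t_sound = fw.t_contrast(glm, fw.sound_contrast_weights())
    sound_mask = fw.embed(t_sound, ds.mask, fill=-np.inf) > fw.T_DEFAULT
    return ds, X, glm, sound_mask
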