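import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One simulated session with stimulation, shared across tests."""
    from lateralize.simulate import SimConfig, StimSpec, simulate_session

    cfg = SimConfig(seed=1, stim_spec=StimSpec())
    session, truth = simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def fitted(default_session):
    from lateralize.model import SessionAnalysis

    cfg, session, truth = default_session
    results = SessionAnalysis(session).fit()
    return session, truth, results


@pytest.fixture(scope="session")
def scaffold60():
    """60 trials/side scaffold plus per-side release onsets / holding times."""
    from lateralize.simulate import make_trial_scaffold

    rng = np.random.default_rng(2024)
    trials = make_trial_scaffold(60, rng)
    contra = [t for t in trials if t.side == "right"]
    ipsi = [t for t in trials if t.side == "left"]
    return dict(
        trials=trials,
        contra_onsets=[t.release_onset for t in contra],
        ipsi_onsets=[t.release_onset for t in ipsi],
        contra_holding=[t.holding_duration for t in contra],
        ipsi_holding=[t.holding_duration for t in ipsi],
    )
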