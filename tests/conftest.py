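import numpy as np
import pytest

import shiftsim as ss


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sd_config():
    return ss.default_config("SD")


@pytest.fixture
def seds_config():
    return ss.default_config("SEDS")


@pytest.fixture
def rule():
    return ss.default_rule()


@pytest.fixture
def learner():
    """A competent learner with a short session (keeps tests fast)."""
    return ss.make_agent(
        assoc_lr=0.15, attn_lr=0.10, inv_temp=4.0, lapse=0.03,
        p_respond=0.97, satiety_trials=220.0,
    )


def assert_valid_session(log):
    """Shared validator: every emitted trial satisfies its invariants."""
    for t in log.trials:
        problems = ss.core.validate_trial(t, droplet_ul=log.config.droplet_ul)
        assert problems == [], problems
    assert log.total_volume_ul == sum(t.reward_volume_ul for t in log.trials)
    ts = [e.t_ms for e in log.events]
    assert all(b >= a for a, b in zip(ts, ts[1:]))
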