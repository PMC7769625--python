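import numpy as np
import pytest

import cscburst as cb


@pytest.fixture(scope="session")
def post():
    return cb.ModelParameters.post_runup()


@pytest.fixture(scope="session")
def pre():
    return cb.ModelParameters.pre_runup()


@pytest.fixture(scope="session")
def tonic_traj(post):
    """Post-runup spontaneous tonic firing, 4 s."""
    return cb.integrate(post, duration=4000.0)


@pytest.fixture(scope="session")
def sw_traj(post):
    """Square-wave bursting on the 14-spike isola (g_HVA = 0.232), 30 s."""
    return cb.integrate(post.replace(g_HVA=0.232), duration=30000.0)


@pytest.fixture(scope="session")
def fast_orbit_seed(post, tonic_traj):
    """A fast-subsystem state that oscillates when (hA, Ca) are frozen.

    Sampled mid-spike from the tonic attractor; the tonic rhythm is carried
    by the fast subsystem, so freezing the slow pair at the sampled values
    leaves a stable fast-subsystem periodic orbit nearby.
    """
    from cscburst.features import analysis_window
    from cscburst.simulate import fast_state_from_full
    win = analysis_window(tonic_traj)
    st = cb.detect_spikes(win.times, win.V)
    i = np.searchsorted(win.times, st[len(st) // 2])
    y = win.states[i]
    return fast_state_from_full(y), float(y[4]), float(y[7])
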