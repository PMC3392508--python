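import numpy as np
import pytest

import lapskill as lk


@pytest.fixture(scope="session")
def reference_params():
    """Knot-task reference group distributions (novice, expert)."""
    return lk.knot_task_reference_params()


@pytest.fixture(scope="session")
def reference_cohorts(reference_params):
    """One seeded cohort pair sampled from the reference distributions."""
    nov_p, exp_p = reference_params
    s_nov, s_exp = np.random.SeedSequence(20260926).spawn(2)
    return lk.sample_map_cohort(nov_p, s_nov), lk.sample_map_cohort(exp_p, s_exp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trajectory(hand="left", times=None, tilt1=None, tilt2=None,
                    depth=None, roll=None, fs=100.0):
    """Build a Trajectory from plain arrays, broadcasting constants."""
    times = np.asarray(times, dtype=float)
    n = len(times)

    def arr(v, default=0.0):
        if v is None:
            return np.full(n, default)
        v = np.asarray(v, dtype=float)
        return np.full(n, float(v)) if v.ndim == 0 else v

    t1, t2, d, r = arr(tilt1), arr(tilt2), arr(depth, 50.0), arr(roll)
    samples = [
        lk.TrackingSample(t=times[i], tilt1=t1[i], tilt2=t2[i], depth=d[i], roll=r[i])
        for i in range(n)
    ]
    return lk.Trajectory(hand=hand, samples=samples, fs=fs)
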