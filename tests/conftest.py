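import numpy as np
import pytest

import lspheno as lp


@pytest.fixture(scope="session")
def small_scene():
    """A 6x6 single-year scene under the default study conditions."""
    cfg = lp.SceneConfig(ny=6, nx=6, years=(2005,), seed=42)
    return lp.generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise- and contamination-free 4x4 scene (exact-recovery oracle)."""
    cfg = lp.SceneConfig(
        ny=4, nx=4, years=(2005,), seed=3, jitter_sd=0.0,
        contamination=lp.Contamination(noise_sd=0.0, cloud_prob=0.0,
                                       snow_prob=0.0),
    )
    return lp.generate_scene(cfg)


@pytest.fixture(scope="session")
def beck_truth():
    """Reference Beck parameter set with well-separated flanks."""
    return lp.DoubleLogisticParams(mn=0.1, mx=0.6, sos=130.0, rsp=0.2,
                                   eos=280.0, rau=0.1)


def random_separated_params(rng):
    """Draw Beck parameters with genuinely decoupled flanks.

    Beyond the oracle's precondition (eos - sos > 2/rsp + 2/rau + margin),
    each logistic must be saturated at the season midpoint — the tangent
    geometry deviates from the closed form by ~4*s(-x)/rate where
    x = rate*(eos - sos)/2, so x >= 6 keeps every metric within a fraction
    of a day of the closed form.
    """
    while True:
        mn = rng.uniform(0.0, 0.3)
        mx = mn + rng.uniform(0.2, 0.8)
        rsp = rng.uniform(0.05, 0.5)
        rau = rng.uniform(0.05, 0.5)
        sos = rng.uniform(80, 180)
        eos = rng.uniform(sos + 40, 330)
        sep = eos - sos
        if (sep > 2 / rsp + 2 / rau + 15
                and rsp * sep / 2 >= 6 and rau * sep / 2 >= 6):
            return lp.DoubleLogisticParams(mn=mn, mx=mx, sos=sos, rsp=rsp,
                                           eos=eos, rau=rau)
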