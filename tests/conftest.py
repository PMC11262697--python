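"""Shared fixtures.

The coupled 24-hour runs are expensive (~1 min each), so they are
session-scoped and shared between the dynamical property tests and the
acceptance checks.
"""

import numpy as np
import pytest
from hypothesis import settings

from capnet.driver import run
from capnet.params import SimConfig

# property tests run derandomized and without an example database so the
# suite is reproducible and leaves no cache behind
settings.register_profile("capnet", database=None, deadline=None,
                          derandomize=True)
settings.load_profile("capnet")


@pytest.fixture(scope="session")
def null_tables():
    from capnet._dip import NullTables

    return NullTables()


def _run(duration=720, seed=11, **toggles):
    cfg = SimConfig(duration=duration)
    for key, val in toggles.items():
        if key == "mu_h_mult":
            cfg.potts.mu_h *= val
        else:
            setattr(cfg, key, val)
    return run(cfg, seed=seed)


@pytest.fixture(scope="session")
def typical_run():
    """Morphology-on / haptotaxis-on, typical parameters, 24 h."""
    return _run()


@pytest.fixture(scope="session")
def muh4_run():
    """Haptotaxis coefficient quadrupled, 24 h."""
    return _run(mu_h_mult=4.0)


@pytest.fixture(scope="session")
def factorial_runs(typical_run):
    """The four on/off conditions of the factorial design, 24 h."""
    return {
        ("on", "on"): typical_run,
        ("on", "off"): _run(haptotaxis_on=False),
        ("off", "on"): _run(morphology_on=False),
        ("off", "off"): _run(morphology_on=False, haptotaxis_on=False),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
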