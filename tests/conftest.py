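import warnings

import numpy as np
import pytest

import brainswitch as bs
from brainswitch import screening, synth
from brainswitch.classifier import ClassifierConfig


@pytest.fixture(scope="session")
def montage():
    return bs.standard_montage("healthy")


@pytest.fixture()
def cfg():
    return ClassifierConfig()


def _calibration_sessions(n_trials=10, base_seed=60):
    recs = {}
    for i, p in enumerate(("MI", "AEP", "VEP_AO", "VEP_NM")):
        rec, sched, _ = synth.generate_session("calibration", p,
                                               seed=base_seed + i,
                                               n_trials=n_trials)
        recs[p] = (rec, sched)
    return recs


@pytest.fixture(scope="session")
def calibration():
    """Small calibrated subject: sessions, channel plan and template."""
    recs = _calibration_sessions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plan, tpl, diag = screening.run_calibration(
            recs, bs.standard_montage("healthy"), ClassifierConfig())
    return {"recordings": recs, "plan": plan, "template": tpl, "diag": diag}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
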