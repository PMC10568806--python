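import logging
import math

import numpy as np
import pytest

from psmcea import (
    CEModel,
    TrialSimConfig,
    load_config,
    simulate_trial,
)

logging.getLogger("psmcea").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def baseline():
    """Shipped baseline parameter set and sensitivity registry."""
    return load_config(None)


@pytest.fixture(scope="session")
def baseline_params(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def registry(baseline):
    return baseline[1]


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial shared across reconstruction and
    fitting tests."""
    cfg = TrialSimConfig(n_per_arm=200, seed=3)
    return cfg, simulate_trial(cfg)


@pytest.fixture(scope="session")
def exp_model():
    """Cheap analysis model with exponential survival in both arms:
    arm P has a proportional-hazards advantage on both endpoints."""
    lam_pfs = math.log(2) / 365.25
    lam_os = math.log(2) / (3 * 365.25)
    return CEModel(
        {
            ("P", "PFS"): lambda t: math.exp(-0.55 * lam_pfs * t),
            ("P", "OS"): lambda t: math.exp(-0.70 * lam_os * t),
            ("C", "PFS"): lambda t: math.exp(-lam_pfs * t),
            ("C", "OS"): lambda t: math.exp(-lam_os * t),
        }
    )


@pytest.fixture(scope="session")
def fitted_model():
    """CEModel backed by AIC-selected parametric fits to a trial drawn
    from the default generator configuration (the KEYNOTE-like
    fixture)."""
    from psmcea import fit_all_families, select_model, survival_at

    ipd = simulate_trial(TrialSimConfig(seed=1))
    evaluators = {}
    for arm in ("P", "C"):
        for ep in ("PFS", "OS"):
            sub = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == ep)]
            best = select_model(fit_all_families(sub))[0]
            evaluators[(arm, ep)] = lambda t, f=best: survival_at(f, t)
    return CEModel(evaluators)
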