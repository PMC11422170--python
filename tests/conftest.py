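import numpy as np
import pandas as pd
import pytest

import motivecocktail as mc


@pytest.fixture(scope="session")
def session_trials() -> pd.DataFrame:
    return mc.session_frame(123, participant_id="p0")


@pytest.fixture(scope="session")
def cocktail_params() -> dict:
    return {"lambda": 1.0, "alpha": 0.1, "beta": 0.1, "gamma": 0.5,
            "omega": 0.1, "kappa": 0.2, "eta_no": 1.0, "eta_yes": 2.0}


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic participants from the default population."""
    return mc.simulate_cohort(mc.default_population(), 6, seed=42)


def random_motive_params(rng: np.random.Generator, model: str) -> dict:
    """Uniform draw within bounds for any model's free parameters."""
    from motivecocktail.models import MODEL_PARAMS, param_bounds
    names = MODEL_PARAMS[model]
    return {p: float(rng.uniform(lo, hi))
            for p, (lo, hi) in zip(names, param_bounds(model))}
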