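import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidsel import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_sim_config(seed: int = 0, n_ions: int = 60, **overrides) -> sd.SimConfig:
    """A reduced cohort (72 samples, few ions) for fast end-to-end tests."""
    sizes = {
        "phospholipid": n_ions - 40,
        "glycerolipid": 10,
        "sphingolipid": 10,
        "acylcarnitine": 10,
        "cholesteryl-ester": 10,
    }
    defaults = dict(
        n_ions=n_ions,
        category_sizes=sizes,
        effects=[
            sd.EffectSpec(
                factor="genotype",
                target_eta2=0.5,
                n_target=10,
                categories=["phospholipid"],
            )
        ],
        zero_rate=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return sd.SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the default study conditions."""
    matrix, transitions, truth = sd.generate(sd.SimConfig(seed=11))
    return matrix, transitions, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_cohort():
    matrix, transitions, truth = sd.generate(small_sim_config(seed=3))
    return matrix, transitions, truth


@pytest.fixture()
def random_composition(rng):
    """Strictly positive 8 x 5 composition with rows summing to 1."""
    raw = rng.lognormal(0.0, 1.0, size=(8, 5))
    comp = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        comp,
        index=[f"s{i}" for i in range(8)],
        columns=[f"f{j}" for j in range(5)],
    )
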