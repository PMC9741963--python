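import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from markovcea import (
    CycleEconomics,
    LifeTable,
    MarkovSpec,
    ParametricSurvival,
)
from markovcea.synthetic import base_case

#: An exponential rate small enough that S(t) == 1.0 exactly in floating point
#: over any horizon used in the tests — a "zero hazard" that still satisfies
#: the lambda > 0 invariant.
NULL_RATE = 1e-300


@pytest.fixture(scope="session")
def base():
    """The full base-case parameterization (spec, economics, ranges)."""
    return base_case()


@pytest.fixture
def flat_life_table():
    return LifeTable(ages=(0,), annual_death_prob=(0.0,))


def make_homogeneous_spec(
    lam_int: float = 0.02,
    lam_comp: float = 0.05,
    lam_ps: float = 0.03,
    annual_bg: float = 0.0,
    horizon: int = 240,
    **kwargs,
) -> MarkovSpec:
    """Time-homogeneous spec: exponential laws and a flat life table."""
    return MarkovSpec(
        dfs_survival={
            "osimertinib": ParametricSurvival("exponential", lam_int),
            "placebo": ParametricSurvival("exponential", lam_comp),
        },
        ps_death_model=ParametricSurvival("exponential", lam_ps),
        life_table=LifeTable(ages=(0,), annual_death_prob=(annual_bg,)),
        starting_age=60,
        horizon_cycles=horizon,
        **kwargs,
    )


def make_null_econ(**overrides) -> CycleEconomics:
    """Economics with every cost, utility and rate zeroed unless overridden."""
    defaults = dict(
        drug_cost_per_cycle=0.0,
        followup_cost_per_cycle=0.0,
        supportive_care_cost_per_cycle=0.0,
        sae_cost_per_event=0.0,
        sae_probability=0.0,
        utility_dfs=0.0,
        utility_ps=0.0,
        sae_disutility=0.0,
        discount_rate_cost=0.0,
        discount_rate_outcome=0.0,
    )
    defaults.update(overrides)
    return CycleEconomics(**defaults)
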