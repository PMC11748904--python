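import numpy as np
import pytest

from cardioclock import (
    PiecewiseLinear,
    TurnoverScenario,
    stylized_bomb_curve,
)


@pytest.fixture(scope="session")
def curve():
    """Stylized bomb-pulse curve used throughout the suite."""
    return stylized_bomb_curve()


@pytest.fixture
def healthy_scenario():
    """Adult-constant genome content, lifelong healthy renewal."""
    return TurnoverScenario(
        birth=1950.0,
        collection=2015.0,
        phase_boundaries=(),
        renewal_rates=(0.0055,),
        pi_traj=PiecewiseLinear.constant(1.769),
        nu_traj=PiecewiseLinear.constant(1.193),
    )


def random_scenario(rng: np.random.Generator) -> TurnoverScenario:
    """A random but valid two-phase scenario inside the stylized curve span."""
    birth = rng.uniform(1935.0, 1990.0)
    collection = rng.uniform(2005.0, 2025.0)
    onset = rng.uniform(birth + 12.0, collection - 1.0)
    mature = min(birth + 10.0, onset)
    pi_adult = rng.uniform(1.3, 2.2)
    nu_adult = rng.uniform(1.05, 1.35)
    pi_end = pi_adult + rng.uniform(0.0, 1.2)
    nu_end = min(2.0, nu_adult + rng.uniform(0.0, 0.3))
    pi = PiecewiseLinear(
        np.array([birth, mature, onset, collection]),
        np.array([1.0, pi_adult, pi_adult, pi_end]),
    )
    nu = PiecewiseLinear(
        np.array([birth, mature, onset, collection]),
        np.array([1.0, nu_adult, nu_adult, nu_end]),
    )
    return TurnoverScenario(
        birth=birth,
        collection=collection,
        phase_boundaries=(onset,),
        renewal_rates=(rng.uniform(0.0, 0.02), rng.uniform(0.0, 0.05)),
        pi_traj=pi,
        nu_traj=nu,
    )
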