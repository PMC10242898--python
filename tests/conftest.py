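import numpy as np
import pytest

from cotfam import FimlProblem, SimulationConfig, default_parameters, simulate_table


@pytest.fixture(scope="session")
def theta_star():
    """Reference parameter values used across the suite."""
    return default_parameters()


@pytest.fixture(scope="session")
def small_table():
    """A small cohort with default missingness (shared, read-only)."""
    return simulate_table(SimulationConfig(seed=42, n_units=300))


@pytest.fixture(scope="session")
def small_problem(small_table):
    return FimlProblem(small_table)


@pytest.fixture(scope="session")
def complete_table():
    """A small fully observed cohort (no missingness)."""
    return simulate_table(
        SimulationConfig(
            seed=43, n_units=300, family_response=1.0, adult_item_missing=0.0
        )
    )


def random_valid_parameters(rng: np.random.Generator):
    """Draw a parameter set from the interior of the valid region."""
    from cotfam import ParameterSet

    a2 = rng.uniform(0.05, 0.9)
    return ParameterSet.from_variances(
        a2,
        rho_A=rng.uniform(-0.85, 0.85),
        rho_E=rng.uniform(-0.85, 0.85),
        lambda1=rng.uniform(0.3, 2.0),
        lambda2=rng.uniform(0.3, 2.0),
        theta1=rng.uniform(0.05, 2.0),
        theta2=rng.uniform(0.05, 2.0),
        p_m=rng.uniform(-0.6, 0.6),
        p_f=rng.uniform(-0.6, 0.6),
        g=rng.uniform(-0.6, 0.6),
        a_c=rng.uniform(0.0, 1.0),
        c_c=rng.uniform(0.0, 1.0),
        e_c=rng.uniform(0.2, 1.5),
        beta_sex=rng.uniform(-0.3, 0.3),
        beta_parity=rng.uniform(-0.2, 0.2),
        mu1=rng.uniform(-2, 2),
        mu2=rng.uniform(-2, 2),
        mu_o=rng.uniform(-2, 2),
    )
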