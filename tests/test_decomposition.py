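"""Pathway decomposition of parent-child correlations and child variance."""

import numpy as np
import pytest

from cotfam import (
    FamilyStructure,
    ParameterSet,
    implied_moments,
    offspring_variance_shares,
    parent_child_decomposition,
)
from cotfam.decomposition import child_outcome_variance, knockout_decomposition
from conftest import random_valid_parameters


def test_slices_sum_to_total_over_random_draws():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        p = random_valid_parameters(rng)
        for parent in ("MOTHER", "FATHER"):
            dec = parent_child_decomposition(p, parent)
            total = dec.slice_direct + dec.slice_genetic + dec.slice_assortment
            assert total == pytest.approx(dec.total_r, abs=1e-12)
            if dec.total_r != 0:
                assert sum(dec.percent.values()) == pytest.approx(100.0, abs=1e-6)


def test_father_association_entirely_via_assortment_when_only_mother_transmits():
    """With p_f = g = 0 the only father-child route runs through the partner
    correlation to the mother's direct path."""
    p = ParameterSet.from_variances(0.43, rho_A=0.372, rho_E=0.175, p_m=0.36)
    dec = parent_child_decomposition(p, "FATHER")
    assert dec.slice_direct == 0.0
    assert dec.slice_genetic == 0.0
    assert dec.percent["assortment"] == pytest.approx(100.0)
    assert dec.total_cov == pytest.approx(0.36 * p.d, rel=1e-12)


def test_father_association_purely_genetic_without_assortment():
    p = ParameterSet.from_variances(0.43, g=0.16, p_m=0.3)
    dec = parent_child_decomposition(p, "FATHER")
    assert dec.slice_direct == 0.0
    assert dec.slice_assortment == 0.0
    assert dec.percent["genetic"] == pytest.approx(100.0)
    assert dec.total_cov == pytest.approx(0.16 * 0.43 / 2, rel=1e-12)


def test_totals_match_implied_moment_correlations(theta_star):
    """The decomposition's total equals the correlation derived from the
    implied moment matrix — two independent routes to the same number."""
    st = FamilyStructure(
        sibling_link="DZ",
        linking_roles=("MOTHER", "MOTHER"),
        n_children=(1, 0),
        child_sexes=(("BOY",), ()),
        child_parities=((0,), ()),
    )
    mom = implied_moments(theta_star, st)
    i_child = mom.labels.index("c11_out")
    sd_child = np.sqrt(mom.cov[i_child, i_child])
    for parent, slot in (("MOTHER", "s1_n1"), ("FATHER", "sp1_n1")):
        dec = parent_child_decomposition(theta_star, parent)
        i_p = mom.labels.index(slot)
        r_latent = mom.cov[i_p, i_child] / theta_star.lambda1 / sd_child
        assert dec.total_r == pytest.approx(r_latent, abs=1e-10)


def test_slices_match_path_knockout_oracle(theta_star):
    """Differencing implied covariances with path groups removed reproduces
    each slice to 1e-6."""
    sd = np.sqrt(child_outcome_variance(theta_star))
    for parent in ("MOTHER", "FATHER"):
        dec = parent_child_decomposition(theta_star, parent)
        oracle = knockout_decomposition(theta_star, parent)
        assert dec.slice_direct * sd == pytest.approx(oracle["direct"], abs=1e-6)
        assert dec.slice_genetic * sd == pytest.approx(oracle["genetic"], abs=1e-6)
        assert dec.slice_assortment * sd == pytest.approx(oracle["assortment"], abs=1e-6)


def test_variance_shares_trivial_cases():
    none = ParameterSet.from_variances(0.4, a_c=0.5, c_c=0.5, e_c=1.0)
    shares = offspring_variance_shares(none)
    assert shares["intergenerational"] == 0.0
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    p = ParameterSet.from_variances(0.43, p_m=0.3, g=0.2, a_c=0.0, c_c=0.0, e_c=1.1)
    shares = offspring_variance_shares(p)
    inter = (
        0.3**2 + 0.2**2 * 0.43 + 2 * 0.2 * 0.3 * 0.43 / 2
    )  # p^2 + g^2 VarG + 2 g p CovNG at rho_A=0
    assert shares["intergenerational"] == pytest.approx(
        inter / (inter + 1.1**2), rel=1e-12
    )
    assert shares["child_A"] == 0.0


def test_variance_shares_sum_to_one_over_random_draws():
    rng = np.random.default_rng(21)
    for _ in range(200):
        p = random_valid_parameters(rng)
        shares = offspring_variance_shares(p)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(v >= 0 for v in shares.values())


def test_variance_matches_empirical_simulation(theta_star):
    """Implied child-outcome variance against a simulated cohort."""
    from cotfam import SimulationConfig, simulate_table

    p = theta_star.replace(beta_sex=0.0, beta_parity=0.0)
    df = simulate_table(
        SimulationConfig(
            seed=17, n_units=100_000, params=p,
            family_response=1.0, adult_item_missing=0.0,
        )
    )
    child = df["c11_out"].dropna().to_numpy()
    v_emp = child.var()
    v_mod = child_outcome_variance(p)
    se = v_emp * np.sqrt(2.0 / len(child))
    assert abs(v_emp - v_mod) < 3 * se


def test_decomposition_ci_brackets_point_estimate(small_table):
    from cotfam import FitOptions, decomposition_ci, fit_model

    fit = fit_model(small_table, options=FitOptions(n_starts=1))
    dec = decomposition_ci(fit, "MOTHER")
    for name, (lo, hi) in dec.percent_ci.items():
        assert lo <= dec.percent[name] <= hi


def test_indicator_scale_correlation_attenuated_by_reliability(theta_star):
    from cotfam.decomposition import indicator_scale_correlation

    latent = parent_child_decomposition(theta_star, "MOTHER").total_r
    observed = indicator_scale_correlation(theta_star, "MOTHER")
    reliability = theta_star.lambda1**2 / (theta_star.lambda1**2 + theta_star.theta1)
    assert observed == pytest.approx(latent * np.sqrt(reliability), rel=1e-12)
    assert observed < latent
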