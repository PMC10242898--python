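"""Path algebra of the extended-family biometric model."""

import numpy as np
import pytest

from cotfam import (
    FamilyStructure,
    ModelError,
    ParameterSet,
    implied_moments,
    observed_slots,
    relatedness_coefficient,
)
from conftest import random_valid_parameters


@pytest.mark.parametrize(
    "link,alpha",
    [("MZ", 1.0), ("DZ", 0.5), ("FULLSIB", 0.5), ("HALFSIB", 0.25)],
)
def test_relatedness_coefficient(link, alpha):
    assert relatedness_coefficient(link) == alpha


def test_relatedness_rejects_unknown_class():
    with pytest.raises(ModelError, match="unknown sibling relatedness class"):
        relatedness_coefficient("COUSIN")


@pytest.mark.parametrize(
    "n_children,expected",
    [((2, 0), 10), ((0, 0), 8), ((2, 2), 12), ((1, 2), 11)],
)
def test_observed_slot_counts(n_children, expected):
    st = FamilyStructure(sibling_link="DZ", n_children=n_children)
    labels = observed_slots(st)
    assert len(labels) == expected
    assert labels[:8] == [
        "s1_n1", "s1_n2", "sp1_n1", "sp1_n2", "s2_n1", "s2_n2", "sp2_n1", "sp2_n2",
    ]


def test_structure_validation():
    with pytest.raises(ModelError):
        FamilyStructure(sibling_link="DZ", n_children=(3, 0))
    with pytest.raises(ModelError):
        FamilyStructure(sibling_link="DZ", n_children=(1, 1), child_sexes=((), ()))


def test_parameterset_invariants():
    with pytest.raises(ModelError):
        ParameterSet(a=0.9, e=0.9).validate()  # a^2+e^2 > 1
    with pytest.raises(ModelError):
        ParameterSet.from_variances(0.4, theta1=-0.1).validate()
    p = ParameterSet.from_variances(0.43, rho_A=0.372, rho_E=0.175)
    p.validate()
    assert p.d == pytest.approx(0.372 * 0.43 + 0.175 * 0.57, abs=1e-12)


def test_no_connecting_paths_give_zero_cross_covariances():
    """Without transmission or assortment every adult-child and
    spouse-spouse entry vanishes exactly."""
    p = ParameterSet.from_variances(0.5, p_m=0.0, p_f=0.0, g=0.0, rho_A=0.0, rho_E=0.0)
    st = FamilyStructure(sibling_link="MZ", n_children=(2, 2))
    cov = implied_moments(p, st).cov
    assert np.all(cov[:8, 8:] == 0)          # adults x children
    for spouse_pair in ((0, 2), (4, 6)):     # indicator blocks of s and sp
        i, j = spouse_pair
        assert np.all(cov[i : i + 2, j : j + 2] == 0)


@pytest.mark.parametrize("link", ["MZ", "DZ", "FULLSIB", "HALFSIB"])
def test_avuncular_covariance_scales_with_relatedness(link):
    """With only genetic transmission, the co-sibling's indicator covaries
    with the child as lambda1 * alpha * (a^2/2) * g."""
    p = ParameterSet.from_variances(
        0.43, g=0.16, lambda1=1.3, lambda2=0.9, p_m=0.0, p_f=0.0
    )
    st = FamilyStructure(
        sibling_link=link, linking_roles=("MOTHER", "MOTHER"), n_children=(1, 0)
    )
    mom = implied_moments(p, st)
    alpha = relatedness_coefficient(link)
    i = mom.labels.index("s2_n1")
    j = mom.labels.index("c11_out")
    assert mom.cov[i, j] == pytest.approx(1.3 * alpha * 0.43 / 2 * 0.16, rel=1e-12)


def test_cousin_transmitted_genetic_covariance_alpha_ratio():
    """Children of MZ-linked families share twice the transmitted-genetic
    covariance of DZ-linked families — the design's identification lever."""
    p = ParameterSet.from_variances(0.43, g=0.3, a_c=0.0)  # isolate the g route
    covs = {}
    for link in ("MZ", "DZ"):
        st = FamilyStructure(sibling_link=link, n_children=(1, 1))
        mom = implied_moments(p, st)
        covs[link] = mom.cov[mom.labels.index("c11_out"), mom.labels.index("c21_out")]
    assert covs["MZ"] == pytest.approx(2.0 * covs["DZ"], rel=1e-12)


def test_spousal_and_inlaw_covariances():
    """Spouse d = rho_A a^2 + rho_E e^2; in-law rho_A alpha a^2; co-in-law
    rho_A^2 alpha a^2 (unit loadings expose the latent scale)."""
    p = ParameterSet.from_variances(0.43, rho_A=0.372, rho_E=0.175)
    st = FamilyStructure(sibling_link="HALFSIB", n_children=(0, 0))
    cov = implied_moments(p, st).cov
    a2, e2, al = 0.43, 0.57, 0.25
    assert cov[0, 2] == pytest.approx(0.372 * a2 + 0.175 * e2, rel=1e-12)
    assert cov[2, 4] == pytest.approx(0.372 * al * a2, rel=1e-12)      # sibling-in-law
    assert cov[2, 6] == pytest.approx(0.372**2 * al * a2, rel=1e-12)   # co-in-law
    assert cov[0, 4] == pytest.approx(al * a2, rel=1e-12)              # linking sibs


def test_no_assortment_matches_sensitivity_structure():
    """rho_A = rho_E = 0 reproduces the no-assortment sensitivity model."""
    base = ParameterSet.from_variances(0.43, rho_A=0.372, rho_E=0.175, p_m=0.3, g=0.2)
    zeroed = base.replace(rho_A=0.0, rho_E=0.0)
    st = FamilyStructure(sibling_link="DZ", n_children=(2, 2))
    cov = implied_moments(zeroed, st).cov
    # no spousal edge: spouse blocks 0, and sibling covariance is alpha*a^2
    assert cov[0, 2] == 0.0
    assert cov[0, 4] == pytest.approx(0.5 * 0.43, rel=1e-12)


def test_implied_covariance_positive_definite_over_valid_region():
    """Factorization succeeds for random draws from the valid region."""
    rng = np.random.default_rng(123)
    st = FamilyStructure(sibling_link="DZ", linking_roles=("MOTHER", "FATHER"))
    for _ in range(1000):
        p = random_valid_parameters(rng)
        mom = implied_moments(p, st)  # raises on PD failure
        assert np.allclose(mom.cov, mom.cov.T)


def test_means_include_child_covariates():
    p = ParameterSet.from_variances(0.4, beta_sex=0.2, beta_parity=-0.1, mu_o=1.0)
    st = FamilyStructure(
        sibling_link="DZ",
        n_children=(2, 0),
        child_sexes=(("GIRL", "BOY"), ()),
        child_parities=((0, 2), ()),
    )
    mom = implied_moments(p, st)
    assert mom.mean[mom.labels.index("c11_out")] == pytest.approx(1.2)
    assert mom.mean[mom.labels.index("c12_out")] == pytest.approx(0.8)
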