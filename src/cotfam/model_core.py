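"""Biometric model for extended family units in a children-of-twins design.

An extended family unit consists of two linking adult siblings (``s1``,
``s2``) whose genetic relatedness is known from their sibling class
(monozygotic twin, dizygotic twin, full sibling, or half sibling), their
spouses (``sp1``, ``sp2``), and up to two children per nuclear family.

Each adult's latent neuroticism phenotype is

    N = a*A + c*C + e*E,          Var(N) = a**2 + c**2 + e**2 = 1,

measured by two questionnaire indicators ``y_i = mu_i + lambda_i*N + eps_i``.
Spousal resemblance is parameterised by correlations between spouses'
additive-genetic factors (``rho_A``) and unique-environment factors
(``rho_E``); the phenotypic partner correlation is the derived quantity
``d = rho_A*a**2 + rho_E*e**2``.  A child's outcome loads on the mother's
and father's latent phenotypes (direct transmission paths ``p_m``, ``p_f``),
on the transmitted mid-parental genotype (genetic transmission path ``g``),
and on child-specific additive-genetic, nuclear-family shared, and unique
factors (``a_c``, ``c_c``, ``e_c``).

This module defines the parameter and family-structure types and computes
the model-implied mean vector and covariance matrix of the observed
variables of a unit by explicit path rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
import numpy as np

__all__ = [
    "SiblingLink",
    "Role",
    "Sex",
    "ParameterSet",
    "FamilyStructure",
    "MomentStructure",
    "ModelError",
    "NonPositiveDefiniteError",
    "relatedness_coefficient",
    "observed_slots",
    "implied_moments",
    "default_parameters",
    "ADULT_SLOT_LABELS",
    "CHILD_SLOT_LABELS",
    "FULL_SLOT_LABELS",
]


class ModelError(ValueError):
    """Invalid parameter or structure input."""


class NonPositiveDefiniteError(ModelError):
    """The implied covariance matrix is not positive definite."""


class SiblingLink(str, Enum):
    MZ = "MZ"
    DZ = "DZ"
    FULLSIB = "FULLSIB"
    HALFSIB = "HALFSIB"


class Role(str, Enum):
    MOTHER = "MOTHER"
    FATHER = "FATHER"


class Sex(str, Enum):
    GIRL = "GIRL"
    BOY = "BOY"


#: genome share of the linking siblings, by sibling class
_RELATEDNESS = {
    SiblingLink.MZ: 1.0,
    SiblingLink.DZ: 0.5,
    SiblingLink.FULLSIB: 0.5,
    SiblingLink.HALFSIB: 0.25,
}

ADULT_SLOT_LABELS = (
    "s1_n1", "s1_n2", "sp1_n1", "sp1_n2",
    "s2_n1", "s2_n2", "sp2_n1", "sp2_n2",
)
CHILD_SLOT_LABELS = ("c11_out", "c12_out", "c21_out", "c22_out")
FULL_SLOT_LABELS = ADULT_SLOT_LABELS + CHILD_SLOT_LABELS

# adult index (s1, sp1, s2, sp2) owning each of the 8 indicator slots
_SLOT_ADULT = np.repeat(np.arange(4), 2)
# indicator number (0 or 1) of each adult slot
_SLOT_IND = np.tile(np.arange(2), 4)
# nuclear family (0 or 1) of each child slot
_CHILD_FAM = np.array([0, 0, 1, 1])


def relatedness_coefficient(sibling_link: SiblingLink | str) -> float:
    """Genetic relatedness of the two linking siblings.

    MZ twins share all segregating genes (1.0), DZ twins and full siblings
    share half (0.5), half siblings a quarter (0.25).
    """
    try:
        link = SiblingLink(sibling_link)
    except ValueError as exc:
        raise ModelError(
            f"unknown sibling relatedness class: {sibling_link!r}; "
            f"expected one of {[m.value for m in SiblingLink]}"
        ) from exc
    return _RELATEDNESS[link]


@dataclass(frozen=True)
class ParameterSet:
    """Free parameters of the extended children-of-twins model.

    The latent parental phenotype is standardized: ``a**2 + c**2 + e**2``
    must equal 1.  ``c`` (parental shared environment) defaults to zero.
    Optional ``*_f`` fields free the measurement model by parental sex;
    when ``None`` fathers share the mothers' measurement parameters.
    """

    a: float
    e: float
    c: float = 0.0
    rho_A: float = 0.0
    rho_E: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    theta1: float = 0.5
    theta2: float = 0.5
    p_m: float = 0.0
    p_f: float = 0.0
    g: float = 0.0
    a_c: float = 0.0
    c_c: float = 0.0
    e_c: float = 1.0
    beta_sex: float = 0.0
    beta_parity: float = 0.0
    mu1: float = 0.0
    mu2: float = 0.0
    mu_o: float = 0.0
    lambda1_f: float | None = None
    lambda2_f: float | None = None
    theta1_f: float | None = None
    theta2_f: float | None = None
    mu1_f: float | None = None
    mu2_f: float | None = None

    @classmethod
    def from_variances(cls, a2: float, c2: float = 0.0, **kwargs) -> "ParameterSet":
        """Build a parameter set from latent variance shares (``a2 + c2 <= 1``)."""
        if not (0.0 <= a2 <= 1.0 and 0.0 <= c2 <= 1.0 and a2 + c2 <= 1.0):
            raise ModelError(f"invalid latent variance shares a2={a2}, c2={c2}")
        return cls(a=math.sqrt(a2), c=math.sqrt(c2), e=math.sqrt(1.0 - a2 - c2), **kwargs)

    def validate(self) -> None:
        total = self.a**2 + self.c**2 + self.e**2
        if abs(total - 1.0) > 1e-8:
            raise ModelError(
                f"latent parental variance a^2+c^2+e^2 = {total:.6g} != 1"
            )
        if not (abs(self.rho_A) <= 1.0 and abs(self.rho_E) <= 1.0):
            raise ModelError(
                f"spousal factor correlations out of range: "
                f"rho_A={self.rho_A}, rho_E={self.rho_E}"
            )
        for name in ("theta1", "theta2", "theta1_f", "theta2_f"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ModelError(f"residual variance {name}={val} < 0")

    @property
    def d(self) -> float:
        """Phenotypic spousal correlation implied by the factor correlations."""
        return self.rho_A * self.a**2 + self.rho_E * self.e**2

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)

    # measurement parameters per adult sex (column 0 = indicator 1)
    def _measurement(self, name: str, father: bool) -> float:
        if father:
            val = getattr(self, f"{name}_f")
            if val is not None:
                return val
        return getattr(self, name)


def default_parameters() -> ParameterSet:
    """Reference parameter values used throughout the package.

    Latent heritability a^2 = 0.43 with spousal covariance components
    rho_A*a^2 = 0.16 (genetic) and rho_E*e^2 = 0.10 (environmental), so the
    phenotypic partner correlation is 0.26.  Direct maternal transmission
    p_m = 0.36, no direct paternal transmission, genetic transmission
    g = 0.16.  Child-specific components sized so intergenerational
    influences explain ~8.5% of outcome variance.
    """
    a2 = 0.43
    return ParameterSet.from_variances(
        a2,
        rho_A=0.16 / a2,
        rho_E=0.10 / (1.0 - a2),
        lambda1=1.0,
        lambda2=1.0,
        theta1=0.5,
        theta2=0.8,
        p_m=0.36,
        p_f=0.0,
        g=0.16,
        a_c=math.sqrt(0.50),
        c_c=math.sqrt(0.10),
        e_c=math.sqrt(1.30),
        beta_sex=0.10,
        beta_parity=-0.05,
        mu1=3.0,
        mu2=1.5,
        mu_o=2.0,
    )


@dataclass(frozen=True)
class FamilyStructure:
    """Relational skeleton of one extended family unit.

    ``linking_roles[j]`` states whether linking sibling ``j`` is the mother
    or the father of nuclear family ``j``; the spouse takes the other role.
    Child sexes/parities are given per nuclear family, oldest first.
    """

    sibling_link: SiblingLink
    linking_roles: tuple[Role, Role] = (Role.MOTHER, Role.MOTHER)
    n_children: tuple[int, int] = (2, 2)
    child_sexes: tuple[tuple[Sex, ...], tuple[Sex, ...]] | None = None
    child_parities: tuple[tuple[int, ...], tuple[int, ...]] | None = None

    def __post_init__(self):
        object.__setattr__(self, "sibling_link", SiblingLink(self.sibling_link))
        object.__setattr__(
            self, "linking_roles", tuple(Role(r) for r in self.linking_roles)
        )
        if len(self.linking_roles) != 2:
            raise ModelError("linking_roles must name exactly two adults")
        if len(self.n_children) != 2 or any(n not in (0, 1, 2) for n in self.n_children):
            raise ModelError(
                f"n_children per nuclear family must be 0, 1 or 2, got {self.n_children}"
            )
        if self.child_sexes is None:
            object.__setattr__(
                self, "child_sexes", tuple(tuple([Sex.GIRL] * n) for n in self.n_children)
            )
        else:
            object.__setattr__(
                self,
                "child_sexes",
                tuple(tuple(Sex(s) for s in fam) for fam in self.child_sexes),
            )
        if self.child_parities is None:
            object.__setattr__(
                self, "child_parities", tuple(tuple([0] * n) for n in self.n_children)
            )
        for fam_sex, fam_par, n in zip(self.child_sexes, self.child_parities, self.n_children):
            if len(fam_sex) != n or len(fam_par) != n:
                raise ModelError("child_sexes/child_parities lengths must match n_children")
            if any(p < 0 for p in fam_par):
                raise ModelError("child parity must be non-negative")

    @property
    def alpha(self) -> float:
        return relatedness_coefficient(self.sibling_link)

    def child_slot_indices(self) -> list[int]:
        """Indices into the full 12-slot layout of the children present."""
        idx = []
        for fam in (0, 1):
            for k in range(self.n_children[fam]):
                idx.append(8 + 2 * fam + k)
        return idx

    def slot_indices(self) -> list[int]:
        return list(range(8)) + self.child_slot_indices()


def observed_slots(structure: FamilyStructure) -> list[str]:
    """Deterministic variable ordering for one unit's observed slots."""
    return [FULL_SLOT_LABELS[i] for i in structure.slot_indices()]


@dataclass
class MomentStructure:
    """Model-implied (or empirical) means and covariances for one layout."""

    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.labels)
        if self.mean.shape != (k,) or self.cov.shape != (k, k):
            raise ModelError("mean/cov shapes do not match labels")

    def corr(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


# ---------------------------------------------------------------------------
# covariance algebra
# ---------------------------------------------------------------------------

def _structure_codes(structure: FamilyStructure) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """(alpha, mother-of-child-slot, father-of-child-slot, adult-is-father)."""
    alpha = structure.alpha
    mother = np.empty(4, dtype=np.intp)
    father = np.empty(4, dtype=np.intp)
    is_father = np.empty(4, dtype=bool)
    for fam in (0, 1):
        link_adult = 2 * fam       # s1 or s2
        spouse = 2 * fam + 1       # sp1 or sp2
        if structure.linking_roles[fam] == Role.MOTHER:
            m, f = link_adult, spouse
        else:
            m, f = spouse, link_adult
        mother[2 * fam: 2 * fam + 2] = m
        father[2 * fam: 2 * fam + 2] = f
        is_father[link_adult] = structure.linking_roles[fam] == Role.FATHER
        is_father[spouse] = not is_father[link_adult]
    return alpha, mother, father, is_father


def build_moment_stack(
    params: ParameterSet,
    alphas: np.ndarray,
    mother_of_child: np.ndarray,
    father_of_child: np.ndarray,
    adult_is_father: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Full 12-slot implied covariance and base mean for a batch of layouts.

    Parameters are shared across the batch; ``alphas`` has shape ``(S,)``,
    the child-parent maps ``(S, 4)`` (adult index 0..3 per child slot), and
    ``adult_is_father`` ``(S, 4)``.  Returns ``(S, 12, 12)`` covariances and
    ``(S, 12)`` means at zero covariate values.

    All path rules live here.  The joint distribution of the four adults'
    factors follows from the generative construction: linking siblings'
    additive factors correlate ``alpha``, each spouse's factor is
    ``rho*own + independent noise``, which yields in-law correlation
    ``rho_A*alpha`` and co-in-law correlation ``rho_A**2*alpha``.  A child's
    transmitted genotype is the mid-parent breeding value plus segregation
    noise of variance ``a**2/2``.
    """
    S = len(alphas)
    al = np.asarray(alphas, dtype=float)
    a2, e2, c2 = params.a**2, params.e**2, params.c**2
    rA, rE = params.rho_A, params.rho_E

    # adult additive-factor correlations (S, 4, 4): order s1, sp1, s2, sp2
    K_A = np.empty((S, 4, 4))
    K_A[:, [0, 1, 2, 3], [0, 1, 2, 3]] = 1.0
    K_A[:, 0, 1] = K_A[:, 1, 0] = rA
    K_A[:, 2, 3] = K_A[:, 3, 2] = rA
    K_A[:, 0, 2] = K_A[:, 2, 0] = al
    K_A[:, 0, 3] = K_A[:, 3, 0] = rA * al
    K_A[:, 1, 2] = K_A[:, 2, 1] = rA * al
    K_A[:, 1, 3] = K_A[:, 3, 1] = rA * rA * al

    K_E = np.zeros((4, 4))
    np.fill_diagonal(K_E, 1.0)
    K_E[0, 1] = K_E[1, 0] = rE
    K_E[2, 3] = K_E[3, 2] = rE

    # parental shared environment: common to the linking siblings only
    K_C = np.eye(4)
    K_C[0, 2] = K_C[2, 0] = 1.0

    Ncov = a2 * K_A + e2 * K_E[None, :, :] + c2 * K_C[None, :, :]

    s_idx = np.arange(S)[:, None, None]
    m = np.asarray(mother_of_child, dtype=np.intp)
    f = np.asarray(father_of_child, dtype=np.intp)

    # Cov(N_x, G_c) = (a^2/2) * (K_A[x, m_c] + K_A[x, f_c]);  (S, 4 adults, 4 children)
    x_idx = np.arange(4)[None, :, None]
    CovNG = 0.5 * a2 * (K_A[s_idx, x_idx, m[:, None, :]] + K_A[s_idx, x_idx, f[:, None, :]])

    # Cov(G_c, G_c') = (a^2/4) * sum over parent pairs + segregation variance on diagonal
    GG = 0.25 * a2 * (
        K_A[s_idx, m[:, :, None], m[:, None, :]]
        + K_A[s_idx, m[:, :, None], f[:, None, :]]
        + K_A[s_idx, f[:, :, None], m[:, None, :]]
        + K_A[s_idx, f[:, :, None], f[:, None, :]]
    )
    GG[:, np.arange(4), np.arange(4)] += 0.5 * a2

    # child-specific additive factor: 0.5 between full sibs, alpha/4 between
    # cousins (child-specific loci are unaffected by neuroticism assortment)
    samefam = (_CHILD_FAM[:, None] == _CHILD_FAM[None, :]).astype(float)
    KA_child = np.where(samefam[None, :, :] > 0, 0.5, 0.25 * al[:, None, None])
    KA_child = KA_child * np.ones((S, 4, 4))
    KA_child[:, np.arange(4), np.arange(4)] = 1.0
    KC_child = samefam  # nuclear-family shared environment

    # child outcome loadings onto [N_1..N_4, G_1..G_4]
    L = np.zeros((S, 4, 8))
    c_idx = np.arange(4)
    L[np.arange(S)[:, None], c_idx[None, :], m] += params.p_m
    L[np.arange(S)[:, None], c_idx[None, :], f] += params.p_f
    L[:, c_idx, 4 + c_idx] = params.g

    Z = np.empty((S, 8, 8))
    Z[:, :4, :4] = Ncov
    Z[:, :4, 4:] = CovNG
    Z[:, 4:, :4] = np.swapaxes(CovNG, 1, 2)
    Z[:, 4:, 4:] = GG

    # measurement model per adult slot (sex-specific parameters optional)
    is_f = np.asarray(adult_is_father, dtype=bool)
    lam = np.empty((S, 8))
    theta = np.empty((S, 8))
    mu_ad = np.empty((S, 8))
    for ind, (lam_n, th_n, mu_n) in enumerate(
        (("lambda1", "theta1", "mu1"), ("lambda2", "theta2", "mu2"))
    ):
        for father_flag in (False, True):
            lam_v = params._measurement(lam_n, father_flag)
            th_v = params._measurement(th_n, father_flag)
            mu_v = params._measurement(mu_n, father_flag)
            sel = is_f[:, _SLOT_ADULT] == father_flag
            sel = sel & (_SLOT_IND[None, :] == ind)
            lam[sel] = lam_v
            theta[sel] = th_v
            mu_ad[sel] = mu_v

    NO = np.einsum("sxz,scz->sxc", Z[:, :4, :], L)  # Cov(N_x, O_c)
    OO = np.einsum("scz,szw,sdw->scd", L, Z, L)
    OO += params.a_c**2 * KA_child
    OO += params.c_c**2 * KC_child[None, :, :]
    OO[:, np.arange(4), np.arange(4)] += params.e_c**2

    cov = np.empty((S, 12, 12))
    Ncov_slots = Ncov[:, _SLOT_ADULT[:, None], _SLOT_ADULT[None, :]]
    cov[:, :8, :8] = lam[:, :, None] * lam[:, None, :] * Ncov_slots
    cov[:, np.arange(8), np.arange(8)] += theta
    cov[:, :8, 8:] = lam[:, :, None] * NO[:, _SLOT_ADULT, :]
    cov[:, 8:, :8] = np.swapaxes(cov[:, :8, 8:], 1, 2)
    cov[:, 8:, 8:] = OO

    mu = np.empty((S, 12))
    mu[:, :8] = mu_ad
    mu[:, 8:] = params.mu_o
    return cov, mu


def implied_moments(params: ParameterSet, structure: FamilyStructure) -> MomentStructure:
    """Model-implied means and covariances for one unit's observed slots.

    Means include the covariate effects of the children named in the
    structure (sex coded girl=1/boy=0, parity as given).  Raises
    :class:`NonPositiveDefiniteError` if the implied covariance cannot be
    factorized.
    """
    params.validate()
    alpha, mother, father, is_father = _structure_codes(structure)
    cov, mu = build_moment_stack(
        params,
        np.array([alpha]),
        mother[None, :],
        father[None, :],
        is_father[None, :],
    )
    idx = structure.slot_indices()
    cov = cov[0][np.ix_(idx, idx)]
    mean = mu[0][idx].copy()
    pos = 8
    for fam in (0, 1):
        for k in range(structure.n_children[fam]):
            sex = 1.0 if structure.child_sexes[fam][k] == Sex.GIRL else 0.0
            par = float(structure.child_parities[fam][k])
            j = idx.index(8 + 2 * fam + k)
            mean[j] += params.beta_sex * sex + params.beta_parity * par
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NonPositiveDefiniteError(
            "implied covariance is not positive definite for parameters "
            f"a={params.a:.4g}, c={params.c:.4g}, e={params.e:.4g}, "
            f"rho_A={params.rho_A:.4g}, rho_E={params.rho_E:.4g}, "
            f"theta=({params.theta1:.4g},{params.theta2:.4g})"
        ) from exc
    labels = tuple(observed_slots(structure))
    return MomentStructure(mean=mean, cov=cov, labels=labels)
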