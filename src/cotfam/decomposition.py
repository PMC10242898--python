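"""Pathway decomposition of parent–child associations and offspring variance.

A model-implied parent–child covariance is a sum of path-traced terms.
Each term is classified by its route:

* **direct** — the parent's own phenotype-to-child path (``p_m`` or ``p_f``);
* **genetic** — genetic transmission through the parent's own transmitted
  breeding-value half (``g * a^2 / 2``), genetic even under assortment;
* **assortment** — every term whose path traverses at least one spousal
  correlation edge: the co-parent's direct path reached through the partner
  correlation ``d`` and the co-parent's transmitted half reached through
  the spousal genetic correlation (``g * rho_A * a^2 / 2``).

Dividing by the implied standard deviations turns the slices into additive
portions of the parent–child correlation.  The module also partitions the
child's outcome variance into intergenerational (direct + genetic + their
covariance) and child-specific A/C/E shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    FamilyStructure,
    ModelError,
    ParameterSet,
    Role,
    implied_moments,
)

__all__ = [
    "DecompositionResult",
    "parent_child_decomposition",
    "offspring_variance_shares",
    "child_outcome_variance",
    "decomposition_ci",
]


def _core_child_moments(params: ParameterSet) -> dict[str, float]:
    """Closed-form pieces shared by the decompositions (latent scale)."""
    a2 = params.a**2
    rA = params.rho_A
    d = params.d
    var_G = 0.5 * a2 * (2.0 + rA)          # mid-parent + segregation variance
    cov_NG = 0.5 * a2 * (1.0 + rA)         # Cov(parent phenotype, child genotype)
    inter = (
        params.p_m**2 + params.p_f**2 + 2.0 * params.p_m * params.p_f * d
        + params.g**2 * var_G
        + 2.0 * params.g * (params.p_m + params.p_f) * cov_NG
    )
    total_var = inter + params.a_c**2 + params.c_c**2 + params.e_c**2
    return {"a2": a2, "rA": rA, "d": d, "var_G": var_G, "cov_NG": cov_NG,
            "inter_var": inter, "total_var": total_var}


def child_outcome_variance(params: ParameterSet) -> float:
    """Model-implied child outcome variance at fixed covariates."""
    return _core_child_moments(params)["total_var"]


@dataclass
class DecompositionResult:
    """A parent–child correlation split into additive pathway slices."""

    parent: Role
    total_r: float
    slice_direct: float
    slice_genetic: float
    slice_assortment: float
    total_cov: float
    percent: dict[str, float] = field(default_factory=dict)
    percent_ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        resid = self.total_r - (
            self.slice_direct + self.slice_genetic + self.slice_assortment
        )
        if abs(resid) > 1e-10:
            raise ModelError(f"pathway slices do not sum to the total ({resid:.3g})")
        if not self.percent:
            if self.total_r != 0:
                self.percent = {
                    "direct": 100.0 * self.slice_direct / self.total_r,
                    "genetic": 100.0 * self.slice_genetic / self.total_r,
                    "assortment": 100.0 * self.slice_assortment / self.total_r,
                }
            else:
                self.percent = {}


def parent_child_decomposition(
    params: ParameterSet, parent: Role | str
) -> DecompositionResult:
    """Split the model-implied parent–child correlation by pathway.

    On the latent scale the parent phenotype has unit variance, so the
    covariance slices divided by the implied child SD are correlation
    slices.  The three slices sum to the total correlation exactly.
    """
    params.validate()
    parent = Role(parent)
    m = _core_child_moments(params)
    if m["total_var"] <= 0:
        raise ModelError("implied child outcome variance is zero")
    own, other = (
        (params.p_m, params.p_f) if parent == Role.MOTHER else (params.p_f, params.p_m)
    )
    direct = own
    genetic = params.g * 0.5 * m["a2"]
    assort = other * m["d"] + params.g * 0.5 * m["a2"] * m["rA"]
    denom = np.sqrt(m["total_var"])  # parent latent SD = 1
    return DecompositionResult(
        parent=parent,
        total_cov=direct + genetic + assort,
        total_r=(direct + genetic + assort) / denom,
        slice_direct=direct / denom,
        slice_genetic=genetic / denom,
        slice_assortment=assort / denom,
    )


def knockout_decomposition(params: ParameterSet, parent: Role | str) -> dict[str, float]:
    """Independent oracle: difference parent–child covariances from the
    implied-moments algebra with path groups knocked out.

    direct = covariance with the co-parent's direct path and all genetic
    transmission removed; genetic = covariance without assortment minus the
    direct part; assortment = the remainder of the full covariance.
    Returned on the covariance scale of the full model's child SD.
    """
    parent = Role(parent)
    structure = FamilyStructure(
        sibling_link="DZ", linking_roles=(Role.MOTHER, Role.MOTHER), n_children=(1, 0)
    )
    # slot 0 is the linking mother's indicator 1; slot 8 is her child
    lam = params.lambda1

    def parent_child_cov(p: ParameterSet) -> float:
        mom = implied_moments(p, structure)
        i_parent = 0 if parent == Role.MOTHER else mom.labels.index("sp1_n1")
        return mom.cov[i_parent, mom.labels.index("c11_out")] / lam

    own_only = params.replace(
        rho_A=0.0, rho_E=0.0,
        **({"p_f": 0.0, "g": 0.0} if parent == Role.MOTHER else {"p_m": 0.0, "g": 0.0}),
    )
    no_assort = params.replace(rho_A=0.0, rho_E=0.0)
    direct = parent_child_cov(own_only)
    genetic = parent_child_cov(no_assort) - direct
    total = parent_child_cov(params)
    return {"direct": direct, "genetic": genetic, "assortment": total - genetic - direct}


def indicator_scale_correlation(params: ParameterSet, parent: Role | str) -> float:
    """Parent-child correlation on the observed first-indicator scale.

    Measurement error attenuates the latent-scale correlation by the
    indicator reliability: multiply by
    ``lambda1 / sqrt(lambda1^2 + theta1)``.  Reported alongside the latent
    scale because published totals may use either convention.
    """
    dec = parent_child_decomposition(params, parent)
    lam, th = params.lambda1, params.theta1
    return dec.total_r * lam / np.sqrt(lam**2 + th)


def offspring_variance_shares(params: ParameterSet) -> dict[str, float]:
    """Partition the implied child outcome variance.

    ``intergenerational`` covers direct and genetic transmission and their
    covariance; the remaining shares are the child-specific additive,
    nuclear-family shared, and unique components.  Shares sum to 1.
    """
    params.validate()
    m = _core_child_moments(params)
    if m["total_var"] <= 0:
        raise ModelError("implied child outcome variance is zero")
    tv = m["total_var"]
    return {
        "intergenerational": m["inter_var"] / tv,
        "child_A": params.a_c**2 / tv,
        "child_C": params.c_c**2 / tv,
        "child_E": params.e_c**2 / tv,
    }


def decomposition_ci(fit, parent: Role | str, level: float = 0.95) -> DecompositionResult:
    """Decomposition at the fitted parameters with delta-method CIs on the
    percentage of each slice."""
    from scipy import stats

    from .fiml import _assemble

    parent = Role(parent)
    problem = fit.problem
    if problem is None or fit.cov_x is None:
        raise ModelError("decomposition CIs need a fit with covariance information")

    def percents(x: np.ndarray) -> np.ndarray:
        params = _assemble(x, problem.free_names, problem.fixed)
        dec = parent_child_decomposition(params, parent)
        return np.array(
            [dec.percent.get(k, np.nan) for k in ("direct", "genetic", "assortment")]
        )

    x = fit.x
    p0 = percents(x)
    k = len(x)
    J = np.empty((3, k))
    h = 1e-5 * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        J[:, i] = (percents(x + ei) - percents(x - ei)) / (2 * h[i])
    var = np.clip(np.diag(J @ fit.cov_x @ J.T), 0.0, np.inf)
    z = stats.norm.ppf(0.5 + level / 2.0)
    dec = parent_child_decomposition(fit.estimates, parent)
    dec.percent_ci = {
        name: (float(p0[i] - z * np.sqrt(var[i])), float(p0[i] + z * np.sqrt(var[i])))
        for i, name in enumerate(("direct", "genetic", "assortment"))
    }
    return dec
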