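"""Generative simulator for extended family units.

Draws latent factors with exactly the covariance structure the model
algebra implies: linking siblings' additive factors correlate with the
genome share of their sibling class, spouses' factors are built
conditionally (``A_sp = rho_A*A_s + noise``, likewise for E), and each
child's transmitted genotype is the mid-parent breeding value plus
segregation noise of variance ``a**2/2``.  Child-specific additive factors
correlate 0.5 between full siblings and ``alpha/4`` between cousins.

The simulator emulates the sampling frame of a large pregnancy-cohort
children-of-twins study: 11,088 extended family units by default, ~48.9%
girls, family-level outcome response of 70%, and 5% item-level adult
missingness, all configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import validate_table
from .model_core import (
    ADULT_SLOT_LABELS,
    CHILD_SLOT_LABELS,
    MomentStructure,
    ModelError,
    ParameterSet,
    default_parameters,
    relatedness_coefficient,
)

__all__ = [
    "SimulationConfig",
    "simulate_table",
    "simulate_families",
    "empirical_moments",
    "intergenerational_correlations",
]

_CHILD_TAGS = ("c11", "c12", "c21", "c22")
_CHILD_FAM = np.array([0, 0, 1, 1])


def _default_mix() -> dict[str, float]:
    return {"MZ": 0.10, "DZ": 0.15, "FULLSIB": 0.60, "HALFSIB": 0.15}


def _default_parity_probs() -> tuple[float, ...]:
    return (0.45, 0.35, 0.15, 0.05)


@dataclass
class SimulationConfig:
    """Study-design knobs of the simulator.

    Defaults mirror the emulated cohort: 11,088 units, girl fraction 0.489,
    70% family-level outcome response, 5% adult item missingness, and an
    average of ~2.35 children per unit (``two_child_fraction = 0.18``).
    The sibling-class mix is configurable; per-class counts are not printed
    for the emulated study, so the default mix is a plausible placeholder.
    """

    seed: int
    n_units: int = 11088
    structure_mix: Mapping[str, float] = field(default_factory=_default_mix)
    #: probability that a linking sibling is the mother of their nuclear
    #: family; a scalar or one value per linking sibling
    mother_fraction: float | tuple[float, float] = 0.5
    two_child_fraction: float = 0.18
    params: ParameterSet = field(default_factory=default_parameters)
    family_response: float = 0.70
    adult_item_missing: float = 0.05
    girl_fraction: float = 0.489
    parity_probs: tuple[float, ...] = field(default_factory=_default_parity_probs)

    def validate(self) -> None:
        if self.seed is None:
            raise ModelError("a seed is mandatory for reproducible simulation")
        if self.n_units < 1:
            raise ModelError("n_units must be positive")
        probs = dict(self.structure_mix)
        unknown = set(probs) - {"MZ", "DZ", "FULLSIB", "HALFSIB"}
        if unknown:
            raise ModelError(f"unknown sibling classes in structure_mix: {sorted(unknown)}")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ModelError("structure_mix proportions must be non-negative and sum to 1")
        for name in ("two_child_fraction", "family_response",
                     "adult_item_missing", "girl_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ModelError(f"{name}={v} outside [0, 1]")
        mf = np.atleast_1d(np.asarray(self.mother_fraction, dtype=float))
        if mf.size not in (1, 2) or np.any(mf < 0) or np.any(mf > 1):
            raise ModelError(f"mother_fraction={self.mother_fraction} invalid")
        if any(p < 0 for p in self.parity_probs) or abs(sum(self.parity_probs) - 1.0) > 1e-9:
            raise ModelError("parity_probs must be non-negative and sum to 1")
        self.params.validate()


def simulate_table(
    config: SimulationConfig, return_latents: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a wide family table (one row per extended family unit).

    With ``return_latents=True`` also returns the latent state (adult
    phenotypes ``N_*`` and children's transmitted genotypes ``G_*``), which
    test oracles use; latents are never part of the observed table.
    """
    config.validate()
    p = config.params
    rng = np.random.default_rng(config.seed)
    n = config.n_units

    classes = sorted(config.structure_mix)
    probs = np.array([config.structure_mix[c] for c in classes])
    link = rng.choice(np.array(classes, dtype=object), size=n, p=probs).astype(str)
    alpha = np.array([relatedness_coefficient(c) for c in classes])[
        np.searchsorted(classes, link)
    ]

    mf = np.broadcast_to(
        np.atleast_1d(np.asarray(config.mother_fraction, dtype=float)), (2,)
    )
    role_is_mother = rng.random((n, 2)) < mf[None, :]
    n_children = 1 + (rng.random((n, 2)) < config.two_child_fraction).astype(int)

    # --- adult latent factors (order s1, sp1, s2, sp2) ---------------------
    a, c, e = p.a, p.c, p.e
    rA, rE = p.rho_A, p.rho_E
    A = np.empty((n, 4))
    E = np.empty((n, 4))
    A[:, 0] = rng.standard_normal(n)
    A[:, 2] = alpha * A[:, 0] + np.sqrt(1.0 - alpha**2) * rng.standard_normal(n)
    for s_col, sp_col in ((0, 1), (2, 3)):
        A[:, sp_col] = rA * A[:, s_col] + math.sqrt(1.0 - rA**2) * rng.standard_normal(n)
    E[:, 0] = rng.standard_normal(n)
    E[:, 2] = rng.standard_normal(n)
    for s_col, sp_col in ((0, 1), (2, 3)):
        E[:, sp_col] = rE * E[:, s_col] + math.sqrt(1.0 - rE**2) * rng.standard_normal(n)
    C = np.empty((n, 4))
    C[:, 0] = C[:, 2] = rng.standard_normal(n)  # shared by the linking siblings
    C[:, 1] = rng.standard_normal(n)
    C[:, 3] = rng.standard_normal(n)
    N = a * A + c * C + e * E

    # --- measurement model -------------------------------------------------
    is_father = np.empty((n, 4), dtype=bool)
    is_father[:, 0] = ~role_is_mother[:, 0]
    is_father[:, 1] = role_is_mother[:, 0]
    is_father[:, 2] = ~role_is_mother[:, 1]
    is_father[:, 3] = role_is_mother[:, 1]

    adult_values = {}
    for ind, (lam_n, th_n, mu_n) in enumerate(
        (("lambda1", "theta1", "mu1"), ("lambda2", "theta2", "mu2"))
    ):
        lam = np.where(is_father, p._measurement(lam_n, True), p._measurement(lam_n, False))
        th = np.where(is_father, p._measurement(th_n, True), p._measurement(th_n, False))
        mu = np.where(is_father, p._measurement(mu_n, True), p._measurement(mu_n, False))
        y = mu + lam * N + np.sqrt(th) * rng.standard_normal((n, 4))
        for adult, tag in enumerate(("s1", "sp1", "s2", "sp2")):
            adult_values[f"{tag}_n{ind + 1}"] = y[:, adult]

    # --- children ----------------------------------------------------------
    mother_idx = np.empty((n, 4), dtype=np.intp)
    father_idx = np.empty((n, 4), dtype=np.intp)
    for fam in (0, 1):
        m = np.where(role_is_mother[:, fam], 2 * fam, 2 * fam + 1)
        f = np.where(role_is_mother[:, fam], 2 * fam + 1, 2 * fam)
        mother_idx[:, 2 * fam: 2 * fam + 2] = m[:, None]
        father_idx[:, 2 * fam: 2 * fam + 2] = f[:, None]

    rows = np.arange(n)[:, None]
    Atr = a * A  # breeding values on the trait scale
    G = 0.5 * (Atr[rows, mother_idx] + Atr[rows, father_idx]) + math.sqrt(
        0.5 * a**2
    ) * rng.standard_normal((n, 4))

    F_ext = rng.standard_normal(n)
    F_nuc = rng.standard_normal((n, 2))
    A_child = (
        np.sqrt(alpha / 4.0)[:, None] * F_ext[:, None]
        + np.sqrt(0.5 - alpha[:, None] / 4.0) * F_nuc[:, _CHILD_FAM]
        + math.sqrt(0.5) * rng.standard_normal((n, 4))
    )
    C_nuc = rng.standard_normal((n, 2))[:, _CHILD_FAM]
    E_child = rng.standard_normal((n, 4))

    sex = (rng.random((n, 4)) < config.girl_fraction).astype(float)
    parity = rng.choice(
        len(config.parity_probs), size=(n, 4), p=np.asarray(config.parity_probs)
    ).astype(float)

    out = (
        p.mu_o
        + p.beta_sex * sex
        + p.beta_parity * parity
        + p.p_m * N[rows, mother_idx]
        + p.p_f * N[rows, father_idx]
        + p.g * G
        + p.a_c * A_child
        + p.c_c * C_nuc
        + p.e_c * E_child
    )

    # children beyond n_children do not exist
    exists = np.column_stack(
        [np.tile(np.arange(2), 2)[k] < n_children[:, _CHILD_FAM[k]] for k in range(4)]
    )
    out[~exists] = np.nan
    sex[~exists] = np.nan
    parity[~exists] = np.nan

    # family-level outcome response, then item-level adult missingness (MCAR)
    responded = rng.random(n) < config.family_response
    out[~responded, :] = np.nan
    if config.adult_item_missing > 0:
        drop = rng.random((n, 8)) < config.adult_item_missing
        for j, lab in enumerate(ADULT_SLOT_LABELS):
            col = adult_values[lab]
            col[drop[:, j]] = np.nan

    data = {
        "family_id": np.arange(n, dtype=np.int64),
        "sibling_link": link,
        "role1": np.where(role_is_mother[:, 0], "MOTHER", "FATHER"),
        "role2": np.where(role_is_mother[:, 1], "MOTHER", "FATHER"),
        "n_children1": n_children[:, 0].astype(np.int64),
        "n_children2": n_children[:, 1].astype(np.int64),
    }
    for lab in ADULT_SLOT_LABELS:
        data[lab] = adult_values[lab]
    for k, lab in enumerate(CHILD_SLOT_LABELS):
        data[lab] = out[:, k]
    for k, tag in enumerate(_CHILD_TAGS):
        data[f"{tag}_sex"] = sex[:, k]
    for k, tag in enumerate(_CHILD_TAGS):
        data[f"{tag}_parity"] = parity[:, k]
    df = validate_table(pd.DataFrame(data))

    if not return_latents:
        return df
    latents = pd.DataFrame(
        {
            "N_s1": N[:, 0], "N_sp1": N[:, 1], "N_s2": N[:, 2], "N_sp2": N[:, 3],
            "G_c11": G[:, 0], "G_c12": G[:, 1], "G_c21": G[:, 2], "G_c22": G[:, 3],
        }
    )
    return df, latents


def simulate_families(config: SimulationConfig) -> list:
    """Simulate and return per-unit :class:`~cotfam.fiml.FamilyRecord` objects."""
    from .fiml import records_from_frame

    return records_from_frame(simulate_table(config))


def _residualize_children(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove estimated sex/parity effects from child outcomes (pooled OLS)."""
    ys, xs = [], []
    for tag in _CHILD_TAGS:
        y = df[f"{tag}_out"].to_numpy()
        s = df[f"{tag}_sex"].to_numpy()
        q = df[f"{tag}_parity"].to_numpy()
        ok = ~np.isnan(y) & ~np.isnan(s) & ~np.isnan(q)
        ys.append(y[ok])
        xs.append(np.column_stack([np.ones(ok.sum()), s[ok], q[ok]]))
    y_all = np.concatenate(ys)
    X = np.vstack(xs)
    if len(y_all) < 3:
        return df, np.zeros(3)
    beta, *_ = np.linalg.lstsq(X, y_all, rcond=None)
    out = df.copy()
    for tag in _CHILD_TAGS:
        adj = beta[1] * out[f"{tag}_sex"] + beta[2] * out[f"{tag}_parity"]
        out[f"{tag}_out"] = out[f"{tag}_out"] - adj
    return out, beta


def empirical_moments(
    df: pd.DataFrame,
    sibling_link: str | None = None,
    linking_roles: tuple[str, str] | None = None,
    adjust_covariates: bool = True,
) -> MomentStructure:
    """Pairwise-complete sample moments over the full 12-slot layout.

    Optionally filters to one structure class and removes the child
    covariate effects by pooled OLS, so the result is directly comparable
    with :func:`~cotfam.model_core.implied_moments` at zero covariates.
    Pairwise observation counts are attached as ``n_pairwise``.
    """
    sub = df
    if sibling_link is not None:
        sub = sub[sub["sibling_link"] == sibling_link]
    if linking_roles is not None:
        sub = sub[(sub["role1"] == linking_roles[0]) & (sub["role2"] == linking_roles[1])]
    labels = ADULT_SLOT_LABELS + CHILD_SLOT_LABELS
    values = sub.loc[:, list(labels)]
    if (values.notna().sum(axis=1) > 0).sum() < 2:
        raise ModelError("need at least 2 records with data for empirical moments")
    if adjust_covariates:
        sub_adj, _ = _residualize_children(sub)
        values = sub_adj.loc[:, list(labels)]
    mean = values.mean().to_numpy()
    cov = values.cov(min_periods=2).to_numpy()
    var = np.diag(cov)
    if np.any(var <= 0):
        import warnings

        flat = [labels[i] for i in np.flatnonzero(var <= 0)]
        warnings.warn(f"zero variance in columns {flat}", stacklevel=2)
    notna = values.notna().to_numpy().astype(np.int64)
    n_pairwise = notna.T @ notna
    ms = MomentStructure(mean=mean, cov=cov, labels=labels)
    ms.n_pairwise = n_pairwise
    return ms


def intergenerational_correlations(df: pd.DataFrame) -> pd.DataFrame:
    """Raw correlations of adult neuroticism (indicator sum) with the first
    child's outcome, by the adult's relation to the child (mother, father,
    aunt, uncle).  Descriptive report in the layout of a raw-correlation
    table."""
    child = df["c11_out"]
    sums = {tag: df[f"{tag}_n1"] + df[f"{tag}_n2"] for tag in ("s1", "sp1", "s2", "sp2")}
    fam1_mother_is_s1 = df["role1"] == "MOTHER"
    fam2_mother_is_s2 = df["role2"] == "MOTHER"
    relations = {
        "mother": sums["s1"].where(fam1_mother_is_s1, sums["sp1"]),
        "father": sums["sp1"].where(fam1_mother_is_s1, sums["s1"]),
        "aunt": sums["s2"].where(fam2_mother_is_s2, sums["sp2"]),
        "uncle": sums["sp2"].where(fam2_mother_is_s2, sums["s2"]),
    }
    rows = []
    for name, series in relations.items():
        ok = series.notna() & child.notna()
        r = float(np.corrcoef(series[ok], child[ok])[0, 1]) if ok.sum() > 2 else np.nan
        rows.append({"relation": name, "r": r, "n": int(ok.sum())})
    return pd.DataFrame(rows)
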