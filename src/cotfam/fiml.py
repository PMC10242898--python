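"""Full-information maximum likelihood over extended family units.

Each unit contributes the Gaussian log-density of its *observed* subvector
under the sub-selected implied mean and covariance, so arbitrary (MCAR/MAR)
missingness is handled without imputation.  Records sharing a structure and
missingness pattern are grouped so the covariance factorization is done
once per pattern; the contract is defined by the ungrouped per-record
reference path (:func:`family_loglik`) and the two agree to close to
machine precision.

Optimization runs on an unconstrained transformed scale (log for
variances, atanh for correlations, logit for the latent heritability
share) with quasi-Newton iterations (BFGS, L-BFGS-B fallback), the free
mean parameters profiled out exactly by GLS, and optional jittered
multi-starts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from ._kernel import HAVE_NUMBA, fiml_objective
from .io import validate_table
from .model_core import (
    ADULT_SLOT_LABELS,
    FULL_SLOT_LABELS,
    FamilyStructure,
    ModelError,
    ParameterSet,
    Sex,
    build_moment_stack,
    implied_moments,
    observed_slots,
    relatedness_coefficient,
)

__all__ = [
    "FamilyRecord",
    "FitResult",
    "FitOptions",
    "family_loglik",
    "fit_model",
    "param_ci",
    "records_from_frame",
    "frame_from_records",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_CHILD_TAGS = ("c11", "c12", "c21", "c22")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyRecord:
    """Observed values for one extended family unit.

    ``values`` aligns with :func:`~cotfam.model_core.observed_slots` for the
    record's structure; ``None`` marks a missing observation.  Covariates
    (child sex and parity) live on the structure.
    """

    structure: FamilyStructure
    values: tuple[float | None, ...]

    def __post_init__(self):
        n_slots = len(observed_slots(self.structure))
        if len(self.values) != n_slots:
            raise ModelError(
                f"record has {len(self.values)} values but structure defines "
                f"{n_slots} observed slots"
            )

    @property
    def n_observed(self) -> int:
        return sum(v is not None and not np.isnan(v) for v in self.values)


def family_loglik(params: ParameterSet, record: FamilyRecord) -> float:
    """Reference (ungrouped) log-likelihood of one unit.

    Gaussian log-density of the non-missing subvector under the
    sub-selected implied moments:
    ``-0.5 * (k*log(2*pi) + log|S| + (y-m)' S^-1 (y-m))``.
    An all-missing record contributes 0 (logged as a warning).
    """
    moments = implied_moments(params, record.structure)
    y = np.array(
        [np.nan if v is None else float(v) for v in record.values], dtype=float
    )
    obs = ~np.isnan(y)
    k = int(obs.sum())
    if k == 0:
        logger.warning("all-missing family record contributes 0 to the likelihood")
        return 0.0
    mu = moments.mean[obs]
    sigma = moments.cov[np.ix_(obs, obs)]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ModelError(
            "singular observed submatrix for slots "
            f"{[l for l, o in zip(moments.labels, obs) if o]}"
        )
    resid = y[obs] - mu
    quad = resid @ np.linalg.solve(sigma, resid)
    return -0.5 * (k * _LOG2PI + logdet + quad)


def records_from_frame(df: pd.DataFrame) -> list[FamilyRecord]:
    """Convert the wide table to per-unit records (inverse of
    :func:`frame_from_records`)."""
    df = validate_table(df)
    records = []
    for idx, row in df.iterrows():
        n_ch = (int(row["n_children1"]), int(row["n_children2"]))
        sexes, parities, child_values = [], [], []
        for fam, tags in enumerate((("c11", "c12"), ("c21", "c22"))):
            fam_sex, fam_par = [], []
            for k in range(n_ch[fam]):
                tag = tags[k]
                s, q = row[f"{tag}_sex"], row[f"{tag}_parity"]
                if np.isnan(s) or np.isnan(q):
                    raise ModelError(
                        f"row {idx}: child {tag} exists but covariate "
                        f"{'sex' if np.isnan(s) else 'parity'} is missing"
                    )
                fam_sex.append(Sex.GIRL if s == 1.0 else Sex.BOY)
                fam_par.append(int(q))
                v = row[f"{tag}_out"]
                child_values.append(None if np.isnan(v) else float(v))
            sexes.append(tuple(fam_sex))
            parities.append(tuple(fam_par))
        structure = FamilyStructure(
            sibling_link=row["sibling_link"],
            linking_roles=(row["role1"], row["role2"]),
            n_children=n_ch,
            child_sexes=tuple(sexes),
            child_parities=tuple(parities),
        )
        adult_values = [
            None if np.isnan(row[lab]) else float(row[lab]) for lab in ADULT_SLOT_LABELS
        ]
        records.append(FamilyRecord(structure, tuple(adult_values + child_values)))
    return records


def frame_from_records(records: Iterable[FamilyRecord]) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        st = rec.structure
        row = {
            "family_id": i,
            "sibling_link": st.sibling_link.value,
            "role1": st.linking_roles[0].value,
            "role2": st.linking_roles[1].value,
            "n_children1": st.n_children[0],
            "n_children2": st.n_children[1],
        }
        for lab, v in zip(ADULT_SLOT_LABELS, rec.values[:8]):
            row[lab] = np.nan if v is None else v
        child_vals = list(rec.values[8:])
        pos = 0
        for fam, tags in enumerate((("c11", "c12"), ("c21", "c22"))):
            for k in range(2):
                tag = tags[k]
                if k < st.n_children[fam]:
                    v = child_vals[pos]
                    pos += 1
                    row[f"{tag}_out"] = np.nan if v is None else v
                    row[f"{tag}_sex"] = 1.0 if st.child_sexes[fam][k] == Sex.GIRL else 0.0
                    row[f"{tag}_parity"] = float(st.child_parities[fam][k])
                else:
                    row[f"{tag}_out"] = np.nan
                    row[f"{tag}_sex"] = np.nan
                    row[f"{tag}_parity"] = np.nan
        rows.append(row)
    return validate_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

class _Identity:
    def to_natural(self, x): return x
    def to_unconstrained(self, v): return v
    bounds = (-np.inf, np.inf)


class _Log:
    """Positive parameters (residual SDs / variance paths)."""
    def to_natural(self, x): return math.exp(x)
    def to_unconstrained(self, v):
        return math.log(max(v, 1e-10))
    bounds = (0.0, np.inf)


class _Tanh:
    def to_natural(self, x): return math.tanh(x)
    def to_unconstrained(self, v):
        return math.atanh(min(max(v, -1 + 1e-10), 1 - 1e-10))
    bounds = (-1.0, 1.0)


class _SqrtExpit:
    """Paths whose square is a proportion in (0, 1)."""
    def to_natural(self, x): return math.sqrt(expit(x))
    def to_unconstrained(self, v):
        v2 = min(max(v * v, 1e-10), 1 - 1e-10)
        return float(logit(v2))
    bounds = (0.0, 1.0)


#: registry of fittable parameters, in canonical order
_TRANSFORMS: dict[str, object] = {
    "a": _SqrtExpit(),
    "c": _SqrtExpit(),     # interpreted as share of the non-A latent variance
    "rho_A": _Tanh(),
    "rho_E": _Tanh(),
    "lambda1": _Identity(),
    "lambda2": _Identity(),
    "theta1": _Log(),
    "theta2": _Log(),
    "p_m": _Identity(),
    "p_f": _Identity(),
    "g": _Identity(),
    "a_c": _Log(),
    "c_c": _Log(),
    "e_c": _Log(),
    "beta_sex": _Identity(),
    "beta_parity": _Identity(),
    "mu1": _Identity(),
    "mu2": _Identity(),
    "mu_o": _Identity(),
    "lambda1_f": _Identity(),
    "lambda2_f": _Identity(),
    "theta1_f": _Log(),
    "theta2_f": _Log(),
    "mu1_f": _Identity(),
    "mu2_f": _Identity(),
}

PARAM_NAMES = tuple(_TRANSFORMS)

#: parameters held fixed unless explicitly freed
_DEFAULT_FIXED = {
    "c": 0.0,
    "lambda1_f": None, "lambda2_f": None,
    "theta1_f": None, "theta2_f": None,
    "mu1_f": None, "mu2_f": None,
}

_DOMAIN_BOUNDS = {name: tr.bounds for name, tr in _TRANSFORMS.items()}


#: parameters entering the mean structure linearly (profiled out by GLS)
_MEAN_PARAMS = ("mu1", "mu2", "mu_o", "beta_sex", "beta_parity", "mu1_f", "mu2_f")


def _assemble_from_naturals(vals: dict, c_is_share: bool) -> ParameterSet:
    vals = dict(vals)
    a = vals["a"]
    c_val = vals.get("c") or 0.0
    # when c is free its transformed value is a share of the non-additive
    # latent variance, guaranteeing a^2 + c^2 < 1 for any unconstrained input
    c = math.sqrt(c_val**2 * (1.0 - a**2)) if c_is_share else c_val
    e2 = 1.0 - a**2 - c**2
    if e2 <= 0:
        raise ModelError(f"a^2 + c^2 = {a**2 + c**2:.6g} >= 1 leaves no E variance")
    vals["c"] = c
    vals["e"] = math.sqrt(e2)
    return ParameterSet(**vals)


def _assemble(theta: np.ndarray, free_names: Sequence[str], fixed: Mapping) -> ParameterSet:
    vals: dict = dict(fixed)
    for name, x in zip(free_names, theta):
        vals[name] = _TRANSFORMS[name].to_natural(float(x))
    return _assemble_from_naturals(vals, "c" in free_names)


def _disassemble(params: ParameterSet, free_names: Sequence[str]) -> np.ndarray:
    x = np.empty(len(free_names))
    for i, name in enumerate(free_names):
        v = getattr(params, name)
        if name == "c":
            nonA = 1.0 - params.a**2
            v = math.sqrt(params.c**2 / nonA) if nonA > 0 else 0.0
        if v is None:  # sex-specific field freed but unset: start from shared value
            v = getattr(params, name[:-2])
        x[i] = _TRANSFORMS[name].to_unconstrained(float(v))
    return x


# ---------------------------------------------------------------------------
# grouped likelihood
# ---------------------------------------------------------------------------

class FimlProblem:
    """Preprocessed dataset plus constraint map: the −2LL objective."""

    def __init__(self, data, constraints: Mapping | None = None,
                 free_extra: Sequence[str] = ()):
        if isinstance(data, pd.DataFrame):
            df = validate_table(data)
        else:
            df = frame_from_records(list(data))
        constraints = dict(constraints or {})
        for name in list(constraints) + list(free_extra):
            if name not in PARAM_NAMES:
                raise ModelError(f"constraint on unknown parameter {name!r}")
        fixed = dict(_DEFAULT_FIXED)
        for name in free_extra:
            fixed.pop(name, None)
        fixed.update(constraints)
        if "e" in fixed:
            raise ModelError("e is derived from a and c and cannot be constrained")
        self.fixed = fixed
        self.free_names = [p for p in PARAM_NAMES if p not in fixed]
        self._prepare(df)

    def with_constraints(
        self, constraints: Mapping | None = None, free_extra: Sequence[str] = ()
    ) -> "FimlProblem":
        """A view of the same data under a different constraint map."""
        constraints = dict(constraints or {})
        for name in list(constraints) + list(free_extra):
            if name not in PARAM_NAMES:
                raise ModelError(f"constraint on unknown parameter {name!r}")
        sub = FimlProblem.__new__(FimlProblem)
        sub.__dict__.update(self.__dict__)
        fixed = dict(_DEFAULT_FIXED)
        for name in free_extra:
            fixed.pop(name, None)
        fixed.update(constraints)
        sub.fixed = fixed
        sub.free_names = [p for p in PARAM_NAMES if p not in fixed]
        return sub

    # -- data preparation ---------------------------------------------------
    def _prepare(self, df: pd.DataFrame) -> None:
        n = len(df)
        link = df["sibling_link"].to_numpy()
        r1m = (df["role1"] == "MOTHER").to_numpy()
        r2m = (df["role2"] == "MOTHER").to_numpy()
        n_ch = df[["n_children1", "n_children2"]].to_numpy()

        Y = np.full((n, 12), np.nan)
        for j, lab in enumerate(FULL_SLOT_LABELS):
            Y[:, j] = df[lab].to_numpy()
        # non-existent children are structural missing
        child_fam = np.array([0, 0, 1, 1])
        child_k = np.array([0, 1, 0, 1])
        exists = child_k[None, :] < n_ch[:, child_fam]
        Y[:, 8:][~exists] = np.nan

        sex = df[[f"{t}_sex" for t in _CHILD_TAGS]].to_numpy()
        par = df[[f"{t}_parity" for t in _CHILD_TAGS]].to_numpy()
        out_obs = ~np.isnan(Y[:, 8:])
        bad = out_obs & (np.isnan(sex) | np.isnan(par))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ModelError(
                f"row {r}: child {_CHILD_TAGS[c]} outcome observed but covariates missing"
            )
        self.sex = np.nan_to_num(sex)
        self.parity = np.nan_to_num(par)

        # unique base structures (sibling class x linking roles)
        codes = {"MZ": 0, "DZ": 1, "FULLSIB": 2, "HALFSIB": 3}
        link_code = np.array([codes[l] for l in link])
        struct_code = link_code * 4 + r1m.astype(int) * 2 + r2m.astype(int)
        uniq_structs, sid = np.unique(struct_code, return_inverse=True)
        alphas, mothers, fathers, is_father = [], [], [], []
        inv_codes = {v: k for k, v in codes.items()}
        for sc in uniq_structs:
            lc, rest = divmod(int(sc), 4)
            r1, r2 = bool(rest // 2), bool(rest % 2)
            alphas.append(relatedness_coefficient(inv_codes[lc]))
            m = np.empty(4, dtype=np.intp)
            f = np.empty(4, dtype=np.intp)
            isf = np.empty(4, dtype=bool)
            for fam, is_mother in enumerate((r1, r2)):
                lk, sp = 2 * fam, 2 * fam + 1
                mm, ff = (lk, sp) if is_mother else (sp, lk)
                m[2 * fam: 2 * fam + 2] = mm
                f[2 * fam: 2 * fam + 2] = ff
                isf[lk] = not is_mother
                isf[sp] = is_mother
            mothers.append(m)
            fathers.append(f)
            is_father.append(isf)
        self.alphas = np.array(alphas)
        self.mothers = np.array(mothers, dtype=np.int64)
        self.fathers = np.array(fathers, dtype=np.int64)
        self.is_father_arr = np.array(is_father, dtype=bool)
        self.sid = np.ascontiguousarray(sid, dtype=np.int64)

        mask = ~np.isnan(Y)
        self.Y0 = np.nan_to_num(Y)
        self.mask = mask
        self.k_obs = mask.sum(axis=1)
        self.n_all_missing = int((self.k_obs == 0).sum())
        if self.n_all_missing:
            logger.warning(
                "%d all-missing records contribute 0 to the likelihood",
                self.n_all_missing,
            )
        if n - self.n_all_missing < 1:
            raise ModelError("no record contributes data to the likelihood")
        self.n_records = n

        # group by (structure, missingness pattern)
        pattern = mask @ (1 << np.arange(12, dtype=np.int64))
        key = sid.astype(np.int64) * (1 << 12) + pattern
        uniq_keys, first, gid = np.unique(key, return_index=True, return_inverse=True)
        self.gid = np.ascontiguousarray(gid, dtype=np.int64)
        self.group_sid = np.ascontiguousarray(self.sid[first])
        self.group_mask = np.ascontiguousarray(mask[first])
        self.n_groups = len(uniq_keys)

    # -- objective ----------------------------------------------------------
    def implied_stack(self, params: ParameterSet):
        return build_moment_stack(
            params, self.alphas, self.mothers, self.fathers, self.is_father_arr
        )

    @property
    def free_mean_names(self) -> list[str]:
        return [p for p in self.free_names if p in _MEAN_PARAMS]

    @property
    def free_cov_names(self) -> list[str]:
        return [p for p in self.free_names if p not in _MEAN_PARAMS]

    def _mean_design(self) -> np.ndarray:
        """(n, 12, q) design of the free mean parameters, zeroed at missing."""
        key = tuple(self.free_mean_names) + tuple(sorted(self.fixed))
        cache = self.__dict__.setdefault("_mean_design_cache", {})
        if key in cache:
            return cache[key]
        n = self.n_records
        ind1_slots = [0, 2, 4, 6]
        ind2_slots = [1, 3, 5, 7]
        rec_is_father = self.is_father_arr[self.sid]  # (n, 4)
        slot_is_father = rec_is_father[:, np.repeat(np.arange(4), 2)]  # (n, 8)
        cols = []
        for name in self.free_mean_names:
            col = np.zeros((n, 12))
            if name in ("mu1", "mu2"):
                slots = ind1_slots if name == "mu1" else ind2_slots
                sexed = f"{name}_f" in self.free_names or self.fixed.get(f"{name}_f") is not None
                col[:, slots] = 1.0
                if sexed:  # fathers have their own intercept
                    col[:, slots] *= ~slot_is_father[:, [s for s in slots]]
            elif name in ("mu1_f", "mu2_f"):
                slots = ind1_slots if name == "mu1_f" else ind2_slots
                col[:, slots] = slot_is_father[:, [s for s in slots]]
            elif name == "mu_o":
                col[:, 8:] = 1.0
            elif name == "beta_sex":
                col[:, 8:] = self.sex
            elif name == "beta_parity":
                col[:, 8:] = self.parity
            cols.append(col)
        D = np.stack(cols, axis=2) if cols else np.zeros((n, 12, 0))
        D *= self.mask[:, :, None]
        D = np.ascontiguousarray(D)
        cache[key] = D
        return D

    def _assemble_zero_means(self, theta_cov: np.ndarray) -> ParameterSet:
        vals = dict(self.fixed)
        for name, x in zip(self.free_cov_names, theta_cov):
            vals[name] = _TRANSFORMS[name].to_natural(float(x))
        for name in self.free_mean_names:
            vals[name] = 0.0
        return _assemble_from_naturals(vals, "c" in self.free_cov_names)

    def _padded_precision(self, params: ParameterSet):
        """Group-padded covariance factorization; returns (logdet, Pinv, mu)."""
        cov, mu = self.implied_stack(params)
        P = cov[self.group_sid] * (
            self.group_mask[:, :, None] & self.group_mask[:, None, :]
        )
        diag = np.arange(12)
        d = P[:, diag, diag].copy()
        d[~self.group_mask] = 1.0
        P[:, diag, diag] = d
        chol = np.linalg.cholesky(P)  # raises LinAlgError if not PD
        logdet = 2.0 * np.log(chol[:, diag, diag]).sum(axis=1)
        return logdet, np.linalg.inv(P), mu

    def _eval_numpy(self, params: ParameterSet, D: np.ndarray):
        """Grouped-pattern numpy evaluation, GLS-profiling the columns of ``D``."""
        logdet, Pinv, mu = self._padded_precision(params)
        M0 = mu[self.sid].copy()
        M0[:, 8:] += params.beta_sex * self.sex + params.beta_parity * self.parity
        R0 = (self.Y0 - M0) * self.mask
        Pg = Pinv[self.gid]
        U = np.einsum("nij,nj->ni", Pg, R0)
        quad = float((U * R0).sum())
        q = D.shape[2]
        if q:
            PD = np.einsum("nij,njq->niq", Pg, D)
            A = np.einsum("nip,niq->pq", D, PD)
            b = np.einsum("niq,ni->q", D, U)
            mean_hat = np.linalg.solve(A, b)
            quad -= float(mean_hat @ b)
        else:
            mean_hat = np.zeros(0)
        value = float(self.k_obs.sum() * _LOG2PI + logdet[self.gid].sum() + quad)
        return value, mean_hat

    def _eval(self, params: ParameterSet, D: np.ndarray):
        """Dispatch to the compiled kernel when available (same contract)."""
        if not HAVE_NUMBA:
            try:
                return self._eval_numpy(params, D)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(D.shape[2])
        lam = np.array(
            [
                [params._measurement("lambda1", False), params._measurement("lambda1", True)],
                [params._measurement("lambda2", False), params._measurement("lambda2", True)],
            ]
        )
        th = np.array(
            [
                [params._measurement("theta1", False), params._measurement("theta1", True)],
                [params._measurement("theta2", False), params._measurement("theta2", True)],
            ]
        )
        mu_meas = np.array(
            [
                [params._measurement("mu1", False), params._measurement("mu1", True)],
                [params._measurement("mu2", False), params._measurement("mu2", True)],
            ]
        )
        return fiml_objective(
            self.alphas, self.mothers, self.fathers, self.is_father_arr,
            params.a**2, params.c**2, params.e**2, params.rho_A, params.rho_E,
            lam, th, mu_meas,
            params.p_m, params.p_f, params.g,
            params.a_c**2, params.c_c**2, params.e_c**2,
            params.mu_o, params.beta_sex, params.beta_parity,
            self.group_sid, self.group_mask,
            self.sid, self.gid, self.Y0, self.mask, self.sex, self.parity,
            self.k_obs,
            D,
        )

    @property
    def _empty_design(self) -> np.ndarray:
        if "_empty_D" not in self.__dict__:
            self.__dict__["_empty_D"] = np.zeros((self.n_records, 12, 0))
        return self.__dict__["_empty_D"]

    def profiled_minus2ll(self, theta_cov: np.ndarray):
        """−2LL minimized exactly (GLS) over the free mean parameters.

        Returns ``(value, mean_hat)``; the mean structure is linear in the
        free intercepts and covariate effects, so the inner minimization is
        a small weighted least-squares solve per evaluation.
        """
        params0 = self._assemble_zero_means(theta_cov)
        return self._eval(params0, self._mean_design())

    def profiled_objective(self, theta_cov: np.ndarray) -> float:
        try:
            value, _ = self.profiled_minus2ll(theta_cov)
        except (ModelError, OverflowError, np.linalg.LinAlgError):
            return np.inf
        return value

    def minus2ll_params(self, params: ParameterSet) -> float:
        cov, mu = self.implied_stack(params)
        P = cov[self.group_sid] * (
            self.group_mask[:, :, None] & self.group_mask[:, None, :]
        )
        diag = np.arange(12)
        d = P[:, diag, diag].copy()
        d[~self.group_mask] = 1.0
        P[:, diag, diag] = d
        try:
            chol = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(chol[:, diag, diag]).sum(axis=1)
        Pinv = np.linalg.inv(P)

        M = mu[self.sid].copy()
        M[:, 8:] += params.beta_sex * self.sex + params.beta_parity * self.parity
        R = (self.Y0 - M) * self.mask
        T = np.einsum("nij,nj->ni", Pinv[self.gid], R)
        quad = (T * R).sum(axis=1)
        ll = -0.5 * (self.k_obs * _LOG2PI + logdet[self.gid] + quad)
        return float(-2.0 * ll.sum())

    def minus2ll(self, theta: np.ndarray) -> float:
        """Plain objective over the full free vector (no mean profiling)."""
        try:
            params = _assemble(theta, self.free_names, self.fixed)
        except (ModelError, OverflowError):
            return np.inf
        value, _ = self._eval(params, self._empty_design)
        return value

    def reference_minus2ll(self, params: ParameterSet) -> float:
        """Ungrouped per-record path (the contract the fast path must match)."""
        total = 0.0
        cov, mu = self.implied_stack(params)
        for i in range(self.n_records):
            obs = self.mask[i]
            k = obs.sum()
            if k == 0:
                continue
            m = mu[self.sid[i]].copy()
            m[8:] += params.beta_sex * self.sex[i] + params.beta_parity * self.parity[i]
            sigma = cov[self.sid[i]][np.ix_(obs, obs)]
            resid = self.Y0[i][obs] - m[obs]
            sign, logdet = np.linalg.slogdet(sigma)
            total += -0.5 * (k * _LOG2PI + logdet + resid @ np.linalg.solve(sigma, resid))
        return -2.0 * total

    # -- starting values ----------------------------------------------------
    def neutral_start(self) -> ParameterSet:
        ind1 = self.Y0[:, 0::2][:, :4][self.mask[:, 0::2][:, :4]]
        ind2 = self.Y0[:, 1::2][:, :4][self.mask[:, 1::2][:, :4]]
        child = self.Y0[:, 8:][self.mask[:, 8:]]
        v1 = float(np.var(ind1)) if len(ind1) > 1 else 1.0
        v2 = float(np.var(ind2)) if len(ind2) > 1 else 1.0
        vo = float(np.var(child)) if len(child) > 1 else 1.0
        return ParameterSet.from_variances(
            0.4,
            rho_A=0.05,
            rho_E=0.05,
            lambda1=math.sqrt(v1 / 2), lambda2=math.sqrt(v2 / 2),
            theta1=v1 / 2, theta2=v2 / 2,
            p_m=0.1, p_f=0.1, g=0.1,
            a_c=math.sqrt(0.3 * vo), c_c=math.sqrt(0.1 * vo), e_c=math.sqrt(0.5 * vo),
            beta_sex=0.0, beta_parity=0.0,
            mu1=float(np.mean(ind1)) if len(ind1) else 0.0,
            mu2=float(np.mean(ind2)) if len(ind2) else 0.0,
            mu_o=float(np.mean(child)) if len(child) else 0.0,
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer contract: quasi-Newton on the transformed scale with
    jittered multi-starts; convergence by relative −2LL change and the
    projected-gradient criterion of L-BFGS-B (both logged)."""

    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.25
    maxiter: int = 1000
    ftol: float = 1e-10
    #: gradient tolerance per observed data point (scale-free across n)
    gtol_per_obs: float = 1e-5
    fd_step: float = 1e-6
    compute_ci: bool = True
    ci_level: float = 0.95
    start: ParameterSet | None = None


@dataclass
class FitResult:
    estimates: ParameterSet
    minus2LL: float
    n_free: int
    aic: float
    converged: bool
    ci: dict[str, tuple[float, float]]
    fixed_mask: dict
    free_names: list[str]
    se: dict[str, float] | None = None
    ci_method: str = "wald"
    ci_flags: dict[str, str] = field(default_factory=dict)
    grad_norm: float = np.nan
    n_records: int = 0
    seed: int | None = None
    n_starts: int = 1
    x: np.ndarray | None = None
    cov_x: np.ndarray | None = None
    problem: FimlProblem | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.free_names:
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "parameter": name,
                    "estimate": getattr(self.estimates, name),
                    "se": (self.se or {}).get(name, np.nan),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian (dense, symmetric)."""
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k); ej[j] = h[j]
            f1 = fun(x + ei + ej)
            f2 = fun(x + ei - ej)
            f3 = fun(x - ei + ej)
            f4 = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f1 - f2 - f3 + f4) / (4.0 * h[i] * h[j])
    return H


def _natural_free(problem: FimlProblem, x: np.ndarray) -> np.ndarray:
    params = _assemble(x, problem.free_names, problem.fixed)
    return np.array([getattr(params, nm) for nm in problem.free_names], dtype=float)


def _wald_ci(problem, x, cov_x, level):
    """Wald intervals built on the unconstrained scale and mapped back.

    Symmetric on the transformed scale, hence asymmetric — and always
    inside the domain — for bounded parameters (variances, correlations,
    proportions), which markedly improves coverage near boundaries.  The
    reported standard error is the delta-method one on the natural scale.
    """
    k = len(x)
    J = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        J[:, i] = (_natural_free(problem, x + ei) - _natural_free(problem, x - ei)) / (
            2 * h[i]
        )
    cov_nat = J @ cov_x @ J.T
    se = np.sqrt(np.clip(np.diag(cov_nat), 0.0, np.inf))
    se_x = np.sqrt(np.clip(np.diag(cov_x), 0.0, np.inf))
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci, flags, se_map = {}, {}, {}
    for i, name in enumerate(problem.free_names):
        step = np.zeros(k); step[i] = z * se_x[i]
        lo = _natural_free(problem, x - step)[i]
        hi = _natural_free(problem, x + step)[i]
        if lo > hi:
            lo, hi = hi, lo
        ci[name] = (float(lo), float(hi))
        se_map[name] = float(se[i])
    return ci, se_map, flags


def fit_model(
    data,
    constraints: Mapping | None = None,
    options: FitOptions | None = None,
    free_extra: Sequence[str] = (),
) -> FitResult:
    """Maximize the FIML likelihood over the free parameters.

    ``constraints`` maps parameter names to fixed constants (e.g.
    ``{"p_f": 0.0}``); parameters fixed by default (parental C, sex-specific
    measurement) can be released through ``free_extra``.  Deterministic
    given data, start values and the multi-start seed.
    """
    options = options or FitOptions()
    if isinstance(data, FimlProblem):
        problem = data
        if constraints is not None or free_extra:
            problem = data.with_constraints(constraints, free_extra)
    else:
        problem = FimlProblem(data, constraints, free_extra)
    start = options.start or problem.neutral_start()
    x0 = _disassemble(start, problem.free_cov_names)
    rng = np.random.default_rng(options.seed)

    if len(x0) == 0:
        # degenerate optimization: every covariance parameter is fixed;
        # the free means (if any) still have their exact GLS solution
        value, mean_hat = problem.profiled_minus2ll(x0)
        res = optimize.OptimizeResult(
            x=x0, fun=value, success=True, jac=None, message="nothing to optimize"
        )
    else:
        gtol_abs = options.gtol_per_obs * float(problem.k_obs.sum())
        best = None
        for s in range(max(1, options.n_starts)):
            xs = x0 if s == 0 else x0 + options.jitter * rng.standard_normal(len(x0))
            res = optimize.minimize(
                problem.profiled_objective,
                xs,
                method="BFGS",
                options={
                    "maxiter": options.maxiter,
                    "gtol": gtol_abs,
                    "eps": options.fd_step,
                },
            )
            ok = res.success or (
                np.isfinite(res.fun)
                and res.jac is not None
                and np.max(np.abs(res.jac)) < 10.0 * gtol_abs
            )
            if not ok:  # quasi-Newton fallback with looser line search
                res2 = optimize.minimize(
                    problem.profiled_objective,
                    res.x if np.isfinite(res.fun) else xs,
                    method="L-BFGS-B",
                    options={
                        "maxiter": options.maxiter,
                        "ftol": options.ftol,
                        "gtol": gtol_abs,
                        "eps": options.fd_step,
                    },
                )
                if res2.fun <= res.fun or not np.isfinite(res.fun):
                    res = res2
            if best is None or res.fun < best.fun:
                best = res
        res = best
        _, mean_hat = problem.profiled_minus2ll(res.x)
    grad_norm = (
        float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    )
    gtol_ref = options.gtol_per_obs * float(problem.k_obs.sum())
    converged = np.isfinite(res.fun) and (
        bool(res.success) or (np.isfinite(grad_norm) and grad_norm < 10.0 * gtol_ref)
    )
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)
    logger.info(
        "fit: -2LL=%.4f, max|grad|=%.3g, converged=%s", res.fun, grad_norm, converged
    )

    estimates = problem._assemble_zero_means(res.x).replace(
        **dict(zip(problem.free_mean_names, mean_hat))
    )
    x_full = _disassemble(estimates, problem.free_names)
    n_free = len(problem.free_names)
    fit = FitResult(
        estimates=estimates,
        minus2LL=float(res.fun),
        n_free=n_free,
        aic=float(res.fun) + 2.0 * n_free,
        converged=converged,
        ci={},
        fixed_mask=dict(problem.fixed),
        free_names=list(problem.free_names),
        grad_norm=grad_norm,
        n_records=problem.n_records,
        seed=options.seed,
        n_starts=max(1, options.n_starts),
        x=x_full,
        problem=problem,
    )
    if options.compute_ci and len(problem.free_names):
        H = _fd_hessian(problem.minus2ll, x_full)
        try:
            cov_x = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_x = 2.0 * np.linalg.pinv(H)
        fit.cov_x = cov_x
        fit.ci, fit.se, fit.ci_flags = _wald_ci(problem, x_full, cov_x, options.ci_level)
        fit.ci_method = "wald"
    return fit


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def profile_interval(
    nll2,
    x_hat: np.ndarray,
    index: int,
    level: float = 0.95,
    se_hint: float = 1.0,
    max_expand: int = 40,
) -> tuple[float, float]:
    """Profile interval for coordinate ``index`` of a −2LL-shaped objective.

    ``nll2(x_fixed_value)`` must return the objective minimized over the
    remaining coordinates with coordinate ``index`` fixed.  The bound solves
    ``nll2(v) - nll2(v_hat) = chi2(1, level)`` by bracketing + Brent.
    """
    target = stats.chi2.ppf(level, 1)
    v_hat = x_hat[index]
    f_hat = nll2(v_hat)

    def drop(v):
        return nll2(v) - f_hat - target

    bounds = []
    for direction in (-1.0, +1.0):
        step = se_hint
        v = v_hat
        prev = v_hat
        found = None
        for _ in range(max_expand):
            v = v + direction * step
            if drop(v) > 0:
                found = (min(prev, v), max(prev, v))
                break
            prev = v
            step *= 1.6
        if found is None:
            bounds.append(direction * np.inf)
            continue
        sol = optimize.brentq(drop, found[0], found[1], xtol=1e-8)
        bounds.append(sol)
    return bounds[0], bounds[1]


def param_ci(
    fit: FitResult,
    level: float = 0.95,
    method: str = "profile",
    names: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-parameter confidence intervals for a converged fit.

    Default is profile likelihood (χ²(1) cutoff) on the natural scale, with
    the Wald interval as a flagged fallback if profiling fails.  Natural
    domain bounds (e.g. variance ≥ 0) clip the interval, flagged in
    ``fit.ci_flags``.  ``names`` restricts profiling to a subset of the
    free parameters (profiling refits the model per bound).
    """
    if not 0.0 < level < 1.0:
        raise ModelError(f"confidence level must be in (0, 1), got {level}")
    if not fit.converged:
        raise ModelError("confidence intervals require a converged fit")
    if method == "wald":
        if fit.cov_x is None:
            raise ModelError("fit carries no covariance; rerun with compute_ci=True")
        ci, se, flags = _wald_ci(fit.problem, fit.x, fit.cov_x, level)
        fit.ci, fit.se, fit.ci_flags, fit.ci_method = ci, se, flags, "wald"
        return ci
    if method != "profile":
        raise ModelError(f"unknown CI method {method!r}")

    problem = fit.problem
    ci: dict[str, tuple[float, float]] = {}
    flags: dict[str, str] = {}
    wanted = list(names) if names is not None else list(problem.free_names)
    unknown = set(wanted) - set(problem.free_names)
    if unknown:
        raise ModelError(f"cannot profile non-free parameters {sorted(unknown)}")
    for name in wanted:
        est = getattr(fit.estimates, name)
        se_nat = (fit.se or {}).get(name, 0.1) or 0.1

        def nll2(v, _name=name):
            sub = FimlProblem.__new__(FimlProblem)
            sub.__dict__.update(problem.__dict__)
            sub.fixed = dict(problem.fixed)
            sub.fixed[_name] = v
            sub.free_names = [p for p in problem.free_names if p != _name]
            res = fit_model(
                sub,
                options=FitOptions(
                    n_starts=1, compute_ci=False, start=fit.estimates, maxiter=500
                ),
            )
            return res.minus2LL

        try:
            lo, hi = profile_interval(
                nll2, np.array([est]), 0, level=level, se_hint=max(se_nat, 1e-3)
            )
        except Exception as exc:  # noqa: BLE001 - fall back, flagged
            logger.warning("profiling %s failed (%s); using Wald", name, exc)
            lo, hi = fit.ci.get(name, (np.nan, np.nan))
            flags[name] = "wald fallback"
        dlo, dhi = _DOMAIN_BOUNDS[name]
        if lo < dlo:
            lo, flags[name] = dlo, "lower bound clipped to domain"
        if hi > dhi:
            hi, flags[name] = dhi, "upper bound clipped to domain"
        ci[name] = (float(lo), float(hi))
    fit.ci = {**fit.ci, **ci}
    fit.ci_flags, fit.ci_method = flags, "profile"
    return ci
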