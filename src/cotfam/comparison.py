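"""Nested model comparison: likelihood-ratio tests and AIC.

The canonical suite for one outcome fits the full transmission model and
its nested restrictions — no direct maternal transmission (``p_m = 0``),
no direct paternal transmission (``p_f = 0``), no direct transmission at
all, no genetic transmission (``g = 0``) — plus a sensitivity model with
assortative mating fixed to zero.  Transmission paths are interior
parameters, so the standard χ² reference distribution applies (no boundary
mixture).  A low AIC is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .fiml import FitOptions, FitResult, fit_model
from .model_core import ModelError

__all__ = ["LRTResult", "lrt", "lrt_from_stats", "nested_suite", "NESTED_MODELS"]

#: Table-2-shaped model family: label -> constraint map relative to the full model
NESTED_MODELS: dict[str, dict[str, float]] = {
    "2a: no direct maternal transmission (p_m=0)": {"p_m": 0.0},
    "2b: no direct paternal transmission (p_f=0)": {"p_f": 0.0},
    "2c: no direct transmission (p_m=p_f=0)": {"p_m": 0.0, "p_f": 0.0},
    "3: no genetic transmission (g=0)": {"g": 0.0},
    "no assortative mating (rho_A=rho_E=0)": {"rho_A": 0.0, "rho_E": 0.0},
}

#: allow a tiny negative delta from finite optimizer tolerances
_NEG_TOL = 1e-4


@dataclass(frozen=True)
class LRTResult:
    delta_minus2LL: float
    delta_df: int
    p_value: float
    aic_full: float
    aic_constrained: float
    delta_aic: float

    def __post_init__(self):
        if self.delta_minus2LL < 0 or not 0 <= self.p_value <= 1:
            raise ModelError("inconsistent likelihood-ratio statistics")


def lrt_from_stats(delta_minus2LL: float, delta_df: int, aic_full: float) -> LRTResult:
    """Likelihood-ratio arithmetic from summary statistics.

    ``AIC_constrained = AIC_full + delta_minus2LL - 2*delta_df`` and
    ``p = P(chi2(delta_df) >= delta_minus2LL)``.
    """
    if delta_df < 1:
        raise ModelError("delta_df must be a positive integer")
    if delta_minus2LL < 0:
        raise ModelError(f"negative likelihood-ratio statistic {delta_minus2LL}")
    p = float(stats.chi2.sf(delta_minus2LL, delta_df))
    aic_c = aic_full + delta_minus2LL - 2.0 * delta_df
    return LRTResult(
        delta_minus2LL=float(delta_minus2LL),
        delta_df=int(delta_df),
        p_value=p,
        aic_full=float(aic_full),
        aic_constrained=float(aic_c),
        delta_aic=float(delta_minus2LL - 2.0 * delta_df),
    )


def lrt(full: FitResult, constrained: FitResult) -> LRTResult:
    """Likelihood-ratio test of a constrained model against the nesting full model."""
    if not (full.converged and constrained.converged):
        raise ModelError("both fits must have converged for a likelihood-ratio test")
    full_fixed = set(full.fixed_mask)
    con_fixed = set(constrained.fixed_mask)
    if not full_fixed <= con_fixed:
        raise ModelError("models are not nested: constrained fit frees parameters "
                         f"{sorted(full_fixed - con_fixed)} that the full fit fixes")
    for name in full_fixed:
        if constrained.fixed_mask[name] != full.fixed_mask[name]:
            raise ModelError(f"models fix {name!r} at different values; not nested")
    delta_df = full.n_free - constrained.n_free
    if delta_df < 1:
        raise ModelError("constrained model is not a strict restriction of the full model")
    delta = constrained.minus2LL - full.minus2LL
    if delta < -_NEG_TOL:
        raise ModelError(
            f"constrained -2LL is {-delta:.6g} below the full model's: "
            "optimization failure in the full model"
        )
    return lrt_from_stats(max(delta, 0.0), delta_df, full.aic)


def nested_suite(
    data,
    models: Mapping[str, Mapping[str, float]] | None = None,
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit the full model and its nested restrictions; report the comparison.

    Constrained fits start from the full-model solution, guaranteeing a
    non-negative likelihood-ratio statistic.  Returns the comparison table
    (one row per model, best-AIC row flagged) and the fits themselves.
    A non-converged member is flagged in its row, never dropped.
    """
    models = dict(models if models is not None else NESTED_MODELS)
    options = options or FitOptions()
    full = fit_model(data, options=options)
    fits = {"full": full}
    rows = [
        {
            "model": "1: full model", "constraints": "",
            "delta_minus2LL": np.nan, "delta_df": np.nan,
            "aic": full.aic, "delta_aic": np.nan, "p": np.nan,
            "converged": full.converged, "best_aic": False,
        }
    ]
    con_options = FitOptions(
        **{**options.__dict__, "start": full.estimates, "n_starts": 1}
    )
    for label, constraints in models.items():
        fit = fit_model(data, constraints=constraints, options=con_options)
        fits[label] = fit
        row = {
            "model": label,
            "constraints": ",".join(f"{k}={v:g}" for k, v in constraints.items()),
            "aic": fit.aic, "converged": fit.converged and full.converged,
            "best_aic": False,
        }
        if fit.converged and full.converged:
            res = lrt(full, fit)
            row.update(
                delta_minus2LL=res.delta_minus2LL, delta_df=res.delta_df,
                delta_aic=res.delta_aic, p=res.p_value,
            )
        else:
            row.update(delta_minus2LL=np.nan, delta_df=np.nan, delta_aic=np.nan, p=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["converged"]
    if ok.any():
        table.loc[table.loc[ok, "aic"].idxmin(), "best_aic"] = True
    return table, fits
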