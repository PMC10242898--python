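"""FIML engine: likelihood contract, missingness, optimization, intervals."""

import math

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

from cotfam import (
    FamilyRecord,
    FamilyStructure,
    FimlProblem,
    FitOptions,
    ModelError,
    ParameterSet,
    family_loglik,
    fit_model,
    frame_from_records,
    implied_moments,
    records_from_frame,
)
from cotfam.fiml import _MEAN_PARAMS, PARAM_NAMES, profile_interval


def _complete_record(theta_star, seed=0):
    st = FamilyStructure(
        sibling_link="DZ",
        linking_roles=("MOTHER", "FATHER"),
        n_children=(2, 1),
        child_sexes=(("GIRL", "BOY"), ("GIRL",)),
        child_parities=((0, 1), (2,)),
    )
    rng = np.random.default_rng(seed)
    mom = implied_moments(theta_star, st)
    y = rng.multivariate_normal(mom.mean, mom.cov)
    return FamilyRecord(st, tuple(y)), mom


def test_complete_record_equals_full_gaussian_density(theta_star):
    rec, mom = _complete_record(theta_star)
    direct = multivariate_normal(mom.mean, mom.cov).logpdf(np.array(rec.values))
    assert family_loglik(theta_star, rec) == pytest.approx(direct, rel=1e-12)


def test_adult_only_record_marginalizes_child_block(theta_star):
    """A record with only adult indicators is the 8-variable marginal and
    cannot depend on the transmission paths."""
    rec, mom = _complete_record(theta_star)
    adults_only = FamilyRecord(rec.structure, rec.values[:8] + (None,) * 3)
    direct = multivariate_normal(mom.mean[:8], mom.cov[:8, :8]).logpdf(
        np.array(adults_only.values[:8])
    )
    ll = family_loglik(theta_star, adults_only)
    assert ll == pytest.approx(direct, rel=1e-12)
    bent = theta_star.replace(p_m=0.9, p_f=-0.5, g=0.7)
    assert family_loglik(bent, adults_only) == pytest.approx(ll, rel=1e-12)


def test_all_missing_record_contributes_zero(theta_star, caplog):
    rec, _ = _complete_record(theta_star)
    empty = FamilyRecord(rec.structure, (None,) * 11)
    assert family_loglik(theta_star, empty) == 0.0


def test_grouped_paths_match_per_record_oracle(theta_star, small_table):
    """Pattern-grouped total (numpy and compiled) equals a brute-force
    per-record density summation."""
    problem = FimlProblem(small_table)
    records = records_from_frame(small_table)
    oracle = 0.0
    for rec in records:
        y = np.array([np.nan if v is None else v for v in rec.values])
        obs = ~np.isnan(y)
        if not obs.any():
            continue
        mom = implied_moments(theta_star, rec.structure)
        oracle += multivariate_normal(
            mom.mean[obs], mom.cov[np.ix_(obs, obs)]
        ).logpdf(y[obs])
    grouped = problem.minus2ll_params(theta_star)
    assert grouped == pytest.approx(-2.0 * oracle, rel=1e-8)
    kernel, _ = problem._eval(theta_star, problem._empty_design)
    assert kernel == pytest.approx(grouped, rel=1e-10)
    assert problem.reference_minus2ll(theta_star) == pytest.approx(grouped, rel=1e-10)


def test_profiled_kernel_matches_numpy_path(theta_star, small_problem):
    from cotfam.fiml import _disassemble

    x = _disassemble(theta_star, small_problem.free_cov_names)
    params0 = small_problem._assemble_zero_means(x)
    D = small_problem._mean_design()
    v_np, m_np = small_problem._eval_numpy(params0, D)
    v_k, m_k = small_problem._eval(params0, D)
    assert v_k == pytest.approx(v_np, rel=1e-10)
    assert np.allclose(m_k, m_np, atol=1e-8)


def test_likelihood_invariant_to_record_order(theta_star, small_table):
    shuffled = small_table.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = FimlProblem(small_table).minus2ll_params(theta_star)
    b = FimlProblem(shuffled).minus2ll_params(theta_star)
    assert a == pytest.approx(b, rel=1e-12)


def test_all_missing_family_leaves_m2ll_unchanged(theta_star, small_table):
    base = FimlProblem(small_table).minus2ll_params(theta_star)
    st = FamilyStructure(sibling_link="MZ", n_children=(0, 0))
    empty = FamilyRecord(st, (None,) * 8)
    extra = frame_from_records([empty])
    import pandas as pd

    widened = pd.concat([small_table, extra], ignore_index=True)
    prob = FimlProblem(widened)
    assert prob.n_all_missing == 1
    assert prob.minus2ll_params(theta_star) == pytest.approx(base, rel=1e-12)


def test_constrained_fit_never_beats_nesting_model(small_table):
    opts = FitOptions(n_starts=1, compute_ci=False)
    full = fit_model(small_table, options=opts)
    con_opts = FitOptions(n_starts=1, compute_ci=False, start=full.estimates)
    for constraints in ({"g": 0.0}, {"p_m": 0.0}, {"rho_A": 0.0, "rho_E": 0.0}):
        con = fit_model(small_table, constraints=constraints, options=con_opts)
        assert con.minus2LL >= full.minus2LL - 1e-4


def test_fixed_at_truth_is_degenerate_optimization(theta_star, small_table):
    """With every parameter constrained, -2LL equals the likelihood at truth."""
    constraints = {
        name: getattr(theta_star, name)
        for name in PARAM_NAMES
        if getattr(theta_star, name) is not None and name != "c"
    }
    fit = fit_model(small_table, constraints=constraints,
                    options=FitOptions(compute_ci=False))
    assert fit.n_free == 0
    assert fit.aic == fit.minus2LL
    expected = FimlProblem(small_table).minus2ll_params(theta_star)
    assert fit.minus2LL == pytest.approx(expected, rel=1e-10)


def test_unknown_constraint_rejected(small_table):
    with pytest.raises(ModelError, match="unknown parameter"):
        fit_model(small_table, constraints={"delta": 1.0})


def test_profile_interval_matches_wald_for_quadratic():
    """On an exactly quadratic -2LL the profile bound equals the Wald bound."""
    h = 7.3
    v0 = 0.42

    def nll2(v):
        return h * (v - v0) ** 2

    lo, hi = profile_interval(nll2, np.array([v0]), 0, level=0.95, se_hint=0.5)
    half = math.sqrt(chi2.ppf(0.95, 1) / h)
    assert lo == pytest.approx(v0 - half, abs=1e-6)
    assert hi == pytest.approx(v0 + half, abs=1e-6)


def test_wald_ci_respects_domain_for_bounded_parameters(theta_star, small_problem):
    """Mapped Wald intervals stay inside each parameter's domain even when
    the fit is very uncertain (variances positive, correlations in [-1,1])."""
    from cotfam.fiml import _disassemble, _wald_ci

    x = _disassemble(theta_star.replace(c_c=1e-2), small_problem.free_names)
    cov = np.eye(len(x)) * 100.0
    ci, se, flags = _wald_ci(small_problem, x, cov, 0.95)
    assert ci["c_c"][0] >= 0.0
    assert -1.0 <= ci["rho_A"][0] and ci["rho_A"][1] <= 1.0
    assert 0.0 <= ci["a"][0] and ci["a"][1] <= 1.0


def test_profile_ci_clips_variance_path_at_zero(theta_star, small_problem, monkeypatch):
    """A variance-like path whose profile bound crosses zero is clipped to
    the domain and flagged."""
    import cotfam.fiml as fm
    from cotfam.fiml import FitOptions, fit_model, param_ci

    fit = fit_model(
        small_problem,
        constraints={
            name: getattr(theta_star, name)
            for name in ("a", "rho_A", "rho_E", "lambda1", "lambda2", "theta1",
                         "theta2", "p_m", "p_f", "g", "a_c", "e_c")
        },
        options=FitOptions(n_starts=1, compute_ci=True),
    )
    monkeypatch.setattr(fm, "profile_interval", lambda *a, **k: (-0.2, 0.5))
    ci = param_ci(fit, method="profile", names=["c_c"])
    assert ci["c_c"][0] == 0.0
    assert "clipped" in fit.ci_flags["c_c"]


def test_ci_level_validated(small_table):
    from cotfam import param_ci

    fit = fit_model(small_table, options=FitOptions(n_starts=1, compute_ci=False))
    with pytest.raises(ModelError, match="confidence level"):
        param_ci(fit, level=1.5)


def test_profile_ci_contains_estimate_and_brackets_wald(small_table):
    """Profile intervals on a real fit contain the point estimate."""
    from cotfam import param_ci

    fit = fit_model(
        small_table,
        constraints={
            "rho_A": 0.372, "rho_E": 0.175, "g": 0.16, "p_f": 0.0,
            "lambda2": 1.0, "theta2": 0.8, "mu2": 1.5,
        },
        options=FitOptions(n_starts=1),
    )
    sub = {"p_m": fit.ci["p_m"]}
    ci = param_ci(fit, method="profile", names=["p_m"])
    lo, hi = ci["p_m"]
    assert lo < getattr(fit.estimates, "p_m") < hi
    # same order of magnitude as the Wald interval on a well-behaved parameter
    wlo, whi = sub["p_m"]
    assert abs((hi - lo) / (whi - wlo) - 1) < 0.5


def test_missing_covariate_with_observed_outcome_is_an_error(complete_table):
    broken = complete_table.copy()
    broken.loc[0, "c11_sex"] = np.nan
    with pytest.raises(ModelError, match="covariates missing"):
        FimlProblem(broken)


def test_fiml_agrees_between_complete_and_mcar_missing_data():
    """MCAR missingness shifts estimates only within sampling error."""
    from cotfam import SimulationConfig, simulate_table

    opts = FitOptions(n_starts=1, compute_ci=False)
    complete = simulate_table(
        SimulationConfig(seed=77, n_units=1500, family_response=1.0,
                         adult_item_missing=0.0)
    )
    fit_c = fit_model(complete, options=opts)
    missing = simulate_table(SimulationConfig(seed=77, n_units=1500))
    fit_m = fit_model(missing, options=opts)
    # tolerances ~2.5 SE of the estimate difference induced by dropping
    # 30% of outcome blocks and 5% of adult items
    for name, tol in (("a", 0.1), ("p_m", 0.25), ("lambda1", 0.1), ("mu_o", 0.1)):
        assert getattr(fit_m.estimates, name) == pytest.approx(
            getattr(fit_c.estimates, name), abs=tol
        )


def test_single_indicator_configuration(theta_star):
    """Dropping the second indicator and fixing its measurement parameters
    gives a working single-indicator model."""
    from cotfam import SimulationConfig, simulate_table

    df = simulate_table(SimulationConfig(seed=91, n_units=800))
    for col in ("s1_n2", "sp1_n2", "s2_n2", "sp2_n2"):
        df[col] = np.nan
    fit = fit_model(
        df,
        constraints={"lambda2": 1.0, "theta2": 1.0, "mu2": 0.0},
        options=FitOptions(n_starts=1, compute_ci=False),
    )
    assert fit.converged
    assert fit.n_free == 15
    assert 0.3 < fit.estimates.a < 0.95
    assert abs(fit.estimates.p_m - theta_star.p_m) < 0.25


def test_sex_specific_measurement_switch():
    """Freeing the father-specific intercept recovers a simulated sex
    difference in the measurement model."""
    from cotfam import SimulationConfig, default_parameters, simulate_table

    params = default_parameters().replace(mu1_f=3.6)
    df = simulate_table(SimulationConfig(seed=92, n_units=1500, params=params))
    fit = fit_model(
        df, free_extra=["mu1_f"], options=FitOptions(n_starts=1, compute_ci=False)
    )
    assert fit.converged
    assert fit.estimates.mu1_f == pytest.approx(3.6, abs=0.08)
    assert fit.estimates.mu1 == pytest.approx(3.0, abs=0.08)
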