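"""Random-intercept linear mixed models of phenometric timing.

Relates the estimated 10%/50% flight-period DOYs to accumulated growing
degree days (log scale) and life-history traits, with a species random
intercept:

    DOY_su = x_su' beta + alpha_s + eps_su,
    alpha_s ~ N(0, sigma_alpha^2),  eps_su ~ N(0, sigma_eps^2)

Fixed-effect selection is by AIC on ML fits; the winner's coefficients are
reported from a REML refit.  Variance explained is summarized by the
Nakagawa-Schielzeth marginal/conditional pseudo-R2 decomposition.

There is no global intercept by default: the overwinter-stage factor
enters as five stage-level intercepts (egg, larva, pupa, adult, migrant),
so each stage's coefficient is directly the expected DOY at log(GDD) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .types import LmmFit

DEFAULT_FIXED = "0 + C(overwinter_class) + log_gdd"


class SingularDesignError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FormulaSpec:
    """One candidate model: fixed-effect RHS plus random structure."""

    name: str
    fixed: str = DEFAULT_FIXED
    re_formula: str = "1"  # species random intercept
    vc_formula: dict | None = None  # extra variance components, by label


def build_model_frame(paired: pd.DataFrame, gdd_table: pd.DataFrame,
                      traits: pd.DataFrame, percentile: int,
                      source: str) -> pd.DataFrame:
    """Assemble the regression frame for one percentile and one stream.

    ``paired`` holds only units with phenometrics from BOTH streams (see
    :func:`flightwatch.compare.match_paired_units`); the response ``doy``
    is taken from the requested stream.  log_gdd is the natural log of the
    cell-year GDD (a unit with gdd <= 0 raises).  Rows with incomplete
    trait data are dropped and the count recorded in ``frame.attrs``.
    """
    sub = paired[paired["percentile"] == percentile].copy()
    resp = {"survey": "doy_survey", "incidental": "doy_incidental"}[source]
    sub["doy"] = sub[resp]
    sub = sub.merge(gdd_table[["cell_id", "year", "gdd"]],
                    on=["cell_id", "year"], how="left")
    if (sub["gdd"] <= 0).any() or sub["gdd"].isna().any():
        bad = sub.loc[(sub["gdd"].isna()) | (sub["gdd"] <= 0),
                      ["cell_id", "year"]].drop_duplicates()
        raise ValueError(f"nonpositive/missing GDD for units: "
                         f"{bad.to_dict('records')}")
    sub["log_gdd"] = np.log(sub["gdd"])

    trait_cols = ["species_id", "overwinter_class", "voltinism",
                  "host_breadth", "locally_common", "wing_size", "mobility",
                  "canopy_assoc", "egg_cluster", "detectability",
                  "confusability"]
    sub = sub.merge(traits[trait_cols], on="species_id", how="left")
    n_before = len(sub)
    frame = sub.dropna(subset=trait_cols[1:]).reset_index(drop=True)
    frame.attrs["n_dropped_incomplete_traits"] = n_before - len(frame)
    frame.attrs["percentile"] = percentile
    frame.attrs["source"] = source
    return frame


def _check_design(frame: pd.DataFrame, fixed: str) -> None:
    import patsy
    X = patsy.dmatrix(fixed, frame, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # crude collinearity diagnosis: columns whose removal restores rank
        bad = []
        for col in X.columns:
            Xr = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(Xr) == rank:
                bad.append(col)
        raise SingularDesignError(
            f"singular fixed-effect design; collinear columns: {bad}")


def fit_random_intercept_lmm(frame: pd.DataFrame,
                             formula_spec: FormulaSpec | str | None = None,
                             method: str = "REML") -> LmmFit:
    """Fit one candidate mixed model; AIC is always on the ML likelihood.

    ``method`` in {"ML", "REML"}.  Requires >= 2 species.  A constant
    response is handled as the degenerate exact fit (all slopes 0,
    sigma2_resid = 0).
    """
    if isinstance(formula_spec, str) or formula_spec is None:
        formula_spec = FormulaSpec(name="model",
                                   fixed=formula_spec or DEFAULT_FIXED)
    if frame["species_id"].nunique() < 2:
        raise ValueError("need >= 2 species for a species random intercept")
    if method not in ("ML", "REML"):
        raise ValueError("method must be ML or REML")
    _check_design(frame, formula_spec.fixed)

    if frame["doy"].nunique() == 1:
        return _constant_response_fit(frame, formula_spec, method)

    def _fit(reml: bool):
        model = smf.mixedlm(f"doy ~ {formula_spec.fixed}", data=frame,
                            groups="species_id", missing="drop",
                            re_formula=formula_spec.re_formula,
                            vc_formula=formula_spec.vc_formula)
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for opt in ("bfgs", "powell", "nm"):
                try:
                    res = model.fit(reml=reml, method=opt, maxiter=2000)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    return res
        raise ConvergenceError(
            f"mixed-model optimizer failed for {formula_spec.name}")

    res = _fit(reml=(method == "REML"))
    res_ml = res if method == "ML" else _fit(reml=False)
    if not (res.converged and res_ml.converged):
        raise ConvergenceError(
            f"mixed-model optimizer failed to converge for "
            f"{formula_spec.name}: {res.summary() if res else 'n/a'}")

    fe = res.fe_params
    k_fixed = len(fe)
    n_obs = int(res.nobs)
    n_groups = frame["species_id"].nunique()
    df_approx = max(n_obs - k_fixed - n_groups, 1)
    tvals = fe / res.bse_fe
    pvals = 2 * stats.t.sf(np.abs(tvals), df_approx)

    sigma2_species = float(res.cov_re.iloc[0, 0]) if res.k_re else 0.0
    vc = {}
    if formula_spec.vc_formula:
        for name in formula_spec.vc_formula:
            try:
                vc[name] = float(res.vcomp[
                    list(formula_spec.vc_formula).index(name)])
            except Exception:
                vc[name] = float("nan")

    n_var_params = res.k_re2 + res.k_vc + 1  # re cov + vcomps + residual
    k_total = k_fixed + n_var_params
    aic = float(-2 * res_ml.llf + 2 * k_total)

    fit = LmmFit(
        formula=f"doy ~ {formula_spec.fixed} | re={formula_spec.re_formula}"
                + (f" vc={list(formula_spec.vc_formula)}"
                   if formula_spec.vc_formula else ""),
        method=method,
        params=dict(fe), bse=dict(res.bse_fe),
        pvalues=dict(zip(fe.index, pvals)),
        sigma2_species=sigma2_species,
        sigma2_resid=float(res.scale),
        vc_components=vc,
        loglik=float(res.llf), aic=aic, n_obs=n_obs, n_species=n_groups,
        n_params=k_total, converged=True, result=res,
    )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, frame)
    return fit


def _constant_response_fit(frame, formula_spec, method) -> LmmFit:
    val = float(frame["doy"].iloc[0])
    import patsy
    X = patsy.dmatrix(formula_spec.fixed, frame, return_type="dataframe")
    params = {c: 0.0 for c in X.columns}
    # intercept-like columns (stage dummies) absorb the constant
    for c in X.columns:
        if set(np.unique(X[c])) <= {0.0, 1.0}:
            params[c] = val
    return LmmFit(formula=f"doy ~ {formula_spec.fixed}", method=method,
                  params=params, bse={c: 0.0 for c in X.columns},
                  pvalues={c: float("nan") for c in X.columns},
                  sigma2_species=0.0, sigma2_resid=0.0, loglik=float("inf"),
                  aic=-float("inf"), n_obs=len(frame),
                  n_species=frame["species_id"].nunique(),
                  n_params=len(params) + 1, r2_marginal=float("nan"),
                  r2_conditional=float("nan"))


def nakagawa_r2_from_components(var_fixed: float, var_random: float,
                                var_resid: float) -> tuple[float, float]:
    """Marginal/conditional pseudo-R2 from variance components:
    marginal = s2_f / (s2_f + s2_a + s2_e); conditional adds s2_a to the
    numerator."""
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("zero total variance")
    return var_fixed / total, (var_fixed + var_random) / total


def nakagawa_r2(fit: LmmFit, frame: pd.DataFrame) -> tuple[float, float]:
    """Nakagawa-Schielzeth pseudo-R2 for a Gaussian identity-link fit.

    The fixed-effect variance is the population variance of the fixed
    linear predictor over the frame; all random components (species
    intercept plus any extra variance components) count toward the
    conditional numerator.
    """
    import patsy
    rhs = fit.formula.split("~", 1)[1].split("|", 1)[0].strip()
    X = patsy.dmatrix(rhs, frame, return_type="dataframe")
    beta = np.array([fit.params[c] for c in X.columns])
    pred = X.to_numpy() @ beta
    var_fixed = float(np.var(pred))
    var_random = fit.sigma2_species + sum(
        v for v in fit.vc_components.values() if np.isfinite(v))
    return nakagawa_r2_from_components(var_fixed, var_random,
                                       fit.sigma2_resid)


def select_by_aic(frame: pd.DataFrame, candidates: list[FormulaSpec]
                  ) -> tuple[LmmFit, pd.DataFrame]:
    """Fit every candidate by ML on identical rows and return the AIC
    winner (ties go to fewer parameters) refit by REML, plus the AIC
    table."""
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    fits = []
    for spec in candidates:
        fit = fit_random_intercept_lmm(frame, spec, method="ML")
        fits.append((spec, fit))
    n_rows = {f.n_obs for _, f in fits}
    if len(n_rows) > 1:
        raise ValueError(f"candidates fit on differing row sets: {n_rows}")
    table = pd.DataFrame([{
        "name": s.name, "fixed": s.fixed,
        "re_formula": s.re_formula,
        "vc": ",".join(s.vc_formula) if s.vc_formula else "",
        "n_params": f.n_params, "loglik_ml": f.loglik, "aic": f.aic,
    } for s, f in fits]).sort_values(
        ["aic", "n_params"]).reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best_spec = min(fits, key=lambda sf: (sf[1].aic, sf[1].n_params))[0]
    best = fit_random_intercept_lmm(frame, best_spec, method="REML")
    return best, table


def coefficients_table(fit: LmmFit) -> pd.DataFrame:
    """Coefficient layout: Estimate, SE, p value (+ R2 footer rows)."""
    rows = [{"parameter": k, "estimate": fit.params[k],
             "se": fit.bse.get(k, float("nan")),
             "p_value": fit.pvalues.get(k, float("nan"))}
            for k in fit.params]
    rows.append({"parameter": "Marginal R2", "estimate": fit.r2_marginal,
                 "se": float("nan"), "p_value": float("nan")})
    rows.append({"parameter": "Conditional R2",
                 "estimate": fit.r2_conditional,
                 "se": float("nan"), "p_value": float("nan")})
    return pd.DataFrame(rows)
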