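"""Multilevel cross-lagged coupled linear oscillator models of aggression.

The aggressor's next blast is regressed on six kinematic predictors — their
own preceding level, velocity and acceleration, and their target's — with
random intercepts for the dyad and for the individual nested within the dyad.
Fitting is by restricted maximum likelihood; p-values are large-sample Wald
tests.  A pooled ordinary-least-squares variant with cluster-robust standard
errors (clustered on dyad) is available for sensitivity analysis.

Variance explained is partitioned the standard way for mixed models:
marginal R^2 is the fixed-effects share of the total (fixed + dyad +
individual + residual) variance; conditional R^2 adds the random-intercept
variances to the numerator.

The gender-moderated variant restricts the table to woman aggressors and
interacts every predictor (and the intercept) with an indicator for a man
target; the woman-woman pair is the reference, so each interaction estimate
is the woman-man *difference* and a woman-man prediction is reference plus
difference, term by term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .features import PREDICTORS

__all__ = [
    "OscillatorFit",
    "ModeratedFit",
    "DegenerateFitError",
    "GENERAL_MODEL_ESTIMATES",
    "WOMAN_AGGRESSOR_REFERENCE",
    "WOMAN_AGGRESSOR_MAN_TARGET_DELTA",
    "linear_predict",
    "moderated_predict",
    "fit_general",
    "fit_moderated",
    "standardize",
    "r2_decomposition",
    "predict",
]

#: Fixed-effect estimates of the general model as reported for the original
#: study of couples and friends (blast units; aggressor level carried no
#: reported weight).  Used for worked examples and as simulator defaults.
GENERAL_MODEL_ESTIMATES: dict[str, float] = {
    "intercept": 2.00,
    "tgt_level": 0.44,
    "agg_velocity": 1.03,
    "agg_acceleration": -0.36,
    "tgt_velocity": -0.35,
    "tgt_acceleration": 0.11,
}

#: Woman-aggressor model, woman-woman reference estimates (same study).
WOMAN_AGGRESSOR_REFERENCE: dict[str, float] = {
    "intercept": 1.28,
    "tgt_level": 0.49,
    "agg_velocity": 1.03,
    "agg_acceleration": -0.36,
    "tgt_velocity": -0.51,
    "tgt_acceleration": 0.19,
}

#: Woman-man differences for the same model (terms without a reported
#: difference contribute zero to a woman-man prediction).
WOMAN_AGGRESSOR_MAN_TARGET_DELTA: dict[str, float] = {
    "intercept": 1.55,
    "agg_velocity": 0.03,
    "tgt_velocity": 0.30,
}


class DegenerateFitError(ValueError):
    """Raised when the design is singular (e.g. a constant predictor)."""


@dataclass(frozen=True)
class OscillatorFit:
    """Fitted coupled-oscillator model.

    ``coefficients`` maps ``"intercept"`` and each predictor to its fixed
    effect B (blast units per unit predictor); ``standardized_betas`` holds
    B * sd(x)/sd(y); ``variance_components`` the dyad, individual and
    residual variances.
    """

    coefficients: dict[str, float]
    standardized_betas: dict[str, float]
    p_values: dict[str, float]
    variance_components: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    n_rows: int
    n_dyads: int
    n_individuals: int
    method: str = "mixed"
    predictors: tuple[str, ...] = tuple(PREDICTORS)
    random_effects: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "standardized_betas": dict(self.standardized_betas),
            "p_values": dict(self.p_values),
            "variance_components": dict(self.variance_components),
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_rows": self.n_rows,
            "n_dyads": self.n_dyads,
            "n_individuals": self.n_individuals,
            "method": self.method,
        }


@dataclass(frozen=True)
class ModeratedFit:
    """Gender-moderated woman-aggressor model.

    ``reference`` are the woman-woman estimates; ``man_target_delta`` the
    additive woman-man differences, per term.  A woman-man prediction is
    the reference prediction plus the delta prediction.
    """

    base: OscillatorFit
    reference: dict[str, float]
    man_target_delta: dict[str, float]
    delta_p_values: dict[str, float]

    def predict(self, features: Mapping[str, float], target_is_man: bool) -> float:
        return moderated_predict(self.reference, self.man_target_delta, features, target_is_man)

    def to_dict(self) -> dict:
        out = self.base.to_dict()
        out["reference"] = dict(self.reference)
        out["man_target_delta"] = dict(self.man_target_delta)
        out["delta_p_values"] = dict(self.delta_p_values)
        return out


def linear_predict(coefficients: Mapping[str, float], features: Mapping[str, float]) -> float:
    """Evaluate a fixed-effects linear predictor at a feature vector.

    Features absent from the coefficient map (and vice versa) contribute
    zero, so worked examples can be stated sparsely.
    """
    eta = float(coefficients.get("intercept", 0.0))
    for name, value in features.items():
        if name == "intercept":
            raise ValueError("'intercept' is not a feature; it is implied")
        eta += float(coefficients.get(name, 0.0)) * float(value)
    return eta


def moderated_predict(
    reference: Mapping[str, float],
    man_target_delta: Mapping[str, float],
    features: Mapping[str, float],
    target_is_man: bool,
) -> float:
    """Additive reference-plus-difference prediction of the moderated model."""
    eta = linear_predict(reference, features)
    if target_is_man:
        eta += linear_predict(man_target_delta, features)
    return eta


def _validate_rows(rows: pd.DataFrame, predictors: list[str]) -> None:
    needed = ["outcome_blast", "dyad_id", "aggressor_id", *predictors]
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise ValueError(f"modelling table lacks columns: {missing}")
    if rows[needed].isna().any().any():
        raise ValueError("modelling table contains missing values")
    if rows["dyad_id"].nunique() < 2:
        raise ValueError("need at least 2 dyads to fit the multilevel model")
    for name in predictors:
        if float(np.std(rows[name].to_numpy(dtype=float))) == 0.0:
            raise DegenerateFitError(f"predictor {name!r} is constant; the design is singular")


def _nakagawa_r2(
    fixed_pred: np.ndarray, var_dyad: float, var_indiv: float, var_resid: float
) -> tuple[float, float]:
    var_fixed = float(np.var(fixed_pred))
    total = var_fixed + var_dyad + var_indiv + var_resid
    if total <= 0:
        raise ValueError("total variance is zero; R^2 decomposition undefined")
    return var_fixed / total, (var_fixed + var_dyad + var_indiv) / total


def fit_general(
    rows: pd.DataFrame,
    method: str = "mixed",
    predictors: list[str] | None = None,
) -> OscillatorFit:
    """Fit the general coupled-oscillator model to a modelling table.

    ``method="mixed"`` (default) fits random intercepts for dyad and for
    individual-within-dyad by REML; ``method="pooled"`` fits OLS with
    dyad-clustered robust standard errors.
    """
    predictors = list(PREDICTORS) if predictors is None else list(predictors)
    _validate_rows(rows, predictors)
    rows = rows.reset_index(drop=True)
    y = rows["outcome_blast"].to_numpy(dtype=float)
    X = sm.add_constant(rows[predictors].to_numpy(dtype=float), has_constant="add")
    names = ["intercept", *predictors]

    if method == "pooled":
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": rows["dyad_id"]})
        coef = dict(zip(names, (float(b) for b in res.params)))
        pvals = dict(zip(names, (float(p) for p in res.pvalues)))
        var_resid = float(np.var(y - res.fittedvalues))
        vcomp = {"dyad": 0.0, "individual": 0.0, "residual": var_resid}
        r2m, r2c = _nakagawa_r2(np.asarray(res.fittedvalues), 0.0, 0.0, var_resid)
        ranef: dict[str, float] = {}
    elif method == "mixed":
        X_named = pd.DataFrame(X, columns=names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                y,
                X_named,
                groups=rows["dyad_id"],
                exog_re=np.ones((len(rows), 1)),  # dyad random intercept
                exog_vc=_individual_vc(rows),
            )
            res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=500)
        coef = {n: float(res.fe_params.iloc[i]) for i, n in enumerate(names)}
        pvals = {n: float(res.pvalues.iloc[i]) for i, n in enumerate(names)}
        # cov_re and vcomp are already on the response scale in statsmodels
        var_dyad = float(res.cov_re.iloc[0, 0])
        var_indiv = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        var_resid = float(res.scale)
        vcomp = {"dyad": max(var_dyad, 0.0), "individual": max(var_indiv, 0.0), "residual": var_resid}
        fixed_pred = X @ res.fe_params
        r2m, r2c = _nakagawa_r2(fixed_pred, vcomp["dyad"], vcomp["individual"], var_resid)
        ranef = {str(k): float(np.atleast_1d(v)[0]) for k, v in res.random_effects.items()}
    else:
        raise ValueError(f"unknown method {method!r}; use 'mixed' or 'pooled'")

    betas = _standardized_betas(coef, rows, predictors)
    return OscillatorFit(
        coefficients=coef,
        standardized_betas=betas,
        p_values=pvals,
        variance_components=vcomp,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_rows=len(rows),
        n_dyads=int(rows["dyad_id"].nunique()),
        n_individuals=int(rows["aggressor_id"].nunique()),
        method=method,
        predictors=tuple(predictors),
        random_effects=ranef,
    )


def _individual_vc(rows: pd.DataFrame) -> dict:
    """Variance-component design: one indicator column per individual,
    evaluated within each dyad (individual nested in dyad)."""
    vc: dict[str, dict[str, np.ndarray]] = {"individual": {}}
    for dyad, sub in rows.groupby("dyad_id", sort=True):
        dummies = pd.get_dummies(sub["aggressor_id"]).to_numpy(dtype=float)
        vc["individual"][dyad] = dummies
    return vc


def _standardized_betas(
    coefficients: Mapping[str, float], rows: pd.DataFrame, predictors: list[str]
) -> dict[str, float]:
    sd_y = float(rows["outcome_blast"].astype(float).std(ddof=1))
    betas: dict[str, float] = {}
    for name in predictors:
        sd_x = float(rows[name].astype(float).std(ddof=1))
        if sd_x == 0.0:
            raise DegenerateFitError(f"predictor {name!r} has zero variance; beta undefined")
        betas[name] = float(coefficients[name]) * sd_x / sd_y
    return betas


def standardize(fit: OscillatorFit, rows: pd.DataFrame) -> dict[str, float]:
    """Standardised betas B * sd(x)/sd(y) from the fit's source table."""
    return _standardized_betas(fit.coefficients, rows, list(fit.predictors))


def r2_decomposition(fit: OscillatorFit) -> tuple[float, float]:
    """(marginal, conditional) R^2 of a fitted model."""
    return fit.r2_marginal, fit.r2_conditional


def predict(
    fit: OscillatorFit,
    features: Mapping[str, float],
    group: str | None = None,
) -> float:
    """Population-level prediction; add a dyad's random intercept if asked."""
    eta = linear_predict(fit.coefficients, features)
    if group is not None:
        if group not in fit.random_effects:
            raise KeyError(f"unknown group {group!r}; conditional prediction unavailable")
        eta += float(fit.random_effects[group])
    return eta


def fit_moderated(rows: pd.DataFrame, method: str = "mixed") -> ModeratedFit:
    """Fit the woman-aggressor model with target gender as moderator.

    Rows are restricted to woman aggressors; the reference level is a woman
    target and each interaction coefficient is the woman-man difference.
    """
    rows = rows[rows["aggressor_gender"] == "woman"].reset_index(drop=True)
    genders = set(rows["target_gender"].unique()) if len(rows) else set()
    if genders != {"man", "woman"}:
        raise ValueError(
            "moderated fit needs woman-aggressor rows with both target genders; "
            f"found target genders {sorted(genders)}"
        )
    rows = rows.copy()
    rows["tgt_is_man"] = (rows["target_gender"] == "man").astype(float)
    inter_names = [f"{p}:man" for p in PREDICTORS]
    for p, nm in zip(PREDICTORS, inter_names):
        rows[nm] = rows[p] * rows["tgt_is_man"]
    all_predictors = [*PREDICTORS, "tgt_is_man", *inter_names]
    base = fit_general(rows, method=method, predictors=all_predictors)

    reference = {"intercept": base.coefficients["intercept"]}
    delta = {"intercept": base.coefficients["tgt_is_man"]}
    delta_p = {"intercept": base.p_values["tgt_is_man"]}
    for p, nm in zip(PREDICTORS, inter_names):
        reference[p] = base.coefficients[p]
        delta[p] = base.coefficients[nm]
        delta_p[p] = base.p_values[nm]
    return ModeratedFit(base=base, reference=reference, man_target_delta=delta, delta_p_values=delta_p)
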