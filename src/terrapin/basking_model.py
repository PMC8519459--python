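"""Daily basking-occurrence model: binomial regression with backward AIC.

The response is whether a Midday (basking) phase occurred on a given
individual-day; candidate predictors are daily mean air temperature, daily
mean cloud cover, daily rainfall sum and day length, each centred and
reduced (mean 0, variance 1) before fitting.  Individual identity enters as
fixed per-individual intercepts, a deterministic approximation of a
random-intercept GLMM.  Backward elimination retains the most parsimonious
model by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_TERMS = ("t_air", "cloud", "rain", "day_length")


class StandardizationError(ValueError):
    """A predictor is constant: it cannot be centred and reduced."""


class SeparationError(RuntimeError):
    """A term perfectly separates the response classes."""


@dataclass
class ModelFit:
    """A fitted binomial model: retained terms, coefficients and fit stats.

    ``params``/``se``/``z`` are dicts keyed by design-column name (terms and
    intercept columns).  AIC = 2k - 2 logLik.
    """

    terms: tuple
    params: dict
    se: dict
    z: dict
    aic: float
    llf: float
    n: int
    n_params: int
    individual_intercepts: bool = True
    columns: tuple = field(default_factory=tuple)


def standardize(x) -> np.ndarray:
    """Centre to mean 0 and reduce to unit variance (sample sd, n-1).

    Idempotent up to floating point; raises
    :class:`StandardizationError` on a constant column.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise StandardizationError("constant predictor cannot be reduced")
    return (x - np.mean(x)) / sd


def build_design(budgets: pd.DataFrame, daily_weather: pd.DataFrame,
                 terms=DEFAULT_TERMS) -> pd.DataFrame:
    """One row per individual-day with the standardized predictors.

    ``budgets`` must carry ``individual``, ``cycle_date`` and ``midday_h``;
    ``daily_weather`` has one row per day with columns ``day`` plus the raw
    predictors (``t_air`` mean, ``cloud`` mean of the 3-h fractions,
    ``rain`` daily sum in mm, ``day_length`` hours).  The response is
    Midday presence (1/0).
    """
    design = budgets.merge(daily_weather, left_on="cycle_date",
                           right_on="day", how="inner")
    out = pd.DataFrame({
        "individual": design["individual"].astype(str),
        "day": design["cycle_date"].astype(int),
        "response": (design["midday_h"].fillna(0) > 0).astype(int),
    })
    for term in terms:
        out[term] = standardize(design[term])
    return out.reset_index(drop=True)


def aggregate_weather_daily(weather: pd.DataFrame,
                            sun: pd.DataFrame,
                            reference: pd.DataFrame | None = None
                            ) -> pd.DataFrame:
    """Daily covariates from the 3-h weather series and the sun table.

    Cloud cover is the daily mean of the 3-h fractions, rainfall the daily
    sum; temperature is the daily mean of the field air series when a
    reference frame is given, else of the airport series; day length comes
    from sunrise/sunset.
    """
    w = weather.copy()
    w["day"] = np.floor(w["time"] / 86400.0).astype(int)
    daily = w.groupby("day").agg(
        cloud=("cloud_frac", "mean"),
        rain=("rain_mm", "sum"),
        t_air=("t_air_mulhouse", "mean"),
    ).reset_index()
    if reference is not None:
        r = reference.copy()
        r["day"] = np.floor(r["time"] / 86400.0).astype(int)
        t_field = r.groupby("day")["t_air"].mean().rename("t_air_field")
        daily = daily.merge(t_field, on="day", how="left")
        daily["t_air"] = daily["t_air_field"].fillna(daily["t_air"])
        daily = daily.drop(columns=["t_air_field"])
    s = sun.copy()
    s["day_length"] = (s["sunset"] - s["sunrise"]) / 3600.0
    s["day"] = pd.to_numeric(s["date"], errors="coerce")
    if s["day"].isna().any():  # ISO dates: use day offset from first date
        d = pd.to_datetime(sun["date"])
        s["day"] = (d - d.min()).dt.days
    daily = daily.merge(s[["day", "day_length"]], on="day", how="left")
    return daily


def _design_matrix(design: pd.DataFrame, terms,
                   individual_intercepts: bool = True):
    y = design["response"].to_numpy(dtype=float)
    cols, names = [], []
    individuals = sorted(design["individual"].astype(str).unique())
    if individual_intercepts and len(individuals) > 1:
        for ind in individuals:
            cols.append((design["individual"].astype(str) == ind)
                        .to_numpy(dtype=float))
            names.append(f"intercept[{ind}]")
    else:
        cols.append(np.ones(len(design)))
        names.append("intercept")
    for term in terms:
        cols.append(design[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    return y, X, names


def _check_separation(design: pd.DataFrame, terms):
    y = design["response"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise SeparationError("response has a single class")
    for term in terms:
        x = design[term].to_numpy(dtype=float)
        if x[y == 1].min() > x[y == 0].max() or \
                x[y == 0].min() > x[y == 1].max():
            raise SeparationError(f"term {term!r} perfectly separates the "
                                  "response")


def fit_binomial(design: pd.DataFrame, terms,
                 individual_intercepts: bool = True) -> ModelFit:
    """Logistic regression of Midday presence on the given terms.

    Fitted by iteratively reweighted least squares (binomial GLM) with
    fixed per-individual intercepts when several individuals are present.
    Raises :class:`SeparationError` naming the separating term when a
    predictor splits the classes perfectly, and ``RuntimeError`` on
    non-convergence.
    """
    terms = tuple(terms)
    _check_separation(design, terms)
    y, X, names = _design_matrix(design, terms, individual_intercepts)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-8
        )
    except PerfectSeparationError as exc:  # pragma: no cover - guarded above
        raise SeparationError(str(exc)) from exc
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations (deviance trace tail: "
            f"{getattr(res, 'fit_history', {}).get('deviance', [])[-3:]})"
        )
    if np.max(np.abs(res.params)) > 50:
        raise SeparationError(
            "diverging coefficients indicate quasi-separation"
        )
    params = dict(zip(names, map(float, res.params)))
    se = dict(zip(names, map(float, res.bse)))
    z = {k: params[k] / se[k] if se[k] > 0 else np.nan for k in names}
    return ModelFit(
        terms=terms, params=params, se=se, z=z,
        aic=float(res.aic), llf=float(res.llf), n=len(y),
        n_params=X.shape[1],
        individual_intercepts=individual_intercepts and
        design["individual"].nunique() > 1,
        columns=tuple(names),
    )


def coefficient_table(fit: ModelFit) -> pd.DataFrame:
    """Tidy `term,estimate,se,z` table of a fitted model."""
    return pd.DataFrame({
        "term": list(fit.columns),
        "estimate": [fit.params[k] for k in fit.columns],
        "se": [fit.se[k] for k in fit.columns],
        "z": [fit.z[k] for k in fit.columns],
    })


def backward_aic(design: pd.DataFrame, full_terms=DEFAULT_TERMS,
                 individual_intercepts: bool = True):
    """Stepwise backward elimination by AIC.

    Starting from the full model, repeatedly drop the single term whose
    removal lowers AIC most (ties broken by term name order); stop when no
    removal lowers AIC.  Intercept columns are never dropped.  Returns
    ``(best_fit, steps)`` where steps is a list of (terms, aic) per
    elimination step.
    """
    terms = tuple(full_terms)
    current = fit_binomial(design, terms, individual_intercepts)
    steps = [(current.terms, current.aic)]
    while terms:
        candidates = []
        for drop in sorted(terms):
            reduced = tuple(x for x in terms if x != drop)
            fit = fit_binomial(design, reduced, individual_intercepts)
            candidates.append((fit.aic, drop, fit))
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, _, best_fit = candidates[0]
        if best_aic < current.aic:
            current = best_fit
            terms = current.terms
            steps.append((current.terms, current.aic))
        else:
            break
    return current, steps
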