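"""Per-endpoint logistic outcome models on the conditioned twin cohort.

Three binary endpoints are modeled: complete recanalization (complete vs
not complete, fitted on records with follow-up imaging and extrapolated to
the whole cohort), thrombotic recurrence, and major bleeding.  Default
predictors are treatment arm, USVT site and active cancer; age, sex and a
binary good-VKA-control flag (TTR ≥ 70% by default) are optional toggles.

Site dummies carry a small ridge penalty by default: the CVT stratum is
tiny (two patients at source scale) and cannot support unpenalized
maximum-likelihood estimates.  With the penalty at zero the fit is exact
ML, and a treatment-only model reproduces the closed-form saturated
two-group logit.

Treatment-specific marginal risks use counterfactual standardization:
every record is scored once with treatment set to VKA and once to DOAC,
and the per-arm risk is the mean predicted probability.  Confidence
intervals are percentile bootstrap over records with model refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from usvtwin.cohort import Cohort

__all__ = [
    "ENDPOINTS",
    "OutcomeModel",
    "FixedRateModel",
    "MarginalRates",
    "fit_outcome_model",
    "predict_risk",
    "marginal_rates",
    "brier_score",
    "calibration_bins",
    "endpoint_values",
]

ENDPOINTS = ("recanalization_complete", "recurrence", "major_bleed")
DEFAULT_PREDICTORS = ("treatment", "usvt_site", "active_cancer")


def endpoint_values(df: pd.DataFrame, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """(observed mask, 0/1 outcome) for an endpoint column.

    ``recanalization_complete`` is coded complete=1 vs not-complete=0 and is
    observed only for records with follow-up imaging.
    """
    if endpoint == "recanalization_complete":
        observed = df["recanalization"].notna().to_numpy()
        y = (df["recanalization"] == "complete").to_numpy(dtype=float)
    elif endpoint in ("recurrence", "major_bleed", "death"):
        observed = df[endpoint].notna().to_numpy()
        y = df[endpoint].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return observed, y


def _design(
    df: pd.DataFrame, predictors: Sequence[str], ttr_threshold: float
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for p in predictors:
        if p == "treatment":
            cols["treatment_DOAC"] = (df["treatment"] == "DOAC").to_numpy(dtype=float)
        elif p == "usvt_site":
            cols["site_UEDVT"] = (df["usvt_site"] == "UEDVT").to_numpy(dtype=float)
            cols["site_CVT"] = (df["usvt_site"] == "CVT").to_numpy(dtype=float)
        elif p == "active_cancer":
            cols["active_cancer"] = df["active_cancer"].to_numpy(dtype=float)
        elif p == "age":
            cols["age"] = df["age"].to_numpy(dtype=float)
        elif p == "sex":
            cols["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
        elif p == "ttr_control":
            good = (df["treatment"] == "VKA") & (df["ttr"] >= ttr_threshold)
            cols["ttr_control"] = good.to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown predictor {p!r}")
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _penalty_vector(names: Sequence[str], site_ridge: float) -> np.ndarray:
    return np.array(
        [site_ridge if n.startswith("site_") else 0.0 for n in names]
    )


def _fit_logistic(
    x: np.ndarray, y: np.ndarray, penalty: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, bool, float, np.ndarray]:
    """Newton-Raphson for (optionally selectively ridge-penalized) logistic
    regression.  Returns (beta, converged, log-likelihood, covariance),
    the covariance being the inverse (penalized) observed information."""
    beta = np.zeros(x.shape[1])
    lam = np.diag(penalty)
    converged = False
    hess = np.eye(x.shape[1])
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - p) - penalty * beta
        w = p * (1.0 - p)
        hess = (x * w[:, None]).T @ x + lam
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = np.clip(x @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    loglik = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    try:
        cov = np.linalg.inv(hess + 1e-10 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
    return beta, converged, loglik, cov


@dataclass
class OutcomeModel:
    """Fitted logistic model for one endpoint."""

    endpoint: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    converged: bool
    loglik: float
    penalized: bool = False
    site_ridge: float = 0.0
    ttr_threshold: float = 70.0
    cov: np.ndarray | None = None

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Wald confidence intervals from the observed information."""
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        se = np.sqrt(np.diag(self.cov))
        return {
            name: (value - z * s, value + z * s)
            for (name, value), s in zip(self.coefficients.items(), se)
        }

    def predict_risk(self, records: pd.DataFrame) -> np.ndarray:
        x, names = _design(records, self.predictors, self.ttr_threshold)
        beta = np.array([self.coefficients[n] for n in names])
        eta = np.clip(x @ beta, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


class FixedRateModel:
    """Degenerate model holding per-arm probabilities fixed.

    Used for engine validation: feeding known per-arm rates through the
    Monte Carlo layers must reproduce them.
    """

    def __init__(self, endpoint: str, rates: Mapping[str, float]):
        self.endpoint = endpoint
        self.rates = dict(rates)

    def predict_risk(self, records: pd.DataFrame) -> np.ndarray:
        return records["treatment"].map(self.rates).to_numpy(dtype=float)


def fit_outcome_model(
    cohort: Cohort | pd.DataFrame,
    endpoint: str,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    site_ridge: float = 1.0,
    ttr_threshold: float = 70.0,
) -> OutcomeModel:
    """Maximum-likelihood (optionally site-ridge-penalized) logistic fit.

    Recanalization models use only records with follow-up imaging.  On
    separation (runaway coefficients) the fit retries with a global weak
    ridge and is flagged ``penalized``.  An endpoint with a single observed
    class is a degenerate-fit error.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    observed, y = endpoint_values(df, endpoint)
    rows = df.loc[observed]
    y = y[observed]
    if len(rows) == 0 or len(np.unique(y)) < 2:
        raise ValueError(f"degenerate endpoint {endpoint!r}: single observed class")
    x, names = _design(rows, predictors, ttr_threshold)
    penalty = _penalty_vector(names, site_ridge)
    beta, converged, loglik, cov = _fit_logistic(x, y, penalty)
    penalized = site_ridge > 0 and bool(penalty.any())
    if not converged or np.abs(beta).max() > 30:
        penalty = penalty + 1.0
        penalty[0] = 0.0
        beta, converged, loglik, cov = _fit_logistic(x, y, penalty)
        penalized = True
    return OutcomeModel(
        endpoint=endpoint,
        predictors=tuple(predictors),
        coefficients=dict(zip(names, beta)),
        converged=converged,
        loglik=loglik,
        penalized=penalized,
        site_ridge=site_ridge,
        ttr_threshold=ttr_threshold,
        cov=cov,
    )


def predict_risk(model, records: pd.DataFrame) -> np.ndarray:
    """Predicted event probability for each record (inverse-logit scale)."""
    return model.predict_risk(records)


@dataclass
class MarginalRates:
    """Counterfactually standardized per-arm risks, in percent."""

    endpoint: str
    vka: float
    vka_ci: tuple[float, float]
    doac: float
    doac_ci: tuple[float, float]

    @property
    def difference(self) -> float:
        """DOAC − VKA, percentage points."""
        return self.doac - self.vka


def _standardized_rates(model, df: pd.DataFrame) -> tuple[float, float]:
    rates = []
    for arm in ("VKA", "DOAC"):
        cf = df.copy()
        cf["treatment"] = arm
        rates.append(float(model.predict_risk(cf).mean()) * 100.0)
    return rates[0], rates[1]


def marginal_rates(
    model: OutcomeModel,
    cohort: Cohort | pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> MarginalRates:
    """Per-arm marginal risks with percentile-bootstrap CIs.

    Each bootstrap resample of the records refits the model (on its imaged
    subset for recanalization) and recomputes the standardized rates.
    """
    df = (cohort.df if isinstance(cohort, Cohort) else cohort).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty cohort")
    vka, doac = _standardized_rates(model, df)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = rng.integers(0, len(df), len(df))
        sample = df.iloc[idx].reset_index(drop=True)
        try:
            m = fit_outcome_model(
                sample,
                model.endpoint,
                model.predictors,
                model.site_ridge,
                model.ttr_threshold,
            )
        except ValueError:  # degenerate resample
            boots[i] = (np.nan, np.nan)
            continue
        boots[i] = _standardized_rates(m, sample)
    lo_v, hi_v = np.nanpercentile(boots[:, 0], [2.5, 97.5])
    lo_d, hi_d = np.nanpercentile(boots[:, 1], [2.5, 97.5])
    return MarginalRates(
        endpoint=model.endpoint,
        vka=vka,
        vka_ci=(float(lo_v), float(hi_v)),
        doac=doac,
        doac_ci=(float(lo_d), float(hi_d)),
    )


def brier_score(model, cohort: Cohort | pd.DataFrame) -> float:
    """Mean squared difference between predicted probability and outcome."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    observed, y = endpoint_values(df, model.endpoint)
    rows = df.loc[observed]
    p = model.predict_risk(rows)
    return float(np.mean((p - y[observed]) ** 2))


def calibration_bins(
    model, cohort: Cohort | pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-frequency calibration bins: mean predicted vs observed rate.

    Requests for a single bin are rejected; when there are fewer scored
    rows than bins, the bin count is reduced with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    observed, y = endpoint_values(df, model.endpoint)
    rows = df.loc[observed]
    y = y[observed]
    p = model.predict_risk(rows)
    if len(rows) < n_bins:
        warnings.warn(
            f"only {len(rows)} rows for {n_bins} bins; reducing", stacklevel=2
        )
        n_bins = max(2, len(rows))
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, n_bins)
    out = []
    for b, idx in enumerate(splits):
        if len(idx) == 0:
            continue
        out.append(
            {
                "bin": b,
                "mean_predicted": float(p[idx].mean()),
                "observed_rate": float(y[idx].mean()),
                "count": int(len(idx)),
            }
        )
    return pd.DataFrame(out)
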