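"""Propensity-score conditioning of the twin cohort.

The conditioned digital-twin cohort is built by 1:1 propensity-score
matching of DOAC to VKA twins on age, sex, USVT site and active cancer:
a logistic model of treatment on the four covariates supplies scores,
greedy nearest-neighbour matching without replacement on the logit-score
scale (caliper 0.2 SD by default) forms the pairs, and per-variable ASMDs
between the matched arms quantify balance against the 0.10 target and
0.20 acceptability thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from usvtwin.cohort import Cohort
from usvtwin.fidelity import asmd

__all__ = [
    "PropensityModel",
    "MatchedCohort",
    "MATCHING_COVARIATES",
    "estimate_propensity",
    "match_pairs",
    "balance_report",
    "condition_cohort",
]

MATCHING_COVARIATES = ("age", "sex", "usvt_site", "active_cancer")


@dataclass
class PropensityModel:
    """Logistic model of DOAC assignment on the matching covariates."""

    coefficients: dict[str, float]
    penalized: bool = False

    def __repr__(self) -> str:  # compact, coefficient-first
        terms = ", ".join(f"{k}={v:+.3f}" for k, v in self.coefficients.items())
        return f"PropensityModel({terms}{', penalized' if self.penalized else ''})"


def _design(df: pd.DataFrame) -> pd.DataFrame:
    """Matching-covariate design: age, male flag, site dummies (SVT
    reference — the modal category), active cancer, plus intercept."""
    x = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "sex_male": (df["sex"] == "male").astype(float),
            "site_UEDVT": (df["usvt_site"] == "UEDVT").astype(float),
            "site_CVT": (df["usvt_site"] == "CVT").astype(float),
            "active_cancer": df["active_cancer"].astype(float),
        }
    )
    return sm.add_constant(x, has_constant="add")


def estimate_propensity(cohort: Cohort) -> tuple[PropensityModel, np.ndarray]:
    """Fit the propensity model and return it with per-record DOAC scores.

    Maximum-likelihood logistic fit; on separation or non-convergence the
    fit falls back to a weakly L2-penalized solver and is flagged.
    """
    df = cohort.df
    arms = set(df["treatment"].unique())
    if arms != {"VKA", "DOAC"}:
        raise ValueError(f"both treatment arms required, found {sorted(arms)}")
    y = (df["treatment"] == "DOAC").astype(float).to_numpy()
    x_full = _design(df)
    # constant (zero-variance) covariate columns carry no information and
    # make the likelihood flat; drop them and report coefficient 0
    keep = ["const"] + [
        c for c in x_full.columns if c != "const" and x_full[c].nunique() > 1
    ]
    x = x_full[keep]
    penalized = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
        params = res.params
        if not res.mle_retvals.get("converged", False) or not np.isfinite(params).all():
            raise RuntimeError("non-converged")
        if np.abs(params).max() > 50:
            raise RuntimeError("separation suspected")
    except Exception:
        from sklearn.linear_model import LogisticRegression

        penalized = True
        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(x.iloc[:, 1:], y)
        params = pd.Series(
            np.concatenate([lr.intercept_, lr.coef_[0]]), index=x.columns
        )
    params = params.reindex(x_full.columns, fill_value=0.0)
    scores = 1.0 / (1.0 + np.exp(-(x_full.to_numpy() @ np.asarray(params))))
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    return PropensityModel(dict(params), penalized), scores


@dataclass
class MatchedCohort:
    """1:1 matched pairs plus balance diagnostics."""

    pairs: list[tuple[int, int]]  # (DOAC row index, VKA row index)
    caliper: float  # in logit-score SD units
    unmatched: list[int]
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)
    masmd: tuple[float, float] = (np.nan, np.nan)

    def matched_indices(self) -> list[int]:
        return [i for pair in self.pairs for i in pair]


def match_pairs(
    scores: np.ndarray,
    arms: np.ndarray,
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Works on the logit-score scale; the smaller arm is iterated in a
    seeded random order and each record takes its closest available
    partner, rejecting pairs farther apart than ``caliper`` × SD of the
    logit scores (``caliper=inf`` disables the restriction).
    """
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms)
    logit = np.log(scores / (1.0 - scores))
    sd = logit.std(ddof=1) if len(logit) > 1 else 0.0
    max_dist = caliper * sd
    doac_idx = np.flatnonzero(arms == "DOAC")
    vka_idx = np.flatnonzero(arms == "VKA")
    small, large = (doac_idx, vka_idx) if len(doac_idx) <= len(vka_idx) else (vka_idx, doac_idx)
    rng = np.random.default_rng(seed)
    order = small[np.argsort(rng.random(len(small)), kind="stable")]
    available = dict.fromkeys(large.tolist())
    pairs: list[tuple[int, int]] = []
    for i in order:
        if not available:
            break
        cand = np.fromiter(available, dtype=int)
        dists = np.abs(logit[cand] - logit[i])
        j = int(cand[np.argmin(dists)])
        if dists.min() <= max_dist:
            # store as (DOAC, VKA) regardless of which arm is smaller
            pair = (i, j) if arms[i] == "DOAC" else (j, i)
            pairs.append(pair)
            del available[j]
    matched = {i for p in pairs for i in p}
    unmatched = [int(i) for i in np.concatenate([doac_idx, vka_idx]) if i not in matched]
    return MatchedCohort(pairs=pairs, caliper=caliper, unmatched=unmatched)


def balance_report(
    matched: MatchedCohort,
    cohort: Cohort,
    variables=MATCHING_COVARIATES,
) -> pd.DataFrame:
    """Per-variable ASMD between the matched arms, with pass flags.

    Also fills ``matched.balance`` and ``matched.masmd`` in place.
    """
    if not matched.pairs:
        raise ValueError("no matched pairs to report balance on")
    doac_rows = cohort.df.loc[[p[0] for p in matched.pairs]]
    vka_rows = cohort.df.loc[[p[1] for p in matched.pairs]]
    rows = []
    for v in variables:
        kind = cohort.spec(v).kind
        value = asmd(doac_rows[v].to_numpy(), vka_rows[v].to_numpy(), kind)
        rows.append(
            {
                "variable": v,
                "asmd": value,
                "meets_target": value < 0.10,
                "acceptable": value <= 0.20,
            }
        )
    table = pd.DataFrame(rows)
    vals = table["asmd"].to_numpy()
    matched.balance = table
    matched.masmd = (
        float(vals.mean()),
        float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )
    return table


def condition_cohort(
    cohort: Cohort,
    caliper: float = 0.2,
    seed: int = 0,
) -> tuple[Cohort, MatchedCohort, PropensityModel]:
    """Build the conditioned twin cohort: propensity fit, 1:1 matching,
    balance report, and the matched subset as a new :class:`Cohort`."""
    model, scores = estimate_propensity(cohort)
    matched = match_pairs(scores, cohort.df["treatment"].to_numpy(), caliper, seed)
    if matched.pairs:
        balance_report(matched, cohort)
        sub = cohort.df.loc[matched.matched_indices()].reset_index(drop=True)
    else:
        sub = cohort.df.iloc[0:0]
    conditioned = Cohort(sub, list(cohort.schema), label="conditioned-twin")
    return conditioned, matched, model
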