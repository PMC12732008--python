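"""Real-vs-synthetic agreement metrics for twin cohorts.

Four complementary views of fidelity:

* **ASMD / MASMD** — absolute standardized mean differences per variable
  (Cohen's-d-style pooled-variance denominator) and their mean±SD across
  variables; 0.10 is the target threshold, 0.20 the predefined
  acceptability bound.
* **Kolmogorov-Smirnov** two-sample tests on continuous marginals
  (categorical marginals are compared by total-variation distance instead,
  since KS is invalid under heavy ties).
* **Squared maximum mean discrepancy (MMD²)** — unbiased kernel two-sample
  statistic on the standardized continuous block, Gaussian kernel with the
  median-heuristic bandwidth, permutation null for significance.
* **Spearman correlation-structure similarity** — the fraction of variable
  pairs whose rank correlation differs by less than 0.1 between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from usvtwin.cohort import Cohort

__all__ = [
    "asmd",
    "masmd",
    "mmd2",
    "mmd2_permutation_pvalue",
    "ks_two_sample",
    "correlation_similarity",
    "total_variation",
    "FidelityReport",
    "fidelity_report",
    "encode_ordinal",
]

#: fixed ordinal encoding used for rank-correlation work on mixed data
SITE_CODES = {"SVT": 0, "UEDVT": 1, "CVT": 2}
DEFAULT_ENCODINGS: dict[str, Mapping[str, int]] = {
    "usvt_site": SITE_CODES,
    "treatment": {"VKA": 0, "DOAC": 1},
    "sex": {"female": 0, "male": 1},
    "recanalization": {"not_complete": 0, "complete": 1},
}


def asmd(sample_a, sample_b, kind: str = "continuous") -> float:
    """Absolute standardized mean difference between two samples.

    continuous: ``|m_a - m_b| / sqrt((v_a + v_b)/2)`` with sample variances;
    binary: the same with Bernoulli variances ``p(1-p)``; categorical
    samples (label arrays) are the mean of per-level binary ASMDs.
    Zero pooled variance yields 0 for equal means and ``inf`` otherwise.
    """
    a = np.asarray(sample_a)
    b = np.asarray(sample_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ASMD requires non-empty samples")
    if kind == "categorical":
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        if len(levels) <= 1:
            return 0.0
        return float(
            np.mean([asmd((a == l).astype(float), (b == l).astype(float), "binary") for l in levels])
        )
    a = a.astype(float)
    b = b.astype(float)
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        diff = abs(pa - pb)
    elif kind == "continuous":
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        denom = np.sqrt((va + vb) / 2.0)
        diff = abs(a.mean() - b.mean())
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / denom)


def _cohort_asmd(cohort_a: Cohort, cohort_b: Cohort, name: str) -> float:
    spec = cohort_a.spec(name)
    a = cohort_a.df[name].dropna()
    b = cohort_b.df[name].dropna()
    return asmd(a.to_numpy(), b.to_numpy(), spec.kind)


def masmd(
    cohort_a: Cohort,
    cohort_b: Cohort,
    variables: Sequence[str],
) -> tuple[float, float]:
    """Mean and SD (ddof=1) of per-variable ASMDs across *variables*."""
    if not variables:
        raise ValueError("variable list must be non-empty")
    values = np.array([_cohort_asmd(cohort_a, cohort_b, v) for v in variables])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd


def _gaussian_kernel(sq_dists: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-sq_dists / (2.0 * bandwidth**2))


def _sq_dists(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return ((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2)


def median_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pooled sample."""
    pooled = np.vstack([x, y])
    d = np.sqrt(_sq_dists(pooled, pooled))
    upper = d[np.triu_indices(len(pooled), k=1)]
    med = float(np.median(upper))
    return med if med > 0 else 1.0


def mmd2(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    bandwidth: float | str = "auto",
) -> tuple[float, float]:
    """Unbiased squared maximum mean discrepancy with a Gaussian kernel.

    Returns ``(mmd2, bandwidth)``.  ``bandwidth='auto'`` uses the median
    pairwise distance of the pooled sample.  The unbiased estimator omits
    diagonal terms, so it can be slightly negative under the null.
    """
    x = np.atleast_2d(np.asarray(matrix_a, dtype=float))
    y = np.atleast_2d(np.asarray(matrix_b, dtype=float))
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("MMD needs at least 2 rows in each sample")
    if x.shape[1] != y.shape[1]:
        raise ValueError("samples must share the variable set")
    h = median_bandwidth(x, y) if bandwidth == "auto" else float(bandwidth)
    kxx = _gaussian_kernel(_sq_dists(x, x), h)
    kyy = _gaussian_kernel(_sq_dists(y, y), h)
    kxy = _gaussian_kernel(_sq_dists(x, y), h)
    np.fill_diagonal(kxx, 0.0)
    np.fill_diagonal(kyy, 0.0)
    value = (
        kxx.sum() / (m * (m - 1))
        + kyy.sum() / (n * (n - 1))
        - 2.0 * kxy.mean()
    )
    return float(value), h


def mmd2_permutation_pvalue(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    bandwidth: float | str = "auto",
    n_permutations: int = 200,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation-null p-value for the MMD² statistic.

    Returns ``(mmd2_observed, p_value, null_values)``; the bandwidth is
    fixed at the observed pooled-sample value across permutations.
    """
    x = np.atleast_2d(np.asarray(matrix_a, dtype=float))
    y = np.atleast_2d(np.asarray(matrix_b, dtype=float))
    observed, h = mmd2(x, y, bandwidth)
    pooled = np.vstack([x, y])
    rng = np.random.default_rng(seed)
    m = len(x)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pooled))
        null[i], _ = mmd2(pooled[perm[:m]], pooled[perm[m:]], h)
    p = float((1 + np.sum(null >= observed)) / (1 + n_permutations))
    return observed, p, null


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS requires non-empty samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def total_variation(a, b) -> float:
    """Total-variation distance between two empirical categorical marginals."""
    a = pd.Series(a).dropna()
    b = pd.Series(b).dropna()
    levels = sorted(set(a) | set(b))
    pa = np.array([(a == l).mean() for l in levels])
    pb = np.array([(b == l).mean() for l in levels])
    return float(0.5 * np.abs(pa - pb).sum())


def encode_ordinal(
    cohort: Cohort,
    variables: Sequence[str],
    encodings: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Integer-encode mixed variables for rank-correlation work.

    Binary flags stay 0/1; categorical variables use the fixed documented
    codes (USVT site as the ordinal SVT=0, UEDVT=1, CVT=2).
    """
    encodings = {**DEFAULT_ENCODINGS, **(encodings or {})}
    out = {}
    for name in variables:
        spec = cohort.spec(name)
        col = cohort.df[name]
        if spec.kind == "categorical":
            codes = encodings.get(name) or {lvl: i for i, lvl in enumerate(spec.levels)}
            out[name] = col.map(codes).astype(float)
        else:
            out[name] = col.astype(float)
    return pd.DataFrame(out)


def correlation_similarity(
    cohort_a: Cohort,
    cohort_b: Cohort,
    variables: Sequence[str],
    threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, float, list[str]]:
    """Spearman matrices for both cohorts and the fraction of off-diagonal
    pairs whose correlations differ by less than *threshold* in absolute
    value.  Constant variables are excluded (and returned) rather than
    producing undefined correlations."""
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    enc_a = encode_ordinal(cohort_a, variables)
    enc_b = encode_ordinal(cohort_b, variables)
    excluded = [
        v
        for v in variables
        if enc_a[v].dropna().nunique() <= 1 or enc_b[v].dropna().nunique() <= 1
    ]
    keep = [v for v in variables if v not in excluded]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant variables")
    corr_a = enc_a[keep].corr(method="spearman")
    corr_b = enc_b[keep].corr(method="spearman")
    delta = (corr_a - corr_b).abs().to_numpy()
    iu = np.triu_indices(len(keep), k=1)
    fraction = float((delta[iu] < threshold).mean())
    return corr_a, corr_b, fraction, excluded


@dataclass
class FidelityReport:
    """Bundle of real-vs-synthetic agreement metrics."""

    per_variable_asmd: dict[str, float]
    masmd: tuple[float, float]
    ks_results: dict[str, tuple[float, float]]
    tv_results: dict[str, float]
    mmd2: float
    mmd_bandwidth: float
    mmd_pvalue: float
    corr_similarity: float
    corr_excluded: list[str]
    thresholds: tuple[float, float] = (0.10, 0.20)

    @property
    def meets_target(self) -> bool:
        return self.masmd[0] < self.thresholds[0]

    @property
    def acceptable(self) -> bool:
        return self.masmd[0] <= self.thresholds[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": v,
                "asmd": a,
                "ks_stat": self.ks_results.get(v, (np.nan, np.nan))[0],
                "ks_p": self.ks_results.get(v, (np.nan, np.nan))[1],
                "tv_distance": self.tv_results.get(v, np.nan),
            }
            for v, a in self.per_variable_asmd.items()
        ]
        return pd.DataFrame(rows)


def fidelity_report(
    real: Cohort,
    synthetic: Cohort,
    variables: Sequence[str] | None = None,
    corr_variables: Sequence[str] | None = None,
    mmd_variables: Sequence[str] | None = None,
    seed: int | None = None,
) -> FidelityReport:
    """Full agreement report between a source cohort and its twins.

    Defaults: ASMD over every schema variable except the DOAC agent label;
    KS on continuous variables and total-variation on categoricals; MMD on
    the standardized continuous block; Spearman structure over the
    conditioning covariates plus outcomes and labs.
    """
    if variables is None:
        variables = [s.name for s in real.schema if s.name != "doac_agent"]
    per_var = {v: _cohort_asmd(real, synthetic, v) for v in variables}
    vals = np.array(list(per_var.values()))
    masmd_pair = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)

    ks_results, tv_results = {}, {}
    for v in variables:
        spec = real.spec(v)
        a = real.df[v].dropna()
        b = synthetic.df[v].dropna()
        if spec.kind == "continuous" and len(a) and len(b):
            ks_results[v] = ks_two_sample(a, b)
        elif spec.kind in ("binary", "categorical"):
            tv_results[v] = total_variation(a, b)

    if mmd_variables is None:
        mmd_variables = [
            s.name for s in real.schema if s.kind == "continuous" and s.name != "ttr"
        ]
    xa = real.df[list(mmd_variables)].dropna().to_numpy(dtype=float)
    xb = synthetic.df[list(mmd_variables)].dropna().to_numpy(dtype=float)
    mu, sd = xa.mean(axis=0), xa.std(axis=0)
    sd[sd == 0] = 1.0
    observed, p, _ = mmd2_permutation_pvalue((xa - mu) / sd, (xb - mu) / sd, seed=seed)
    _, bw = mmd2((xa - mu) / sd, (xb - mu) / sd)

    if corr_variables is None:
        corr_variables = [
            "age",
            "sex",
            "usvt_site",
            "treatment",
            "active_cancer",
            "hemoglobin",
            "platelets",
            "d_dimer",
            "recurrence",
            "major_bleed",
        ]
    _, _, fraction, excluded = correlation_similarity(real, synthetic, corr_variables)

    return FidelityReport(
        per_variable_asmd=per_var,
        masmd=masmd_pair,
        ks_results=ks_results,
        tv_results=tv_results,
        mmd2=observed,
        mmd_bandwidth=bw,
        mmd_pvalue=p,
        corr_similarity=fraction,
        corr_excluded=excluded,
    )
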