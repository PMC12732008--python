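"""Patient data model, cohort IO and baseline descriptive summaries.

A :class:`Cohort` wraps a validated :class:`pandas.DataFrame` together with
a schema (a list of :class:`VariableSpec`).  The schema covers demographics,
thrombosis site (SVT / UEDVT / CVT), treatment arm (VKA / DOAC), comorbidity
flags, laboratory values, time in therapeutic range (TTR, VKA patients only),
follow-up and the binary / ordinal outcomes (recanalization, recurrence,
major bleeding, death).

:func:`summarize_cohort` produces a baseline-characteristics table in the
style customary for observational treatment comparisons: continuous
variables as mean±SD or median (IQR) depending on a Shapiro-Wilk normality
screen, categorical variables as counts and percentages, with Student's
t-test / Mann-Whitney U for continuous and chi-square / Fisher's exact test
(when any expected cell count is below five) for categorical comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "VariableSpec",
    "Cohort",
    "CohortValidationError",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "proportion",
    "round_half_up",
    "format_p",
]


class CohortValidationError(ValueError):
    """A cohort table violates its schema or a cross-field invariant."""


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one cohort variable.

    ``kind`` is one of ``continuous``, ``binary`` or ``categorical``;
    categorical variables carry an ordered list of allowed ``levels``.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    units: str = ""
    missing_allowed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if (self.kind == "categorical") != bool(self.levels):
            raise ValueError(
                f"{self.name}: levels must be non-empty iff kind=categorical"
            )


SITES = ("SVT", "UEDVT", "CVT")
TREATMENTS = ("VKA", "DOAC")
DOAC_AGENTS = ("apixaban", "edoxaban", "rivaroxaban", "dabigatran")
COMORBIDITIES = (
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "obesity",
    "smoker",
    "chf",
    "copd_asthma",
    "cerebrovascular",
    "ckd",
    "estrogen",
    "liver_disease",
    "active_cancer",
    "mps",
)
OUTCOME_FLAGS = ("recurrence", "major_bleed", "death")


def default_schema() -> list[VariableSpec]:
    """Schema of the USVT registry table used throughout the package."""
    specs: list[VariableSpec] = [
        VariableSpec("age", "continuous", units="years"),
        VariableSpec("sex", "categorical", ("female", "male")),
        VariableSpec("usvt_site", "categorical", SITES),
        VariableSpec("treatment", "categorical", TREATMENTS),
        VariableSpec("doac_agent", "categorical", DOAC_AGENTS, missing_allowed=True),
    ]
    specs += [VariableSpec(name, "binary") for name in COMORBIDITIES]
    specs += [
        VariableSpec("thrombophilia", "binary"),
        VariableSpec("hemoglobin", "continuous", units="g/dL"),
        VariableSpec("platelets", "continuous", units="1e9/L"),
        VariableSpec("d_dimer", "continuous", units="ng/mL"),
        VariableSpec("ttr", "continuous", units="percent", missing_allowed=True),
        VariableSpec("antiplatelet", "binary"),
        VariableSpec("follow_up", "continuous", units="months"),
        VariableSpec(
            "recanalization",
            "categorical",
            ("complete", "not_complete"),
            missing_allowed=True,
        ),
    ]
    specs += [VariableSpec(name, "binary") for name in OUTCOME_FLAGS]
    return specs


@dataclass
class Cohort:
    """A validated table of patient records plus its schema."""

    df: pd.DataFrame
    schema: list[VariableSpec] = field(default_factory=default_schema)
    label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise CohortValidationError("duplicate variable names in schema")
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise CohortValidationError(f"missing required columns: {missing}")
        self.df = self.df.loc[:, names].reset_index(drop=True)
        _validate(self.df, self.schema)

    def __len__(self) -> int:
        return len(self.df)

    def spec(self, name: str) -> VariableSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def variables(self, kinds: Iterable[str] | None = None) -> list[str]:
        kinds = set(kinds) if kinds is not None else None
        return [s.name for s in self.schema if kinds is None or s.kind in kinds]


def _validate(df: pd.DataFrame, schema: Sequence[VariableSpec]) -> None:
    for s in schema:
        col = df[s.name]
        null = col.isna()
        if null.any() and not s.missing_allowed:
            row = int(null.idxmax())
            raise CohortValidationError(
                f"row {row}: variable {s.name!r} does not allow missing values"
            )
        if s.kind == "categorical":
            bad = ~null & ~col.isin(s.levels)
            if bad.any():
                row = int(bad.idxmax())
                raise CohortValidationError(
                    f"row {row}: {s.name}={col[row]!r} not in levels {list(s.levels)}"
                )
        elif s.kind == "binary":
            vals = col[~null]
            if not vals.isin([0, 1]).all():
                row = int((~null & ~col.isin([0, 1])).idxmax())
                raise CohortValidationError(
                    f"row {row}: {s.name}={col[row]!r} is not a 0/1 flag"
                )
        else:
            if not pd.api.types.is_numeric_dtype(col):
                raise CohortValidationError(f"{s.name}: non-numeric continuous column")

    names = {s.name for s in schema}
    # cross-field invariants of the USVT record model
    if {"treatment", "ttr"} <= names:
        bad = df["ttr"].notna() & (df["treatment"] != "VKA")
        if bad.any():
            raise CohortValidationError(
                f"row {int(bad.idxmax())}: TTR is defined for a non-VKA record"
            )
        bad = df["ttr"].notna() & ((df["ttr"] < 0) | (df["ttr"] > 100))
        if bad.any():
            raise CohortValidationError(
                f"row {int(bad.idxmax())}: TTR outside [0, 100]"
            )
    if {"treatment", "doac_agent"} <= names:
        bad = df["doac_agent"].notna() & (df["treatment"] != "DOAC")
        if bad.any():
            raise CohortValidationError(
                f"row {int(bad.idxmax())}: doac_agent set for a non-DOAC record"
            )
        bad = df["doac_agent"].isna() & (df["treatment"] == "DOAC")
        if bad.any():
            raise CohortValidationError(
                f"row {int(bad.idxmax())}: DOAC record without doac_agent"
            )
    if "age" in names and len(df) and (df["age"] < 18).any():
        raise CohortValidationError(
            f"row {int((df['age'] < 18).idxmax())}: age below 18"
        )
    if "follow_up" in names and len(df) and (df["follow_up"] < 0).any():
        raise CohortValidationError(
            f"row {int((df['follow_up'] < 0).idxmax())}: negative follow-up"
        )


# ---------------------------------------------------------------------------
# IO: comma-separated UTF-8, one header row, missing values as empty strings
# ---------------------------------------------------------------------------

def read_cohort(path, schema: Sequence[VariableSpec] | None = None, label: str = "") -> Cohort:
    """Read and validate a cohort CSV against *schema* (default schema if None)."""
    schema = list(schema) if schema is not None else default_schema()
    df = pd.read_csv(path, dtype={s.name: object for s in schema if s.kind == "categorical"})
    missing = [s.name for s in schema if s.name not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    for s in schema:
        if s.kind in ("continuous", "binary"):
            df[s.name] = pd.to_numeric(df[s.name], errors="raise")
    return Cohort(df, schema, label=label)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.df.to_csv(path, index=False, na_rep="")


def read_schema_yaml(path) -> list[VariableSpec]:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        VariableSpec(
            e["name"],
            e["kind"],
            tuple(e.get("levels", ()) or ()),
            e.get("units", ""),
            bool(e.get("missing_allowed", False)),
        )
        for e in entries
    ]


def write_schema_yaml(schema: Sequence[VariableSpec], path) -> None:
    entries = [
        {
            "name": s.name,
            "kind": s.kind,
            "levels": list(s.levels),
            "units": s.units,
            "missing_allowed": s.missing_allowed,
        }
        for s in schema
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def proportion(events: int, denom: int) -> float:
    """Percentage ``100*events/denom`` rounded to one decimal place."""
    if denom <= 0:
        raise ValueError("proportion undefined for denom <= 0")
    if not 0 <= events <= denom:
        raise ValueError("events must lie in [0, denom]")
    return round_half_up(100.0 * events / denom, 1)


def format_p(p: float) -> str:
    """p-value to three decimals with a '<0.001' floor."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def select_categorical_test(table: np.ndarray) -> str:
    """Chi-square unless any expected cell count is below five (then Fisher).

    Pure function of the 2x2 contingency table.
    """
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return "fisher"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return "fisher" if (expected < 5).any() else "chi2"


def _categorical_p(table: np.ndarray) -> tuple[str, float]:
    test = select_categorical_test(table)
    if test == "fisher":
        _, p = stats.fisher_exact(table)
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return test, float(p)


def _binary_row(name, level_label, x0, x1, g0, g1):
    n0, n1 = int(x0.sum()), int(x1.sum())
    d0, d1 = len(x0), len(x1)
    table = np.array([[n0, d0 - n0], [n1, d1 - n1]])
    test, p = _categorical_p(table)
    return {
        "variable": name,
        "level": level_label,
        "type": "categorical",
        f"{g0}_summary": f"{n0} ({proportion(n0, d0) if d0 else float('nan')})",
        f"{g1}_summary": f"{n1} ({proportion(n1, d1) if d1 else float('nan')})",
        f"{g0}_n": n0,
        f"{g0}_denom": d0,
        f"{g1}_n": n1,
        f"{g1}_denom": d1,
        "test": test,
        "p": p,
        "p_formatted": format_p(p),
    }


def summarize_cohort(
    cohort: Cohort,
    group_var: str = "treatment",
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline table: per-variable summaries by *group_var* with tests.

    Continuous variables are screened for normality with Shapiro-Wilk on the
    pooled sample at ``shapiro_alpha``; normal variables are summarized as
    mean±SD and compared by Student's t-test, non-normal ones as
    median (IQR) with the Mann-Whitney U test.  Binary variables and each
    level of a multi-level categorical are counts (%) compared by chi-square,
    or Fisher's exact test when any expected cell count is below five.
    Variables with missing values (e.g. follow-up recanalization) use
    complete-case denominators.
    """
    df = cohort.df
    spec = cohort.spec(group_var)
    if spec.kind == "categorical":
        groups = [lvl for lvl in spec.levels if (df[group_var] == lvl).any()]
    else:
        groups = sorted(df[group_var].dropna().unique())
    if len(groups) != 2:
        raise ValueError(
            f"group variable {group_var!r} must have exactly two non-empty "
            f"levels, found {groups}"
        )
    g0, g1 = (str(g) for g in groups)
    mask0 = df[group_var] == groups[0]
    mask1 = df[group_var] == groups[1]
    if not mask0.any() or not mask1.any():
        raise ValueError("degenerate group with zero members")

    rows = []
    for s in cohort.schema:
        if s.name in (group_var, "doac_agent"):
            continue
        col = df[s.name]
        c0 = col[mask0 & col.notna()]
        c1 = col[mask1 & col.notna()]
        if s.kind == "continuous":
            pooled = col.dropna().to_numpy(dtype=float)
            if len(pooled) >= 3 and np.ptp(pooled) > 0:
                normal = stats.shapiro(pooled).pvalue >= shapiro_alpha
            else:
                normal = True
            if len(c0) < 2 or len(c1) < 2:
                p = float("nan")
                test = "none"
            elif normal:
                _, p = stats.ttest_ind(c0, c1, equal_var=True)
                test = "t"
            else:
                _, p = stats.mannwhitneyu(c0, c1, alternative="two-sided")
                test = "mannwhitney"
            if normal:
                fmt = lambda c: f"{c.mean():.1f} (±{c.std(ddof=1):.1f})"
            else:
                fmt = lambda c: (
                    f"{c.median():.1f} ({c.quantile(0.25):.1f}–{c.quantile(0.75):.1f})"
                )
            rows.append(
                {
                    "variable": s.name,
                    "level": "",
                    "type": "normal" if normal else "non-normal",
                    f"{g0}_summary": fmt(c0) if len(c0) else "",
                    f"{g1}_summary": fmt(c1) if len(c1) else "",
                    f"{g0}_n": len(c0),
                    f"{g0}_denom": len(c0),
                    f"{g1}_n": len(c1),
                    f"{g1}_denom": len(c1),
                    "test": test,
                    "p": float(p),
                    "p_formatted": format_p(p) if np.isfinite(p) else "",
                }
            )
        elif s.kind == "binary":
            rows.append(_binary_row(s.name, "", c0, c1, g0, g1))
        else:
            # one row per level, each its own 2x2 (the convention of
            # clinical baseline tables)
            for lvl in s.levels:
                rows.append(
                    _binary_row(s.name, lvl, (c0 == lvl).astype(int), (c1 == lvl).astype(int), g0, g1)
                )
    return pd.DataFrame(rows)


def render_summary_text(summary: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a summary table."""
    cols = list(summary.columns)
    sum_cols = [c for c in cols if c.endswith("_summary")]
    out_cols = ["variable", "level", *sum_cols, "test", "p_formatted"]
    widths = {
        c: max(len(c), *(len(str(v)) for v in summary[c])) if len(summary) else len(c)
        for c in out_cols
    }
    lines = ["  ".join(c.ljust(widths[c]) for c in out_cols)]
    for _, r in summary.iterrows():
        lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in out_cols))
    return "\n".join(lines)
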