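"""Method- and operator-agreement statistics for ICV measurement tables.

Works on a long-format table with columns ``subject_id, group, sex, age,
method, phase, icv_l`` (one measurement per subject x method x phase).
Provides:

* MRPAD — mean related percentage of absolute difference,
  (1/n) sum_i |est_i - ref_i| / ref_i x 100, the headline agreement number
  for automated-vs-manual and phase-vs-phase comparisons;
* paired t-tests and Pearson correlations between paired measurement
  columns;
* a four-factor general linear model of ICV on Group, Sex, Age and Method
  with all interactions, reported as a Type III ANOVA table with
  sum-to-zero contrasts.  Method is physically a within-subject factor but
  is entered in a single between-style GLM (the layout the protocol
  analysis uses); the Method F therefore ignores within-subject
  correlation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "mrpad",
    "paired_t_test",
    "pearson_r",
    "factorial_glm_anova",
    "type3_anova",
    "comparison_battery",
    "intra_method_battery",
    "validate_icv_table",
    "comparisons_to_frame",
]

ICV_TABLE_COLUMNS = ("subject_id", "group", "sex", "age", "method", "phase", "icv_l")


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement of one method pair within one group."""

    group: str
    method_a: str
    method_b: str
    t_stat: float
    p_value: float
    df: int
    pearson_r: float
    mrpad_percent: float
    n: int


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def mrpad(estimates: Sequence[float], references: Sequence[float]) -> float:
    """Mean related percentage of absolute difference (percent)."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and references must be equal-length 1D and non-empty")
    if (ref <= 0).any():
        raise ValueError("all references must be > 0")
    return float(np.mean(np.abs(est - ref) / ref) * 100.0)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns (t, p, df) with df = n - 1.

    Identical samples give (0, 1, df).  A nonzero constant difference has
    zero variance: the result is flagged degenerate with t = +/-inf and
    p = nan.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean), math.nan, df
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1D with n >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(a, b).statistic
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Factorial GLM
# ---------------------------------------------------------------------------

_TERM_ORDER = [
    ("Group",),
    ("Sex",),
    ("Age",),
    ("Method",),
    ("Group", "Sex"),
    ("Group", "Age"),
    ("Sex", "Age"),
    ("Group", "Method"),
    ("Sex", "Method"),
    ("Age", "Method"),
    ("Group", "Sex", "Age"),
    ("Group", "Sex", "Method"),
    ("Group", "Age", "Method"),
    ("Sex", "Age", "Method"),
    ("Group", "Sex", "Age", "Method"),
]

_PATSY_NAMES = {
    "Group": "C(group, Sum)",
    "Sex": "C(sex, Sum)",
    "Age": "age_c",
    "Method": "C(method, Sum)",
}


def type3_anova(
    table: pd.DataFrame,
    response: str,
    factor_codes: dict[str, str],
    terms: Sequence[tuple[str, ...]],
) -> pd.DataFrame:
    """Type III ANOVA table for an explicit term list.

    ``factor_codes`` maps display names to model codes (e.g. ``{"Group":
    "C(group, Sum)"}``); ``terms`` lists the tested terms as tuples of
    display names, in output order.  Ordinary least squares; F and p per
    term via Type III sums of squares (the convention that is meaningful
    with sum-to-zero contrasts).  Raises a ValueError naming the first
    aliased term when the design is rank deficient.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = f"{response} ~ " + " + ".join(
        ":".join(factor_codes[f] for f in term) for term in terms
    )
    model = smf.ols(formula, data=table)
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        design = model.data.design_info
        cols_so_far: list[int] = []
        for term, slc in design.term_name_slices.items():
            new = cols_so_far + list(range(slc.start, slc.stop))
            if np.linalg.matrix_rank(exog[:, new]) < len(new):
                raise ValueError(f"design is rank deficient: term '{term}' is aliased")
            cols_so_far = new
        raise ValueError("design is rank deficient")
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=3)

    rows = []
    for term in terms:
        patsy_term = ":".join(factor_codes[f] for f in term)
        if patsy_term not in anova.index:
            raise ValueError(f"term '{':'.join(term)}' missing from the ANOVA table")
        rec = anova.loc[patsy_term]
        rows.append(
            {
                "term": ":".join(term),
                "F": float(rec["F"]),
                "p": float(rec["PR(>F)"]),
                "df": float(rec["df"]),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def factorial_glm_anova(
    table: pd.DataFrame,
    response: str = "icv_l",
    center_age: bool = True,
    max_order: int = 4,
) -> pd.DataFrame:
    """Type III ANOVA of ICV on Group, Sex, Age, Method and interactions.

    Ordinary least squares with sum-to-zero contrasts for the categorical
    factors; age is mean-centered by default so that main effects are
    evaluated at the average age.  ``max_order`` limits the interaction
    depth (4 = all interactions up to the four-way term).  Returns a
    DataFrame with one row per term (main effects, then 2-, 3- and 4-way
    interactions) and columns ``F, p, df``.
    """
    if not 1 <= max_order <= 4:
        raise ValueError("max_order must be in 1..4")
    df = table.copy()
    missing = [c for c in ("group", "sex", "age", "method", response) if c not in df]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    for col in ("group", "sex", "method"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor '{col}' needs at least 2 levels present")
    df["age_c"] = df["age"].astype(float) - (df["age"].astype(float).mean() if center_age else 0.0)
    terms = [t for t in _TERM_ORDER if len(t) <= max_order]
    return type3_anova(df, response, _PATSY_NAMES, terms)


# ---------------------------------------------------------------------------
# Batteries over ICV tables
# ---------------------------------------------------------------------------

def validate_icv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table contract; returns the table."""
    missing = [c for c in ICV_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ICV table is missing columns: {missing}")
    if (table["icv_l"] <= 0).any():
        raise ValueError("all icv_l values must be > 0")
    dup = table.duplicated(subset=["subject_id", "method", "phase"])
    if dup.any():
        raise ValueError(
            "duplicate (subject_id, method, phase) rows: "
            f"{table.loc[dup, 'subject_id'].tolist()}"
        )
    return table


def _paired_columns(
    table: pd.DataFrame,
    spec_a: tuple[str, int],
    spec_b: tuple[str, int],
    group: str | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    sub = table if group is None else table[table["group"] == group]
    a = sub[(sub["method"] == spec_a[0]) & (sub["phase"] == spec_a[1])]
    b = sub[(sub["method"] == spec_b[0]) & (sub["phase"] == spec_b[1])]
    merged = a.merge(b, on="subject_id", suffixes=("_a", "_b"))
    missing = set(a["subject_id"]).symmetric_difference(set(b["subject_id"]))
    if missing:
        raise ValueError(
            f"methods {spec_a} and {spec_b} are not paired for subjects: {sorted(missing)}"
        )
    if len(merged) == 0:
        raise ValueError(f"no paired measurements for {spec_a} vs {spec_b}")
    return (
        merged["icv_l_a"].to_numpy(),
        merged["icv_l_b"].to_numpy(),
        len(merged),
    )


def _battery_row(
    group: str | None,
    name_a: str,
    name_b: str,
    a: np.ndarray,
    b: np.ndarray,
    n: int,
) -> ComparisonResult:
    t, p, df = paired_t_test(a, b)
    try:
        r = pearson_r(a, b)
    except ValueError:
        r = math.nan
    return ComparisonResult(
        group=group if group is not None else "all",
        method_a=name_a,
        method_b=name_b,
        t_stat=t,
        p_value=p,
        df=df,
        pearson_r=r,
        mrpad_percent=mrpad(a, b),
        n=n,
    )


def comparison_battery(
    table: pd.DataFrame,
    reference_method: str = "manual_op1",
    group: str | None = None,
    phase: int = 1,
    reference_phase: int = 1,
) -> list[ComparisonResult]:
    """Each method vs the reference within a group: paired t, r and MRPAD.

    MRPAD is computed with the reference as denominator; the reference
    method itself is excluded from the comparisons.
    """
    validate_icv_table(table)
    sub = table if group is None else table[table["group"] == group]
    methods = sorted(m for m in sub["method"].unique() if m != reference_method)
    results = []
    for method in methods:
        est, ref, n = _paired_columns(
            sub, (method, phase), (reference_method, reference_phase), None
        )
        results.append(_battery_row(group, method, reference_method, est, ref, n))
    return results


def intra_method_battery(
    table: pd.DataFrame,
    group: str | None = None,
    phases: tuple[int, int] = (1, 2),
) -> list[ComparisonResult]:
    """Phase-to-phase consistency of each method: paired t, r and MRPAD.

    MRPAD uses the first phase as denominator.  Methods present in only one
    phase are skipped.
    """
    validate_icv_table(table)
    sub = table if group is None else table[table["group"] == group]
    results = []
    for method in sorted(sub["method"].unique()):
        present = set(sub.loc[sub["method"] == method, "phase"].unique())
        if not {phases[0], phases[1]} <= present:
            continue
        b, a, n = _paired_columns(sub, (method, phases[1]), (method, phases[0]), None)
        results.append(
            _battery_row(group, f"{method}_p{phases[1]}", f"{method}_p{phases[0]}", b, a, n)
        )
    return results
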