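"""Case-control statistical battery.

Implements the analyses used to compare case (at risk of preterm delivery)
and control groups: Student's pooled-variance two-sample t-test (from raw
samples or from published summary statistics), Pearson chi-squared tests
on contingency tables (no continuity correction), the Pearson
product-moment correlation, and multiple logistic regression with Wald
odds ratios and 95% confidence intervals. Also builds the descriptive
case/control summary table.

Conventions fixed here and used throughout:

* pooled-variance (not Welch) t with df = n1 + n2 - 2, two-sided;
* chi-squared without Yates correction;
* Wald CI multiplier 1.96 (normal approximation);
* smoking enters the regression as a single ordinal code 0/1/2
  (nonsmoker / stopped during pregnancy / smoker during pregnancy) by
  default, or as a binary any-smoking indicator;
* the relative difference between two group means is reported as a
  percentage of the larger mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import DELIVERY_BINS, SMOKING_LEVELS, SubjectSummary, classify_delivery
from .errors import DataError, SeparationError

__all__ = [
    "GroupSummary",
    "RegressionResult",
    "CorrelationResult",
    "t_test_two_sample",
    "t_test_from_samples",
    "chi_squared_test",
    "pearson_r",
    "logistic_fit",
    "build_table1",
    "percent_difference",
    "odds_ratio_from_beta",
]

Z_95 = 1.96  # Wald multiplier for a 95% CI


@dataclass
class GroupSummary:
    """One row of the descriptive case/control table.

    For a continuous variable ``case_stat``/``control_stat`` are
    ``(mean, sd)``; for a categorical level they are ``(count, pct)``.
    """

    variable: str
    kind: Literal["continuous", "categorical"]
    case_stat: tuple[float, float]
    control_stat: tuple[float, float]
    case_n: int
    control_n: int
    p_value: float | None
    test: Literal["t", "chi_squared", "none"]


@dataclass
class RegressionResult:
    """Multiple logistic regression output (one row per predictor)."""

    outcome: str
    n: int
    converged: bool
    log_likelihood: float
    predictors: list[str]
    beta: dict[str, float]
    std_error: dict[str, float]
    wald_p: dict[str, float]
    odds_ratio: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.predictors:
            rows.append(
                {
                    "predictor": name,
                    "beta": self.beta[name],
                    "std_error": self.std_error[name],
                    "wald_p": self.wald_p[name],
                    "odds_ratio": self.odds_ratio[name],
                    "ci_lower": self.ci_lower[name],
                    "ci_upper": self.ci_upper[name],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float | None = None


# ---------------------------------------------------------------------------
# Elementary tests


def t_test_two_sample(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t-test from summary statistics.

    Returns ``(t, df, two_sided_p)`` with df = n1 + n2 - 2. Works directly
    from published group means and standard deviations, which is how a
    printed summary table is re-checked.
    """
    if n1 < 2 or n2 < 2:
        raise DataError(f"need n >= 2 per group, got n1={n1}, n2={n2}")
    if sd1 < 0 or sd2 < 0:
        raise DataError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if mean1 == mean2:
            warnings.warn("zero variance in both groups with equal means; p = 1")
            return 0.0, df, 1.0
        raise DataError("zero variance in both groups with unequal means")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def t_test_from_samples(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled t-test from raw samples (summaries computed internally)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return t_test_two_sample(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def chi_squared_test(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns ``(statistic, df, p)`` with df = (rows-1)(cols-1).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataError(f"need a 2-D table with >= 2 rows and columns, got {arr.shape}")
    if (arr < 0).any():
        raise DataError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero marginal")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DataError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise DataError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p_value=float(res.pvalue))


def percent_difference(mean_a: float, mean_b: float) -> float:
    """Relative difference between two group means, as a percentage of the
    larger mean."""
    big = max(abs(mean_a), abs(mean_b))
    if big == 0:
        raise DataError("percent difference undefined for two zero means")
    return 100.0 * abs(mean_a - mean_b) / big


def odds_ratio_from_beta(
    beta: float, std_error: float | None = None
) -> tuple[float, float | None, float | None]:
    """OR = exp(beta) and, when an SE is given, the Wald 95% CI
    ``exp(beta +- 1.96 se)``."""
    or_ = float(np.exp(beta))
    if std_error is None:
        return or_, None, None
    return (
        or_,
        float(np.exp(beta - Z_95 * std_error)),
        float(np.exp(beta + Z_95 * std_error)),
    )


# ---------------------------------------------------------------------------
# Logistic regression


def _find_separating_predictor(y: np.ndarray, X: pd.DataFrame) -> str | None:
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        a, b = v[y == 1], v[y == 0]
        if a.size and b.size and (a.min() >= b.max() or b.min() >= a.max()):
            return col
    return None


def logistic_fit(
    outcome: Sequence[int],
    predictors: pd.DataFrame | dict[str, Sequence[float]],
    outcome_name: str = "case",
) -> RegressionResult:
    """Maximum-likelihood multiple logistic regression with Wald inference.

    An intercept is always included. Fitting is Newton-Raphson with a
    1e-8 convergence tolerance and at most 100 iterations; standard
    errors come from the inverse observed information. Per predictor the
    result carries beta (per-unit log-odds), its SE, the two-sided Wald
    p, and OR = exp(beta) with exp(beta +- 1.96 SE) as the 95% CI.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DataError("outcome has a single class; logistic model undefined")
    if len(y) != len(X):
        raise DataError(f"outcome length {len(y)} != predictor rows {len(X)}")
    if len(y) <= X.shape[1] + 1:
        raise DataError("need n > number of predictors + 1")

    design = sm.add_constant(X, prepend=True, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as exc:
            culprit = _find_separating_predictor(y, X)
            raise SeparationError(
                "logistic fit failed to converge"
                + (f"; predictor {culprit!r} separates the classes" if culprit else ""),
                predictor=culprit,
            ) from exc

    names = list(X.columns)
    beta = {k: float(fit.params[k]) for k in names}
    se = {k: float(fit.bse[k]) for k in names}
    wald_p = {
        k: float(2.0 * sps.norm.sf(abs(beta[k] / se[k]))) if se[k] > 0 else float("nan")
        for k in names
    }
    return RegressionResult(
        outcome=outcome_name,
        n=len(y),
        converged=bool(fit.mle_retvals["converged"]),
        log_likelihood=float(fit.llf),
        predictors=names,
        beta=beta,
        std_error=se,
        wald_p=wald_p,
        odds_ratio={k: float(np.exp(beta[k])) for k in names},
        ci_lower={k: float(np.exp(beta[k] - Z_95 * se[k])) for k in names},
        ci_upper={k: float(np.exp(beta[k] + Z_95 * se[k])) for k in names},
    )


# ---------------------------------------------------------------------------
# Descriptive case/control table


def _group_arrays(
    summaries: Sequence[SubjectSummary], attr: str
) -> tuple[np.ndarray, np.ndarray]:
    case = np.array(
        [getattr(s, attr) for s in summaries if s.group == "case"], dtype=float
    )
    ctrl = np.array(
        [getattr(s, attr) for s in summaries if s.group == "control"], dtype=float
    )
    return case, ctrl


def _continuous_row(name: str, case: np.ndarray, ctrl: np.ndarray) -> GroupSummary:
    _, _, p = t_test_two_sample(
        case.mean(), case.std(ddof=1), len(case), ctrl.mean(), ctrl.std(ddof=1), len(ctrl)
    )
    return GroupSummary(
        variable=name,
        kind="continuous",
        case_stat=(round(float(case.mean()), 2), round(float(case.std(ddof=1)), 2)),
        control_stat=(round(float(ctrl.mean()), 2), round(float(ctrl.std(ddof=1)), 2)),
        case_n=len(case),
        control_n=len(ctrl),
        p_value=round(p, 3),
        test="t",
    )


def _categorical_rows(
    name: str,
    levels: Sequence[str],
    case_labels: Sequence[str],
    ctrl_labels: Sequence[str],
    with_test: bool = True,
) -> list[GroupSummary]:
    case_counts = [sum(1 for v in case_labels if v == lv) for lv in levels]
    ctrl_counts = [sum(1 for v in ctrl_labels if v == lv) for lv in levels]
    p = None
    if with_test:
        # drop all-empty levels so the chi-squared table has no zero marginal
        keep = [i for i in range(len(levels)) if case_counts[i] + ctrl_counts[i] > 0]
        table = [[case_counts[i] for i in keep], [ctrl_counts[i] for i in keep]]
        if len(keep) >= 2:
            _, _, p_raw = chi_squared_test(table)
            p = round(p_raw, 3)
    n_case, n_ctrl = len(case_labels), len(ctrl_labels)
    rows = []
    for i, lv in enumerate(levels):
        rows.append(
            GroupSummary(
                variable=f"{name}: {lv}",
                kind="categorical",
                case_stat=(case_counts[i], round(100.0 * case_counts[i] / n_case)),
                control_stat=(ctrl_counts[i], round(100.0 * ctrl_counts[i] / n_ctrl)),
                case_n=n_case,
                control_n=n_ctrl,
                p_value=p if i == 0 else None,
                test="chi_squared" if (with_test and i == 0) else "none",
            )
        )
    return rows


def build_table1(summaries: Sequence[SubjectSummary]) -> list[GroupSummary]:
    """Descriptive case-vs-control table.

    Continuous variables get mean (sd) per group with a pooled t-test p;
    categoricals get n (%) per group with a chi-squared p attached to the
    first level of each variable; delivery outcome is tabulated in the
    four gestational-age bins without a test (descriptive only, unknown
    outcomes dropped). Rounding: 2 dp for means/sds, 3 dp for p, whole
    percent for categorical percentages.
    """
    if not summaries:
        raise DataError("no subject summaries")
    groups = {s.group for s in summaries}
    if groups != {"case", "control"}:
        raise DataError(f"need both groups present, got {sorted(groups)}")

    rows: list[GroupSummary] = []
    for attr, label in [
        ("mean_coverage_pct", "Mean plaque coverage (%)"),
        ("mean_delta_r_pct", "Mean red fluorescence (dR%)"),
        ("maternal_age", "Mean maternal age (years)"),
    ]:
        case, ctrl = _group_arrays(summaries, attr)
        rows.append(_continuous_row(label, case, ctrl))

    case_s = [s for s in summaries if s.group == "case"]
    ctrl_s = [s for s in summaries if s.group == "control"]

    rows.extend(
        _categorical_rows(
            "Maternal age",
            ["<=35", ">35"],
            ["<=35" if s.maternal_age <= 35 else ">35" for s in case_s],
            ["<=35" if s.maternal_age <= 35 else ">35" for s in ctrl_s],
        )
    )
    rows.extend(
        _categorical_rows(
            "Smoking status",
            list(SMOKING_LEVELS),
            [s.smoking for s in case_s],
            [s.smoking for s in ctrl_s],
        )
    )
    case_bmi, ctrl_bmi = _group_arrays(summaries, "bmi")
    rows.append(_continuous_row("BMI before pregnancy", case_bmi, ctrl_bmi))

    def bmi_cat(b: float) -> str:
        if b < 19:
            return "underweight"
        if b <= 25:
            return "normal"
        return "overweight"

    rows.extend(
        _categorical_rows(
            "BMI category",
            ["underweight", "normal", "overweight"],
            [bmi_cat(s.bmi) for s in case_s],
            [bmi_cat(s.bmi) for s in ctrl_s],
        )
    )
    rows.extend(
        _categorical_rows(
            "Delivery outcome",
            list(DELIVERY_BINS),
            [c for s in case_s if (c := classify_delivery(s.delivery_weeks)) != "unknown"],
            [c for s in ctrl_s if (c := classify_delivery(s.delivery_weeks)) != "unknown"],
            with_test=False,
        )
    )
    return rows


def table1_to_frame(rows: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "kind": [r.kind for r in rows],
            "case": [f"{r.case_stat[0]} ({r.case_stat[1]})" for r in rows],
            "control": [f"{r.control_stat[0]} ({r.control_stat[1]})" for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test for r in rows],
        }
    )
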