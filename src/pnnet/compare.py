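"""Complete- vs incomplete-group comparison with FDR adjustment.

Mirrors the descriptive-table machinery of cohort studies: each variable
is compared between the two groups with a test chosen by its declared
kind -- chi-square on contingency counts for categorical variables, an
unpaired two-sample t-test for normally distributed continuous
variables, and a Mann-Whitney U test (normal approximation with tie and
continuity correction; exact enumeration for very small groups) for
skewed continuous variables -- and the raw two-sided p-values are
adjusted by the Benjamini-Hochberg step-up false-discovery-rate
procedure.  Significance is declared at adjusted p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compare_groups", "bh_fdr", "ALPHA"]

#: significance level on the adjusted p-values
ALPHA = 0.05

_KINDS = ("categorical", "normal", "skewed")

#: below this per-group size the Mann-Whitney p-value is computed exactly
_EXACT_MW_N = 8


def bh_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) adjusted p-values.

    Step-up adjustment: sort ascending, multiply ``p_(i)`` by ``m / i``,
    enforce monotonicity from the largest down, cap at 1; values are
    returned in the original input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method=sm_method)[1]


def _chi_square(a: pd.Series, b: pd.Series, yates: bool):
    counts = pd.crosstab(
        pd.concat([pd.Series("a", index=range(len(a))), pd.Series("b", index=range(len(b)))],
                  ignore_index=True),
        pd.concat([a.reset_index(drop=True), b.reset_index(drop=True)], ignore_index=True),
    )
    counts = counts.reindex(index=["a", "b"], fill_value=0)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    stat, p, _, _ = stats.chi2_contingency(counts.to_numpy(), correction=yates)
    return "chi-square", float(stat), float(p), counts


def _summary(x: pd.Series, kind: str) -> str:
    x = x.dropna()
    if kind == "categorical":
        vc = x.value_counts()
        return "; ".join(f"{lvl}: {cnt} ({cnt / len(x):.1%})" for lvl, cnt in vc.items())
    if kind == "normal":
        return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"
    q25, med, q75 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} ({q25:.2f}-{q75:.2f})"


def compare_groups(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    variable_kinds: dict[str, str],
    yates: bool = False,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-variable two-group comparison report.

    ``variable_kinds`` maps each variable to ``"categorical"``,
    ``"normal"`` or ``"skewed"``; the test is selected accordingly.
    Returns one row per variable with the test name, statistic, raw and
    FDR-adjusted two-sided p-value, group summaries (mean/SD,
    median/IQR, or counts/percent) and a significance flag at adjusted
    p < 0.05.
    """
    if len(panel_a) == 0 or len(panel_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var, kind in variable_kinds.items():
        if kind not in _KINDS:
            raise ValueError(f"{var}: kind must be one of {_KINDS}, got {kind!r}")
        a, b = panel_a[var].dropna(), panel_b[var].dropna()
        if kind == "categorical":
            test, stat, p, _ = _chi_square(a, b, yates)
        elif kind == "normal":
            res = stats.ttest_ind(a, b)
            test, stat, p = "t-test", float(res.statistic), float(res.pvalue)
        else:
            method = "exact" if min(len(a), len(b)) < _EXACT_MW_N else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            test, stat, p = "mann-whitney-u", float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": var,
                "test": test,
                "statistic": stat,
                "p_raw": p,
                "summary_a": _summary(a, kind),
                "summary_b": _summary(b, kind),
            }
        )
    report = pd.DataFrame(rows).set_index("variable")
    report["p_adjusted"] = bh_fdr(report["p_raw"], method=fdr_method)
    report["significant"] = report["p_adjusted"] < ALPHA
    return report
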