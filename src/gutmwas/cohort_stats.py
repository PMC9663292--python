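"""Per-variable case/control metadata contrasts (Table-1-style analysis).

Categorical variables are compared with Fisher's exact test; the reported
odds ratio is the conditional maximum-likelihood estimate of the noncentral
hypergeometric odds parameter with an exact conditional CI (the R
``fisher.test`` convention), except when the 2x2 table contains a zero cell,
where the Haldane-corrected sample OR with a Woolf log-normal CI is used.
Quantitative variables are compared with the two-sided Wilcoxon rank-sum
test. p-values are deliberately not corrected for multiple testing: the aim
of this screen is to flag any trend that could confound downstream models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gutmwas.exceptions import DegenerateTableError

__all__ = ["TwoByTwo", "ORResult", "fisher_exact_or", "wilcoxon_rank_sum", "metadata_table"]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (cases exposed, cases unexposed, controls exposed, controls unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise DegenerateTableError("each group needs at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str  # "conditional-MLE" or "Woolf"


def fisher_exact_or(table: TwoByTwo) -> ORResult:
    """Two-sided Fisher exact test with conditional-MLE OR, Woolf fallback on zeros.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed table's.
    """
    arr = table.as_array()
    if arr[:, 0].sum() == 0 or arr[:, 1].sum() == 0:
        raise DegenerateTableError("empty exposure margin")
    p = float(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    if arr.min() == 0:
        # Haldane-Anscombe 0.5 correction + Woolf log-normal CI
        a, b, c, d = (arr + 0.5).ravel()
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = or_ * np.exp(-1.96 * se), or_ * np.exp(1.96 * se)
        return ORResult(float(or_), float(lo), float(hi), p, "Woolf")
    res = stats.contingency.odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    return ORResult(float(res.statistic), float(ci.low), float(ci.high), p, "conditional-MLE")


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for n <= 25 per group without ties,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def metadata_table(
    metadata: pd.DataFrame,
    variables: list[tuple[str, str]],
    group_col: str = "case_status",
    case_label: str = "case",
) -> pd.DataFrame:
    """One row per (variable, kind) with kind in {"categorical", "quantitative"}.

    Missing values are dropped per variable; the per-group N with data is
    reported. Categorical variables must be binary 0/1 (or boolean) and yield
    an OR with CI; quantitative variables yield a Wilcoxon p and mean +/- SD
    summaries. Degenerate tables are surfaced per variable without aborting
    the run.
    """
    is_case = metadata[group_col] == case_label
    rows = []
    for name, kind in variables:
        if name not in metadata.columns:
            raise KeyError(f"unknown metadata variable: {name!r}")
        col = metadata[name]
        ok = col.notna()
        vc, vn = col[ok & is_case], col[ok & ~is_case]
        row: dict = {"variable": name, "kind": kind, "n_case": len(vc), "n_control": len(vn)}
        try:
            if kind == "categorical":
                a = int((vc.astype(float) > 0).sum())
                c = int((vn.astype(float) > 0).sum())
                res = fisher_exact_or(TwoByTwo(a, len(vc) - a, c, len(vn) - c))
                row.update(
                    summary_case=f"{a} ({100 * a / max(len(vc), 1):.0f}%)",
                    summary_control=f"{c} ({100 * c / max(len(vn), 1):.0f}%)",
                    p_value=res.p_value,
                    odds_ratio=res.odds_ratio,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    ci_method=res.ci_method,
                )
            elif kind == "quantitative":
                row.update(
                    summary_case=f"{vc.mean():.1f} +/- {vc.std():.1f}",
                    summary_control=f"{vn.mean():.1f} +/- {vn.std():.1f}",
                    p_value=wilcoxon_rank_sum(vc.to_numpy(float), vn.to_numpy(float)),
                    odds_ratio=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    ci_method="",
                )
            else:
                raise ValueError(f"variable kind must be categorical or quantitative, got {kind!r}")
        except DegenerateTableError as exc:
            row.update(p_value=np.nan, odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, ci_method="", error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
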