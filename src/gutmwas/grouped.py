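"""Hypothesis-driven collapsed-group differential tests.

A named set of features (e.g., a sub-genus of individually rare species, a
network cluster of opportunistic pathogens, or a family of sporulation gene
groups) is collapsed by summing relative abundances per sample, and the
collapsed fraction is tested with the same log2 linear model used feature-wise
— but with no multiplicity correction, since each test is a single
pre-specified hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gutmwas.diffabund import CASE_TERM, build_design

__all__ = [
    "GroupedTestResult",
    "collapse_features",
    "grouped_lm_test",
    "sporulation_constipation_analysis",
]


@dataclass
class GroupedTestResult:
    group_name: str
    n_features_collapsed: int
    term: str  # coefficient tested
    beta: float  # log2 scale
    fold_change: float
    ci: tuple[float, float]
    p_value: float  # two-sided, uncorrected
    n_samples: int


def collapse_features(relab: pd.DataFrame, feature_set: list[str]) -> pd.Series:
    """Per-sample sum of the listed features' relative abundances."""
    if not feature_set:
        raise ValueError("feature_set is empty")
    missing = [f for f in feature_set if f not in relab.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    return relab[list(feature_set)].sum(axis=1)


def grouped_lm_test(
    collapsed: pd.Series,
    metadata: pd.DataFrame,
    terms: list[str],
    group_name: str = "group",
    n_features: int = 1,
    term_of_interest: str = CASE_TERM,
) -> GroupedTestResult:
    """OLS of log2(collapsed + pseudocount) on the terms; FC = 2^beta with a
    1.96*se Wald CI for the term of interest. The pseudocount is half the
    smallest nonzero collapsed value (same rule as the feature-wise model)."""
    if not collapsed.index.equals(metadata.index):
        raise ValueError("collapsed vector and metadata are not aligned")
    vals = collapsed.to_numpy(float)
    if (vals == 0).all():
        raise ValueError("collapsed abundance is zero in every sample")
    pseudo = vals[vals > 0].min() / 2.0
    y = np.log2(vals + pseudo)
    x, names = build_design(metadata, terms)
    if term_of_interest not in names:
        raise KeyError(f"term {term_of_interest!r} not in design ({names})")
    target = names.index(term_of_interest)
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("singular design")
    resid = y - x @ coef
    dof = len(y) - x.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(x.T @ x))[target])
    beta = float(coef[target])
    p = float(2.0 * stats.t.sf(abs(beta) / se, dof))
    return GroupedTestResult(
        group_name=group_name,
        n_features_collapsed=n_features,
        term=term_of_interest,
        beta=beta,
        fold_change=float(2.0**beta),
        ci=(float(2.0 ** (beta - 1.96 * se)), float(2.0 ** (beta + 1.96 * se))),
        p_value=p,
        n_samples=len(y),
    )


def select_sporulation_set(
    da_a: pd.DataFrame, da_b: pd.DataFrame, name_contains: str = "sporulation", fdr: float = 0.05
) -> list[str]:
    """Features whose name contains the keyword and that reach FDR < ``fdr``
    in both DA results — the selection rule for the sporulation KO set."""
    common = [f for f in da_a.index if name_contains in str(f)]
    return [f for f in common if da_a.loc[f, "q"] < fdr and da_b.loc[f, "q"] < fdr]


def sporulation_constipation_analysis(
    ko_relab: pd.DataFrame,
    sporulation_set: list[str],
    metadata: pd.DataFrame,
    technical_terms: list[str] | None = None,
) -> dict[str, GroupedTestResult]:
    """Three tests of the collapsed sporulation KO-group abundance:

    (i) constipated vs. not within cases, (ii) within controls, and
    (iii) case vs. control adjusting for constipation. Samples missing the
    constipation flag are dropped; an empty stratum is skipped with a warning.
    """
    if "constipation" not in metadata.columns:
        raise KeyError("metadata lacks a 'constipation' column")
    technical_terms = technical_terms or ["total_sequence_count", "collection_kit"]
    collapsed = collapse_features(ko_relab, sporulation_set)
    has_flag = metadata["constipation"].notna()
    md = metadata.loc[has_flag]
    vec = collapsed.loc[has_flag]
    results: dict[str, GroupedTestResult] = {}
    for label, group in (("within_cases", "case"), ("within_controls", "control")):
        mask = md[CASE_TERM] == group
        sub_md = md.loc[mask]
        if sub_md["constipation"].nunique() < 2:
            warnings.warn(f"stratum {label} has no constipation contrast; skipped")
            continue
        results[label] = grouped_lm_test(
            vec.loc[mask],
            sub_md,
            ["constipation"] + technical_terms,
            group_name=f"sporulation_{label}",
            n_features=len(sporulation_set),
            term_of_interest="constipation",
        )
    results["case_vs_control_adj_constipation"] = grouped_lm_test(
        vec,
        md,
        [CASE_TERM, "constipation"] + technical_terms,
        group_name="sporulation_case_vs_control",
        n_features=len(sporulation_set),
        term_of_interest=CASE_TERM,
    )
    return results
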