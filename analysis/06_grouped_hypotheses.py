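"""Hypothesis-driven collapsed-group tests.

Three pre-specified hypotheses, each a single linear-model test on a
collapsed relative abundance (no multiplicity correction): (1) the planted
elevated features as a rare-taxa sub-group (the sub-genus style test);
(2) the first planted correlation cluster as a polymicrobial unit (the
pathogen-cluster style test); (3) the planted reduced features vs. the
constipation flag, within cases, within controls, and case-vs-control
adjusting for constipation (the sporulation-gene style analysis). Writes
results/grouped_tests.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gutmwas import grouped
from gutmwas.io import read_abundance_table, read_metadata

TERMS = ["case_status", "total_sequence_count", "collection_kit"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    relab = read_abundance_table(args.cohort / "relabund.tsv", validate_relative=True)
    md = read_metadata(args.cohort / "metadata.tsv")
    truth = json.loads((args.cohort / "truth.json").read_text())
    diff = truth["differential_features"]
    elevated = [f for f, l in diff.items() if l > 0]
    reduced = [f for f, l in diff.items() if l < 0]
    cluster0 = [f for f, c in truth["cluster_assignment"].items() if c == 0]

    results = {}
    results["elevated_subgroup"] = grouped.grouped_lm_test(
        grouped.collapse_features(relab, elevated), md, TERMS,
        group_name="elevated_subgroup", n_features=len(elevated),
    )
    results["cluster_0"] = grouped.grouped_lm_test(
        grouped.collapse_features(relab, cluster0), md, TERMS,
        group_name="cluster_0", n_features=len(cluster0),
    )
    spor = grouped.sporulation_constipation_analysis(relab, reduced, md)
    results.update({f"reduced_set/{k}": v for k, v in spor.items()})

    rows = []
    for name, r in results.items():
        rows.append({"test": name, "n_features": r.n_features_collapsed, "term": r.term,
                     "fold_change": round(r.fold_change, 3), "ci_lo": round(r.ci[0], 3),
                     "ci_hi": round(r.ci[1], 3), "p": f"{r.p_value:.2g}", "n": r.n_samples})
        print(f"{name:42s} FC {r.fold_change:5.2f} [{r.ci[0]:.2f}-{r.ci[1]:.2f}]  p = {r.p_value:.2g}")
    pd.DataFrame(rows).to_csv(args.outdir / "grouped_tests.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
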