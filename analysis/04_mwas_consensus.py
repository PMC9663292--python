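"""Feature-wise association study with dual-method consensus.

After the 5% prevalence filter, every feature is tested with the log2
relative-abundance linear model and the bias-corrected log-count model;
BH FDR is applied per method and a feature is called disease-associated
under the asymmetric consensus rule (FDR < 0.05 by one method, <= 0.1 by
the other). Calls are compared against the generator's truth record, and
the called set is re-tested in an extended model with the behavioral
covariates to probe confounding. Writes results/mwas_species.tsv,
results/mwas_confusion.tsv and results/mwas_confounders.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gutmwas import diffabund as da
from gutmwas.io import read_abundance_table, read_metadata

TERMS = ["case_status", "total_sequence_count", "collection_kit"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = read_abundance_table(args.cohort / "counts.tsv")
    relab = read_abundance_table(args.cohort / "relabund.tsv", validate_relative=True)
    md = read_metadata(args.cohort / "metadata.tsv")
    truth = json.loads((args.cohort / "truth.json").read_text())

    kept = da.prevalence_filter(relab)
    print(f"prevalence filter: {kept.shape[1]} / {relab.shape[1]} features tested")
    lm = da.lm_log2_relab(kept, md, TERMS)
    bc = da.bias_corrected_da(counts[kept.columns], md, TERMS)
    calls = da.consensus_calls(lm, bc)
    merged = lm.add_suffix("_lm").join(bc.add_suffix("_bc")).join(calls[["direction", "tier", "called"]])
    merged.to_csv(args.outdir / "mwas_species.tsv", sep="\t")

    called = set(calls.index[calls["called"]])
    planted = set(truth["differential_features"]) & set(kept.columns)
    tp = len(called & planted)
    confusion = {"tp": tp, "fp": len(called - planted), "fn": len(planted - called),
                 "tn": kept.shape[1] - len(called | planted)}
    pd.Series(confusion).to_csv(args.outdir / "mwas_confusion.tsv", sep="\t", header=False)
    n_both = int((calls["tier"] == "both<0.05").sum())
    print(f"consensus: {len(called)} of {kept.shape[1]} features called "
          f"({n_both} at FDR<0.05 by both methods)")
    print(f"vs truth: {tp} true positives, {confusion['fp']} false, {confusion['fn']} missed")

    extra = [c for c in ("laxatives", "alcohol", "probiotics") if c in md.columns]
    case_tab, symbols, n_case, n_control = da.covariate_rerun(sorted(called), kept, md, extra)
    out = case_tab[["beta", "q", "fold_change"]].join(symbols)
    out.to_csv(args.outdir / "mwas_confounders.tsv", sep="\t")
    persist = int((case_tab["q"] < 0.1).sum())
    print(f"confounder rerun ({n_case} cases / {n_control} controls with complete data): "
          f"{persist}/{len(called)} calls persist at FDR<0.1")


if __name__ == "__main__":
    main()
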