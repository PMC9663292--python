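"""Generate the study cohort: 200 cases / 200 controls, 257 species-level
features, 20 planted fold changes, 3 correlation clusters, and covariates
whose odds ratios mirror the metadata contrasts (laxative use elevated in
cases, alcohol intake reduced). Writes the count/relative-abundance tables,
metadata (with a constipation flag tied to the planted reduced features),
and the ground-truth record under results/cohort/.
"""

import argparse
from pathlib import Path

from gutmwas.io import write_abundance_table, write_metadata
from gutmwas.simulate import CohortConfig, CovariateSpec, generate_cohort, generate_constipation_layer


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = CohortConfig(
        n_clusters=3,
        cluster_size_range=(8, 8),
        covariate_specs=[
            CovariateSpec("laxatives", 3.8, 0.11),
            CovariateSpec("alcohol", 0.6, 0.51),
            CovariateSpec("probiotics", 0.6, 0.19),
        ],
        seed=args.seed,
    )
    counts, relab, metadata, truth = generate_cohort(cfg)
    reduced = [f for f, l in truth.differential_features.items() if l < 0]
    metadata = generate_constipation_layer(
        metadata, relab[reduced].sum(axis=1), effect_log2=-0.5, seed=args.seed + 1
    )

    write_abundance_table(counts, args.outdir / "counts.tsv")
    write_abundance_table(relab, args.outdir / "relabund.tsv")
    write_metadata(metadata, args.outdir / "metadata.tsv")
    truth.to_json(args.outdir / "truth.json")

    n_up = sum(l > 0 for l in truth.differential_features.values())
    print(f"cohort: {cfg.n_cases} cases / {cfg.n_controls} controls, {cfg.n_features} features")
    print(f"planted: {len(truth.differential_features)} differential ({n_up} elevated), "
          f"{len(set(truth.cluster_assignment.values()))} clusters")
    print(f"constipation prevalence: cases "
          f"{metadata.loc[metadata.case_status == 'case', 'constipation'].mean():.2f}, controls "
          f"{metadata.loc[metadata.case_status == 'control', 'constipation'].mean():.2f}")
    print(f"wrote tables to {args.outdir}")


if __name__ == "__main__":
    main()
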