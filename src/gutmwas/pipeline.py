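"""End-to-end pipeline driver over a synthetic (or loaded) cohort.

Stages run in order — cohort stats, composition, differential abundance with
consensus, per-group correlation networks, grouped tests — writing TSV/JSON
outputs plus a structured run log (stage, seed, feature attrition) into the
output directory. Identical config + seeds give identical outputs. A stage
failure aborts with a stage-named error; outputs of earlier stages remain.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import gutmwas
from gutmwas import composition, cohort_stats, diffabund, grouped, network
from gutmwas.io import write_abundance_table, write_metadata
from gutmwas.simulate import CohortConfig, generate_cohort, generate_constipation_layer

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

TECHNICAL_TERMS = [diffabund.CASE_TERM, "total_sequence_count", "collection_kit"]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str | Path = "results/pipeline"
    min_prevalence: float = 0.05
    consensus_primary: float = 0.05
    consensus_secondary: float = 0.1
    r_threshold: float = 0.2
    p_threshold: float = 0.05
    n_perm_composition: int = 999
    n_random_network: int = 200
    sparcc_iterations: int = 20
    network_max_features: int = 80  # SparCC feature cap per group network
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_prevalence", "consensus_primary", "consensus_secondary", "r_threshold", "p_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on a freshly generated synthetic cohort; returns a
    report dict of the headline quantities and writes everything under
    ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {}

    def stage(name):
        def deco(fn):
            try:
                entry = {"stage": name}
                fn(entry)
                log.append(entry)
            except Exception as exc:  # abort, keep partial outputs
                raise StageError(name, exc) from exc

        return deco

    state: dict = {}

    @stage("simulate")
    def _(entry):
        counts, relab, metadata, truth = generate_cohort(config.cohort)
        # constipation flag tied to the planted features (slope 0 when none planted)
        anchor = list(truth.differential_features) or list(relab.columns[:5])
        effect = -0.3 if truth.differential_features else 0.0
        metadata = generate_constipation_layer(
            metadata, relab[anchor].sum(axis=1), effect_log2=effect, seed=config.cohort.seed + 1
        )
        write_abundance_table(counts, outdir / "counts.tsv")
        write_abundance_table(relab, outdir / "relabund.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        truth.to_json(outdir / "truth.json")
        state.update(counts=counts, relab=relab, metadata=metadata, truth=truth)
        entry.update(seed=config.cohort.seed, n_samples=len(metadata), n_features=counts.shape[1])

    @stage("cohort_stats")
    def _(entry):
        md = state["metadata"]
        variables = [("total_sequence_count", "quantitative")] + [
            (c.name, "categorical") for c in config.cohort.covariate_specs
        ]
        tab = cohort_stats.metadata_table(md, variables)
        tab.to_csv(outdir / "table1.tsv", sep="\t", index=False)
        state["table1"] = tab
        entry.update(n_variables=len(tab))

    @stage("composition")
    def _(entry):
        counts, md = state["counts"], state["metadata"]
        clr = composition.clr_transform(counts)
        pca = composition.aitchison_pca(clr)
        pca.scores.iloc[:, :10].to_csv(outdir / "pca_scores.tsv", sep="\t")
        from scipy.spatial.distance import squareform, pdist

        dist = squareform(pdist(clr.to_numpy()))
        labels = md[diffabund.CASE_TERM].to_numpy()
        seq = (md["total_sequence_count"].to_numpy(float) - md["total_sequence_count"].mean()) / md[
            "total_sequence_count"
        ].std()
        perma = composition.permanova(dist, labels, covariates=seq[:, None], n_perm=config.n_perm_composition, seed=config.seed)
        disp = composition.permdisp(dist, labels, n_perm=config.n_perm_composition, seed=config.seed + 1)
        report["permanova"] = {"F": perma.statistic, "p": perma.p_value, "n_perm": perma.n_permutations}
        report["permdisp"] = {"F": disp.statistic, "p": disp.p_value, "n_perm": disp.n_permutations}
        with open(outdir / "composition_tests.json", "w") as fh:
            json.dump({"permanova": report["permanova"], "permdisp": report["permdisp"]}, fh, indent=1)
        entry.update(n_perm=config.n_perm_composition)

    @stage("diffabund")
    def _(entry):
        counts, relab, md, truth = state["counts"], state["relab"], state["metadata"], state["truth"]
        kept = diffabund.prevalence_filter(relab, config.min_prevalence)
        feats = kept.columns
        da_lm = diffabund.lm_log2_relab(kept, md, TECHNICAL_TERMS)
        da_bc = diffabund.bias_corrected_da(counts[feats], md, TECHNICAL_TERMS)
        calls = diffabund.consensus_calls(da_lm, da_bc, config.consensus_primary, config.consensus_secondary)
        merged = da_lm.add_suffix("_lm").join(da_bc.add_suffix("_bc")).join(calls[["direction", "tier", "called"]])
        merged.to_csv(outdir / "mwas_species.tsv", sep="\t")
        state.update(da_lm=da_lm, da_bc=da_bc, calls=calls, tested_features=list(feats))
        called = set(calls.index[calls["called"]])
        planted = set(truth.differential_features) & set(feats)
        tp = len(called & planted)
        confusion = {
            "tp": tp,
            "fp": len(called - planted),
            "fn": len(planted - called),
            "tn": len(set(feats) - called - planted),
        }
        report["consensus"] = {
            "n_tested": len(feats),
            "n_called": int(calls["called"].sum()),
            "confusion": confusion,
        }
        pd.Series(confusion).to_csv(outdir / "confusion.tsv", sep="\t", header=False)
        entry.update(n_in=relab.shape[1], n_tested=len(feats), n_called=int(calls["called"].sum()))

    @stage("network")
    def _(entry):
        counts, md, calls = state["counts"], state["metadata"], state["calls"]
        summaries = {}
        for group in ("case", "control"):
            sub = counts.loc[md[diffabund.CASE_TERM] == group]
            detected = sub.columns[(sub > 0).any(axis=0)]
            if len(detected) > config.network_max_features:
                order = sub[detected].sum(axis=0).sort_values(ascending=False)
                detected = order.index[: config.network_max_features]
            sub = sub[detected]
            r = network.sparcc(sub, n_iterations=config.sparcc_iterations, seed=config.seed + 10)
            perm_p = network.permutation_pvalues(
                sub, r, n_random=config.n_random_network, seed=config.seed + 11,
                n_iterations=max(config.sparcc_iterations // 4, 5),
            )
            net = network.build_network(r, perm_p, config.r_threshold, config.p_threshold)
            network.louvain_clusters(net, seed=config.seed + 12)
            summary = network.map_hits(net, calls)
            edges = pd.DataFrame(net.edges, columns=["feature_i", "feature_j", "r"])
            edges.to_csv(outdir / f"network_edges_{group}.tsv", sep="\t", index=False)
            nodes = pd.DataFrame(
                {
                    "feature": list(net.graph.nodes),
                    "cluster": [net.cluster_id[n] for n in net.graph.nodes],
                    "degree": [net.degree[n] for n in net.graph.nodes],
                    "hit": [net.hit_annotation[n] for n in net.graph.nodes],
                }
            )
            nodes.to_csv(outdir / f"network_nodes_{group}.tsv", sep="\t", index=False)
            network.export_graphml(net, outdir / f"network_{group}.graphml")
            summaries[group] = {"n_edges": len(net.edges), "n_nodes": net.graph.number_of_nodes(),
                                "n_clusters": len(set(net.cluster_id.values()))}
            state[f"network_{group}"] = net
            if not summary.empty:
                summary.to_csv(outdir / f"network_clusters_{group}.tsv", sep="\t", index=False)
        report["network"] = summaries
        entry.update(**{f"{g}_edges": s["n_edges"] for g, s in summaries.items()})

    @stage("grouped_tests")
    def _(entry):
        relab, md, truth = state["relab"], state["metadata"], state["truth"]
        results = {}
        clusters = sorted(set(truth.cluster_assignment.values()))
        if clusters:
            members = [f for f, c in truth.cluster_assignment.items() if c == clusters[0]]
            vec = grouped.collapse_features(relab, members)
            res = grouped.grouped_lm_test(
                vec, md, TECHNICAL_TERMS, group_name=f"cluster_{clusters[0]}", n_features=len(members)
            )
            results[res.group_name] = res
        if "constipation" in md.columns:
            spor_feats = list(truth.differential_features) or list(relab.columns[:5])
            spor = grouped.sporulation_constipation_analysis(relab, spor_feats, md)
            results.update({f"sporulation/{k}": v for k, v in spor.items()})
        rows = [
            {
                "test": name, "group": r.group_name, "n_features": r.n_features_collapsed,
                "fold_change": r.fold_change, "ci_lo": r.ci[0], "ci_hi": r.ci[1], "p": r.p_value,
            }
            for name, r in results.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "grouped_tests.tsv", sep="\t", index=False)
        report["grouped_tests"] = {name: {"fold_change": r.fold_change, "p": r.p_value} for name, r in results.items()}
        entry.update(n_tests=len(rows))

    run_log = {
        "package_version": gutmwas.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "thresholds": {
            "min_prevalence": config.min_prevalence,
            "consensus": [config.consensus_primary, config.consensus_secondary],
            "network": [config.r_threshold, config.p_threshold],
        },
        "stages": log,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    report["run_log"] = run_log
    return report
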