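"""Synthetic case/control metagenome cohorts with planted, recorded effects.

The generator emulates processed shotgun-metagenomics tables (a species x
sample count table plus a parallel relative-abundance table and per-sample
metadata) for a two-group cohort, and returns a ground-truth record of
everything planted, so that downstream differential-abundance, network and
grouped tests can be validated by recovery rather than by fixture files.

Model
-----
Per sample *s* and feature *f*, the latent natural-log absolute abundance is

    L_sf = alpha_f + I(case_s) * ln(2) * lfc_f + sigma_c * g_{s,c(f)} + eps_sf

where ``alpha_f`` is a feature baseline, ``lfc_f`` a planted log2 fold change
(zero for non-differential features), ``g_{s,c}`` a per-sample standard-normal
latent factor shared by all members of correlation cluster *c* (scaled by
``latent_factor_sd``), and ``eps_sf`` i.i.d. residual noise. Counts are drawn
multinomially from the closed composition ``softmax(L_s)`` at a log-normal
per-sample depth, which composes planted fold changes, cluster correlation and
per-sample sampling-fraction variation additively on the log scale — matching
the additive log-scale models fitted downstream.

The true sampling fraction recorded for each sample is
``y_s = ln(depth_s) - ln(sum_f exp(L_sf))``, mean-centered: the offset that
relates expected observed counts to latent absolute abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from gutmwas.exceptions import AlignmentError, ConfigurationError

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_constipation_layer",
]


@dataclass(frozen=True)
class CovariateSpec:
    """A binary covariate drawn conditionally on case status.

    ``target_odds_ratio`` is realized in expectation by a logistic draw:
    control prevalence is ``control_prevalence`` and case odds are
    ``target_odds_ratio`` times control odds.
    """

    name: str
    target_odds_ratio: float
    control_prevalence: float

    def case_prevalence(self) -> float:
        odds = self.target_odds_ratio * self.control_prevalence / (1.0 - self.control_prevalence)
        return odds / (1.0 + odds)


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort.

    Defaults emulate the study conditions of a two-group cohort at desk scale:
    200 cases / 200 controls, 257 species-level features, 20 planted effects
    with |log2 FC| in [1, 2] and random sign, sequencing depth log-normal
    around 36 M reads, and a detection limit of 1e-5 relative abundance.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_features: int = 257
    depth_log_mean: float = float(np.log(3.6e7))  # ln reads per sample
    depth_log_sd: float = 0.5
    baseline_log_abundance_sd: float = 2.0  # spread of feature baselines, ln units
    sample_log_noise_sd: float = 1.0  # per-sample residual noise, ln units
    n_differential: int = 20
    log2_fc_range: tuple[float, float] = (1.0, 2.0)  # |log2 FC| magnitudes; sign random
    # planted effects go on minor taxa only (expected baseline composition share
    # at most this value): fold changes are specified on the relative scale, and
    # planting on a dominant taxon would let compositional closure distort both
    # the planted effect and every null feature
    differential_max_share: float = 0.005
    n_clusters: int = 0
    cluster_size_range: tuple[int, int] = (5, 10)
    latent_factor_sd: float = 0.8  # gives within-cluster ln-abundance r ~ 0.4 at noise sd 1
    detection_limit: float = 1e-5  # relative abundance below which a feature is undetected
    covariate_specs: Sequence[CovariateSpec] = field(default_factory=tuple)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigurationError("need at least 2 cases and 2 controls")
        if not (0.0 <= self.detection_limit < 1.0):
            raise ConfigurationError("detection_limit must be in [0, 1)")
        lo, hi = self.log2_fc_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("log2_fc_range must be positive magnitudes (sign is drawn)")
        if self.n_differential > self.n_features:
            raise ConfigurationError("more differential features than features")
        if self.n_clusters > 0:
            if self.cluster_size_range[0] < 2:
                raise ConfigurationError("clusters need at least 2 members")
            if self.n_clusters * self.cluster_size_range[1] > self.n_features:
                raise ConfigurationError(
                    f"{self.n_clusters} clusters of up to {self.cluster_size_range[1]} "
                    f"features exceed n_features={self.n_features}"
                )


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    differential_features: dict[str, float]  # feature -> signed planted log2 FC
    cluster_assignment: dict[str, int]  # feature -> cluster id (absent = none)
    covariate_or: dict[str, float]
    sampling_fraction: pd.Series  # per sample, ln units, mean-centered

    def to_json(self, path) -> None:
        payload = {
            "differential_features": self.differential_features,
            "cluster_assignment": self.cluster_assignment,
            "covariate_or": self.covariate_or,
            "sampling_fraction": self.sampling_fraction.round(10).to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: (counts, relative abundances, metadata, truth).

    Tables are samples x features. Relative-abundance rows sum to 1 within
    1e-9 after detection-limit zeroing and renormalization. A single RNG
    stream seeded from ``config.seed`` drives every draw, in the fixed order:
    baselines, differential features, clusters, depths, latent factors,
    residual noise, multinomial counts, covariates — so identical configs
    give identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    f = config.n_features
    samples = [f"case_{i + 1:04d}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(config.n_controls)
    ]
    features = [f"sp_{j + 1:04d}" for j in range(f)]
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    # 1) feature baselines (ln relative scale)
    alpha = rng.normal(0.0, config.baseline_log_abundance_sd, size=f)

    # 2) planted effects: signed log2 fold changes on case samples, drawn from
    # features whose expected composition share stays below the dominance cap
    lfc = np.zeros(f)
    share = np.exp(alpha) / np.exp(alpha).sum()
    eligible = np.flatnonzero(share <= config.differential_max_share)
    if len(eligible) < config.n_differential:
        raise ConfigurationError(
            f"only {len(eligible)} features fall below differential_max_share="
            f"{config.differential_max_share}; cannot plant {config.n_differential}"
        )
    diff_idx = eligible[rng.choice(len(eligible), size=config.n_differential, replace=False)]
    if config.n_differential:
        mags = rng.uniform(*config.log2_fc_range, size=config.n_differential)
        signs = rng.choice([-1.0, 1.0], size=config.n_differential)
        lfc[diff_idx] = mags * signs

    # 3) disjoint correlation clusters
    cluster_of = np.full(f, -1, dtype=int)
    pool = rng.permutation(f)
    cursor = 0
    for c in range(config.n_clusters):
        size = int(rng.integers(config.cluster_size_range[0], config.cluster_size_range[1] + 1))
        members = pool[cursor : cursor + size]
        cluster_of[members] = c
        cursor += size

    # 4) per-sample depth
    depth = np.maximum(1, np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=n))).astype(
        np.int64
    )

    # 5) latent cluster factors, 6) residual noise
    g = rng.normal(size=(n, max(config.n_clusters, 1)))
    eps = rng.normal(0.0, config.sample_log_noise_sd, size=(n, f))

    log_abs = alpha[None, :] + np.log(2.0) * lfc[None, :] * is_case[:, None] + eps
    clustered = cluster_of >= 0
    if clustered.any():
        log_abs[:, clustered] += config.latent_factor_sd * g[:, cluster_of[clustered]]

    # closure + multinomial sampling
    comp = np.exp(log_abs - log_abs.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty((n, f), dtype=np.int64)
    for s in range(n):
        counts[s] = rng.multinomial(depth[s], comp[s])

    # true sampling fractions: ln depth - ln total absolute abundance, centered
    log_total_abs = np.log(np.exp(log_abs - log_abs.max(axis=1, keepdims=True)).sum(axis=1)) + log_abs.max(
        axis=1
    )
    y_true = np.log(depth.astype(float)) - log_total_abs
    y_true -= y_true.mean()

    # detection limit applied consistently to both tables
    rel = counts / counts.sum(axis=1, keepdims=True)
    if config.detection_limit > 0:
        undetected = rel < config.detection_limit
        counts[undetected] = 0
        rel = np.where(undetected, 0.0, rel)
        rel = rel / rel.sum(axis=1, keepdims=True)

    count_table = pd.DataFrame(counts, index=samples, columns=features)
    relab_table = pd.DataFrame(rel, index=samples, columns=features)

    metadata = pd.DataFrame(
        {
            "case_status": np.where(is_case, "case", "control"),
            "collection_kit": "kit_A",
            "total_sequence_count": depth,
        },
        index=samples,
    )
    covariate_or: dict[str, float] = {}
    for spec in config.covariate_specs:
        prev = np.where(is_case, spec.case_prevalence(), spec.control_prevalence)
        metadata[spec.name] = (rng.random(n) < prev).astype(int)
        covariate_or[spec.name] = spec.target_odds_ratio

    truth = SyntheticTruth(
        differential_features={features[j]: float(lfc[j]) for j in sorted(diff_idx)},
        cluster_assignment={features[j]: int(cluster_of[j]) for j in range(f) if cluster_of[j] >= 0},
        covariate_or=covariate_or,
        sampling_fraction=pd.Series(y_true, index=samples, name="sampling_fraction"),
    )
    return count_table, relab_table, metadata, truth


def generate_constipation_layer(
    metadata: pd.DataFrame,
    ko_group_abundance: pd.Series,
    effect_log2: float,
    seed: int,
    case_prevalence: float = 0.44,
    control_prevalence: float = 0.12,
) -> pd.DataFrame:
    """Add a binary ``constipation`` flag tied to a collapsed KO-group abundance.

    The flag's log-odds vary linearly with centered log2 abundance at slope
    ``effect_log2`` (a negative slope makes low-abundance samples more likely
    constipated), around group baselines whose defaults mirror observed
    prevalences of 44% in cases and 12% in controls. With ``effect_log2=0``
    the flag is independent of abundance.
    """
    if not metadata.index.equals(ko_group_abundance.index):
        raise AlignmentError("ko_group_abundance is not aligned with metadata samples")
    rng = np.random.default_rng(seed)
    nonzero = ko_group_abundance[ko_group_abundance > 0]
    pseudo = (nonzero.min() / 2.0) if len(nonzero) else 1e-9
    x = np.log2(ko_group_abundance.to_numpy(float) + pseudo)
    x = x - x.mean()
    is_case = (metadata["case_status"] == "case").to_numpy()
    base = np.where(
        is_case,
        np.log(case_prevalence / (1 - case_prevalence)),
        np.log(control_prevalence / (1 - control_prevalence)),
    )
    p = 1.0 / (1.0 + np.exp(-(base + effect_log2 * x)))
    out = metadata.copy()
    out["constipation"] = (rng.random(len(out)) < p).astype(int)
    return out


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["covariate_specs"] = [asdict(s) for s in config.covariate_specs]
    return d
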