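"""MWAS engine: filtering, both models, FDR, sampling fractions, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmwas import CohortConfig, generate_cohort
from gutmwas import diffabund as da
from tests.conftest import TECHNICAL_TERMS, make_counts


class TestPrevalenceFilter:
    def test_five_percent_boundary(self, rng):
        # 36/724 samples (4.97%) is dropped; 37/724 (5.11%) is kept
        n = 724
        arr = np.zeros((n, 2))
        arr[:36, 0] = 1
        arr[:37, 1] = 1
        kept = da.prevalence_filter(make_counts(arr), 0.05)
        assert list(kept.columns) == ["f1"]

    def test_zero_threshold_is_identity(self, rng):
        tab = make_counts(rng.integers(0, 3, size=(20, 10)))
        pd.testing.assert_frame_equal(da.prevalence_filter(tab, 0.0), tab)

    def test_kept_set_matches_brute_force(self, rng):
        tab = make_counts(rng.integers(0, 2, size=(40, 30)))
        kept = da.prevalence_filter(tab, 0.2)
        brute = [c for c in tab.columns if (tab[c] > 0).sum() >= 0.2 * len(tab)]
        assert list(kept.columns) == brute

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            da.prevalence_filter(make_counts(np.zeros((10, 3))), 0.05)


class TestLinearModels:
    def test_fold_change_round_trips_to_beta(self, planted_cohort):
        counts, relab, md, _ = planted_cohort
        kept = da.prevalence_filter(relab)
        lm = da.lm_log2_relab(kept, md, TECHNICAL_TERMS)
        bc = da.bias_corrected_da(counts[kept.columns], md, TECHNICAL_TERMS)
        assert np.allclose(np.log2(lm["fold_change"]), lm["beta"], atol=1e-12)
        assert np.allclose(np.log(bc["fold_change"]), bc["beta"], atol=1e-12)
        assert (lm["fold_change"] > 0).all() and (bc["fold_change"] > 0).all()

    def test_planted_effects_recovered_by_both_models(self, planted_cohort):
        counts, relab, md, truth = planted_cohort
        kept = da.prevalence_filter(relab)
        lm = da.lm_log2_relab(kept, md, TECHNICAL_TERMS)
        bc = da.bias_corrected_da(counts[kept.columns], md, TECHNICAL_TERMS)
        planted = {f: l for f, l in truth.differential_features.items() if f in kept.columns}
        lm_err = [lm.loc[f, "beta"] - l for f, l in planted.items()]
        bc_err = [bc.loc[f, "beta"] / np.log(2) - l for f, l in planted.items()]
        assert abs(np.mean(lm_err)) < 0.3
        assert abs(np.mean(bc_err)) < 0.3

    def test_null_ci_brackets_one(self, small_null_cohort):
        _, relab, md, _ = small_null_cohort
        lm = da.lm_log2_relab(da.prevalence_filter(relab), md, TECHNICAL_TERMS)
        frac = ((lm["fc_lo"] <= 1) & (1 <= lm["fc_hi"])).mean()
        assert frac > 0.9  # ~95% coverage under the null

    def test_matches_statsmodels_single_feature(self, small_null_cohort):
        import statsmodels.api as sm

        _, relab, md, _ = small_null_cohort
        kept = da.prevalence_filter(relab)
        lm = da.lm_log2_relab(kept, md, TECHNICAL_TERMS)
        f = kept.columns[3]
        pseudo = da.feature_pseudocounts(kept)[f]
        y = np.log2(kept[f].to_numpy() + pseudo)
        x, names = da.build_design(md, TECHNICAL_TERMS)
        fit = sm.OLS(y, x).fit()
        j = names.index("case_status")
        assert lm.loc[f, "beta"] == pytest.approx(fit.params[j], rel=1e-10)
        assert lm.loc[f, "se"] == pytest.approx(fit.bse[j], rel=1e-10)
        assert lm.loc[f, "p"] == pytest.approx(fit.pvalues[j], rel=1e-8)


class TestSamplingFractions:
    def test_scaled_sample_shifts_by_one_log_unit(self, rng):
        base = rng.integers(50, 5000, size=(20, 100))
        scaled = base.astype(float)
        scaled[3] = np.round(scaled[3] * np.e)
        sf = da.estimate_sampling_fractions(make_counts(scaled), ["g"] * 20)
        others = np.delete(sf.y.to_numpy(), 3)
        assert sf.y.iloc[3] - others.mean() == pytest.approx(1.0, abs=0.1)

    def test_identical_samples_give_zero_offsets(self):
        arr = np.tile(np.arange(1, 21), (10, 1))
        sf = da.estimate_sampling_fractions(make_counts(arr), ["g"] * 10)
        assert np.allclose(sf.y, 0.0, atol=1e-9)
        assert sf.converged

    def test_truth_recovery_correlation(self):
        cfg = CohortConfig(n_cases=100, n_controls=100, n_features=100, n_differential=0, seed=17)
        counts, _, md, truth = generate_cohort(cfg)
        sf = da.estimate_sampling_fractions(counts, md["case_status"].to_numpy())
        assert np.corrcoef(sf.y, truth.sampling_fraction)[0, 1] > 0.9

    def test_offsets_are_centered(self, small_null_cohort):
        counts, _, md, _ = small_null_cohort
        sf = da.estimate_sampling_fractions(counts, md["case_status"].to_numpy())
        assert abs(sf.y.mean()) < 1e-9


class TestBiasCorrectedAbundances:
    def test_zero_offsets_recover_counts_plus_one(self):
        counts = make_counts([[0, 5], [2, 7]])
        sf = da.SamplingFractions(pd.Series(0.0, index=counts.index), True, 1)
        out = da.bias_corrected_abundances(counts, sf)
        assert np.allclose(out, counts.to_numpy() + 1.0)

    def test_spot_cell(self):
        counts = make_counts([[9]])
        sf = da.SamplingFractions(pd.Series([0.5], index=counts.index), True, 1)
        out = da.bias_corrected_abundances(counts, sf)
        assert out.iloc[0, 0] == pytest.approx(np.exp(np.log(10.0) - 0.5))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = da.bh_fdr(pd.Series([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_is_unchanged(self):
        assert da.bh_fdr(pd.Series([0.2])).iloc[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_naive_quadratic_oracle(self, pvals):
        q = da.bh_fdr(pd.Series(pvals)).to_numpy()
        m = len(pvals)
        sp = sorted(pvals)
        naive = [
            min(min(sp[j] * m / (j + 1) for j in range(m) if sp[j] >= p), 1.0)
            for p in pvals
        ]
        assert np.allclose(q, naive, atol=1e-12)

    def test_nan_propagates(self):
        q = da.bh_fdr(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(q.iloc[1]) and np.isfinite(q.iloc[0])


class TestConsensus:
    @staticmethod
    def _da(qs, betas):
        feats = [f"f{i}" for i in range(len(qs))]
        return pd.DataFrame({"q": qs, "beta": betas}, index=feats)

    @pytest.mark.parametrize(
        "qa,qb,called",
        [(0.04, 0.09, True), (0.04, 0.2, False), (0.06, 0.06, False), (0.04, 0.04, True)],
    )
    def test_rule_application(self, qa, qb, called):
        calls = da.consensus_calls(self._da([qa], [1.0]), self._da([qb], [1.0]))
        assert bool(calls["called"].iloc[0]) is called

    def test_tiers(self):
        calls = da.consensus_calls(self._da([0.04, 0.04], [1, 1]), self._da([0.04, 0.09], [1, 1]))
        assert list(calls["tier"]) == ["both<0.05", "primary<0.05&other<=0.1"]

    def test_discordant_signs_demoted_with_warning(self):
        with pytest.warns(UserWarning, match="discordant"):
            calls = da.consensus_calls(self._da([0.01], [1.0]), self._da([0.01], [-1.0]))
        assert not calls["called"].iloc[0]
        assert calls["direction"].iloc[0] == "none"


class TestCovariateRerun:
    def test_independent_extra_term_keeps_calls(self, planted_cohort):
        counts, relab, md, truth = planted_cohort
        kept = da.prevalence_filter(relab)
        planted = [f for f in truth.differential_features if f in kept.columns]
        case_tab, symbols, n_case, n_control = da.covariate_rerun(
            planted, kept, md, ["collection_kit", "laxatives"]
        )
        assert (case_tab["q"] < 0.1).mean() > 0.8
        assert n_case == 200 and n_control == 200
        assert "laxatives" in symbols.columns

    def test_fully_confounded_covariate_raises_named_error(self, planted_cohort):
        _, relab, md, truth = planted_cohort
        md = md.copy()
        md["shadow"] = (md["case_status"] == "case").astype(float)
        feats = list(relab.columns[:5])
        with pytest.raises(ValueError, match="shadow"):
            da.covariate_rerun(feats, relab, md, ["shadow"])

    def test_listwise_deletion_counts(self, planted_cohort):
        _, relab, md, _ = planted_cohort
        md = md.copy()
        md.loc[md.index[:10], "laxatives"] = np.nan
        feats = list(relab.columns[:5])
        _, _, n_case, n_control = da.covariate_rerun(feats, relab, md, ["laxatives"])
        assert n_case + n_control == len(md) - 10
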