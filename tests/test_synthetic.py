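"""Generators: determinism, planted truth, noise models."""

import numpy as np
import pandas as pd
import pytest

from pdcscreen import synthetic
from pdcscreen.cohort_stats import logrank_test
from pdcscreen.dose_response import derive_ic50, fit_4pl
from pdcscreen.variant_filter import apply_filters, summarize_spectrum


class TestDeterminism:
    def test_variant_tables_byte_identical(self, tmp_path):
        spec = synthetic.CohortSpec(n_samples=15, seed=9)
        a = synthetic.generate_variant_candidates(spec, artifact_rate=0.2)
        b = synthetic.generate_variant_candidates(spec, artifact_rate=0.2)
        fa, fb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(fa, sep="\t", index=False)
        b.to_csv(fb, sep="\t", index=False)
        assert fa.read_bytes() == fb.read_bytes()

    def test_all_generators_reproducible(self):
        spec = synthetic.CoverageSimSpec(n_bins=200, seed=4)
        pd.testing.assert_frame_equal(
            synthetic.generate_coverage(spec), synthetic.generate_coverage(spec)
        )
        panel = synthetic.PanelSpec(n_lines=4, drugs=("palbociclib", "d2"),
                                    planted_effects=(),
                                    event_carrier_counts={"G:loss": 2})
        alt = synthetic.generate_panel_alterations(panel, seed=1)
        pd.testing.assert_frame_equal(
            synthetic.generate_viability(panel, alt, seed=2),
            synthetic.generate_viability(panel, alt, seed=2),
        )
        pd.testing.assert_frame_equal(
            synthetic.generate_survival({"a": 10}, {"a": 0.1}, 0.3, seed=3),
            synthetic.generate_survival({"a": 10}, {"a": 0.1}, 0.3, seed=3),
        )


class TestVariantGeneration:
    def test_zero_artifact_rate_all_pass(self):
        spec = synthetic.CohortSpec(n_samples=25, seed=1)
        cands = synthetic.generate_variant_candidates(spec, artifact_rate=0.0)
        _, decisions = apply_filters(cands)
        assert decisions["pass"].all()

    def test_artifacts_fail_exactly_their_named_criterion(self):
        spec = synthetic.CohortSpec(n_samples=40, seed=2)
        cands = synthetic.generate_variant_candidates(spec, artifact_rate=0.35)
        _, decisions = apply_filters(cands)
        artifacts = cands[cands["is_artifact"]]
        assert len(artifacts) > 50
        assert (
            decisions.loc[artifacts.index, "failed_criteria"]
            == artifacts["violated_criterion"]
        ).all()
        assert decisions.loc[~cands["is_artifact"], "pass"].all()

    def test_normal_vaf_artifacts_exceed_threshold(self):
        spec = synthetic.CohortSpec(n_samples=60, seed=3)
        cands = synthetic.generate_variant_candidates(spec, artifact_rate=0.5)
        nv = cands[cands["violated_criterion"] == "max_normal_vaf"]
        assert len(nv) > 0
        assert (nv["normal_vaf"] > 0.03).all()

    def test_invalid_rate_rejected(self):
        spec = synthetic.CohortSpec(n_samples=5, seed=1)
        with pytest.raises(ValueError, match="artifact_rate"):
            synthetic.generate_variant_candidates(spec, artifact_rate=1.5)

    def test_ct_transition_is_modal(self):
        spec = synthetic.CohortSpec(n_samples=100, seed=5)
        cands = synthetic.generate_variant_candidates(spec)
        retained, _ = apply_filters(cands)
        subs = summarize_spectrum(retained)["substitution"]
        assert subs.idxmax() == "C>T"


class TestCoverageGeneration:
    def test_noise_free_flat_ratio_exactly_one(self):
        spec = synthetic.CoverageSimSpec(n_bins=100, noise="none", seed=0)
        cov = synthetic.generate_coverage(spec)
        assert np.allclose(cov["tumor_count"] / cov["normal_count"], 1.0)

    def test_noise_free_planted_segment_ratio_exact(self):
        spec = synthetic.CoverageSimSpec(
            n_bins=100, planted_segments=((20, 40, 1.0),), noise="none", seed=0
        )
        cov = synthetic.generate_coverage(spec)
        ratio = cov["tumor_count"] / cov["normal_count"]
        assert np.allclose(ratio[20:40], 2.0)
        assert np.allclose(np.delete(ratio.to_numpy(), np.s_[20:40]), 1.0)

    def test_noisy_segment_mean_within_three_se(self):
        spec = synthetic.CoverageSimSpec(
            n_bins=2000, planted_segments=((500, 700, 1.0),),
            depth_mean=100.0, seed=8,
        )
        cov = synthetic.generate_coverage(spec)
        lr = np.log2(cov["tumor_count"][500:700] / cov["normal_count"][500:700])
        # per-bin variance of log2 ratio ~ (1/mu_t + 1/mu_n) / ln(2)^2
        mu_n = 100.0 * synthetic.default_gc_bias(cov["gc"][500:700].to_numpy())
        var_bin = (1 / (2 * mu_n) + 1 / mu_n) / np.log(2) ** 2
        se = np.sqrt(var_bin.mean() / 200)
        assert abs(lr.mean() - 1.0) < 3 * se

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthetic.CoverageSimSpec(
                n_bins=100, planted_segments=((10, 30, 1.0), (25, 40, -1.0))
            )


class TestViabilityGeneration:
    def test_exact_dilution_series_from_top_dose(self, small_panel):
        alt = synthetic.generate_panel_alterations(small_panel, seed=0)
        viab = synthetic.generate_viability(small_panel, alt, seed=0)
        one = viab[(viab["line"] == "PDC01") & (viab["drug"] == "palbociclib")
                   & (viab["replicate"] == 1)]
        conc = one["concentration_uM"].to_numpy()
        assert len(conc) == 10
        assert conc[0] == 10.0
        assert np.allclose(conc[:-1] / conc[1:], 3.3)

    def test_quadruplicate_wells(self, small_panel):
        alt = synthetic.generate_panel_alterations(small_panel, seed=0)
        viab = synthetic.generate_viability(small_panel, alt, seed=0)
        assert set(viab["replicate"]) == {1, 2, 3, 4}

    def test_noise_free_fit_recovers_planted_fold(self):
        panel = synthetic.PanelSpec(cv_noise=0.0, base_ic50=5.0)
        alt = synthetic.generate_panel_alterations(panel, seed=1)
        viab = synthetic.generate_viability(panel, alt, seed=1)
        carriers = alt.index[alt["CDKN2AB:loss"] == 1]
        one = viab[(viab["line"] == carriers[0])
                   & (viab["drug"] == "palbociclib")
                   & (viab["replicate"] == 1)]
        p = fit_4pl(one["concentration_uM"].to_numpy(), one["viability"].to_numpy())
        r = derive_ic50(p, (one["concentration_uM"].min(),
                            one["concentration_uM"].max()))
        assert r.ic50 == pytest.approx(5.0 * 0.05, rel=1e-6)

    def test_noise_free_non_carrier_at_base(self):
        panel = synthetic.PanelSpec(cv_noise=0.0, base_ic50=5.0)
        alt = synthetic.generate_panel_alterations(panel, seed=1)
        viab = synthetic.generate_viability(panel, alt, seed=1)
        non_carrier = alt.index[alt["CDKN2AB:loss"] == 0][0]
        one = viab[(viab["line"] == non_carrier)
                   & (viab["drug"] == "palbociclib")
                   & (viab["replicate"] == 1)]
        p = fit_4pl(one["concentration_uM"].to_numpy(), one["viability"].to_numpy())
        r = derive_ic50(p, (one["concentration_uM"].min(),
                            one["concentration_uM"].max()))
        assert r.ic50 == pytest.approx(5.0, rel=1e-6)

    def test_planted_effect_on_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="unknown drug"):
            synthetic.PanelSpec(
                drugs=("a", "b"),
                planted_effects=(("zzz", "G:loss", 0.1),),
                event_carrier_counts={"G:loss": 2},
            )


class TestSurvivalGeneration:
    def test_zero_censoring_all_events(self):
        surv = synthetic.generate_survival({"a": 30, "b": 30},
                                           {"a": 0.1, "b": 0.2},
                                           censor_rate=0.0, seed=1)
        assert (surv["event"] == 1).all()

    def test_equal_hazards_calibrated_rejection_rate(self):
        """Log-rank on null data rejects at ~ the nominal 5% level."""
        n_reps = 400
        rejections = 0
        for seed in range(n_reps):
            surv = synthetic.generate_survival(
                {"a": 30, "b": 30}, {"a": 0.1, "b": 0.1},
                censor_rate=0.1, seed=seed,
            )
            _, p = logrank_test(surv)
            rejections += p < 0.05
        rate = rejections / n_reps
        # 3 SE binomial band around 0.05
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_strong_hazard_ratio_detected(self):
        ps = []
        for seed in range(10):
            surv = synthetic.generate_survival(
                {"a": 100, "b": 100}, {"a": 0.3, "b": 0.1},
                censor_rate=0.1, seed=seed,
            )
            ps.append(logrank_test(surv)[1])
        assert np.median(ps) < 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_survival({"a": 5}, {"a": -1.0})
        with pytest.raises(ValueError):
            synthetic.generate_survival({"a": 5}, {"b": 1.0})
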