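"""Dual-reporter normalisation and percent-inhibition classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifscreen import (
    InhibitionClassifier,
    ReporterNormalizer,
    aggregate_replicates,
    amplicon_summaries,
    classify_secondary,
    classify_tertiary,
    normalized_activity,
    percent_inhibition,
    simulate_screen,
)
from hifscreen.simulate import SimulationConfig, reagent_table


class TestNormalizedActivity:
    def test_simple_ratio(self):
        assert normalized_activity(500, 100) == 5.0

    def test_zero_firefly_is_zero_ratio(self):
        assert normalized_activity(0, 100) == 0.0

    @pytest.mark.parametrize("renilla", [0.0, float("nan"), None])
    def test_absent_constitutive_signal_is_hard_error(self, renilla):
        with pytest.raises(ValueError, match="viability/measurement failure"):
            normalized_activity(500, renilla)


class TestPercentInhibition:
    def test_sample_at_control_mean_is_zero(self):
        assert percent_inhibition(5.0, [4.0, 6.0]) == 0.0

    def test_hand_example_fifty_percent(self):
        assert percent_inhibition(500 / 100, [1000 / 100]) == 50.0

    def test_activation_is_negative_and_retained(self):
        assert percent_inhibition(15.0, [10.0]) == -50.0

    def test_no_valid_controls_is_hard_error(self):
        with pytest.raises(ValueError, match="control"):
            percent_inhibition(1.0, [])


class TestAggregateReplicates:
    def test_equal_duplicates(self):
        assert aggregate_replicates([60, 60]) == (60.0, 0.0, 2)

    def test_sample_sd_of_duplicates(self):
        mean, sd, n = aggregate_replicates([80, 90])
        assert (mean, n) == (85.0, 2)
        assert sd == pytest.approx(7.0710678, abs=1e-6)

    def test_single_value_has_no_sd(self):
        mean, sd, n = aggregate_replicates([63.0])
        assert (mean, n) == (63.0, 1)
        assert np.isnan(sd)


class TestClassification:
    @pytest.mark.parametrize("amps,label", [
        ((80.3, 74.6), "group_A"),   # strong with one of two amplicons
        ((63.0,), "group_B"),        # single tested amplicon
        ((50.0, 50.0), "non_hit"),   # strictly-greater boundary
        ((75.0,), "group_B"),        # 75 exactly is not "over 75"
        ((96.0, 96.0), "group_A"),
        ((-30.0, 20.0), "non_hit"),  # activation never promotes
    ])
    def test_secondary_rule(self, amps, label):
        assert classify_secondary(amps) == label

    @pytest.mark.parametrize("amps,label", [
        ((38.0, 28.2), "negative"),
        ((83.3, 42.0), "positive"),  # at least one amplicon suffices
        ((50.0,), "negative"),
    ])
    def test_tertiary_rule(self, amps, label):
        assert classify_tertiary(amps) == label

    def test_inclusive_boundary_option(self):
        assert classify_secondary((75.0,), inclusive=True) == "group_A"
        assert classify_tertiary((50.0,), inclusive=True) == "positive"

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1,
                    max_size=3),
           st.floats(min_value=0, max_value=30))
    @settings(max_examples=100, deadline=None)
    def test_labels_monotone_in_inhibition(self, amps, bump):
        """Raising any amplicon's inhibition never softens the label."""
        severity = {"non_hit": 0, "group_B": 1, "group_A": 2}
        before = severity[classify_secondary(amps)]
        bumped = [amps[0] + bump] + list(amps[1:])
        assert severity[classify_secondary(bumped)] >= before

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1,
                    max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_secondary_hit_implies_tertiary_positive(self, amps):
        """Logical consistency of the two stages on identical inputs."""
        if classify_secondary(amps) != "non_hit":
            assert classify_tertiary(amps) == "positive"


class TestReporterNormalizer:
    def test_plate_factor_cancels_exactly_in_noiseless_screen(self, noiseless_sim):
        """The firefly/Renilla ratio removes the plate scale: in a noise-free
        simulation with large plate effects, percent inhibition equals the
        planted knockdown exactly."""
        cfg, ds, truth, reagents = noiseless_sim
        norm = ReporterNormalizer().fit(ds)
        summ = amplicon_summaries(norm.transform(ds), reagents)
        merged = summ.merge(truth.genes, on="gene_id")
        regs = merged["true_class"] == "hif_regulator"
        np.testing.assert_allclose(
            merged.loc[regs, "mean_inhibition"],
            100 * merged.loc[regs, "knockdown"], atol=1e-9)
        np.testing.assert_allclose(
            merged.loc[merged["true_class"] != "hif_regulator",
                       "mean_inhibition"], 0, atol=1e-9)

    def test_scale_invariance_of_percent_inhibition(self, noiseless_sim):
        """Multiplying both channels of a plate by c > 0 changes nothing."""
        cfg, ds, _, reagents = noiseless_sim
        summ0 = amplicon_summaries(
            ReporterNormalizer().fit(ds).transform(ds), reagents)
        scaled = ds.wells.copy()
        first = scaled["plate_id"] == scaled["plate_id"].iloc[0]
        scaled.loc[first, ["firefly", "renilla"]] *= 37.5
        scaled["replicate"] = scaled["plate_id"].map(ds.replicate_map)
        summ1 = amplicon_summaries(
            ReporterNormalizer().fit(scaled).transform(scaled), reagents)
        pd.testing.assert_frame_equal(summ0, summ1)

    def test_missing_negative_controls_is_hard_error(self, toy_plate):
        no_ctrl = toy_plate[toy_plate["role"] != "negative_control"]
        with pytest.raises(ValueError, match="negative_control"):
            ReporterNormalizer().fit(no_ctrl)

    def test_failed_wells_dropped_and_counted(self, toy_plate):
        toy_plate.loc[0, "renilla"] = 0.0
        norm = ReporterNormalizer().fit(toy_plate)
        out = norm.transform(toy_plate)
        assert norm.n_failed_wells_ == 1
        assert len(out) == 3

    def test_strong_knockdown_recovers_as_group_A_across_seeds(self):
        """Planted knockdown >= 0.8 at noise_cv 0.2 lands in group A for
        >= 95% of gene-seed draws (20 seeds)."""
        total = in_a = 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=100, fraction_true_hits=0.1,
                                   hit_effect=(0.8, 0.95), noise_cv=0.2,
                                   with_renilla=True, seed=seed)
            ds, truth = simulate_screen(cfg)
            summ = amplicon_summaries(
                ReporterNormalizer().fit(ds).transform(ds), reagent_table(cfg))
            calls = InhibitionClassifier(stage="secondary").fit(summ).calls_
            group_a = set(calls.loc[calls["label"] == "group_A", "gene_id"])
            regs = truth.of_class("hif_regulator")
            total += len(regs)
            in_a += sum(g in group_a for g in regs)
        assert in_a / total >= 0.95
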