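"""Plate Z-scores, threshold hit calling, replicate correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifscreen import (
    PlateZScorer,
    call_primary_hits,
    gene_ztable,
    plate_zscores,
    replicate_correlation,
)
from hifscreen.simulate import SimulationConfig, reagent_table, simulate_screen


def _plate(values, role="sample"):
    n = len(values)
    return pd.DataFrame({
        "plate_id": ["p1"] * n,
        "row": ["A"] * n,
        "col": range(1, n + 1),
        "reagent_id": [f"r{i}" for i in range(n)],
        "role": [role] * n,
        "firefly": [float(v) for v in values],
    })


class TestPlateZScores:
    def test_hand_example_sample_sd(self):
        """{100,200,300}: sample SD is 100, so the low well sits at z=-1."""
        z = plate_zscores(_plate([100, 200, 300]))["z"]
        assert z.tolist() == [-1.0, 0.0, 1.0]

    def test_well_at_plate_mean_scores_zero(self):
        z = plate_zscores(_plate([5, 10, 15, 10]))
        assert (z.loc[z["firefly"] == 10, "z"] == 0).all()

    def test_matches_brute_force_two_pass_oracle(self):
        """On small plates, z equals the naive mean/SD computation exactly."""
        rng = np.random.default_rng(0)
        for n in (3, 5, 10):
            vals = rng.uniform(10, 1e5, size=n)
            mean = sum(vals) / n
            sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
            expected = [(v - mean) / sd for v in vals]
            got = plate_zscores(_plate(vals))["z"].to_numpy()
            np.testing.assert_array_equal(got, expected)

    @given(
        a=st.floats(min_value=0.01, max_value=1e4),
        b=st.floats(min_value=-1e5, max_value=1e5),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        """z is unchanged by x -> a*x + b with a > 0."""
        base = np.array([120.0, 340.0, 77.0, 1500.0, 990.0])
        z0 = plate_zscores(_plate(base))["z"].to_numpy()
        z1 = plate_zscores(_plate(a * base + b))["z"]
        np.testing.assert_allclose(z1.to_numpy(), z0, atol=1e-9)

    def test_plate_z_has_zero_mean_unit_sd(self, dual_sim):
        _, ds, _, _ = dual_sim
        z = plate_zscores(ds)
        for _, grp in z.groupby("plate_id"):
            assert abs(grp["z"].mean()) < 1e-9
            assert abs(grp["z"].std(ddof=1) - 1) < 1e-9

    def test_exclude_controls_standardises_on_samples_only(self):
        df = _plate([100, 200, 300])
        ctrl = _plate([1e6], role="negative_control")
        ctrl["col"] = [10]
        both = pd.concat([df, ctrl], ignore_index=True)
        z = PlateZScorer(include_controls=False).fit(both).transform(both)
        np.testing.assert_allclose(
            z.loc[z["role"] == "sample", "z"], [-1.0, 0.0, 1.0])

    def test_population_sd_option(self):
        z = plate_zscores(_plate([100, 200, 300]), ddof=0)
        np.testing.assert_allclose(z["z"].iloc[0], -np.sqrt(3 / 2))

    def test_degenerate_plate_is_hard_error(self):
        with pytest.raises(ValueError, match="zero signal SD"):
            plate_zscores(_plate([7, 7, 7]))

    def test_fewer_than_three_wells_is_hard_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            plate_zscores(_plate([1, 2]))


class TestCallPrimaryHits:
    @staticmethod
    def _ztable(*gene_reps):
        rows = [(g, rep + 1, z)
                for g, zs in gene_reps for rep, z in enumerate(zs)]
        return pd.DataFrame(rows, columns=["gene_id", "replicate", "z"])

    def test_strong_negative_z_is_hit(self):
        calls = call_primary_hits(self._ztable(("sima", (-6.4, -6.4))))
        assert calls["label"].tolist() == ["hit"]

    def test_boundary_is_strict_under_both_rules(self):
        zt = self._ztable(("g", (-2.5, -2.5)))
        for rule in ("any", "mean"):
            assert call_primary_hits(zt, rule=rule)["label"].tolist() == ["non_hit"]

    def test_any_versus_mean_rule_disagree_on_split_replicates(self):
        zt = self._ztable(("g", (-3.0, -1.0)))
        assert call_primary_hits(zt, rule="any")["label"].tolist() == ["hit"]
        assert call_primary_hits(zt, rule="mean")["label"].tolist() == ["non_hit"]

    def test_null_screen_hit_rate_below_gaussian_tail(self):
        """With no planted effects the hit fraction is small: the log-normal
        left tail is lighter than the Gaussian tail the cutoff implies."""
        cfg = SimulationConfig(n_genes=3000, fraction_true_hits=0,
                               fraction_viability=0, noise_cv=0.2, seed=11)
        ds, _ = simulate_screen(cfg)
        zt = gene_ztable(plate_zscores(ds), reagent_table(cfg))
        frac = (call_primary_hits(zt, rule="mean")["label"] == "hit").mean()
        assert frac <= 0.0062  # one-replicate Gaussian expectation at -2.5


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self):
        assert replicate_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        assert replicate_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert replicate_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_is_hard_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            replicate_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_is_hard_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            replicate_correlation([1, 2], [1, 2])
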