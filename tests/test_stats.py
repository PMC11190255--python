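"""Normalization, RFU, scaling, and the nonparametric statistics battery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bh_stepup_oracle, mann_whitney_enumeration
from oleoscreen.stats import (
    bh_adjust,
    compare_to_reference,
    compute_rfu,
    fold_change,
    lipid_content_tests,
    mann_whitney_u,
    max_abs_scale,
    normality_variance_gate,
    relative_fitness,
    rfu_table,
)
from oleoscreen.synthetic import SyntheticTruth, generate_lipid_assay


class TestNormalization:
    @pytest.mark.parametrize(
        "scfa,glucose,expected",
        [(1500.0, 1500.0, 100.0), (0.0, 1500.0, 0.0), (403.0, 1500.0, 26.87)],
    )
    def test_relative_fitness(self, scfa, glucose, expected):
        assert relative_fitness(scfa, glucose) == pytest.approx(expected, abs=0.005)

    def test_relative_fitness_missing_reference(self):
        assert np.isnan(relative_fitness(100.0, 0.0))
        assert np.isnan(relative_fitness(100.0, np.nan))

    @pytest.mark.parametrize(
        "value,ref,expected", [(10.0, 10.0, 0.0), (20.0, 10.0, 1.0), (34.5, 10.0, 2.45)]
    )
    def test_fold_change(self, value, ref, expected):
        assert fold_change(value, ref) == pytest.approx(expected)

    def test_fold_change_zero_reference_is_missing(self):
        assert np.isnan(fold_change(5.0, 0.0))


class TestRFU:
    def test_background_equal_stained_gives_zero(self):
        assert compute_rfu(100.0, 100.0, 0.5) == 0.0

    def test_arithmetic(self):
        assert compute_rfu(600.0, 100.0, 0.5) == pytest.approx(1000.0)

    def test_negative_difference_clamped(self):
        assert compute_rfu(50.0, 100.0, 0.5) == 0.0

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            compute_rfu(600.0, 100.0, 0.0)

    def test_noiseless_assay_rfu_proportional_to_planted_lipid(self):
        truths = [SyntheticTruth(f"S{i}", {}, lipid_content=x)
                  for i, x in enumerate(np.linspace(0.02, 0.4, 12))]
        assay = generate_lipid_assay(truths, seed=0, noise_cv=0.0, n_replicates=1)
        rfu = rfu_table(assay)
        planted = [t.lipid_content for t in truths]
        r = np.corrcoef(planted, rfu["rfu"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


class TestMaxAbsScale:
    def test_hand_example(self):
        out = max_abs_scale(pd.DataFrame({"x": [2.0, 4.0, -8.0]}))
        np.testing.assert_allclose(out["x"], [0.25, 0.5, -1.0])

    def test_already_scaled_identity(self):
        df = pd.DataFrame({"x": [0.5, -1.0, 0.25]})
        np.testing.assert_allclose(max_abs_scale(df)["x"], df["x"])

    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        df = pd.DataFrame({"x": [2.0, 4.0, -8.0]})
        np.testing.assert_allclose(
            max_abs_scale(c * df)["x"], max_abs_scale(df)["x"], rtol=1e-12
        )

    def test_idempotent(self):
        df = pd.DataFrame({"x": [2.0, 4.0, -8.0], "y": [1.0, 0.5, 0.1]})
        once = max_abs_scale(df)
        twice = max_abs_scale(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_column_warned_and_left(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "z": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="z"):
            out = max_abs_scale(df)
        assert (out["z"] == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_abs_scale(pd.DataFrame())


class TestGate:
    def test_identical_normal_samples_pass_levene(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 100)
        report = normality_variance_gate({"a": a, "b": a.copy()})
        assert report.levene_p > 0.05

    def test_constant_group_skipped_with_reason(self):
        report = normality_variance_gate({"c": np.full(10, 3.0),
                                          "d": np.arange(10.0)})
        assert report.shapiro_p["c"] is None
        assert "constant" in report.skipped["c"]

    def test_tiny_group_skipped(self):
        report = normality_variance_gate({"c": np.array([1.0, 2.0]),
                                          "d": np.arange(10.0)})
        assert "n=2" in report.skipped["c"]

    def test_skewed_sample_routes_nonparametric(self):
        rng = np.random.default_rng(7)
        skewed = np.exp(rng.normal(0, 1, 50))
        report = normality_variance_gate({"s": skewed, "n": rng.normal(0, 1, 50)})
        assert report.shapiro_p["s"] < 0.05
        assert report.nonparametric


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        # identical groups necessarily contain ties -> tie-corrected normal
        # approximation, which is exactly 1 at z = 0
        u, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert u == pytest.approx(8.0)  # n1*n2/2 region
        assert p == pytest.approx(1.0)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 5)
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == len(a) * len(b)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 7)]:
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            u, p = mann_whitney_u(a, b)
            u_ref, p_ref = mann_whitney_enumeration(a, b)
            assert u == u_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_adjusted_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLipidContentTests:
    def test_identical_groups_f_zero(self):
        out = lipid_content_tests([np.array([1.0, 2.0, 3.0]),
                                   np.array([1.0, 2.0, 3.0])])
        assert out["anova_f"] == 0.0
        assert out["kruskal_p"] >= 0.99

    def test_degenerate_constant_data_no_exception(self):
        out = lipid_content_tests([np.full(5, 2.0), np.full(4, 2.0)])
        assert out == {"anova_f": 0.0, "anova_p": 1.0,
                       "kruskal_h": 0.0, "kruskal_p": 1.0}

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(10, 1, 10)
        g2 = rng.normal(13, 1, 10)  # 3 SD shift
        out = lipid_content_tests([g1, g2])
        assert out["anova_p"] < 0.01
        assert out["kruskal_p"] < 0.01

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            lipid_content_tests([np.array([1.0]), np.array([1.0, 2.0])])


class TestCompareToReference:
    def make_long(self):
        rng = np.random.default_rng(0)
        rows = []
        for strain, shift in [("REF", 0.0), ("A", 2.0), ("B", 0.1)]:
            for medium in ("M1", "M2"):
                for rep in range(6):
                    rows.append({"strain_id": strain, "medium_id": medium,
                                 "variable": "fitness",
                                 "value": 10 + shift + rng.normal(0, 0.3)})
        return pd.DataFrame(rows)

    def test_table_structure_and_bh_families(self):
        table = compare_to_reference(self.make_long(), "REF")
        assert set(table["strain_id"]) == {"A", "B"}
        assert len(table) == 4  # 2 strains x 2 media
        assert (table["p_adj_bh"] >= table["p_value"] - 1e-15).all()
        assert table["bh_family"].nunique() == 2  # one family per (variable, medium)
        strong = table[table["strain_id"] == "A"]
        assert (strong["fold_change"] > 0.1).all()
        assert (strong["p_adj_bh"] < 0.05).all()

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            compare_to_reference(self.make_long(), "NOPE")
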