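import numpy as np
import pytest
from scipy.stats import chisquare

from crossconn import kc_model as kc
from crossconn.io_formats import EdgeTable

from oracles import participation_ratio_spectral


class TestObservedK:
    def kc_table(self):
        rows = [
            ("pn1", "kc1", "CA_L", 5),
            ("pn2", "kc1", "CA_L", 3),
            ("pn3", "kc1", "CA_L", 1),
            ("pn1", "kc2", "CA_L", 2),
            ("pn4", "kc2", "CA_L", 2),
            ("pn5", "kc3", "CA_L", 9),
        ]
        channels = {"pn1": "DA1", "pn2": "DL3", "pn3": "VA6", "pn4": "DA1", "pn5": "DM2"}
        return EdgeTable.from_rows(rows), channels

    def test_uniform_three_channel_wiring(self):
        rows = [(f"pn{c}", f"kc{k}", "CA_L", 2) for k in range(4) for c in range(3)]
        channels = {f"pn{c}": f"G{c}" for c in range(3)}
        t = EdgeTable.from_rows(rows)
        per, mean = kc.observed_K(t, [f"kc{k}" for k in range(4)], channels)
        assert set(per.values()) == {3} and mean == 3.0

    def test_k_bounded_by_channel_count(self, rng):
        channels = {f"pn{i}": f"G{i % 58}" for i in range(200)}
        rows = [
            (f"pn{rng.integers(0, 200)}", f"kc{rng.integers(0, 20)}", "CA_L",
             int(rng.integers(1, 5)))
            for _ in range(500)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = EdgeTable(
                __import__("pandas").DataFrame(
                    rows, columns=["pre_id", "post_id", "neuropil", "weight"]
                )
            )
        per, _ = kc.observed_K(t, [f"kc{k}" for k in range(20)], channels)
        assert max(per.values()) <= 58

    def test_threshold_sweep_matches_set_counting_oracle(self):
        t, channels = self.kc_table()
        kcs = ["kc1", "kc2", "kc3", "kc_empty"]
        for thr in (0, 1, 2, 4, 10):
            per, _ = kc.observed_K(t, kcs, channels, threshold=thr)
            # oracle: count channels with summed weight > thr per KC
            expected = {k: 0 for k in kcs}
            sums = {}
            for pre, post, _, w in t.df.itertuples(index=False):
                if post in expected and pre in channels:
                    sums[(post, channels[pre])] = sums.get((post, channels[pre]), 0) + w
            for (post, ch), w in sums.items():
                if w > thr:
                    expected[post] += 1
            assert per == expected

    def test_kc_with_no_inputs_counts_zero(self):
        t, channels = self.kc_table()
        per, _ = kc.observed_K(t, ["kc_empty"], channels)
        assert per == {"kc_empty": 0}


class TestBuildWeightMatrix:
    def test_full_k_gives_all_excitatory_entries(self):
        p = kc.KCModelParams(M=5, N=4)
        W = kc.build_weight_matrix(p, K=4, seed=0)
        np.testing.assert_allclose(W, 1 - p.alpha)

    def test_row_sums_exact(self):
        p = kc.KCModelParams(M=50, N=20)
        W = kc.build_weight_matrix(p, K=7, seed=1)
        np.testing.assert_allclose(W.sum(axis=1), 7 - 20 * p.alpha, atol=1e-12)
        vals = np.unique(np.round(W, 12))
        assert len(vals) == 2

    def test_column_usage_uniform(self):
        p = kc.KCModelParams(M=10000, N=10)
        W = kc.build_weight_matrix(p, K=3, seed=2)
        counts = (W > 0).sum(axis=0)
        assert chisquare(counts).pvalue > 0.01

    def test_k_out_of_range_rejected(self):
        p = kc.KCModelParams(M=5, N=4)
        with pytest.raises(ValueError, match="K"):
            kc.build_weight_matrix(p, K=5)


class TestDimensionality:
    def test_identity_weight_matrix_gives_full_dimension(self):
        assert kc.dimensionality(np.eye(7)) == pytest.approx(7.0)

    def test_identical_rows_give_dimension_one(self):
        W = np.tile(np.array([1.0, -0.2, 0.5]), (6, 1))
        assert kc.dimensionality(W) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_spectral_oracle(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(10, 20))
        assert kc.dimensionality(W) == pytest.approx(
            participation_ratio_spectral(W), abs=1e-9
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            kc.dimensionality(np.zeros((3, 4)))

    def test_invariant_under_channel_relabelling(self, rng):
        W = rng.normal(size=(12, 8))
        perm = rng.permutation(8)
        assert kc.dimensionality(W[:, perm]) == pytest.approx(
            kc.dimensionality(W), abs=1e-9
        )


class TestDimensionalityCurve:
    def test_single_kc_gives_constant_curve(self):
        p = kc.KCModelParams(M=1, N=6, A=0.0, realisations=5, seed=0)
        curve = kc.dimensionality_curve(p, range(1, 7))
        np.testing.assert_allclose(curve["mean_dim"], 1.0)
        assert kc.optimal_K(curve) == 1

    def test_bitwise_reproducible_under_fixed_seed(self):
        p = kc.KCModelParams(M=30, N=10, realisations=20, seed=5)
        c1 = kc.dimensionality_curve(p, range(1, 11))
        c2 = kc.dimensionality_curve(p, range(1, 11))
        assert c1.equals(c2)

    def test_curve_matches_exhaustive_small_case_oracle(self):
        """Without inhibition (alpha = 0) the mean dimensionality per K must
        match an independent exhaustive sweep: spectral participation ratio
        averaged over fresh random K-subsets drawn with a separate RNG.
        K = N collapses every row to the same all-ones vector (dim 1), so
        diversity -- small K -- is what maximises dimensionality here."""
        p = kc.KCModelParams(M=20, N=6, A=0.0, realisations=1000, seed=3)
        curve = kc.dimensionality_curve(p, range(1, 7))
        rng = np.random.default_rng(12345)
        for K in range(1, 7):
            dims = []
            for _ in range(1000):
                W = np.zeros((20, 6))
                for i in range(20):
                    W[i, rng.choice(6, K, replace=False)] = 1.0
                dims.append(participation_ratio_spectral(W))
            se = np.std(dims, ddof=1) / np.sqrt(len(dims)) if K < 6 else 1e-9
            assert abs(curve.loc[K, "mean_dim"] - np.mean(dims)) <= 4 * se + 1e-6
        assert kc.optimal_K(curve) == 1
        assert curve.loc[6, "mean_dim"] == pytest.approx(1.0)

    def test_empty_range_rejected(self):
        p = kc.KCModelParams(M=5, N=4)
        with pytest.raises(ValueError, match="range"):
            kc.dimensionality_curve(p, [])


class TestSelfConsistency:
    def test_model_wiring_fed_back_recovers_k(self):
        # A small enough that 1 - alpha stays positive for this tiny M
        p = kc.KCModelParams(M=12, N=9, A=1.2)
        K = 4
        W = kc.build_weight_matrix(p, K=K, seed=7)
        rows = []
        channels = {}
        for j in range(p.N):
            channels[f"pn{j}"] = f"G{j}"
        for i in range(p.M):
            for j in range(p.N):
                if W[i, j] > 0:
                    rows.append((f"pn{j}", f"kc{i}", "CA_L", 3))
        t = EdgeTable.from_rows(rows)
        per, mean = kc.observed_K(t, [f"kc{i}" for i in range(p.M)], channels)
        assert set(per.values()) == {K} and mean == K


class TestBudgets:
    def table(self):
        return EdgeTable.from_rows(
            [
                ("apl", "kc_a", "CA_L", 32),
                ("apl", "kc_b", "CA_L", 68),
                ("apl", "other", "CA_L", 50),
                ("kc_a", "apl", "CA_L", 10),
                ("kc_b", "apl", "CA_L", 30),
            ]
        )

    def test_single_group_gets_everything(self):
        frac = kc.budget_fraction(self.table(), ["apl"], {"kc_a": "KC", "kc_b": "KC"})
        assert frac == {"KC": pytest.approx(1.0)}

    def test_output_budget_split_32_68(self):
        frac = kc.budget_fraction(
            self.table(), ["apl"], {"kc_a": "KCa", "kc_b": "KCb"}
        )
        assert frac["KCa"] == pytest.approx(0.32)
        assert frac["KCb"] == pytest.approx(0.68)

    def test_input_budget_direction(self):
        frac = kc.budget_fraction(
            self.table(), ["apl"], {"kc_a": "KCa", "kc_b": "KCb"},
            direction="input_of_target",
        )
        assert frac["KCa"] == pytest.approx(0.25)
        assert frac["KCb"] == pytest.approx(0.75)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            kc.budget_fraction(self.table(), ["nobody"], {"kc_a": "KC"})


class TestEiRatio:
    def table(self):
        return EdgeTable.from_rows(
            [
                ("pn1", "kc1", "CA_L", 20),
                ("apl", "kc1", "CA_L", 10),
                ("pn1", "kc2", "CA_L", 40),
                ("apl", "kc2", "CA_L", 20),
                ("pn1", "kc3", "CA_L", 8),
            ]
        )

    def test_identical_wiring_normalises_to_one(self):
        ratios, excluded = kc.ei_ratio(
            self.table(), ["pn1"], ["apl"], ["kc1", "kc2"]
        )
        assert ratios == {"kc1": pytest.approx(1.0), "kc2": pytest.approx(1.0)}
        assert excluded == 0

    def test_scaling_both_inputs_leaves_ratio_invariant(self):
        # kc2 has double the inputs of kc1 but the same E/I ratio
        ratios, _ = kc.ei_ratio(self.table(), ["pn1"], ["apl"], ["kc1", "kc2"])
        assert ratios["kc1"] == pytest.approx(ratios["kc2"])

    def test_zero_inhibition_excluded_with_count(self):
        ratios, excluded = kc.ei_ratio(
            self.table(), ["pn1"], ["apl"], ["kc1", "kc2", "kc3"]
        )
        assert excluded == 1 and "kc3" not in ratios

    def test_overlapping_source_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            kc.ei_ratio(self.table(), ["pn1"], ["pn1"], ["kc1"])

    def test_three_cell_hand_computation(self):
        t = EdgeTable.from_rows(
            [
                ("e", "a", "CA_L", 10), ("i", "a", "CA_L", 10),   # ratio 1
                ("e", "b", "CA_L", 30), ("i", "b", "CA_L", 10),   # ratio 3
                ("e", "c", "CA_L", 20), ("i", "c", "CA_L", 10),   # ratio 2
            ]
        )
        ratios, _ = kc.ei_ratio(t, ["e"], ["i"], ["a", "b", "c"])
        assert ratios["a"] == pytest.approx(0.5)
        assert ratios["b"] == pytest.approx(1.5)
        assert ratios["c"] == pytest.approx(1.0)
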