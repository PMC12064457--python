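"""Biomarker ranking/merging, Kruskal-Wallis, normality gate, PCA, bands."""

from itertools import combinations

import numpy as np
import pytest

from uroftir.attribute import (
    DEFAULT_BAND_TABLE,
    BandAssignment,
    annotate_bands,
    attribution_stability,
    confirm_frequencies,
    kruskal_wallis,
    normality_gate,
    pca_selected,
    rank_and_select,
)
from uroftir.errors import (
    DegenerateSpectrumError,
    LookupError_,
    ParameterError,
    StratificationError,
)


class TestRankAndSelect:
    def test_adjacent_peak_merge(self):
        """Two importances one wavenumber apart describe the same band: only
        the stronger (1773) survives and the next distinct band (2093) is
        selected."""
        grid = np.array([2093.0, 1774.0, 1773.0])
        attributions = np.array([[0.45, 0.40, 0.50]])
        rep = rank_and_select(attributions, grid, k=2, merge_window=2.0)
        assert rep.selected_top == [1773.0, 2093.0]

    def test_window_zero_is_plain_topk(self):
        grid = np.array([30.0, 20.0, 10.0])
        attributions = np.array([[0.3, 0.5, 0.4]])
        rep = rank_and_select(attributions, grid, k=2, merge_window=0.0)
        assert rep.selected_top == [20.0, 10.0]

    def test_all_zero_attributions_select_nothing(self):
        grid = np.array([30.0, 20.0, 10.0])
        rep = rank_and_select(np.zeros((4, 3)), grid, k=2, relevance_floor=0.1)
        assert rep.selected_top == []
        assert rep.n_relevant == 0

    def test_ranking_is_non_increasing(self, rng):
        grid = np.arange(50.0)[::-1]
        rep = rank_and_select(rng.normal(size=(10, 50)), grid, k=3)
        imps = [imp for _, imp in rep.ranking]
        assert all(a >= b for a, b in zip(imps, imps[1:]))

    def test_selected_respect_merge_separation(self, rng):
        grid = np.arange(100.0)[::-1]
        rep = rank_and_select(rng.normal(size=(5, 100)), grid, k=5, merge_window=7.0)
        for a, b in combinations(rep.selected_top, 2):
            assert abs(a - b) > 7.0

    def test_k_exceeds_features(self):
        with pytest.raises(ParameterError):
            rank_and_select(np.ones((2, 3)), np.array([3.0, 2.0, 1.0]), k=4)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..6, R1 = 6, R2 = 15: H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
        out = kruskal_wallis(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert np.isclose(out["H"], 27 / 7)

    def test_identical_groups(self):
        out = kruskal_wallis(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert out["H"] <= 1e-12

    def test_all_values_identical(self):
        out = kruskal_wallis(np.ones(3), np.ones(4))
        assert out == {"H": 0.0, "p": 1.0}

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        out1 = kruskal_wallis(a, b)
        out2 = kruskal_wallis(np.exp(a), np.exp(b))
        assert np.isclose(out1["H"], out2["H"])

    def test_chi_square_p_close_to_exact_permutation_p(self, rng):
        """Two groups of six: the chi-square approximation tracks the exact
        permutation distribution.  At N = 12 the one-degree-of-freedom
        chi-square approximation is known to deviate by up to ~0.07 in
        absolute p; the test pins that empirical accuracy."""
        for _ in range(12):
            pooled = rng.normal(size=12)
            a, b = pooled[:6], pooled[6:]
            out = kruskal_wallis(a, b)
            h_obs = out["H"]
            count = 0
            total = 0
            idx = range(12)
            for keep in combinations(idx, 6):
                mask = np.zeros(12, dtype=bool)
                mask[list(keep)] = True
                h = kruskal_wallis(pooled[mask], pooled[~mask])["H"]
                count += h >= h_obs - 1e-12
                total += 1
            assert abs(out["p"] - count / total) <= 0.08

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            kruskal_wallis(np.array([1.0]))
        with pytest.raises(ParameterError):
            kruskal_wallis(np.array([1.0]), np.array([], dtype=float))


class TestConfirmFrequencies:
    def test_planted_bands_significant_control_higher(self, small_set):
        out = confirm_frequencies(small_set, [1773.0, 2093.0], alpha=0.05)
        for wn in (1773.0, 2093.0):
            assert out[wn]["significant"]
            assert out[wn]["direction"] == "control-higher"

    def test_nearest_neighbour_lookup(self, small_set):
        out = confirm_frequencies(small_set, [1773.4])
        assert out[1773.4]["grid_wavenumber"] == 1773.0

    def test_off_grid_error(self, small_set):
        with pytest.raises(LookupError_):
            confirm_frequencies(small_set, [900.0])

    def test_single_class_error(self, small_set):
        import dataclasses

        broken = dataclasses.replace(
            small_set, labels=np.zeros_like(small_set.labels),
            matrix=small_set.matrix.copy(), patient_ids=list(small_set.patient_ids))
        with pytest.raises(StratificationError):
            confirm_frequencies(broken, [1773.0])


class TestNormalityGate:
    def test_statistic_range(self, rng):
        out = normality_gate(rng.normal(size=50))
        assert 0.0 < out["W"] <= 1.0

    def test_bimodal_rejected(self, rng):
        x = np.concatenate([rng.normal(-3, 0.1, 50), rng.normal(3, 0.1, 50)])
        out = normality_gate(x)
        assert out["normal"] is False

    def test_constant_vector(self):
        with pytest.raises(DegenerateSpectrumError):
            normality_gate(np.ones(10))


class TestAttributionStability:
    def test_duplicate_seed_gives_full_overlap(self, small_proc):
        out = attribution_stability(small_proc.matrix, small_proc.labels,
                                    small_proc.grid.values, seeds=[3, 3], k=3)
        assert out["mean_jaccard"] == 1.0
        assert out["top_k"][0] == out["top_k"][1]

    def test_one_ranking_per_seed(self, small_proc):
        out = attribution_stability(small_proc.matrix, small_proc.labels,
                                    small_proc.grid.values, seeds=[1, 2, 3], k=3)
        assert len(out["top_k"]) == 3

    def test_needs_two_seeds(self, small_proc):
        with pytest.raises(ParameterError):
            attribution_stability(small_proc.matrix, small_proc.labels,
                                  small_proc.grid.values, seeds=[1])


class TestPcaSelected:
    def test_outputs(self, small_set):
        out = pca_selected(small_set, [1773.0, 2093.0, 1460.0, 1160.0], n_pc=3)
        evr = out["explained_variance_ratio"]
        assert all(a >= b for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1.0 + 1e-12
        scores = out["scores"]
        G = scores.T @ scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-8 * np.abs(np.diag(G)).max()

    def test_full_reconstruction(self, small_set):
        cols = [1773.0, 2093.0, 1460.0]
        out = pca_selected(small_set, cols, n_pc=3)
        sub = small_set.matrix[:, [small_set.grid.index_of(c) for c in cols]]
        recon = out["scores"] @ out["components"] + out["mean"]
        assert np.allclose(recon, sub, atol=1e-8)

    def test_too_many_components(self, small_set):
        with pytest.raises(ParameterError):
            pca_selected(small_set, [1773.0], n_pc=2)


class TestAnnotateBands:
    def test_carbonyl_region(self):
        out = annotate_bands([1773.0])
        assert "Carbonyl" in out[1773.0]

    def test_nitrile_region(self):
        out = annotate_bands([2093.0])
        assert "C#N" in out[2093.0]

    def test_unassigned(self):
        assert annotate_bands([3999.0])[3999.0] == "unassigned"

    def test_overlapping_table_rejected(self):
        with pytest.raises(ParameterError):
            BandAssignment(((1000.0, 1200.0, "a"), (1100.0, 1300.0, "b")))

    def test_default_table_total(self):
        for wn in (400.0, 1500.0, 1750.0, 2100.0, 3999.0):
            assert isinstance(DEFAULT_BAND_TABLE.lookup(wn), str)
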