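"""State assignment: enrichment labeling, deconvolution, pathway counts."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statefate as sf
from statefate.synthetic import generate_network_with_attractors, generate_reference_and_bulk


def exact_upper_tail(N, K, n, k):
    """Independent oracle: P(X >= k) by explicit PMF summation."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / denom


class TestHypergeometricEnrichment:
    def test_zero_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(50)}
        markers = {f"g{i}" for i in range(10)}
        module = {f"g{i}" for i in range(40, 50)}
        # k = 0 is always in the upper tail's support
        assert sf.hypergeometric_enrichment(markers - module, module, universe) == 1.0

    def test_matches_pmf_summation_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        markers = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 62)}
        # N=100, K=10, n=20, k=8
        p = sf.hypergeometric_enrichment(markers, module, universe)
        assert p == pytest.approx(exact_upper_tail(100, 10, 20, 8), abs=1e-12)

    def test_certain_event(self):
        universe = {f"g{i}" for i in range(7)}
        assert sf.hypergeometric_enrichment(universe, universe, universe) == 1.0

    def test_empty_module_convention(self):
        assert sf.hypergeometric_enrichment({"a"}, set(), {"a", "b"}) == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sf.hypergeometric_enrichment(set(), set(), set())

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_random_configurations_match_oracle(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        universe = {f"g{i}" for i in range(N)}
        module = {f"g{i}" for i in range(K)}
        marker_ids = data.draw(
            st.lists(st.integers(0, N - 1), min_size=n, max_size=n, unique=True)
        )
        markers = {f"g{i}" for i in marker_ids}
        k = len(markers & module)
        p = sf.hypergeometric_enrichment(markers, module, universe)
        if K == 0:
            assert p == 1.0
        else:
            assert p == pytest.approx(exact_upper_tail(N, K, n, k), abs=1e-10)


class TestLabelClusters:
    def _modules(self):
        universe = {f"g{i}" for i in range(100)}
        return sf.GeneModuleSet(
            modules={
                "modA": {f"g{i}" for i in range(20)},
                "modB": {f"g{i}" for i in range(20, 40)},
            },
            universe=universe,
        )

    def test_seeded_cluster_wins_its_module(self):
        modules = self._modules()
        markers = {f"g{i}" for i in range(15)}  # 15 of modA's 20 genes
        table = sf.label_clusters({"c0": markers}, modules)
        assert table.winner["c0"] == "modA"
        assert table.scores.loc["c0", "modA"] > table.scores.loc["c0", "modB"]

    def test_single_module_zero_overlap_still_wins(self):
        universe = {"a", "b", "c", "d"}
        modules = sf.GeneModuleSet(modules={"only": {"a"}}, universe=universe)
        table = sf.label_clusters({"c0": {"b", "c"}}, modules)
        assert table.winner["c0"] == "only"
        assert table.scores.loc["c0", "only"] == 0.0
        assert table.ties["c0"] is False

    def test_symmetric_overlap_breaks_ties_lexicographically(self):
        universe = {f"g{i}" for i in range(40)}
        shared = {f"g{i}" for i in range(10)}
        modules = sf.GeneModuleSet(
            modules={"zeta": shared, "alpha": shared}, universe=universe
        )
        table = sf.label_clusters({"c0": {f"g{i}" for i in range(5)}}, modules)
        assert table.winner["c0"] == "alpha"
        assert table.ties["c0"] is True

    def test_stray_markers_dropped_with_warning(self):
        modules = self._modules()
        with pytest.warns(UserWarning, match="outside the universe"):
            table = sf.label_clusters({"c0": {"g0", "not_a_gene"}}, modules)
        assert table.winner["c0"] == "modA"


class TestEstimateCompositions:
    def _two_state_reference(self, n_genes=30, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        sig_a = np.concatenate([np.full(n_genes // 2, 100.0), np.full(n_genes - n_genes // 2, 5.0)])
        sig_b = sig_a[::-1].copy()
        cells, labels = {}, {}
        for i in range(10):
            cells[f"a{i}"] = sig_a
            labels[f"a{i}"] = "A"
            cells[f"b{i}"] = sig_b
            labels[f"b{i}"] = "B"
        ref = pd.DataFrame(cells, index=genes)
        return ref, pd.Series(labels), sig_a, sig_b, genes

    def test_noiseless_mixture_recovered_exactly(self):
        ref, labels, sig_a, sig_b, genes = self._two_state_reference()
        bulk = pd.DataFrame({"s": 0.7 * sig_a + 0.3 * sig_b}, index=genes)
        comp = sf.estimate_compositions(bulk, ref, labels)
        assert comp.proportions.loc["s", "A"] == pytest.approx(0.7, abs=1e-6)
        assert comp.proportions.loc["s", "B"] == pytest.approx(0.3, abs=1e-6)

    def test_pure_signature_maps_to_vertex(self):
        ref, labels, sig_a, _, genes = self._two_state_reference()
        bulk = pd.DataFrame({"s": sig_a}, index=genes)
        comp = sf.estimate_compositions(bulk, ref, labels)
        assert comp.proportions.loc["s", "A"] == pytest.approx(1.0, abs=1e-6)

    def test_scale_invariance_of_bulk_counts(self):
        ref, labels, sig_a, sig_b, genes = self._two_state_reference()
        bulk = pd.DataFrame({"s": 0.4 * sig_a + 0.6 * sig_b}, index=genes)
        scaled = bulk * 37.5
        c1 = sf.estimate_compositions(bulk, ref, labels)
        c2 = sf.estimate_compositions(scaled, ref, labels)
        pd.testing.assert_frame_equal(c1.proportions, c2.proportions)

    def test_collinear_signatures_rejected_by_name(self):
        genes = [f"g{i}" for i in range(20)]
        sig = np.linspace(1, 20, 20)
        ref = pd.DataFrame({"a0": sig, "a1": sig, "b0": sig, "b1": sig}, index=genes)
        labels = pd.Series({"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        bulk = pd.DataFrame({"s": sig}, index=genes)
        with pytest.raises(ValueError, match="rank-deficient"):
            sf.estimate_compositions(bulk, ref, labels)

    def test_too_few_shared_genes_rejected(self):
        ref, labels, *_ = self._two_state_reference()
        bulk = pd.DataFrame({"s": [1.0] * 5}, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="share"):
            sf.estimate_compositions(bulk, ref, labels)

    def test_synthetic_cohort_recovery(self):
        """Dominant-state accuracy and proportion RMSE on a known cohort."""
        truth = generate_network_with_attractors(12, 2, 2.0, seed=11)
        ref, labels, bulk, props = generate_reference_and_bulk(
            truth, n_samples=100, nb_dispersion=10.0, seed=1
        )
        comp = sf.estimate_compositions(bulk, ref, labels)
        dominant = sf.classify_dominant_state(comp)
        acc = np.mean([dominant[s] == truth.labels[s] for s in props.index])
        rmse = np.sqrt(((comp.proportions[props.columns] - props) ** 2).to_numpy().mean())
        assert acc >= 0.9
        assert rmse < 0.10


class TestClassifyDominantState:
    def _comp(self, rows):
        df = pd.DataFrame(rows, columns=["MES", "NPC", "AC", "OPC"])
        df.index = [f"s{i}" for i in range(len(df))]
        return sf.CompositionEstimate(proportions=df)

    def test_row_argmax(self):
        comp = self._comp([[0.1, 0.2, 0.3, 0.4]])
        assert sf.classify_dominant_state(comp)["s0"] == "OPC"

    def test_tie_uses_fixed_state_order(self):
        comp = self._comp([[0.25, 0.25, 0.25, 0.25]])
        assert sf.classify_dominant_state(comp)["s0"] == "MES"
        assert comp.ties["s0"] is True

    def test_column_permutation_invariance(self):
        df = pd.DataFrame(
            [[0.1, 0.5, 0.2, 0.2]], columns=["MES", "NPC", "AC", "OPC"], index=["s0"]
        )
        comp1 = sf.CompositionEstimate(proportions=df)
        comp2 = sf.CompositionEstimate(proportions=df[["OPC", "AC", "NPC", "MES"]])
        assert sf.classify_dominant_state(comp1) == sf.classify_dominant_state(comp2)


class TestCountPathwayMembership:
    def test_counts_and_descending_order(self):
        universe = {"EGFR", "AKT1", "TP53", "MYC", "KRAS"}
        pathways = sf.GeneModuleSet(
            modules={
                "growth": {"EGFR", "AKT1", "MYC"},
                "none": {"KRAS"},
                "guardian": {"TP53"},
            },
            universe=universe,
        )
        counts = sf.count_pathway_membership({"EGFR", "AKT1", "TP53"}, pathways)
        assert counts["growth"] == 2
        assert counts["guardian"] == 1
        assert counts["none"] == 0
        assert list(counts) == ["growth", "guardian", "none"]

    def test_containment_and_disjoint(self):
        universe = {"a", "b", "c"}
        pathways = sf.GeneModuleSet(modules={"p": {"a", "b"}}, universe=universe)
        assert sf.count_pathway_membership({"a", "b", "c"}, pathways)["p"] == 2
        assert sf.count_pathway_membership(set(), pathways)["p"] == 0
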