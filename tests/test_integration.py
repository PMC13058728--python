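"""Interactome filtering, cross-referencing, MAD selection, correlation,
and client prioritization."""

import numpy as np
import pandas as pd
import pytest

from turnomix.integration import (correlate_layers, cross_reference,
                                  export_edges, filter_interactors,
                                  mad_select, prioritize_clients)
from turnomix.io import ExperimentDesign, RunConfig
from turnomix.simulate import SimulationSpec
from turnomix import pipeline


def interactome(pairs):
    return pd.DataFrame(pairs, columns=["protein_id", "enrichment_ratio"])


def diff_table(condition, rows, design):
    """rows: (protein, p_adj, dir_497, dir_506); p_value = p_adj for toys."""
    mutants = [g for g in design.genotypes if g != design.reference_genotype]
    cols = (["feature_id", "condition", "p_value", "p_adj", "tested"]
            + [f"direction_{g}" for g in mutants])
    recs = []
    for pid, p_adj, d1, d2 in rows:
        rec = dict(feature_id=pid, condition=condition, p_value=p_adj,
                   p_adj=p_adj, tested=True)
        for g, d in zip(mutants, (d1, d2)):
            rec[f"direction_{g}"] = d
        recs.append(rec)
    return pd.DataFrame(recs, columns=cols)


class TestFilterInteractors:
    def test_cutoff_is_strictly_greater_than(self):
        table = interactome([("A", 12.0), ("B", 10.0), ("C", 9.0),
                             ("D", 30.0), ("E", 0.5)])
        assert filter_interactors(table, 10.0) == {"A", "D"}

    def test_bad_cutoff_rejected(self):
        with pytest.raises(Exception):
            filter_interactors(interactome([("A", 1.0)]), 0.0)


class TestCrossReference:
    def test_empty_interactor_set(self, design):
        cm = diff_table("CM", [], design)
        gs = diff_table("GS", [], design)
        s = cross_reference(set(), cm, gs, design)
        assert s.n_prolonged == s.n_accelerated == s.n_interactors == 0

    def test_toy_classification(self, design):
        cm = diff_table("CM", [
            ("P1", 0.01, "prolonged", "prolonged"),
            ("P2", 0.01, "prolonged", "none"),
            ("P3", 0.01, "shortened", "shortened"),
            ("P4", 0.9, "none", "none"),
        ], design)
        gs = diff_table("GS", [
            ("P1", 0.001, "prolonged", "prolonged"),
            ("P2", 0.6, "none", "none"),
            ("P3", 0.2, "none", "none"),
            ("P4", 0.8, "none", "none"),
        ], design)
        s = cross_reference({"P1", "P2", "P3", "P4"}, cm, gs, design)
        assert (s.n_prolonged, s.n_accelerated) == (2, 1)
        assert (s.n_both, s.n_first_only, s.n_second_only) == (1, 1, 0)
        assert s.n_prolonged == s.n_both + s.n_first_only + s.n_second_only

    def test_unquantified_interactors_reported_separately(self, design):
        cm = diff_table("CM", [("P1", 0.01, "prolonged", "prolonged")], design)
        gs = diff_table("GS", [("P1", 0.01, "prolonged", "prolonged")], design)
        s = cross_reference({"P1", "P9"}, cm, gs, design)
        assert s.n_unquantified == 1
        assert s.n_prolonged == 1

    def test_both_mutant_mode_is_stricter(self, design):
        cm = diff_table("CM", [("P1", 0.01, "prolonged", "none")], design)
        gs = diff_table("GS", [("P1", 0.5, "none", "none")], design)
        either = cross_reference({"P1"}, cm, gs, design, mode="either")
        both = cross_reference({"P1"}, cm, gs, design, mode="both")
        assert either.n_prolonged == 1
        assert both.n_prolonged == 0


class TestMadSelect:
    def test_interpolated_quantile_threshold(self):
        # MADs are 0, 1, 2, 3; the 0.75-quantile is 2.25: one survivor
        rows = {
            "f0": [5.0] * 5,
            "f1": [0, 1, 2, 3, 4],
            "f2": [0, 2, 4, 6, 8],
            "f3": [0, 3, 6, 9, 12],
        }
        m = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list("abcde")).astype(float)
        kept = mad_select(m, 0.75)
        assert kept.index.tolist() == ["f3"]

    def test_quantile_zero_keeps_all_varying(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["const", "vary"], columns=list("abc"))
        kept = mad_select(m, 0.0)
        assert kept.index.tolist() == ["vary"]

    def test_all_constant_matrix_gives_empty_selection(self):
        m = pd.DataFrame([[1.0] * 4, [2.0] * 4], index=["x", "y"],
                         columns=list("abcd"))
        assert len(mad_select(m, 0.5)) == 0


class TestCorrelateLayers:
    def _layers(self, a_rows, b_rows, cols):
        a = pd.DataFrame(a_rows, columns=cols).astype(float)
        b = pd.DataFrame(b_rows, columns=cols).astype(float)
        a.index = [f"A{i}" for i in range(len(a))]
        b.index = [f"B{i}" for i in range(len(b))]
        return a, b

    def test_identical_negated_and_hand_pearson(self):
        a, b = self._layers([[1, 2, 3]], [[1, 2, 3], [-1, -2, -3], [1, 3, 2]],
                            list("xyz"))
        edges = correlate_layers(a, b).set_index("id_b")
        assert edges.at["B0", "r"] == pytest.approx(1.0, abs=1e-12)
        assert edges.at["B1", "r"] == pytest.approx(-1.0, abs=1e-12)
        assert edges.at["B2", "r"] == pytest.approx(0.5, abs=1e-12)
        assert (edges["n_samples"] == 3).all()

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.normal(0, 1, (3, 10)),
                         index=list("pqr"),
                         columns=[f"s{i}" for i in range(10)])
        edges = correlate_layers(a, a)
        diag = edges.loc[edges["id_a"] == edges["id_b"], "r"]
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)

    def test_symmetry_under_layer_swap(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(8)]
        a = pd.DataFrame(rng.normal(0, 1, (2, 8)), index=["a0", "a1"],
                         columns=cols)
        b = pd.DataFrame(rng.normal(0, 1, (3, 8)), index=["b0", "b1", "b2"],
                         columns=cols)
        ab = correlate_layers(a, b).set_index(["id_a", "id_b"])["r"]
        ba = correlate_layers(b, a).set_index(["id_b", "id_a"])["r"]
        for key in ab.index:
            assert ab[key] == pytest.approx(ba[key], abs=1e-12)

    def test_missing_values_use_complete_observations(self):
        a, b = self._layers([[1, 2, 3, np.nan]], [[1, 2, 3, 100]], list("wxyz"))
        edges = correlate_layers(a, b)
        assert edges.loc[0, "n_samples"] == 3
        assert edges.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)

    def test_pairs_below_min_n_are_omitted(self):
        a, b = self._layers([[1, np.nan, np.nan, 2]], [[1, 2, 3, 4]],
                            list("wxyz"))
        edges = correlate_layers(a, b)
        assert len(edges) == 0

    def test_too_few_shared_samples_is_an_error(self):
        a, b = self._layers([[1, 2]], [[1, 2]], list("xy"))
        with pytest.raises(Exception):
            correlate_layers(a, b)


class TestPrioritize:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["layer_a", "id_a", "layer_b",
                                           "id_b", "r", "n_samples"])

    def _diff(self, design, rows):
        return diff_table("GS", rows, design)

    def test_inclusion_and_exclusion_rules(self, design):
        diff = self._diff(design, [("P1", 0.01, "prolonged", "prolonged"),
                                   ("P2", 0.01, "prolonged", "prolonged"),
                                   ("P3", 0.5, "none", "none")])
        edges = self._edges([
            ("protein", "P1", "lipid", "L1", 0.7, 24),
            ("protein", "P2", "lipid", "L1", 0.3, 24),
            ("protein", "P3", "lipid", "L1", 0.9, 24),
        ])
        entries = interactome([("P1", 12.0), ("P2", 15.0), ("P3", 20.0)])
        cands, kept = prioritize_clients(entries, diff, edges, 0.6, 0.05)
        # P1 passes; P2 has no strong edge; P3 is not significant
        assert cands["protein_id"].tolist() == ["P1"]
        assert kept["id_a"].tolist() == ["P1"]

    def test_negative_correlations_pass_with_sign_preserved(self, design):
        diff = self._diff(design, [("P1", 0.01, "prolonged", "prolonged")])
        edges = self._edges([("protein", "P1", "lipid", "L1", -0.8, 24)])
        cands, kept = prioritize_clients(interactome([("P1", 11.0)]), diff,
                                         edges, 0.6, 0.05)
        assert cands.loc[0, "best_r"] == pytest.approx(-0.8)

    def test_sorted_by_enrichment_descending(self, design):
        diff = self._diff(design, [("P1", 0.01, "prolonged", "prolonged"),
                                   ("P2", 0.01, "prolonged", "prolonged")])
        edges = self._edges([("protein", "P1", "lipid", "L1", 0.9, 24),
                             ("protein", "P2", "lipid", "L2", 0.9, 24)])
        entries = interactome([("P1", 11.0), ("P2", 40.0)])
        cands, _ = prioritize_clients(entries, diff, edges, 0.6, 0.05)
        assert cands["protein_id"].tolist() == ["P2", "P1"]

    def test_threshold_monotonicity(self, design):
        rng = np.random.default_rng(5)
        diff = self._diff(design, [(f"P{i}", 0.01, "prolonged", "prolonged")
                                   for i in range(10)])
        edges = self._edges([("protein", f"P{i}", "lipid", f"L{i}",
                              rng.uniform(-1, 1), 24) for i in range(10)])
        entries = interactome([(f"P{i}", rng.uniform(10.5, 50)) for i in range(10)])
        prev = None
        for thr in [0.0, 0.3, 0.6, 0.9]:
            got = set(prioritize_clients(entries, diff, edges, thr,
                                         0.05)[0]["protein_id"])
            if prev is not None:
                assert got <= prev
            prev = got


class TestExportEdges:
    def test_round_trip_and_deterministic_order(self, tmp_path, design):
        edges = pd.DataFrame([
            ("protein", "P2", "lipid", "L1", 0.9, 24),
            ("protein", "P1", "transcript", "T1", -0.7, 24),
            ("protein", "P1", "lipid", "L2", 0.8, 24),
        ], columns=["layer_a", "id_a", "layer_b", "id_b", "r", "n_samples"])
        cands = pd.DataFrame({"protein_id": ["P1", "P2"]})
        path = tmp_path / "edges.tsv"
        kept = export_edges(cands, edges, path)
        assert kept["id_a"].tolist() == ["P1", "P1", "P2"]
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["r"], kept["r"], rtol=1e-12)

    def test_empty_candidates_write_headers_only(self, tmp_path):
        edges = pd.DataFrame(columns=["layer_a", "id_a", "layer_b", "id_b",
                                      "r", "n_samples"])
        path = tmp_path / "edges.tsv"
        export_edges(pd.DataFrame({"protein_id": []}), edges, path)
        assert path.read_text().strip() == "\t".join(
            ["layer_a", "id_a", "layer_b", "id_b", "r", "n_samples"])


class TestEndToEnd:
    def test_no_planted_clients_yields_empty_candidate_set(self, tmp_path):
        spec = SimulationSpec(seed=4, n_proteins=60, n_planted_clients=0,
                              n_interactors=6, n_decoy_interactome=10,
                              n_lipids=30, n_transcripts=40)
        res = pipeline.run_all(RunConfig(seed=4), spec, tmp_path)
        assert len(res["integration"]["candidates"]) == 0

    def test_recall_degrades_gracefully_at_doubled_noise(self, tmp_path):
        recalls = []
        for seed in (1, 7, 11):
            spec = SimulationSpec(seed=seed, intensity_sd=0.4)
            res = pipeline.run_all(RunConfig(seed=seed), spec,
                                   tmp_path / f"s{seed}")
            truth = res["data"]["protein_truth"]
            planted = set(truth.loc[truth["is_planted_client"], "protein_id"])
            got = set(res["integration"]["candidates"]["protein_id"])
            assert got <= planted | set()  # decoys stay out
            recalls.append(len(got & planted) / len(planted))
        assert np.mean(recalls) >= 0.8
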