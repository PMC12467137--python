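"""Correlation edges, thresholds, triple assembly and export."""
import itertools
import json

import numpy as np
import pytest

from cernet import network
from cernet.network import (
    CorrelationEdge,
    assemble_triples,
    build_edges,
    export_network,
    pearson_edge,
    spearman_edge,
    spearman_exact_p,
)

from _oracles import (
    enumerate_triples,
    pearson_from_definition,
    spearman_from_definition,
)


class TestCoefficients:
    def test_antimonotone_vectors_have_rho_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        rho, _ = spearman_edge(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_monotone_transform_has_rho_one(self):
        x = np.array([0.5, 1.2, 2.0, 3.3, 5.1, 8.0])
        rho, _ = spearman_edge(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_affine_map_has_r_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        r, _ = pearson_edge(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_orthogonalized_residual_has_r_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        xc = x - x.mean()
        resid = y - (y - y.mean()) @ xc / (xc @ xc) * xc
        # subtract only the projection; re-centre the construction
        resid = y - ((y - y.mean()) @ xc / (xc @ xc)) * xc
        r, _ = pearson_edge(x, resid)
        assert abs(r) < 1e-12

    def test_coefficients_match_from_definition_oracles(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, y = rng.normal(size=(2, 10))
            assert pearson_edge(x, y)[0] == pytest.approx(
                pearson_from_definition(x, y), abs=1e-12)
            assert spearman_edge(x, y)[0] == pytest.approx(
                spearman_from_definition(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_edge(np.ones(6), np.arange(6.0))
        with pytest.raises(ValueError):
            pearson_edge(np.arange(6.0), np.full(6, 2.0))


class TestExactPermutationP:
    def test_t_approximation_tracks_exact_p_at_n_seven(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.normal(size=(2, 7))
            rho_a, p_approx = spearman_edge(x, y)
            rho_e, p_exact = spearman_exact_p(x, y)
            assert rho_a == pytest.approx(rho_e, abs=1e-12)
            assert abs(p_approx - p_exact) < 0.05

    def test_exact_p_of_perfect_anticorrelation(self):
        x = np.arange(6.0)
        _, p = spearman_exact_p(x, -x)
        # two permutations of 6! reach |rho| = 1
        assert p == pytest.approx(2 / 720)

    def test_ties_are_rejected(self):
        with pytest.raises(ValueError):
            spearman_exact_p([1.0, 1.0, 2.0, 3.0, 4.0], np.arange(5.0))


def _exact_rho_pair(n, target_d):
    """Vectors whose rank displacement sum is exactly target_d."""
    for perm in itertools.permutations(range(n)):
        if sum((p - i) ** 2 for i, p in enumerate(perm)) == target_d:
            return np.arange(n, dtype=float), np.array(perm, dtype=float)
    raise AssertionError("no permutation with requested displacement")


class TestBuildEdges:
    def _expr(self, rows, cols=10, seed=3):
        import pandas as pd

        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(len(rows), cols)), index=rows)

    def test_scc_exactly_minus_half_is_rejected(self):
        import pandas as pd

        # rho = 1 - 6D/(n(n^2-1)); n=8, D=126 gives rho = -0.5 exactly
        x, y = _exact_rho_pair(8, 126)
        rho, _ = spearman_edge(x, y)
        assert rho == pytest.approx(-0.5)
        expr_c = pd.DataFrame([x], index=["c1"])
        expr_m = pd.DataFrame([y], index=["m1"])
        expr_g = pd.DataFrame([y], index=["g1"])
        cm, mg, cg = build_edges({("m1", "c1")}, expr_c, expr_m, expr_g)
        assert cm == []

    def test_pcc_exactly_point_seven_is_rejected(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        z = rng.normal(size=10)
        xs = (x - x.mean()) / x.std()
        zc = z - z.mean() - (z - z.mean()) @ xs / (xs @ xs) * xs
        zs = zc / zc.std()
        y = 0.7 * xs + np.sqrt(1 - 0.49) * zs  # sample r = 0.7 by construction
        r, _ = pearson_edge(x, y)
        assert r == pytest.approx(0.7)
        expr_c = pd.DataFrame([x], index=["c1"])
        expr_m = pd.DataFrame([-x], index=["m1"])
        expr_g = pd.DataFrame([y], index=["g1"])
        # a coefficient exactly at the threshold fails the strict comparison
        _, _, cg = build_edges({("m1", "c1"), ("m1", "g1")},
                               expr_c, expr_m, expr_g, pcc_thr=r)
        assert cg == []
        _, _, cg2 = build_edges({("m1", "c1"), ("m1", "g1")},
                                expr_c, expr_m, expr_g,
                                pcc_thr=r - 1e-9, p_thr=0.05)
        assert len(cg2) == 1

    def test_only_predicted_pairs_are_tested(self):
        import pandas as pd

        x = np.arange(10.0)
        expr_c = pd.DataFrame([x], index=["c1"])
        expr_m = pd.DataFrame([-x], index=["m1"])
        expr_g = pd.DataFrame([x], index=["g1"])
        cm, mg, cg = build_edges(set(), expr_c, expr_m, expr_g)
        assert cm == [] and mg == [] and cg == []

    def test_strong_sign_structure_passes_all_three_legs(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        base = np.concatenate([np.zeros(5), np.ones(5) * 4])
        x = base + rng.normal(scale=0.1, size=10)
        y = -base + rng.normal(scale=0.1, size=10)
        z = base + rng.normal(scale=0.1, size=10)
        cm, mg, cg = build_edges(
            {("m1", "c1"), ("m1", "g1")},
            pd.DataFrame([x], index=["c1"]),
            pd.DataFrame([y], index=["m1"]),
            pd.DataFrame([z], index=["g1"]))
        assert len(cm) == len(mg) == len(cg) == 1
        triples = assemble_triples(cm, mg, cg)
        assert [(t.circ_id, t.mirna_id, t.mrna_id) for t in triples] == [
            ("c1", "m1", "g1")]

    def test_missing_expression_row_skips_pair(self):
        import pandas as pd

        x = np.arange(10.0)
        cm, mg, cg = build_edges(
            {("m1", "c_absent"), ("m1", "g1")},
            pd.DataFrame([x], index=["c1"]),
            pd.DataFrame([-x], index=["m1"]),
            pd.DataFrame([x], index=["g1"]))
        assert cm == [] and len(mg) == 1


class TestAssembleTriples:
    def _edge(self, a, ca, b, cb, method="spearman", coef=-0.9, p=0.001):
        return CorrelationEdge(a, ca, b, cb, method, coef, p, 10)

    def test_complete_edge_set_gives_one_triple(self):
        triples = assemble_triples(
            [self._edge("c1", "circ", "m1", "mirna")],
            [self._edge("m1", "mirna", "g1", "mrna")],
            [self._edge("c1", "circ", "g1", "mrna", "pearson", 0.9)])
        assert len(triples) == 1

    def test_missing_pcc_leg_gives_no_triple(self):
        assert assemble_triples(
            [self._edge("c1", "circ", "m1", "mirna")],
            [self._edge("m1", "mirna", "g1", "mrna")], []) == []

    def test_join_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        circs = [f"c{i}" for i in range(20)]
        mirs = [f"m{i}" for i in range(20)]
        genes = [f"g{i}" for i in range(20)]
        cm_pairs = {(c, m) for c in circs for m in mirs if rng.random() < 0.1}
        mg_pairs = {(m, g) for m in mirs for g in genes if rng.random() < 0.1}
        cg_pairs = {(c, g) for c in circs for g in genes if rng.random() < 0.3}
        triples = assemble_triples(
            [self._edge(c, "circ", m, "mirna") for c, m in cm_pairs],
            [self._edge(m, "mirna", g, "mrna") for m, g in mg_pairs],
            [self._edge(c, "circ", g, "mrna", "pearson", 0.9) for c, g in cg_pairs])
        got = [(t.circ_id, t.mirna_id, t.mrna_id) for t in triples]
        assert got == enumerate_triples(cm_pairs, mg_pairs, cg_pairs)
        assert got == sorted(got), "deterministic lexicographic order"


class TestExport:
    def _triple(self, c="c1", m="m1", g="g1"):
        from cernet.network import CeRNATriple

        return CeRNATriple(c, m, g, -0.9, -0.8, 0.9, 0.001, 0.002, 0.003)

    def test_single_triple_yields_three_nodes_two_links(self, tmp_path):
        sankey = export_network([self._triple()], str(tmp_path))
        assert len(sankey["nodes"]) == 3 and len(sankey["links"]) == 2
        saved = json.loads((tmp_path / "cerna_sankey.json").read_text())
        assert saved == sankey

    def test_duplicate_triples_deduplicated(self, tmp_path):
        sankey = export_network([self._triple(), self._triple()], str(tmp_path))
        assert len(sankey["links"]) == 2

    def test_counts_match_independent_tally(self, tmp_path):
        triples = [self._triple(f"c{i}", f"m{i % 2}", f"g{i}") for i in range(4)]
        sankey = export_network(triples, str(tmp_path))
        nodes = {t.circ_id for t in triples} | {t.mirna_id for t in triples} | {
            t.mrna_id for t in triples}
        links = {(t.circ_id, t.mirna_id) for t in triples} | {
            (t.mirna_id, t.mrna_id) for t in triples}
        assert len(sankey["nodes"]) == len(nodes)
        assert len(sankey["links"]) == len(links)

    def test_empty_network_writes_valid_files(self, tmp_path):
        sankey = export_network([], str(tmp_path))
        assert sankey == {"nodes": [], "links": []}
        assert (tmp_path / "cerna_triples.tsv").exists()
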