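"""Pearson correlation, bait neighborhoods, network building and export."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexstream.matrix import ExpressionMatrix
from coexstream.network import (
    DEFAULT_STYLE,
    AnnotationTable,
    NetworkParams,
    bait_neighborhood,
    build_network,
    export_cyjs,
    pearson,
    write_edge_list,
)


def brute_force_pearson(x, y):
    """Independent oracle: the explicit sum formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestPearson:
    def test_identity(self):
        assert pearson(np.array([1, 2, 3]), np.array([1, 2, 3])) == 1.0

    def test_perfect_anticorrelation(self):
        assert pearson(np.array([1, 2, 3]), np.array([3, 2, 1])) == -1.0

    def test_hand_example(self):
        # cov = 1, var_x = var_y = 2 -> r = 0.5
        assert pearson(np.array([1, 2, 3]),
                       np.array([1, 3, 2])) == pytest.approx(0.5, abs=1e-15)

    def test_zero_variance_signals_undefined(self):
        assert math.isnan(pearson(np.array([1.0, 1.0, 1.0]),
                                  np.array([1, 2, 3])))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.array([1, 2]), np.array([1, 2]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(
                brute_force_pearson(x.tolist(), y.tolist()), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.01, 100),
           b=st.floats(-50, 50))
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-9)


def _matrix(rows, genes, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"SRR{i:07d}" for i in range(1, rows.shape[1] + 1)]
    return ExpressionMatrix(rows, gene_ids=genes, sample_ids=samples)


class TestBaitNeighborhood:
    def test_planted_duplicate_ranks_first(self, rng):
        bait_profile = rng.lognormal(size=20)
        rows = [bait_profile, bait_profile * 3.0]
        genes = ["bait", "twin"]
        for i in range(10):
            rows.append(rng.lognormal(size=20))
            genes.append(f"noise{i}")
        m = _matrix(np.array(rows), genes)
        nb = bait_neighborhood(m, NetworkParams(bait="bait"))
        assert nb[0][0] == "twin"
        assert nb[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_other_genes_excluded(self):
        m = _matrix([[1, 2, 3, 4], [5, 5, 5, 5], [2, 2, 2, 2]],
                    ["bait", "c1", "c2"])
        assert bait_neighborhood(m, NetworkParams(bait="bait")) == []

    def test_tie_broken_by_gene_id(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix([base, 2 * base, 5 * base], ["bait", "zz", "aa"])
        nb = bait_neighborhood(m, NetworkParams(bait="bait"))
        assert [g for g, _ in nb] == ["aa", "zz"]

    def test_bait_absent_is_lookup_error(self):
        m = _matrix([[1, 2, 3]], ["g1"])
        with pytest.raises(KeyError):
            bait_neighborhood(m, NetworkParams(bait="nope"))

    def test_constant_bait_is_error(self):
        m = _matrix([[5, 5, 5], [1, 2, 3]], ["bait", "g1"])
        with pytest.raises(ValueError, match="constant"):
            bait_neighborhood(m, NetworkParams(bait="bait"))

    def test_truncation_and_floor(self, module_matrix):
        _, matrix, truth = module_matrix
        params = NetworkParams(bait="M00G000", max_neighbors=5, min_pcc=0.7)
        nb = bait_neighborhood(matrix, params)
        assert len(nb) <= 5
        assert all(w >= 0.7 for _, w in nb)
        pccs = [w for _, w in nb]
        assert pccs == sorted(pccs, reverse=True)

    def test_lower_floor_is_superset_below_cap(self, module_matrix):
        _, matrix, _ = module_matrix
        strict = bait_neighborhood(
            matrix, NetworkParams(bait="M00G000", max_neighbors=500,
                                  min_pcc=0.9))
        loose = bait_neighborhood(
            matrix, NetworkParams(bait="M00G000", max_neighbors=500,
                                  min_pcc=0.7))
        assert {g for g, _ in strict} <= {g for g, _ in loose}

    def test_planted_module_recovery(self, module_matrix):
        _, matrix, truth = module_matrix
        nb = bait_neighborhood(matrix,
                               NetworkParams(bait="M00G000",
                                             max_neighbors=19))
        in_module = [truth[g] == "module0" for g, _ in nb]
        assert np.mean(in_module) >= 0.9


class TestBuildNetwork:
    def test_single_neighbor(self):
        m = _matrix([[1, 2, 3, 4], [2, 4, 6, 8]], ["bait", "g1"])
        params = NetworkParams(bait="bait")
        nb = bait_neighborhood(m, params)
        net = build_network(m, nb, params)
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1

    def test_mutually_correlated_triangle(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix([base, 2 * base, 0.5 * base], ["bait", "g1", "g2"])
        params = NetworkParams(bait="bait")
        net = build_network(m, bait_neighborhood(m, params), params)
        assert net.graph.number_of_nodes() == 3
        assert net.graph.number_of_edges() == 3

    def test_star_topology_switch(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix([base, 2 * base, 0.5 * base], ["bait", "g1", "g2"])
        params = NetworkParams(bait="bait", neighbor_edges=False)
        net = build_network(m, bait_neighborhood(m, params), params)
        assert net.graph.number_of_edges() == 2

    def test_empty_neighborhood_gives_bait_only(self):
        m = _matrix([[1, 2, 3], [3, 3, 3]], ["bait", "g1"])
        params = NetworkParams(bait="bait")
        net = build_network(m, [], params)
        assert net.nodes == [("bait", "unannotated", True)]
        assert net.edges == []

    def test_annotation_bins_attached(self):
        m = _matrix([[1, 2, 3, 4], [2, 4, 6, 8]], ["bait", "g1"])
        ann = AnnotationTable({"bait": "secondary metabolism"})
        params = NetworkParams(bait="bait")
        net = build_network(m, bait_neighborhood(m, params), params, ann)
        bins = dict((g, b) for g, b, _ in net.nodes)
        assert bins == {"bait": "secondary metabolism", "g1": "unannotated"}

    def test_edge_weights_at_least_floor(self, module_matrix):
        _, matrix, _ = module_matrix
        params = NetworkParams(bait="M00G000")
        net = build_network(matrix, bait_neighborhood(matrix, params), params)
        assert all(w >= params.min_pcc for _, _, w in net.edges)
        assert sum(1 for _, _, is_bait in net.nodes if is_bait) == 1


class TestExportCyjs:
    def _net(self):
        m = _matrix([[1, 2, 3, 4], [2, 4, 6, 8]], ["bait", "g1"])
        params = NetworkParams(bait="bait")
        ann = AnnotationTable({"bait": "transport"})
        return build_network(m, bait_neighborhood(m, params), params, ann)

    def test_round_trip_counts(self):
        doc = json.loads(export_cyjs(self._net()))
        assert len(doc["elements"]["nodes"]) == 2
        assert len(doc["elements"]["edges"]) == 1
        edge = doc["elements"]["edges"][0]["data"]
        assert {"id", "source", "target", "weight"} <= set(edge)

    def test_styles_applied_and_default_fallback(self):
        style = {"transport": ("triangle", "#1f77b4")}
        doc = json.loads(export_cyjs(self._net(), style))
        by_id = {n["data"]["id"]: n["data"]
                 for n in doc["elements"]["nodes"]}
        assert by_id["bait"]["shape"] == "triangle"
        assert by_id["bait"]["is_bait"] is True
        assert (by_id["g1"]["shape"], by_id["g1"]["color"]) == DEFAULT_STYLE

    def test_edge_source_is_smaller_id(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix([base, 2 * base], ["zz_bait", "aa"])
        params = NetworkParams(bait="zz_bait")
        net = build_network(m, bait_neighborhood(m, params), params)
        doc = json.loads(export_cyjs(net))
        edge = doc["elements"]["edges"][0]["data"]
        assert edge["source"] == "aa"
        assert edge["target"] == "zz_bait"

    def test_deterministic_serialization(self):
        assert export_cyjs(self._net()) == export_cyjs(self._net())

    def test_edge_list_tsv(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list(self._net(), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "source\ttarget\tpcc"
        assert len(lines) == 2


def test_annotation_table_tsv(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("g1\ttransport\n# comment\ng2\tsecondary metabolism\n")
    ann = AnnotationTable.read_tsv(path)
    assert ann["g1"] == "transport"
    assert ann["missing"] == "unannotated"
    assert len(ann) == 2
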