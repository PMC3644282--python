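"""BDeu scoring, structure search and the consensus dependency matrix."""

import numpy as np
import pytest
from scipy.special import gammaln

from ctxnet.io import TrinaryMatrix
from ctxnet.network import (
    ConsensusNetwork,
    SearchConfig,
    call_edges,
    consensus,
    family_score,
    read_network,
    search_structure,
    write_network,
)
from ctxnet.specificity import SpecificityResult


def make_matrix(columns: dict[str, np.ndarray]) -> TrinaryMatrix:
    ids = list(columns)
    values = np.vstack([columns[k] for k in ids]).astype(np.int8)
    return TrinaryMatrix(values, ids, [f"s{i}" for i in range(values.shape[1])])


def bdeu_reference(data: TrinaryMatrix, child: str, parents: list[str], ess=1.0):
    """Independent BDeu implementation via pandas grouping + scipy gammaln."""
    import pandas as pd

    df = pd.DataFrame(data.values.T, columns=data.row_ids)
    q = 3 ** len(parents)
    a_j, a_jk = ess / q, ess / (q * 3)
    if parents:
        groups = df.groupby(parents)[child]
    else:
        groups = [((), df[child])]
    total = 0.0
    for _, col in groups:
        n_j = len(col)
        total += gammaln(a_j) - gammaln(a_j + n_j)
        for _, n_jk in col.value_counts().items():
            total += gammaln(a_jk + n_jk) - gammaln(a_jk)
    return total


class TestFamilyScore:
    def test_copied_column_gains(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 200).astype(np.int8)
        data = make_matrix({"X": x, "Y": x.copy()})
        assert family_score(data, "Y", ["X"]) > family_score(data, "Y")

    def test_independent_column_penalized(self):
        rng = np.random.default_rng(1)
        data = make_matrix({
            "X": rng.integers(0, 2, 500).astype(np.int8),
            "Y": rng.integers(0, 2, 500).astype(np.int8),
        })
        assert family_score(data, "Y", ["X"]) < family_score(data, "Y")

    def test_state_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.integers(-1, 2, 150).astype(np.int8)
        y = rng.integers(-1, 2, 150).astype(np.int8)
        relabel = {-1: 1, 0: -1, 1: 0}
        y2 = np.vectorize(relabel.get)(y).astype(np.int8)
        a = family_score(make_matrix({"X": x, "Y": y}), "Y", ["X"])
        b = family_score(make_matrix({"X": x, "Y": y2}), "Y", ["X"])
        assert a == pytest.approx(b, abs=1e-9)

    def test_score_equivalence_of_edge_orientation(self):
        rng = np.random.default_rng(3)
        x = rng.integers(-1, 2, 120).astype(np.int8)
        y = np.where(rng.random(120) < 0.7, x, rng.integers(-1, 2, 120)).astype(np.int8)
        data = make_matrix({"X": x, "Y": y})
        fwd = family_score(data, "X") + family_score(data, "Y", ["X"])
        rev = family_score(data, "Y") + family_score(data, "X", ["Y"])
        assert fwd == pytest.approx(rev, abs=1e-8)

    @pytest.mark.parametrize("parents", [[], ["X"], ["X", "Z"]])
    def test_matches_reference_implementation(self, parents):
        rng = np.random.default_rng(4)
        data = make_matrix({
            "X": rng.integers(-1, 2, 80).astype(np.int8),
            "Y": rng.integers(-1, 2, 80).astype(np.int8),
            "Z": rng.integers(-1, 2, 80).astype(np.int8),
        })
        got = family_score(data, "Y", parents, ess=2.5)
        want = bdeu_reference(data, "Y", parents, ess=2.5)
        assert got == pytest.approx(want, abs=1e-8)

    def test_child_in_parents_rejected(self, small_trinary):
        with pytest.raises(ValueError, match="own parent"):
            family_score(small_trinary, "g1", ["g1"])


class TestSearchStructure:
    def test_dependent_pair_connected(self, copied_pair_data):
        dag = search_structure(copied_pair_data, SearchConfig(R=1), seed=5)
        assert ("A", "B") in dag.undirected_edges()

    def test_independent_pair_unconnected(self):
        rng = np.random.default_rng(6)
        data = make_matrix({
            "X": rng.integers(-1, 2, 600).astype(np.int8),
            "Y": rng.integers(-1, 2, 600).astype(np.int8),
        })
        dag = search_structure(data, SearchConfig(R=1), seed=7)
        assert dag.undirected_edges() == []

    def test_seed_determinism(self, copied_pair_data):
        cfg = SearchConfig(R=1)
        a = search_structure(copied_pair_data, cfg, seed=11)
        b = search_structure(copied_pair_data, cfg, seed=11)
        assert a.parents == b.parents

    def test_respects_max_parents(self):
        rng = np.random.default_rng(8)
        latent = rng.integers(0, 2, 300).astype(np.int8)
        cols = {"Y": latent}
        for i in range(6):
            noisy = np.where(rng.random(300) < 0.85, latent, 1 - latent)
            cols[f"P{i}"] = noisy.astype(np.int8)
        dag = search_structure(make_matrix(cols), SearchConfig(R=1, max_parents=2), seed=9)
        assert all(len(ps) <= 2 for ps in dag.parents.values())

    def test_result_is_acyclic(self, copied_pair_data):
        import networkx as nx

        dag = search_structure(copied_pair_data, SearchConfig(R=1), seed=13)
        g = nx.DiGraph(
            [(p, c) for c, ps in dag.parents.items() for p in ps]
        )
        assert nx.is_directed_acyclic_graph(g)


class TestConsensus:
    def test_d_properties(self, copied_pair_data):
        cfg = SearchConfig(R=16, base_seed=1)
        net = consensus(copied_pair_data, cfg)
        assert np.allclose(net.d, net.d.T)
        assert np.all((net.d >= 0) & (net.d <= 1))
        scaled = net.d * cfg.R
        assert np.allclose(scaled, np.round(scaled))

    def test_perfect_dependency_unit_likelihood(self, copied_pair_data):
        net = consensus(copied_pair_data, SearchConfig(R=32, base_seed=2))
        assert net.d_of("A", "B") == 1.0

    def test_sample_order_invariance(self, copied_pair_data):
        cfg = SearchConfig(R=8, base_seed=3)
        a = consensus(copied_pair_data, cfg)
        reversed_samples = copied_pair_data.select_samples(
            list(reversed(copied_pair_data.sample_ids))
        )
        b = consensus(reversed_samples, cfg)
        assert np.allclose(a.d, b.d)

    def test_two_node_matches_score_indicator(self):
        """On two variables d must be exactly the 0/1 score-comparison."""
        for t in range(10):
            rng = np.random.default_rng(100 + t)
            n = int(rng.integers(40, 300))
            x = rng.integers(-1, 2, n).astype(np.int8)
            if t % 2 == 0:
                y = np.where(rng.random(n) < 0.8, x, rng.integers(-1, 2, n)).astype(np.int8)
            else:
                y = rng.integers(-1, 2, n).astype(np.int8)
            data = make_matrix({"X": x, "Y": y})
            net = consensus(data, SearchConfig(R=16, base_seed=t))
            gain = family_score(data, "Y", ["X"]) - family_score(data, "Y")
            assert net.d_of("X", "Y") == (1.0 if gain > 0 else 0.0)

    def test_constant_variable_isolated(self):
        rng = np.random.default_rng(5)
        x = rng.integers(-1, 2, 100).astype(np.int8)
        data = make_matrix({"X": x, "Y": x.copy(), "K": np.zeros(100, dtype=np.int8)})
        net = consensus(data, SearchConfig(R=8, base_seed=4))
        assert net.d_of("K", "X") == 0.0 and net.d_of("K", "Y") == 0.0
        assert net.d_of("X", "Y") == 1.0

    def test_independent_variables_rarely_called(self):
        rng = np.random.default_rng(6)
        cols = {f"V{i}": rng.integers(-1, 2, 500).astype(np.int8) for i in range(10)}
        net = consensus(make_matrix(cols), SearchConfig(R=32, base_seed=5))
        assert len(net.called_edges()) <= 2  # 5% of the 45 pairs

    def test_monte_carlo_stability_between_seed_blocks(self):
        rng = np.random.default_rng(7)
        x = rng.integers(-1, 2, 300).astype(np.int8)
        y = np.where(rng.random(300) < 0.8, x, rng.integers(-1, 2, 300)).astype(np.int8)
        z = rng.integers(-1, 2, 300).astype(np.int8)
        data = make_matrix({"X": x, "Y": y, "Z": z})
        R = 64
        a = consensus(data, SearchConfig(R=R, base_seed=1000))
        b = consensus(data, SearchConfig(R=R, base_seed=2000))
        for i in range(3):
            for j in range(i + 1, 3):
                p = (a.d[i, j] + b.d[i, j]) / 2
                band = 2.576 * np.sqrt(max(p * (1 - p), 1e-9) * 2 / R) + 2 / R
                assert abs(a.d[i, j] - b.d[i, j]) <= band


class TestCallEdges:
    def test_strict_threshold(self):
        d = np.array([[0, 0.5, 0.7], [0.5, 0, 0.2], [0.7, 0.2, 0]])
        net = ConsensusNetwork(["a", "b", "c"], d, R=10, d_theta=0.5)
        assert call_edges(net) == [("a", "c")]

    def test_empty_network(self):
        net = ConsensusNetwork(["a", "b"], np.zeros((2, 2)), R=4)
        assert call_edges(net) == []


class TestNetworkSerialization:
    def make_net(self):
        d = np.array([[0, 0.7, 0.3], [0.7, 0, 0.625], [0.3, 0.625, 0]])
        return ConsensusNetwork(["s1", "s2", "s3"], d, R=8, d_theta=0.5)

    def test_edge_row_with_specificity(self, tmp_path):
        net = self.make_net()
        rec = SpecificityResult(
            edge=("s1", "s2"), condition="melanoma", d_all=0.7, d_without=0.1,
            gamma=7.0, H=0, M=100, p=0.0, specific=True,
        )
        path = tmp_path / "net.tsv"
        write_network(net, [rec], path, "tsv")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        header = lines[0].split("\t")
        assert header == ["set_i", "set_j", "d", "melanoma:gamma", "melanoma:p", "melanoma:specific"]
        rows = [l.split("\t") for l in lines[1:]]
        assert len(rows) == 2  # only the two called edges
        assert rows[0][:3] == ["s1", "s2", "0.7"] and rows[0][3:] == ["7.0", "0.0", "True"]

    def test_subthreshold_network_writes_header_only(self, tmp_path):
        net = ConsensusNetwork(["a", "b"], np.array([[0, 0.4], [0.4, 0]]), R=10)
        path = tmp_path / "net.tsv"
        write_network(net, [], path, "tsv")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["set_i\tset_j\td"]

    def test_round_trip_d_exact(self, tmp_path):
        net = self.make_net()
        path = tmp_path / "net.tsv"
        write_network(net, [], path, "tsv")
        back = read_network(path)
        assert back.R == 8 and back.d_theta == 0.5
        for a, b in net.called_edges():
            assert back.d_of(a, b) == net.d_of(a, b)

    def test_unknown_node_in_record_rejected(self, tmp_path):
        net = self.make_net()
        rec = SpecificityResult(("s1", "zz"), "c", 0.7, 0.1, 7.0, 0, 10, 0.0, True)
        with pytest.raises(ValueError, match="unknown node"):
            write_network(net, [rec], tmp_path / "x.tsv", "tsv")

    def test_graphml_attributes(self, tmp_path):
        import networkx as nx

        net = self.make_net()
        path = tmp_path / "net.graphml"
        write_network(net, [], path, "graphml")
        g = nx.read_graphml(path)
        assert g.edges[("s1", "s2")]["d"] == pytest.approx(0.7)


class TestSearchConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(R=0)
        with pytest.raises(ValueError):
            SearchConfig(ess=0)
        with pytest.raises(ValueError):
            SearchConfig(max_parents=0)

    def test_default_edge_probability_sparse(self):
        assert SearchConfig().edge_prob(41) == pytest.approx(0.05)
        assert SearchConfig().edge_prob(3) == 0.5
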