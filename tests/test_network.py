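"""Network data model, TSV dialect, filters, and Laplacian blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npa.network import (
    NetworkFormatError,
    TwoLayerNetwork,
    _from_edges,
    build_laplacian_blocks,
    prune_underrepresented,
    read_network,
    restrict_to_scorable,
    write_network,
)

from conftest import npa_edge_sum, objective_sum, random_instance


def _write(tmp_path, text, name="net.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "source\tsign\ttarget\tlayer\n"


class TestReadNetwork:
    def test_reads_three_row_file(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER + "a\t1\tb\tfunctional\na\t1\tG1\ttranscript\nb\t-1\tG2\ttranscript\n",
        )
        net = read_network(p)
        assert net.backbone_nodes == {"a", "b"}
        assert net.gene_nodes == {"G1", "G2"}
        assert net.backbone_edges == (("a", "b", 1),)
        assert ("b", "G2", -1) in net.transcript_edges

    def test_sign_alias_tokens_equivalent(self, tmp_path):
        numeric = read_network(
            _write(tmp_path, HEADER + "a\t1\tb\tfunctional\na\t-1\tG1\ttranscript\n", "a.tsv")
        )
        causal = read_network(
            _write(
                tmp_path,
                HEADER + "a\tincreases\tb\tfunctional\na\tdecreases\tG1\ttranscript\n",
                "b.tsv",
            )
        )
        assert numeric.backbone_edges == causal.backbone_edges
        assert numeric.transcript_edges == causal.transcript_edges

    def test_empty_transcript_layer_rejected(self, tmp_path):
        p = _write(tmp_path, HEADER + "a\t1\tb\tfunctional\n")
        with pytest.raises(NetworkFormatError, match="no transcript layer"):
            read_network(p)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = _write(tmp_path, HEADER + "a\t1\tb\tfunctional\na\t1\tG1\n")
        with pytest.raises(NetworkFormatError, match=":3"):
            read_network(p)

    def test_unknown_layer_and_sign_rejected(self, tmp_path):
        with pytest.raises(NetworkFormatError, match="layer"):
            read_network(_write(tmp_path, HEADER + "a\t1\tG1\tgenes\n", "l.tsv"))
        with pytest.raises(NetworkFormatError, match="sign"):
            read_network(_write(tmp_path, HEADER + "a\t2\tG1\ttranscript\n", "s.tsv"))

    def test_duplicate_edge_warns_and_dedups(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER
            + "a\t1\tb\tfunctional\na\t1\tG1\ttranscript\na\t1\tG1\ttranscript\n",
        )
        with pytest.warns(UserWarning, match="duplicate"):
            net = read_network(p)
        assert len(net.transcript_edges) == 1

    def test_self_loop_rejected(self, tmp_path):
        p = _write(tmp_path, HEADER + "a\t1\ta\tfunctional\na\t1\tG1\ttranscript\n")
        with pytest.raises(NetworkFormatError, match="self-loop"):
            read_network(p)

    def test_sidecar_meta_and_roundtrip(self, tmp_path):
        net = _from_edges(
            [("a", "b", -1)], [("a", "G1", 1), ("b", "G2", -1)],
            name="mynet", family="stress",
        )
        p = tmp_path / "out.tsv"
        write_network(net, p)
        back = read_network(p)
        assert back.name == "mynet" and back.family == "stress"
        assert set(back.backbone_edges) == set(net.backbone_edges)
        assert set(back.transcript_edges) == set(net.transcript_edges)


class TestInvariantsOfType:
    def test_overlapping_layers_rejected(self):
        with pytest.raises(NetworkFormatError, match="overlap"):
            TwoLayerNetwork(
                backbone_nodes=frozenset({"a", "x"}),
                gene_nodes=frozenset({"x"}),
                backbone_edges=(),
                transcript_edges=(("a", "x", 1),),
            )

    def test_bad_sign_rejected(self):
        with pytest.raises(NetworkFormatError, match="sign"):
            _from_edges([("a", "b", 2)], [("a", "G", 1)])


class TestPruneUnderrepresented:
    def _net(self, k):
        tedges = [("a", f"G{i}", 1) for i in range(k)] + [("b", f"H{i}", 1) for i in range(6)]
        return _from_edges([("a", "b", 1)], tedges)

    @pytest.mark.parametrize(
        "k,remaining_a", [(4, 0), (5, 5), (1, 0), (6, 6)]
    )
    def test_five_downstream_rule(self, k, remaining_a):
        pruned = prune_underrepresented(self._net(k), min_downstream=5)
        a_edges = [e for e in pruned.transcript_edges if e[0] == "a"]
        assert len(a_edges) == remaining_a
        # backbone untouched, node with >=5 untouched
        assert pruned.backbone_edges == (("a", "b", 1),)
        assert len([e for e in pruned.transcript_edges if e[0] == "b"]) == 6

    def test_threshold_one_is_vacuous(self):
        net = self._net(2)
        assert prune_underrepresented(net, min_downstream=1) is net

    def test_zero_footprint_nodes_untouched(self):
        net = _from_edges(
            [("a", "b", 1)], [("b", f"H{i}", 1) for i in range(6)]
        )
        assert prune_underrepresented(net) is net

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            prune_underrepresented(self._net(5), min_downstream=0)


class TestRestrictToScorable:
    def test_chain_with_middle_footprint_keeps_all(self):
        # a->b->c, only b measured: a has descendant b, c has ancestor b
        net = _from_edges(
            [("a", "b", 1), ("b", "c", 1)],
            [("b", f"G{i}", 1) for i in range(5)],
        )
        out = restrict_to_scorable(net)
        assert out.backbone_nodes == {"a", "b", "c"}

    def test_isolated_unmeasured_node_removed(self):
        net = _from_edges(
            [("a", "b", 1)],
            [("a", "G0", 1), ("b", "G1", 1)],
            extra_backbone_nodes=["z"],
        )
        out = restrict_to_scorable(net)
        assert "z" not in out.backbone_nodes
        assert out.backbone_nodes == {"a", "b"}

    def test_node_with_no_measured_relative_removed(self):
        # a->b (b measured), a->w: w reaches no measured node either way
        net = _from_edges(
            [("a", "b", 1), ("a", "w", 1)], [("b", "G0", 1)]
        )
        out = restrict_to_scorable(net)
        assert out.backbone_nodes == {"a", "b"}
        assert out.backbone_edges == (("a", "b", 1),)

    def test_vacuous_when_all_measured(self):
        net = _from_edges(
            [("a", "b", 1)], [("a", "G0", 1), ("b", "G1", 1)]
        )
        assert restrict_to_scorable(net) is net

    def test_idempotent_and_monotone(self, rng):
        for _ in range(20):
            net, _ = random_instance(rng)
            once = restrict_to_scorable(net)
            assert restrict_to_scorable(once) is once
            assert once.backbone_nodes <= net.backbone_nodes

    def test_errors_when_nothing_scorable(self):
        net = TwoLayerNetwork(
            backbone_nodes=frozenset({"a", "b"}),
            gene_nodes=frozenset(),
            backbone_edges=(("a", "b", 1),),
            transcript_edges=(),
        )
        with pytest.raises(NetworkFormatError, match="no scorable"):
            restrict_to_scorable(net)

    def test_filter_pipeline_idempotent(self, rng):
        from npa.network import prepare_network

        for _ in range(20):
            net, _ = random_instance(rng)
            once = prepare_network(net, min_downstream=1)
            twice = prepare_network(once, min_downstream=1)
            assert twice.backbone_nodes == once.backbone_nodes
            assert set(twice.transcript_edges) == set(once.transcript_edges)


class TestLaplacianBlocks:
    def test_two_node_example(self, two_node_net):
        b = build_laplacian_blocks(two_node_net)
        assert np.array_equal(b.L3, [[2, -1], [-1, 2]])
        assert np.array_equal(b.Q, [[1, 1], [1, 1]])
        assert b.E_size == 1
        assert np.array_equal(b.L2, [[-1, 0], [0, -1]])

    def test_contradictory_parallel_edges_cancel_offdiagonal(self):
        net = _from_edges(
            [("a", "b", 1), ("a", "b", -1)],
            [("a", "G0", 1), ("b", "G1", 1)],
        )
        b = build_laplacian_blocks(net)
        assert b.E_size == 2
        assert b.L3[0, 1] == 0 and b.Q[0, 1] == 0
        assert b.L3[0, 0] == 3  # two backbone edges + one transcript edge
        assert b.Q[0, 0] == 2

    def test_missing_transcript_edges_rejected(self):
        net = TwoLayerNetwork(
            backbone_nodes=frozenset({"a", "b"}),
            gene_nodes=frozenset(),
            backbone_edges=(("a", "b", 1),),
            transcript_edges=(),
        )
        with pytest.raises(NetworkFormatError, match="transcript"):
            build_laplacian_blocks(net)

    def test_singular_backbone_names_components(self):
        # two components, one without any transcript support
        net = _from_edges(
            [("a", "b", 1), ("c", "d", 1)],
            [("a", "G0", 1), ("b", "G1", 1)],
        )
        with pytest.raises(NetworkFormatError, match=r"\['c', 'd'\]"):
            build_laplacian_blocks(net)

    def test_q_quadratic_form_equals_edge_sum(self, rng):
        for _ in range(100):
            net, _ = random_instance(rng)
            b = build_laplacian_blocks(net)
            f = rng.normal(0, 1, size=b.n_backbone)
            fd = dict(zip(b.node_order, f))
            explicit = npa_edge_sum(net, fd)
            viaq = float(f @ b.Q @ f) / b.E_size
            assert viaq == pytest.approx(explicit, rel=1e-10, abs=1e-12)

    def test_full_laplacian_reproduces_objective(self, rng):
        for _ in range(100):
            net, beta = random_instance(rng)
            b = build_laplacian_blocks(net)
            f = rng.normal(0, 1, size=b.n_backbone)
            bv = np.array([beta[g] for g in b.gene_order])
            # L1 block (gene-gene): diagonal of transcript degrees per gene
            gdeg = np.zeros(len(b.gene_order))
            gidx = {g: i for i, g in enumerate(b.gene_order)}
            for _, g, _ in net.transcript_edges:
                gdeg[gidx[g]] += 1
            quad = f @ b.L3 @ f + 2 * f @ b.L2 @ bv + bv @ (gdeg * bv)
            explicit = objective_sum(
                net, dict(zip(b.node_order, f)), beta
            )
            assert quad == pytest.approx(explicit, rel=1e-10, abs=1e-12)

    def test_l3_symmetric_with_total_degree_diagonal(self, rng):
        for _ in range(20):
            net, _ = random_instance(rng)
            b = build_laplacian_blocks(net)
            assert np.array_equal(b.L3, b.L3.T)
            deg = {x: 0 for x in b.node_order}
            for s, t, _ in net.backbone_edges:
                deg[s] += 1
                deg[t] += 1
            for s, _, _ in net.transcript_edges:
                deg[s] += 1
            assert np.array_equal(
                np.diag(b.L3), [deg[x] for x in b.node_order]
            )
            # Q is PSD
            assert np.linalg.eigvalsh(b.Q).min() > -1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        signs=st.lists(st.sampled_from([-1, 1]), min_size=2, max_size=7),
        fvals=st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=8, max_size=8
        ),
    )
    def test_chain_quadratic_form_identity(self, signs, fvals):
        """On arbitrary signed chains, f'Qf/|E| equals the explicit edge sum."""
        nodes = [f"n{i}" for i in range(len(signs) + 1)]
        backbone = [
            (nodes[i], nodes[i + 1], s) for i, s in enumerate(signs)
        ]
        tedges = [(x, f"g_{x}", 1) for x in nodes]
        net = _from_edges(backbone, tedges)
        b = build_laplacian_blocks(net)
        f = np.array(fvals[: b.n_backbone])
        fd = dict(zip(b.node_order, f))
        assert float(f @ b.Q @ f) / b.E_size == pytest.approx(
            npa_edge_sum(net, fd), rel=1e-10, abs=1e-12
        )
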