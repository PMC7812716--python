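"""Recursive assembly: frontier exploration, depth limits, complexes."""

import pytest

from paxnet.assembler import (
    add_complex_membership_edges,
    filter_unsigned,
    reconstruct,
)
from paxnet.errors import UsageError
from paxnet.expansion import ExpansionConfig, load_synonym_table
from paxnet.graphs import SignedEdge
from paxnet.synthetic_kb import (
    KbSpec,
    generate_kb,
    ground_truth_upstream,
    influence_edge_tuples,
    write_gene_info,
)

from conftest import PREFIX, kb_from_ttl

ALL_ON = ExpansionConfig(use_synonyms=True, use_complex_decomposition=True,
                         use_label_expansion=True)


@pytest.fixture
def chain():
    """Planted activation chain N003 -> N002 -> N001 -> G000."""
    spec = KbSpec(n_genes=1, n_levels=3, branching=1.0, p_inhibition=0.0,
                  seed=7)
    return generate_kb(spec)


class TestReconstruct:
    def test_chain_recovered_at_full_depth(self, chain):
        kb, truth = chain
        result = reconstruct(kb, truth.input_genes, max_depth=3)
        graph = result.influence_graph
        assert graph.n_nodes == 4
        assert graph.n_edges == 3
        assert all(e.sign == "ACTIVATION" for e in graph.edges())
        assert result.levels_run == 3

    def test_depth_one_gives_single_edge(self, chain):
        kb, truth = chain
        result = reconstruct(kb, truth.input_genes, max_depth=1)
        assert result.influence_graph.n_nodes == 2
        assert result.influence_graph.n_edges == 1
        assert result.levels_run == 1

    def test_absent_gene_yields_empty_graph_and_zero_coverage(self, chain):
        kb, _ = chain
        result = reconstruct(kb, ["NOT_THERE"], max_depth=3)
        assert result.influence_graph.n_edges == 0
        assert result.coverage.S == 0.0
        # frontier exhausted immediately after the first round
        assert result.levels_run == 1

    def test_empty_gene_list_is_usage_error(self, chain):
        with pytest.raises(UsageError):
            reconstruct(chain[0], [], max_depth=3)

    def test_exploration_stops_when_frontier_exhausts(self, chain):
        kb, truth = chain
        result = reconstruct(kb, truth.input_genes, max_depth=50)
        assert result.levels_run <= 5  # 3 real levels + querying the leaves

    def test_autoregulation_self_loop_terminates(self):
        ttl = PREFIX + """
        ex:reg1 a bp:TemplateReactionRegulation ;
            bp:controlled ex:tmpl1 ; bp:controller ex:g ;
            bp:controlType "ACTIVATION" .
        ex:tmpl1 a bp:TemplateReaction ; bp:product ex:g .
        ex:g a bp:Protein ; bp:displayName "g" .
        """
        result = reconstruct(kb_from_ttl(ttl), ["g"], max_depth=10)
        [edge] = list(result.influence_graph.edges())
        assert (edge.source, edge.target) == ("g", "g")
        assert result.levels_run == 1  # g never re-enters the frontier

    def test_decorated_controller_is_stripped_before_node_creation(self):
        ttl = PREFIX + """
        ex:reg1 a bp:TemplateReactionRegulation ;
            bp:controlled ex:tmpl1 ; bp:controller ex:myc ;
            bp:controlType "ACTIVATION" .
        ex:tmpl1 a bp:TemplateReaction ; bp:product ex:a .
        ex:myc a bp:Protein ; bp:displayName "expression of MYC" .
        ex:a a bp:Protein ; bp:displayName "A" .
        """
        cfg = ExpansionConfig(use_label_expansion=True)
        result = reconstruct(kb_from_ttl(ttl), ["A"], max_depth=1, config=cfg)
        assert result.influence_graph.node_names() == {"MYC", "A"}

    def test_provenance_histogram_counts_influence_edges(self, chain):
        kb, truth = chain
        result = reconstruct(kb, truth.input_genes, max_depth=3)
        planted = {}
        for _, _, _, _, db in truth.upstream_edges:
            planted[db] = planted.get(db, 0) + 1
        assert result.provenance_histogram == planted


class TestComplexes:
    def test_complex_controller_contributes_part_of_edges(self):
        spec = KbSpec(n_genes=1, n_levels=1, branching=1.0, p_inhibition=0.0,
                      n_complexes=1, complex_size=(2, 2), seed=3)
        kb, truth = generate_kb(spec)
        [(label, members)] = truth.complexes.items()
        result = reconstruct(kb, truth.input_genes, max_depth=1,
                             config=ExpansionConfig(use_complex_decomposition=True))
        part_of = [e for e in result.influence_graph.edges()
                   if e.sign == "PART_OF"]
        assert {(e.source, e.target) for e in part_of} == {
            (m, label) for m in members
        }
        # membership edges point member -> complex-classed node
        for e in part_of:
            assert e.kind == "membership"
            assert result.influence_graph.entity(e.target).entity_class == "complex"

    def test_without_decomposition_no_membership_edges(self):
        spec = KbSpec(n_genes=1, n_levels=1, branching=1.0, n_complexes=1,
                      seed=3)
        kb, truth = generate_kb(spec)
        result = reconstruct(kb, truth.input_genes, max_depth=1)
        assert all(e.sign != "PART_OF" for e in result.influence_graph.edges())

    def test_label_only_complex_decomposes_syntactically(self):
        edges, members = add_complex_membership_edges(set(), "A/B", ["A", "B"])
        assert members == ["A", "B"]
        assert edges == {
            SignedEdge("A", "A/B", "PART_OF", "membership"),
            SignedEdge("B", "A/B", "PART_OF", "membership"),
        }


class TestInvariants:
    def test_depth_monotonicity(self):
        """Edge set at depth d is a subset of the edge set at depth d+1."""
        spec = KbSpec(n_genes=3, n_levels=5, branching=1.5, p_inhibition=0.3,
                      p_unknown=0.1, n_complexes=2, seed=11,
                      reuse_probability=0.2)
        kb, truth = generate_kb(spec)
        previous = set()
        for depth in range(1, 6):
            result = reconstruct(kb, truth.input_genes, max_depth=depth,
                                 config=ALL_ON)
            current = influence_edge_tuples(result.influence_graph)
            assert previous <= current
            previous = current

    def test_determinism(self):
        spec = KbSpec(n_genes=2, n_levels=3, branching=1.5, seed=4,
                      n_complexes=1)
        kb, truth = generate_kb(spec)
        a = reconstruct(kb, truth.input_genes, max_depth=3, config=ALL_ON)
        b = reconstruct(kb, truth.input_genes, max_depth=3, config=ALL_ON)
        assert influence_edge_tuples(a.influence_graph) == \
            influence_edge_tuples(b.influence_graph)
        assert a.influence_graph.node_names() == b.influence_graph.node_names()

    def test_exclusion_removes_exactly_tagged_edges(self):
        spec = KbSpec(n_genes=3, n_levels=2, branching=2.0, seed=9,
                      source_names=("ctd", "pid", "panther"))
        kb, truth = generate_kb(spec)
        full = ground_truth_upstream(truth, set(truth.input_genes), 2)
        for excluded in ({"ctd"}, {"pid", "panther"}):
            result = reconstruct(kb, truth.input_genes, max_depth=2,
                                 excluded_sources=excluded)
            got = influence_edge_tuples(result.influence_graph)
            assert all(db not in excluded for *_, db in got)
            # every surviving ground-truth edge reachable without the
            # excluded sources must still be present
            assert got <= {t for t in full if t[4] not in excluded}

    def test_drop_unknown_traversal(self):
        spec = KbSpec(n_genes=2, n_levels=3, branching=1.5, p_unknown=0.5,
                      seed=13)
        kb, truth = generate_kb(spec)
        result = reconstruct(kb, truth.input_genes, max_depth=3,
                             drop_unknown=True)
        got = influence_edge_tuples(result.influence_graph)
        assert all(sign != "UNKNOWN" for _, _, sign, _, _ in got)
        assert got == ground_truth_upstream(truth, set(truth.input_genes), 3,
                                            drop_unknown=True)


class TestFilterUnsigned:
    def test_removes_exactly_unknown(self):
        edges = {
            SignedEdge("a", "b", "ACTIVATION", "transcriptional"),
            SignedEdge("b", "c", "INHIBITION", "transcriptional"),
            SignedEdge("c", "d", "UNKNOWN", "transcriptional"),
            SignedEdge("m", "k", "PART_OF", "membership"),
        }
        kept = filter_unsigned(edges)
        assert {e.sign for e in kept} == {"ACTIVATION", "INHIBITION", "PART_OF"}

    def test_all_unknown_gives_empty(self):
        edges = {SignedEdge("a", "b", "UNKNOWN", "signaling")}
        assert filter_unsigned(edges) == set()

    def test_empty_set(self):
        assert filter_unsigned(set()) == set()
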