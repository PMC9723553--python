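"""Relationship graph: parsing, canonical form, published designs, queries,
and agreement with brute-force oracles on random small graphs."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixs_sa import (
    MetadataTable,
    SampleRecord,
    build_graph,
    canonicalize_edges,
    colocated,
    contains_closure,
    export_edges,
    nested_within,
    parse_relationships,
    replicate_groups,
    validate_graph,
)
from mixs_sa.errors import (
    FormatNotSupportedError,
    RelationshipSyntaxError,
    SampleNotFoundError,
)
from mixs_sa.relgraph import RelationshipEdge, SampleGraph, parse_relationship_entry

from .conftest import FIG1A_CANONICAL_EDGES, FIG1B_CANONICAL_EDGES, edge
from .oracles import (
    brute_force_has_cycle,
    fixpoint_closure,
    fixpoint_closure_reverse,
    bfs_levels,
    random_digraph,
)


def graph_of(edges, nodes=None):
    nodes = nodes or sorted({e.subject for e in edges} | {e.object for e in edges})
    return SampleGraph(nodes={n: "water" for n in nodes}, edges=canonicalize_edges(list(edges)))


# ------------------------------------------------------------------ parsing

def test_parse_relationships_of_a_record():
    rec = SampleRecord(
        "SA1234", "symbiont-associated",
        relationship_entries=["within:HA8974", "next to:SA7890"],
    )
    assert parse_relationships(rec) == [
        edge("SA1234", "within", "HA8974"),
        edge("SA1234", "next_to", "SA7890"),
    ]


@pytest.mark.parametrize(
    "entry,ok",
    [
        ("'technical replicate of' : X2", True),
        ("NEXT TO:Y", True),
        ("technical_replicate_of:X2", True),
        ("contains: Z9", True),
    ],
)
def test_predicate_matching_is_case_and_form_insensitive(entry, ok):
    assert parse_relationship_entry("A", entry).object in {"X2", "Y", "Z9"}


@pytest.mark.parametrize(
    "subject,entry,code",
    [
        ("A", "inside:H1", "BAD_PREDICATE"),
        ("A", "no-separator", "BAD_PREDICATE"),
        ("A", "within:  ", "BAD_TARGET"),
        ("SA1234", "within:SA1234", "SELF_RELATION"),
    ],
)
def test_malformed_entries_raise_with_stable_codes(subject, entry, code):
    with pytest.raises(RelationshipSyntaxError) as exc:
        parse_relationship_entry(subject, entry)
    assert exc.value.code == code


# --------------------------------------------------------------- canonical

def test_canonicalization_rewrites_sugar_and_orients_symmetric_edges():
    assert canonicalize_edges([edge("H1", "contains", "S1")]) == {edge("S1", "within", "H1")}
    assert canonicalize_edges([edge("B", "after", "A")]) == {edge("A", "before", "B")}
    assert canonicalize_edges([edge("E2", "next_to", "E1")]) == {edge("E1", "next_to", "E2")}


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["A", "B", "C", "D"]),
            st.sampled_from(
                ["within", "contains", "before", "after", "next_to", "technical_replicate_of"]
            ),
            st.sampled_from(["A", "B", "C", "D"]),
        ).filter(lambda t: t[0] != t[2]),
        max_size=12,
    )
)
def test_canonicalization_is_idempotent(triples):
    edges = [RelationshipEdge(*t) for t in triples]
    once = canonicalize_edges(edges)
    assert canonicalize_edges(list(once)) == once


def test_inverse_pair_equivalence(fig1a_table):
    """A table written with 'contains' edges builds the same graph as the
    same table written with flipped 'within' edges."""
    flipped = MetadataTable(bioproject_id=fig1a_table.bioproject_id)
    moves = []  # (target_record_id, new_entry)
    for rec in fig1a_table.records:
        keep = []
        for entry in rec.relationship_entries:
            pred, _, target = entry.partition(":")
            if pred.strip() == "within":
                moves.append((target.strip(), f"contains:{rec.sample_id}"))
            else:
                keep.append(entry)
        flipped.records.append(
            SampleRecord(rec.sample_id, rec.package, dict(rec.attributes), keep)
        )
    for target_id, entry in moves:
        flipped.get(target_id).relationship_entries.append(entry)
    assert build_graph(flipped).edges == build_graph(fig1a_table).edges


# --------------------------------------------------- published study designs

def test_trematode_design_reproduces_the_declared_structure(fig1a_graph):
    assert set(fig1a_graph.nodes) == {"S1", "S2", "S3", "S4", "H1", "H2", "H3", "E1", "E2"}
    assert fig1a_graph.edges == FIG1A_CANONICAL_EDGES
    assert fig1a_graph.issues == []
    assert [i for i in validate_graph(fig1a_graph) if i.severity == "ERROR"] == []


def test_parasitic_plant_design_reproduces_the_declared_structure(fig1b_graph):
    assert set(fig1b_graph.nodes) == {"S5", "S6", "P1", "P2", "P3", "E3", "E4"}
    assert fig1b_graph.edges == FIG1B_CANONICAL_EDGES
    assert [i for i in validate_graph(fig1b_graph) if i.severity == "ERROR"] == []


def test_dangling_reference_is_collected_not_fatal(fig1a_table):
    fig1a_table.get("S1").relationship_entries.append("within:X9")
    g = build_graph(fig1a_table)
    assert [i.code for i in g.issues] == ["DANGLING_REFERENCE"]
    assert g.edges == FIG1A_CANONICAL_EDGES  # offending edge dropped


# --------------------------------------------------------------- validation

def test_containment_and_temporal_cycles_detected():
    g = graph_of([edge("A", "within", "B"), edge("B", "within", "A")])
    assert [i.code for i in validate_graph(g)] == ["CONTAINMENT_CYCLE"]
    g = graph_of([edge("A", "before", "B"), edge("B", "before", "C"), edge("C", "before", "A")])
    assert [i.code for i in validate_graph(g)] == ["TEMPORAL_CYCLE"]


def test_contradictory_relation_is_a_warning():
    g = graph_of([edge("S1", "within", "H1"), edge("S1", "next_to", "H1")])
    issues = validate_graph(g)
    assert [(i.code, i.severity) for i in issues] == [("CONTRADICTORY_RELATION", "WARNING")]


def test_replicates_in_different_packages_warn():
    g = SampleGraph(
        nodes={"A": "water", "B": "soil"},
        edges=canonicalize_edges([edge("A", "technical_replicate_of", "B")]),
    )
    assert [i.code for i in validate_graph(g)] == ["REPLICATE_PACKAGE_MISMATCH"]


# ------------------------------------------------------------------ queries

def test_nesting_queries_on_the_trematode_design(fig1a_graph):
    assert nested_within(fig1a_graph, "S1") == ["H1", "E2"]
    assert nested_within(fig1a_graph, "E2") == []
    assert contains_closure(fig1a_graph, "E2") == {"S1", "S2", "S3", "S4", "H1", "H2", "H3"}
    assert contains_closure(fig1a_graph, "S1") == set()
    assert colocated(fig1a_graph, "E1") == {"H1", "E2"}
    assert colocated(fig1a_graph, "S2") == set()
    with pytest.raises(SampleNotFoundError):
        nested_within(fig1a_graph, "nope")


def test_nesting_queries_on_the_plant_design(fig1b_graph):
    assert nested_within(fig1b_graph, "S6") == ["P1", "E3"]
    assert contains_closure(fig1b_graph, "P1") == {"S6"}
    assert colocated(fig1b_graph, "P2") == {"P1", "P3"}


def test_colocated_is_symmetric(fig1a_graph, fig1b_graph):
    for g in (fig1a_graph, fig1b_graph):
        for a in g.nodes:
            for b in colocated(g, a):
                assert a in colocated(g, b)


def test_replicate_groups_partition():
    g = graph_of(
        [
            edge("A", "technical_replicate_of", "B"),
            edge("B", "technical_replicate_of", "C"),
            edge("D", "technical_replicate_of", "E"),
        ],
        nodes=["A", "B", "C", "D", "E", "F"],
    )
    groups = replicate_groups(g)
    assert groups == [frozenset({"A", "B", "C"}), frozenset({"D", "E"})]
    covered = set().union(*groups)
    assert "F" not in covered and all(len(b) >= 2 for b in groups)


def test_replicate_groups_empty_on_fig1a(fig1a_graph):
    assert replicate_groups(fig1a_graph) == []


# ------------------------------------------------------------------- export

def test_edge_tsv_export(fig1a_graph):
    doc = export_edges(fig1a_graph, "edge-tsv")
    lines = doc.strip().split("\n")
    assert lines[0] == "subject\tpredicate\tobject"
    assert len(lines) - 1 == 9
    assert "E1\tnext to\tE2" in lines
    assert export_edges(SampleGraph(), "edge-tsv") == "subject\tpredicate\tobject\n"


def test_dot_export_styles(fig1a_graph):
    doc = export_edges(fig1a_graph, "dot")
    assert doc.startswith("digraph") and "dir=none" in doc
    with pytest.raises(FormatNotSupportedError):
        export_edges(fig1a_graph, "xlsx")


# --------------------------------------------------------- oracle agreement

def test_cycle_detection_and_closures_match_brute_force():
    """On 200 random graphs of <= 8 nodes, cycle detection agrees with simple
    path enumeration and the closure queries with naive fixpoint expansion."""
    rng = random.Random(20_260_929)
    for _ in range(200):
        nodes, arcs = random_digraph(rng)
        g = SampleGraph(
            nodes={n: "water" for n in nodes},
            edges={edge(a, "within", b) for (a, b) in arcs},
        )
        has_cycle = any(i.code == "CONTAINMENT_CYCLE" for i in validate_graph(g))
        assert has_cycle == brute_force_has_cycle(nodes, arcs)
        if has_cycle:
            continue
        for n in nodes:
            assert set(nested_within(g, n)) == fixpoint_closure(n, arcs)
            assert nested_within(g, n) == bfs_levels(n, arcs)
            assert contains_closure(g, n) == fixpoint_closure_reverse(n, arcs)
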