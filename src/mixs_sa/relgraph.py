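"""Cross-package sample-relationship graph: parse, canonicalize, validate, query.

The "relationship to other samples" term links samples of one Bioproject with a
closed six-predicate vocabulary: 'technical replicate of', 'after', 'before',
'next to', 'within' and 'contains'. Within/contains and after/before are
inverse pairs; next-to and technical-replicate-of are symmetric. Edges are
stored in a canonical form — ``contains(a, b)`` as ``within(b, a)``,
``after(a, b)`` as ``before(a's object first)``, symmetric edges with the
lexicographically smaller endpoint first — so containment and temporal
queries run over a single stored direction.

Containment is deliberately a DAG, not a tree (a sample may sit within several
containers, e.g. a snail both next to a sediment sample and within the water
body), and 'next to' is not transitive: queries return only what the declared
edges state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import (
    FormatNotSupportedError,
    RelationshipSyntaxError,
    SampleNotFoundError,
)
from .records import MetadataTable, SampleRecord
from .validator import ValidationIssue

__all__ = [
    "PREDICATES",
    "SYMMETRIC_PREDICATES",
    "INVERSE_PREDICATES",
    "RelationshipEdge",
    "SampleGraph",
    "parse_relationship_entry",
    "parse_relationships",
    "canonicalize_edges",
    "build_graph",
    "validate_graph",
    "nested_within",
    "contains_closure",
    "colocated",
    "replicate_groups",
    "export_edges",
]

#: token -> display form as written in relationship cells.
PREDICATES: dict[str, str] = {
    "technical_replicate_of": "technical replicate of",
    "after": "after",
    "before": "before",
    "next_to": "next to",
    "within": "within",
    "contains": "contains",
}

SYMMETRIC_PREDICATES = frozenset({"next_to", "technical_replicate_of"})

#: sugar -> canonical stored predicate (the edge direction flips).
INVERSE_PREDICATES: dict[str, str] = {"contains": "within", "after": "before"}

_PREDICATE_LOOKUP = {
    token.replace("_", " "): token for token in PREDICATES
} | {token: token for token in PREDICATES}


@dataclass(frozen=True, order=True)
class RelationshipEdge:
    """One directed relation between two samples of a Bioproject."""

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise RelationshipSyntaxError(
                "BAD_PREDICATE", f"unknown predicate {self.predicate!r}"
            )
        if self.subject == self.object:
            raise RelationshipSyntaxError(
                "SELF_RELATION", f"sample {self.subject!r} related to itself"
            )

    @property
    def display_predicate(self) -> str:
        return PREDICATES[self.predicate]


# ------------------------------------------------------------------ parsing

def parse_relationship_entry(subject: str, entry: str) -> RelationshipEdge:
    """Parse one ``predicate:target`` relationship-cell entry.

    The predicate is matched case-insensitively against the vocabulary in
    either display ('next to') or token ('next_to') form; surrounding straight
    quotes are tolerated.
    """
    pred_part, sep, target = entry.partition(":")
    if not sep:
        raise RelationshipSyntaxError(
            "BAD_PREDICATE", f"entry {entry!r} is not of the form predicate:target"
        )
    pred_key = pred_part.strip().strip("'\"").lower().replace("-", " ")
    token = _PREDICATE_LOOKUP.get(pred_key) or _PREDICATE_LOOKUP.get(
        pred_key.replace(" ", "_")
    )
    if token is None:
        raise RelationshipSyntaxError(
            "BAD_PREDICATE",
            f"unknown predicate {pred_part.strip()!r} "
            f"(accepted: {', '.join(sorted(PREDICATES.values()))})",
        )
    target = target.strip()
    if not target:
        raise RelationshipSyntaxError("BAD_TARGET", f"entry {entry!r} has no target")
    return RelationshipEdge(subject=subject, predicate=token, object=target)


def parse_relationships(record: SampleRecord) -> list[RelationshipEdge]:
    """All relationship edges declared by one record (subject = the record)."""
    return [
        parse_relationship_entry(record.sample_id, entry)
        for entry in record.relationship_entries
    ]


# ----------------------------------------------------------- canonical form

def canonicalize_edge(edge: RelationshipEdge) -> RelationshipEdge:
    if edge.predicate in INVERSE_PREDICATES:
        return RelationshipEdge(
            subject=edge.object,
            predicate=INVERSE_PREDICATES[edge.predicate],
            object=edge.subject,
        )
    if edge.predicate in SYMMETRIC_PREDICATES and edge.object < edge.subject:
        return RelationshipEdge(
            subject=edge.object, predicate=edge.predicate, object=edge.subject
        )
    return edge


def canonicalize_edges(edges: list[RelationshipEdge]) -> set[RelationshipEdge]:
    """Rewrite sugar predicates, orient symmetric edges, drop duplicates.

    Idempotent: canonicalizing an already-canonical set is the identity.
    """
    return {canonicalize_edge(e) for e in edges}


# -------------------------------------------------------------------- graph

@dataclass
class SampleGraph:
    """All samples of a table plus the canonical relationship edge set.

    ``issues`` collects problems found while building (malformed entries,
    dangling targets); the graph is still usable minus the offending edges.
    """

    nodes: dict[str, str] = field(default_factory=dict)  # sample_id -> package
    edges: set[RelationshipEdge] = field(default_factory=set)
    issues: list[ValidationIssue] = field(default_factory=list)

    def _require(self, sample: str) -> None:
        if sample not in self.nodes:
            raise SampleNotFoundError(f"sample {sample!r} not in graph")

    def subgraph(self, predicate: str) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (e.subject, e.object) for e in self.edges if e.predicate == predicate
        )
        return g

    def symmetric_view(self, predicate: str) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(
            (e.subject, e.object) for e in self.edges if e.predicate == predicate
        )
        return g


def build_graph(table: MetadataTable) -> SampleGraph:
    """Assemble the canonical sample graph of a metadata table.

    Malformed relationship entries and edges pointing outside the table are
    reported as ERROR issues on the returned graph rather than raised, so a
    single pass surfaces every problem.
    """
    graph = SampleGraph(nodes={r.sample_id: r.package for r in table.records})
    raw_edges: list[RelationshipEdge] = []
    for record in table.records:
        for entry in record.relationship_entries:
            try:
                edge = parse_relationship_entry(record.sample_id, entry)
            except RelationshipSyntaxError as exc:
                graph.issues.append(
                    ValidationIssue(
                        severity="ERROR",
                        code=exc.code,
                        sample_id=record.sample_id,
                        term="relationship_to_other_samples",
                        message=str(exc),
                    )
                )
                continue
            if edge.object not in graph.nodes:
                graph.issues.append(
                    ValidationIssue(
                        severity="ERROR",
                        code="DANGLING_REFERENCE",
                        sample_id=record.sample_id,
                        term="relationship_to_other_samples",
                        message=(
                            f"relationship target {edge.object!r} is not a sample "
                            "of this table (relationships must stay within one "
                            "Bioproject)"
                        ),
                    )
                )
                continue
            raw_edges.append(edge)
    graph.edges = canonicalize_edges(raw_edges)
    return graph


# --------------------------------------------------------------- validation

def validate_graph(graph: SampleGraph) -> list[ValidationIssue]:
    """Structural checks over the canonical edge set.

    * containment ('within') must be acyclic — a sample cannot transitively
      contain itself;
    * temporal order ('before') must be acyclic;
    * a pair related by both 'within' and 'next to' is contradictory
      (contained vs adjacent) — advisory, the standard does not forbid it;
    * technical replicates reported under different packages are flagged,
      since replicates of one material are expected to share a package.
    """
    issues: list[ValidationIssue] = []
    for predicate, code in (("within", "CONTAINMENT_CYCLE"), ("before", "TEMPORAL_CYCLE")):
        sub = graph.subgraph(predicate)
        if not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            path = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
            issues.append(
                ValidationIssue(
                    severity="ERROR",
                    code=code,
                    sample_id=cycle[0][0],
                    term=None,
                    message=f"cycle in {predicate!r} edges: {path}",
                )
            )
    within_pairs = {
        frozenset((e.subject, e.object)) for e in graph.edges if e.predicate == "within"
    }
    for e in sorted(graph.edges):
        if e.predicate == "next_to" and frozenset((e.subject, e.object)) in within_pairs:
            issues.append(
                ValidationIssue(
                    severity="WARNING",
                    code="CONTRADICTORY_RELATION",
                    sample_id=e.subject,
                    term=None,
                    message=(
                        f"{e.subject} and {e.object} are related by both "
                        "'within' and 'next to'"
                    ),
                )
            )
        if (
            e.predicate == "technical_replicate_of"
            and graph.nodes.get(e.subject) != graph.nodes.get(e.object)
        ):
            issues.append(
                ValidationIssue(
                    severity="WARNING",
                    code="REPLICATE_PACKAGE_MISMATCH",
                    sample_id=e.subject,
                    term=None,
                    message=(
                        f"technical replicates {e.subject} ({graph.nodes.get(e.subject)}) "
                        f"and {e.object} ({graph.nodes.get(e.object)}) use different packages"
                    ),
                )
            )
    return issues


# ------------------------------------------------------------------ queries

def nested_within(graph: SampleGraph, sample: str) -> list[str]:
    """Transitive containers of a sample, in breadth-first (innermost-first)
    order with duplicates removed; ties within a nesting level are sorted."""
    graph._require(sample)
    sub = graph.subgraph("within")
    order: list[str] = []
    seen = {sample}
    frontier = [sample]
    while frontier:
        level = sorted(
            {c for node in frontier for c in sub.successors(node)} - seen
        )
        order.extend(level)
        seen.update(level)
        frontier = level
    return order


def contains_closure(graph: SampleGraph, sample: str) -> set[str]:
    """All samples transitively contained in the query sample."""
    graph._require(sample)
    sub = graph.subgraph("within")
    # within edges point contained -> container, so descendants are ancestors
    # of the query in the stored direction.
    return set(nx.ancestors(sub, sample))


def colocated(graph: SampleGraph, sample: str) -> set[str]:
    """Direct 'next to' neighbors (no transitive closure)."""
    graph._require(sample)
    view = graph.symmetric_view("next_to")
    if sample not in view:
        return set()
    return set(view.neighbors(sample))


def replicate_groups(graph: SampleGraph) -> list[frozenset[str]]:
    """Replicate groups: connected components under technical-replicate edges.

    Samples with no replicate edge are excluded, so every group has >= 2
    members; the groups partition the replicate-edge endpoints.
    """
    view = graph.symmetric_view("technical_replicate_of")
    groups = [frozenset(c) for c in nx.connected_components(view)]
    return sorted(groups, key=lambda g: sorted(g)[0])


# ------------------------------------------------------------------- export

def _sorted_edges(graph: SampleGraph) -> list[RelationshipEdge]:
    return sorted(graph.edges, key=lambda e: (e.subject, e.predicate, e.object))


def export_edges(graph: SampleGraph, format: str = "edge-tsv") -> str:
    """Render the canonical edge set as an edge TSV or a Graphviz DOT digraph."""
    if format == "edge-tsv":
        lines = ["subject\tpredicate\tobject"]
        lines += [
            f"{e.subject}\t{e.display_predicate}\t{e.object}"
            for e in _sorted_edges(graph)
        ]
        return "\n".join(lines) + "\n"
    if format == "dot":
        lines = ["digraph samples {"]
        for node in sorted(graph.nodes):
            lines.append(f'  "{node}" [label="{node}\\n{graph.nodes[node]}"];')
        for e in _sorted_edges(graph):
            style = ' [dir=none, style=dashed]' if e.predicate in SYMMETRIC_PREDICATES else ""
            lines.append(
                f'  "{e.subject}" -> "{e.object}" '
                f'[label="{e.display_predicate}"]{style};'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise FormatNotSupportedError(f"unsupported export format {format!r}")
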