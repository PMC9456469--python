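"""Minimal OBO ontology handling: parse, write, annotation propagation.

Only ``is_a`` edges are followed; a gene directly annotated to a term is
implicitly annotated to every ancestor (true-path rule).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class GoDag:
    """Acyclic is_a graph over ontology terms.

    ``graph`` holds one directed edge child -> parent per is_a relation.
    """

    terms: dict[str, tuple[str, str]]  # id -> (label, namespace)
    graph: nx.DiGraph

    @property
    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if self.graph.out_degree(t) == 0)

    def label(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        return nx.descendants(self.graph, term_id)  # edges point child->parent

    def filter_namespace(self, namespace: str) -> "GoDag":
        keep = {t for t, (_, ns) in self.terms.items() if ns == namespace}
        sub = self.graph.subgraph(keep).copy()
        return GoDag(terms={t: self.terms[t] for t in keep}, graph=sub)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        roots = set(self.roots)
        for t in self.terms:
            if t in roots:
                continue
            if not (self.ancestors(t) & roots):
                raise ValueError(f"term {t} does not reach a root")


@dataclass
class GoAnnotation:
    """Direct gene -> terms map plus its ancestor-closed term -> genes map."""

    direct: dict[str, set[str]]
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.direct)


_TERM_RE = re.compile(r"^\[(?P<stanza>[^\]]+)\]\s*$")


def parse_obo(text: str) -> GoDag:
    """Parse a minimal OBO 1.2 document into a :class:`GoDag`.

    Handles ``[Term]`` stanzas with ``id``, ``name``, ``namespace`` and
    ``is_a`` tags.  Obsolete terms are skipped; trailing ``! comment`` text
    on is_a targets is ignored.  Raises on cycles and dangling is_a targets.
    """
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str]] = []
    stanza: dict | None = None

    def flush(cur: dict | None) -> None:
        if not cur or cur.get("obsolete"):
            return
        tid = cur.get("id")
        if tid is None:
            raise ValueError("[Term] stanza without an id")
        terms[tid] = (cur.get("name", tid), cur.get("namespace", ""))
        for parent in cur.get("is_a", []):
            edges.append((tid, parent))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _TERM_RE.match(line)
        if m:
            flush(stanza)
            stanza = {"is_a": []} if m.group("stanza") == "Term" else None
            continue
        if stanza is None or ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.split("!", 1)[0].strip()
        if tag == "id":
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = value
        elif tag == "is_a":
            stanza["is_a"].append(value)
        elif tag == "is_obsolete" and value.lower() == "true":
            stanza["obsolete"] = True
    flush(stanza)

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, parent in edges:
        if parent not in terms:
            raise ValueError(f"is_a target {parent!r} of {child!r} is not a term")
        graph.add_edge(child, parent)
    dag = GoDag(terms=terms, graph=graph)
    dag.validate()
    return dag


def write_obo(dag: GoDag, namespace_default: str = "biological_process") -> str:
    """Serialize a :class:`GoDag` to canonical OBO text (sorted, stable)."""
    lines = ["format-version: 1.2", ""]
    for tid in sorted(dag.terms):
        label, ns = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {label}")
        lines.append(f"namespace: {ns or namespace_default}")
        for parent in sorted(dag.parents(tid)):
            lines.append(f"is_a: {parent} ! {dag.label(parent)}")
        lines.append("")
    return "\n".join(lines)


def propagate(dag: GoDag, direct: dict[str, set[str]]) -> GoAnnotation:
    """Ancestor-close direct annotations (true-path rule).

    ``propagated[t]`` is the union of direct genes over t and all of its
    descendants, computed bottom-up in reverse-topological order.
    """
    unknown = sorted(
        {t for ts in direct.values() for t in ts if t not in dag.terms}
    )
    if unknown:
        raise ValueError(f"annotation references unknown terms: {unknown}")
    gene_sets: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in direct.items():
        for t in terms:
            gene_sets[t].add(gene)
    # edges point child->parent, so a topological order lists children first
    for t in nx.topological_sort(dag.graph):
        for parent in dag.parents(t):
            gene_sets[parent] |= gene_sets[t]
    propagated = {t: frozenset(g) for t, g in gene_sets.items()}
    return GoAnnotation(direct={g: set(ts) for g, ts in direct.items()}, propagated=propagated)


def restrict_to_universe(
    ann: GoAnnotation, universe, min_size: int = 1
) -> GoAnnotation:
    """Intersect propagated sets with ``universe``; drop terms below min_size."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    propagated = {}
    for t, genes in ann.propagated.items():
        restricted = genes & universe
        if len(restricted) >= min_size:
            propagated[t] = frozenset(restricted)
    direct = {
        g: set(ts) for g, ts in ann.direct.items() if g in universe
    }
    return GoAnnotation(direct=direct, propagated=propagated)


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> direct annotation map."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("gene"):
            fh.seek(0)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gene, term = line.split("\t")[:2]
            direct.setdefault(gene, set()).add(term)
    return direct


def write_annotations(direct: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")
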