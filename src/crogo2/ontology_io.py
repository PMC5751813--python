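"""Ontology and annotation handling.

Parses an OBO ontology with two or more namespaces (categories), parses gene
annotations (GAF 2.x or a minimal two-column TSV), and propagates annotations
up the DAG following the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor reachable over ``is_a`` and ``part_of``
edges within the term's own category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable

import obonet

log = logging.getLogger(__name__)

#: Parent relations followed during propagation (the GO Consortium default).
PROPAGATING_RELATIONS = frozenset({"is_a", "part_of"})


class OboParseError(ValueError):
    """Raised for a structurally malformed OBO file."""


@dataclass
class OntologyDAG:
    """A multi-category ontology restricted to is_a / part_of parent edges.

    Parent edges never cross categories; the parent relation within each
    category is acyclic. Obsolete terms are kept (flagged) but excluded from
    propagation and similarity.
    """

    #: term id -> category (namespace) label
    _category: dict[str, str] = field(default_factory=dict)
    #: term id -> set of (parent id, relation)
    _parents: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    #: term id -> set of child term ids (derived)
    _children: dict[str, set[str]] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    names: dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_term(self, term: str, category: str, *, name: str = "",
                 obsolete: bool = False) -> None:
        self._category[term] = category
        self._parents.setdefault(term, set())
        self._children.setdefault(term, set())
        if name:
            self.names[term] = name
        if obsolete:
            self.obsolete.add(term)

    def add_parent(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in PROPAGATING_RELATIONS:
            return
        if self._category.get(child) != self._category.get(parent):
            log.warning("dropping cross-category edge %s -%s-> %s",
                        child, relation, parent)
            return
        self._parents[child].add((parent, relation))
        self._children[parent].add(child)

    # -- queries ----------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._category)

    def __contains__(self, term: str) -> bool:
        return term in self._category

    def category(self, term: str) -> str:
        return self._category[term]

    def categories(self) -> set[str]:
        return set(self._category.values())

    def parents(self, term: str) -> set[tuple[str, str]]:
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def terms_in(self, category: str, *, include_obsolete: bool = False) -> set[str]:
        out = {t for t, c in self._category.items() if c == category}
        if not include_obsolete:
            out -= self.obsolete
        return out

    def descendants(self, term: str) -> set[str]:
        """Transitive closure under child edges, excluding ``term`` itself."""
        if term not in self._category:
            raise KeyError(f"unknown term: {term}")
        seen: set[str] = set()
        stack = list(self._children[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self._children[t])
        return seen

    def ancestors(self, term: str) -> set[str]:
        """Transitive closure under parent edges, excluding ``term`` itself."""
        if term not in self._category:
            raise KeyError(f"unknown term: {term}")
        seen: set[str] = set()
        stack = [p for p, _ in self._parents[term]]
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(p for p, _ in self._parents[t])
        return seen

    def topological_order(self) -> list[str]:
        """Terms ordered children before parents; raises on a cycle."""
        ts: TopologicalSorter[str] = TopologicalSorter()
        for term in sorted(self._category):
            ts.add(term, *sorted(self._children[term]))
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise OboParseError(f"cycle detected in ontology: {exc.args[1]}") from exc


def _prevalidate_obo(path: Path) -> None:
    """Cheap structural scan so malformed stanzas fail with a line number."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(
                        f"{path}:{lineno}: malformed stanza header {line!r}")
                continue
            if ":" not in line:
                raise OboParseError(
                    f"{path}:{lineno}: expected 'tag: value', got {line!r}")


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``is_a`` and ``relationship: part_of`` parent edges are retained.
    Cross-namespace parent edges are dropped with a warning. Obsolete terms
    are flagged and take no part in propagation.
    """
    path = Path(path)
    _prevalidate_obo(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet's own failures
        raise OboParseError(f"failed to parse {path}: {exc}") from exc

    dag = OntologyDAG()
    for term, data in graph.nodes(data=True):
        namespace = data.get("namespace", "")
        if not namespace:
            log.warning("term %s has no namespace; labelled 'unknown'", term)
            namespace = "unknown"
        dag.add_term(term, namespace, name=data.get("name", ""),
                     obsolete=str(data.get("is_obsolete", "")).lower() == "true")
    # obonet edges run child -> parent keyed by relation type
    for child, parent, relation in graph.edges(keys=True):
        if relation in PROPAGATING_RELATIONS and parent in dag:
            dag.add_parent(child, parent, relation)
    dag.topological_order()  # acyclicity check up front
    log.info("parsed %d terms (%d obsolete) in categories %s",
             len(dag.terms), len(dag.obsolete), sorted(dag.categories()))
    return dag


@dataclass
class AnnotationMap:
    """Direct and propagated gene sets per term, plus per-category universes."""

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)
    universe: dict[str, set[str]] = field(default_factory=dict)
    n_dropped: int = 0

    def genes(self, term: str) -> set[str]:
        """Propagated annotation set (empty set for unannotated terms)."""
        return self.propagated.get(term, set())

    def annotated_terms(self, dag: OntologyDAG, category: str) -> list[str]:
        """Terms of ``category`` with a nonempty propagated set, sorted."""
        return sorted(t for t in dag.terms_in(category) if self.propagated.get(t))


def _looks_like_gaf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("!"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def parse_annotations(path: str | Path, dag: OntologyDAG, *,
                      exclude_evidence: Iterable[str] = ()) -> AnnotationMap:
    """Read gene-term annotations from a GAF 2.x file or a 2-column TSV.

    Rows pointing at unknown or obsolete terms are dropped (counted in
    ``n_dropped``); GAF rows with a NOT qualifier are excluded. Evidence codes
    are not filtered unless ``exclude_evidence`` names some (e.g. ``["IEA"]``).
    Direct sets only; call :func:`propagate` afterwards.
    """
    path = Path(path)
    exclude_evidence = set(exclude_evidence)
    rows: list[tuple[str, str]] = []
    n_not = 0
    if _looks_like_gaf(path):
        from Bio.UniProt import GOA
        with open(path) as fh:
            for rec in GOA.gafiterator(fh):
                if any(q.strip().upper().startswith("NOT")
                       for q in rec.get("Qualifier", [])):
                    n_not += 1
                    continue
                if exclude_evidence and rec.get("Evidence") in exclude_evidence:
                    continue
                rows.append((rec["DB_Object_Symbol"] or rec["DB_Object_ID"],
                             rec["GO_ID"]))
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'gene<TAB>term', got {line!r}")
                rows.append((fields[0], fields[1]))

    ann = AnnotationMap()
    for gene, term in rows:
        if term not in dag or term in dag.obsolete:
            ann.n_dropped += 1
            continue
        ann.direct.setdefault(term, set()).add(gene)
    if not ann.direct:
        raise ValueError(f"no usable annotation rows in {path}")
    if ann.n_dropped:
        log.warning("%d annotation rows dropped (unknown/obsolete terms)",
                    ann.n_dropped)
    if n_not:
        log.info("%d NOT-qualified GAF rows excluded", n_not)
    return ann


def propagate(ann: AnnotationMap, dag: OntologyDAG) -> AnnotationMap:
    """Apply the true-path rule: propagated(t) = union of direct sets over
    the descendant closure of t (including t), within t's category.

    Also fills ``universe[C]`` = union of propagated sets over all terms of C.
    Obsolete terms receive no propagated set. Returns ``ann`` mutated in place.
    """
    order = dag.topological_order()  # children before parents
    for term in order:
        if term in dag.obsolete:
            continue
        genes = set(ann.direct.get(term, ()))
        for child in dag.children(term):
            if child not in dag.obsolete:
                genes |= ann.propagated.get(child, set())
        ann.propagated[term] = genes
    for category in dag.categories():
        universe: set[str] = set()
        for term in dag.terms_in(category):
            universe |= ann.propagated.get(term, set())
        ann.universe[category] = universe
    return ann


def descendants(dag: OntologyDAG, term: str) -> set[str]:
    """Module-level alias for :meth:`OntologyDAG.descendants`."""
    return dag.descendants(term)
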