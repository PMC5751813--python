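"""Cross-category term association network.

Scores every cross-category term pair, attaches empirical FDR q-values
(empirical null from uniformly sampled random cross-category pairs +
Benjamini-Hochberg), filters at the FDR threshold, assigns edge directions,
and exports the resulting directed network.

Direction rule: for a term t1 with filtered cross-category neighbor set T2,
the directed edge t1 -> t2 is deleted whenever some t3 in T2 is a descendant
of t2. Edges therefore point only at the most specific related terms. The rule
is applied from both sides in a single pass over the original neighbor sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .diffusion import DiffusionResult
from .ontology_io import AnnotationMap, OntologyDAG
from .similarity import TermPairScore, score_pair

log = logging.getLogger(__name__)


@dataclass
class DirectedEdge:
    source: str
    target: str
    sim: float
    q_value: float


@dataclass
class AssociationNetwork:
    """Directed, FDR-filtered cross-category term graph with provenance."""

    nodes: dict[str, str]  # term -> category
    edges: list[DirectedEdge]
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def score_all_pairs(ann: AnnotationMap, dag: OntologyDAG,
                    result: DiffusionResult, cat1: str,
                    cat2: str) -> list[TermPairScore]:
    """Score every unordered cross-category pair of annotation-bearing terms.

    Output order is deterministic: lexicographic by (cat1 term, cat2 term).
    Terms with empty propagated sets are excluded (their similarity is
    undefined); category roots are retained and score 0 through the
    shallow-annotation weight.
    """
    if cat1 == cat2:
        raise ValueError("cat1 and cat2 must differ")
    terms_1 = ann.annotated_terms(dag, cat1)
    terms_2 = ann.annotated_terms(dag, cat2)
    if not terms_1 or not terms_2:
        raise ValueError("both categories need at least one annotated term")
    scores = [score_pair(t1, t2, ann, dag, result)
              for t1 in terms_1 for t2 in terms_2]
    log.info("scored %d x %d = %d cross-category pairs",
             len(terms_1), len(terms_2), len(scores))
    return scores


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Right-tail empirical p-values: p = (1 + #{null >= s}) / (1 + n_null)."""
    null_sorted = np.sort(np.asarray(null))
    n = len(null_sorted)
    # count of null samples >= each observed score
    ge = n - np.searchsorted(null_sorted, np.asarray(observed), side="left")
    return (1.0 + ge) / (1.0 + n)


def empirical_fdr(scores: list[TermPairScore], ann: AnnotationMap,
                  dag: OntologyDAG, result: DiffusionResult, *,
                  n_null: int = 10_000, seed: int = 0,
                  cat1: str | None = None,
                  cat2: str | None = None) -> list[TermPairScore]:
    """Attach empirical p-values and Benjamini-Hochberg q-values.

    The null distribution is built by scoring ``n_null`` uniformly sampled
    (with replacement) random cross-category term pairs, mirroring the use of
    random term pairs as the negative model in evaluation. Deterministic for
    a given seed. Returns the input list with p/q fields filled in place.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    if cat1 is None or cat2 is None:
        cats = sorted({dag.category(s.t1) for s in scores} |
                      {dag.category(s.t2) for s in scores})
        if len(cats) != 2:
            raise ValueError("could not infer the two categories from scores")
        cat1, cat2 = cats
    terms_1 = ann.annotated_terms(dag, cat1)
    terms_2 = ann.annotated_terms(dag, cat2)
    rng = np.random.default_rng(seed)
    i1 = rng.integers(0, len(terms_1), size=n_null)
    i2 = rng.integers(0, len(terms_2), size=n_null)
    null_scores = np.array([
        score_pair(terms_1[a], terms_2[b], ann, dag, result).sim
        for a, b in zip(i1, i2)])
    pvals = empirical_pvalues(np.array([s.sim for s in scores]), null_scores)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for s, p, q in zip(scores, pvals, qvals):
        s.p_value = float(p)
        s.q_value = float(q)
    return scores


def assign_directions(edges: list[TermPairScore],
                      dag: OntologyDAG) -> AssociationNetwork:
    """Turn FDR-filtered undirected pairs into directed edges and prune
    edges pointing at non-specific terms.

    Every retained pair first contributes both directions; then, per term t1,
    the edge t1 -> t2 is deleted if the original neighbor set of t1 contains a
    descendant of t2. Neighbor sets are not updated within the pass.
    """
    for s in edges:
        for t in (s.t1, s.t2):
            if t not in dag:
                raise KeyError(f"term absent from ontology: {t}")
    neighbors: dict[str, set[str]] = {}
    for s in edges:
        neighbors.setdefault(s.t1, set()).add(s.t2)
        neighbors.setdefault(s.t2, set()).add(s.t1)
    desc_cache: dict[str, set[str]] = {}

    def desc(t: str) -> set[str]:
        if t not in desc_cache:
            desc_cache[t] = dag.descendants(t)
        return desc_cache[t]

    kept: list[DirectedEdge] = []
    nodes: dict[str, str] = {}
    for s in edges:
        q = s.q_value if s.q_value is not None else float("nan")
        for t1, t2 in ((s.t1, s.t2), (s.t2, s.t1)):
            t2_set = neighbors[t1]
            if any(t3 != t2 and t3 in desc(t2) for t3 in t2_set):
                continue
            kept.append(DirectedEdge(source=t1, target=t2, sim=s.sim, q_value=q))
            nodes[t1] = dag.category(t1)
            nodes[t2] = dag.category(t2)
    log.info("direction rule kept %d of %d directed edges",
             len(kept), 2 * len(edges))
    return AssociationNetwork(nodes=nodes, edges=kept)


def build_association_network(ann: AnnotationMap, dag: OntologyDAG,
                              result: DiffusionResult, cat1: str, cat2: str, *,
                              fdr: float = 0.05, n_null: int = 10_000,
                              seed: int = 0) -> AssociationNetwork:
    """Full pipeline from scores to the directed FDR-filtered network."""
    scores = score_all_pairs(ann, dag, result, cat1, cat2)
    scores = empirical_fdr(scores, ann, dag, result, n_null=n_null, seed=seed,
                           cat1=cat1, cat2=cat2)
    passed = [s for s in scores if s.q_value < fdr]
    log.info("%d of %d pairs pass FDR < %g", len(passed), len(scores), fdr)
    net = assign_directions(passed, dag)
    net.provenance = {"alpha": result.alpha, "fdr": fdr, "n_null": n_null,
                      "seed": seed, "cat1": cat1, "cat2": cat2}
    return net


def export_network(net: AssociationNetwork, path: str | Path,
                   format: str = "tsv") -> None:
    """Write the directed network as TSV, SIF, or GraphML."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for key in sorted(net.provenance):
                fh.write(f"# {key} = {net.provenance[key]}\n")
            fh.write("source\ttarget\tsource_category\ttarget_category\t"
                     "sim\tq_value\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{net.nodes[e.source]}\t"
                         f"{net.nodes[e.target]}\t{e.sim:.10g}\t{e.q_value:.6g}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.source}\tcrogo2\t{e.target}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for term, cat in net.nodes.items():
            g.add_node(term, category=cat)
        for e in net.edges:
            g.add_edge(e.source, e.target, sim=e.sim, q_value=e.q_value)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def load_network_tsv(path: str | Path) -> AssociationNetwork:
    """Re-read a TSV written by :func:`export_network` (round-trip)."""
    nodes: dict[str, str] = {}
    edges: list[DirectedEdge] = []
    provenance: dict = {}
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                provenance[key.strip()] = value.strip()
                continue
            if not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            src, tgt, cat_s, cat_t, sim, q = line.split("\t")
            nodes[src] = cat_s
            nodes[tgt] = cat_t
            edges.append(DirectedEdge(source=src, target=tgt,
                                      sim=float(sim), q_value=float(q)))
    return AssociationNetwork(nodes=nodes, edges=edges, provenance=provenance)
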