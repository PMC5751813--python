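"""Cross-category term-pair scoring.

A pair (t1, t2) of terms from two different ontology categories is scored in
three parts:

* ``sim_net`` — a soft overlap of the propagated annotation sets G1, G2:

      sim_net = (|G1 u G2| - |G1 - G2| - |G2 - G1|) / |G1 u G2|

  where the set difference is softened through the diffusion scores r_ij:

      |G1 - G2| = |G1| - sum_{gi in G1} (1 - prod_{gj in G2} (1 - r_ij))

  A gene of G1 is "covered" by G2 to the extent at least one G2 gene is
  associated with it; shared genes are fully covered because r with itself
  is 1, so identical sets give a soft difference of exactly 0 and sim_net = 1.

* ``sim_go`` — a shallow-annotation weight. Terms near a category root
  annotate almost the whole category after propagation, so any overlap-based
  score would rate unrelated high-level pairs highly. The weight

      sim_go = sqrt((1 - |G1|/|G_C1|) * (1 - |G2|/|G_C2|))

  vanishes at the roots and approaches 1 for specific terms.

* ``sim = sim_net * sim_go`` — the combined score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .diffusion import DiffusionResult
from .ontology_io import AnnotationMap, OntologyDAG


@dataclass
class TermPairScore:
    """Score record for one unordered cross-category term pair."""

    t1: str
    t2: str
    sim_net: float
    sim_go: float
    sim: float
    n_genes_1: int
    n_genes_2: int
    p_value: float | None = None
    q_value: float | None = None


def soft_difference(genes_1: Iterable[str], genes_2: Iterable[str],
                    result: DiffusionResult) -> float:
    """Soft set difference |G1 - G2| under the diffusion scores.

    Lies in [0, |G1|]; exactly 0 when G1 is a subset of G2 (every gene is
    self-covered through r = 1).
    """
    g1 = sorted(set(genes_1))
    g2 = sorted(set(genes_2))
    if not g1:
        raise ValueError("G1 must be nonempty")
    if not g2:
        return float(len(g1))
    r = result.pair_matrix(g1, g2)
    if r.min() < 0 or r.max() > 1:
        raise ValueError("association scores outside [0, 1]")
    covered = 1.0 - np.prod(1.0 - r, axis=1)
    return float(len(g1) - covered.sum())


def sim_net(t1: str, t2: str, ann: AnnotationMap,
            result: DiffusionResult) -> float:
    """Network-based similarity of the two terms' propagated gene sets."""
    g1, g2 = ann.genes(t1), ann.genes(t2)
    union = len(g1 | g2)
    if union == 0:
        raise ValueError(f"{t1} and {t2} annotate no genes")
    d12 = soft_difference(g1, g2, result)
    d21 = soft_difference(g2, g1, result)
    value = (union - d12 - d21) / union
    if value > 1 + 1e-9 or value < -1e-9 - 1:
        raise AssertionError(f"sim_net out of range: {value}")
    return value


def sim_go(t1: str, t2: str, ann: AnnotationMap, dag: OntologyDAG) -> float:
    """Shallow-annotation weight from annotation-set sizes relative to the
    category universes; 0 at a category root, near 1 for specific terms."""
    g1, g2 = ann.genes(t1), ann.genes(t2)
    if not g1 or not g2:
        raise ValueError("both terms must annotate at least one gene")
    u1 = len(ann.universe[dag.category(t1)])
    u2 = len(ann.universe[dag.category(t2)])
    return float(np.sqrt((1 - len(g1) / u1) * (1 - len(g2) / u2)))


def score_pair(t1: str, t2: str, ann: AnnotationMap, dag: OntologyDAG,
               result: DiffusionResult) -> TermPairScore:
    """Full combined score for a cross-category pair; symmetric in (t1, t2)."""
    if dag.category(t1) == dag.category(t2):
        raise ValueError(
            f"{t1} and {t2} are both {dag.category(t1)}; cross-category only")
    s_net = sim_net(t1, t2, ann, result)
    s_go = sim_go(t1, t2, ann, dag)
    return TermPairScore(t1=t1, t2=t2, sim_net=s_net, sim_go=s_go,
                         sim=s_net * s_go, n_genes_1=len(ann.genes(t1)),
                         n_genes_2=len(ann.genes(t2)))


def write_scores(scores: list[TermPairScore], path) -> None:
    """Write scores as TSV: term1 term2 sim_net sim_go sim n1 n2 [p q]."""
    with open(path, "w") as fh:
        fh.write("term1\tterm2\tsim_net\tsim_go\tsim\tn1\tn2\tp_value\tq_value\n")
        for s in scores:
            p = "" if s.p_value is None else f"{s.p_value:.6g}"
            q = "" if s.q_value is None else f"{s.q_value:.6g}"
            fh.write(f"{s.t1}\t{s.t2}\t{s.sim_net:.10g}\t{s.sim_go:.10g}\t"
                     f"{s.sim:.10g}\t{s.n_genes_1}\t{s.n_genes_2}\t{p}\t{q}\n")
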