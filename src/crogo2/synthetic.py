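"""Self-contained synthetic benchmark generator.

Emulates the four inputs the scoring pipeline consumes, without any downloads:

* a two-category ontology (two rooted trees of configurable size, written as
  OBO) standing in for the BP and MF namespaces;
* direct leaf annotations over disjoint gene blocks (two-column TSV), which
  the consumer propagates upward;
* a modular weighted co-function network (TSV edge list): for each "planted"
  cross-category leaf pair, the union of the two leaves' gene blocks is
  densely wired; everything else is sparse background;
* a gold standard listing the planted pairs as positives plus an equal number
  of uniformly sampled non-planted cross-category pairs as randoms.

Planted relatedness is encoded purely in the network — planted leaves never
share annotated genes — so recovering planted pairs exercises the
network-diffusion pathway of the score rather than crisp annotation overlap.
In ``indirect_only`` mode the two blocks of a planted pair are wired to a
small shared hub gene set with no direct cross-block edges at all, so the
relation is only visible through length-2 network paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_CATEGORIES = ("biological_process", "molecular_function")
_ID_PREFIX = {0: "GO:1", 1: "GO:2"}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe a desk-scale analogue of a genome-wide run: two
    40-term categories (depth-3 ternary trees, 27 leaves each), 400 genes,
    8 planted cross-category pairs with dense (p=0.8) module wiring over a
    sparse (p=0.01) background.
    """

    n_terms_per_category: int = 40
    dag_branching: int = 3
    n_genes: int = 400
    genes_per_leaf: int = 7
    n_planted_pairs: int = 8
    within_module_edge_prob: float = 0.8
    background_edge_prob: float = 0.01
    edge_weight_range: tuple[float, float] = (0.5, 1.0)
    indirect_only: bool = False
    hubs_per_pair: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_module_edge_prob <= self.background_edge_prob:
            raise ValueError(
                "within_module_edge_prob must exceed background_edge_prob")
        for p in (self.within_module_edge_prob, self.background_edge_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        for name in ("n_terms_per_category", "dag_branching", "n_genes",
                     "genes_per_leaf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_pairs < 0:
            raise ValueError("n_planted_pairs must be >= 0")
        lo, hi = self.edge_weight_range
        if not 0 < lo <= hi:
            raise ValueError("edge_weight_range must be 0 < lo <= hi")
        n_leaves = len(_tree_leaves(self.n_terms_per_category,
                                    self.dag_branching))
        if self.n_planted_pairs > n_leaves:
            raise ValueError(
                f"n_planted_pairs > {n_leaves} leaves per category")
        needed = 2 * n_leaves * self.genes_per_leaf
        if self.indirect_only:
            needed += self.n_planted_pairs * self.hubs_per_pair
        if self.n_genes < needed:
            raise ValueError(
                f"gene budget too small: need at least {needed} genes "
                f"({2 * n_leaves} leaf blocks of {self.genes_per_leaf}"
                + (f" + {self.n_planted_pairs * self.hubs_per_pair} hubs"
                   if self.indirect_only else "") + f"), got {self.n_genes}")


@dataclass
class SyntheticBundle:
    """File paths and ground truth of one generated instance."""

    obo: Path
    annotations: Path
    network: Path
    gold_standard: Path
    planted_pairs: list[tuple[str, str]]
    leaf_genes: dict[str, list[str]]
    spec: SyntheticSpec = field(repr=False, default=None)


def _tree_parent(i: int, branching: int) -> int:
    return (i - 1) // branching


def _tree_leaves(n_terms: int, branching: int) -> list[int]:
    return [i for i in range(n_terms) if branching * i + 1 >= n_terms]


def _term_id(cat_idx: int, node: int) -> str:
    return f"{_ID_PREFIX[cat_idx]}{node + 1:06d}"


def generate(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticBundle:
    """Write the four benchmark files into ``out_dir``.

    Fully deterministic given ``spec.seed``: the same spec produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_terms = spec.n_terms_per_category
    branching = spec.dag_branching
    leaves = _tree_leaves(n_terms, branching)
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]

    # --- ontology -------------------------------------------------------
    obo_path = out_dir / "ontology.obo"
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: crogo2-synthetic\n")
        for c, namespace in enumerate(_CATEGORIES):
            for i in range(n_terms):
                fh.write(f"\n[Term]\nid: {_term_id(c, i)}\n"
                         f"name: synthetic {namespace} term {i}\n"
                         f"namespace: {namespace}\n")
                if i > 0:
                    fh.write(f"is_a: {_term_id(c, _tree_parent(i, branching))}\n")

    # --- leaf gene blocks ----------------------------------------------
    leaf_genes: dict[str, list[str]] = {}
    cursor = 0
    for c in range(2):
        for i in leaves:
            leaf_genes[_term_id(c, i)] = genes[cursor:cursor + spec.genes_per_leaf]
            cursor += spec.genes_per_leaf
    hub_pool = genes[cursor:]

    ann_path = out_dir / "annotations.tsv"
    with open(ann_path, "w") as fh:
        for term in sorted(leaf_genes):
            for gene in leaf_genes[term]:
                fh.write(f"{gene}\t{term}\n")

    # --- planted pairs --------------------------------------------------
    planted_a = rng.choice(leaves, size=spec.n_planted_pairs, replace=False)
    planted_b = rng.choice(leaves, size=spec.n_planted_pairs, replace=False)
    planted = [(_term_id(0, a), _term_id(1, b))
               for a, b in zip(planted_a, planted_b)]

    # --- network --------------------------------------------------------
    n = spec.n_genes
    index = {g: k for k, g in enumerate(genes)}
    prob = np.full((n, n), spec.background_edge_prob)
    for k, (ta, tb) in enumerate(planted):
        block_a = [index[g] for g in leaf_genes[ta]]
        block_b = [index[g] for g in leaf_genes[tb]]
        if spec.indirect_only:
            hubs = [index[g] for g in
                    hub_pool[k * spec.hubs_per_pair:(k + 1) * spec.hubs_per_pair]]
            for grp in (block_a, block_b, hubs):
                prob[np.ix_(grp, grp)] = spec.within_module_edge_prob
            for blk in (block_a, block_b):
                prob[np.ix_(blk, hubs)] = spec.within_module_edge_prob
                prob[np.ix_(hubs, blk)] = spec.within_module_edge_prob
            # the planted relation must be visible only through the hubs
            prob[np.ix_(block_a, block_b)] = 0.0
            prob[np.ix_(block_b, block_a)] = 0.0
        else:
            module = block_a + block_b
            prob[np.ix_(module, module)] = spec.within_module_edge_prob
    coin = rng.random((n, n))
    lo, hi = spec.edge_weight_range
    weight = rng.uniform(lo, hi, size=(n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = coin[iu, ju] < prob[iu, ju]

    net_path = out_dir / "network.tsv"
    with open(net_path, "w") as fh:
        fh.write("# synthetic co-function network\n")
        for i, j in zip(iu[present], ju[present]):
            fh.write(f"{genes[i]}\t{genes[j]}\t{weight[i, j]:.6f}\n")

    # --- gold standard --------------------------------------------------
    all_cross = [(_term_id(0, i), _term_id(1, j))
                 for i in range(n_terms) for j in range(n_terms)]
    planted_set = set(planted)
    candidates = [p for p in all_cross if p not in planted_set]
    pick = rng.choice(len(candidates), size=spec.n_planted_pairs, replace=False)
    randoms = [candidates[k] for k in sorted(pick)]

    gold_path = out_dir / "gold_standard.tsv"
    with open(gold_path, "w") as fh:
        fh.write("term1\tterm2\tlabel\n")
        for t1, t2 in planted:
            fh.write(f"{t1}\t{t2}\tpositive\n")
        for t1, t2 in randoms:
            fh.write(f"{t1}\t{t2}\trandom\n")

    return SyntheticBundle(obo=obo_path, annotations=ann_path,
                           network=net_path, gold_standard=gold_path,
                           planted_pairs=planted, leaf_genes=leaf_genes,
                           spec=spec)


#: Named presets for the CLI and tests.
PRESETS = {
    "default": SyntheticSpec(),
    "indirect": SyntheticSpec(indirect_only=True),
    "null": SyntheticSpec(n_planted_pairs=0),
}


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """A named preset spec with the given seed."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def worked_example(out_dir: str | Path) -> SyntheticBundle:
    """A fixed 6-term / 7-gene instance whose scores are hand-derivable.

    Categories hold a root with two leaf children each. One cross-category
    leaf pair shares an identical annotation set (so its network similarity is
    exactly 1); the other two leaves form the planted pair, related only
    through dense network wiring of their disjoint gene blocks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obo = out_dir / "ontology.obo"
    obo.write_text(
        "format-version: 1.2\nontology: crogo2-worked-example\n"
        "\n[Term]\nid: GO:1000001\nname: category A root\n"
        "namespace: biological_process\n"
        "\n[Term]\nid: GO:1000002\nname: process with shared annotation\n"
        "namespace: biological_process\nis_a: GO:1000001\n"
        "\n[Term]\nid: GO:1000003\nname: planted process\n"
        "namespace: biological_process\nis_a: GO:1000001\n"
        "\n[Term]\nid: GO:2000001\nname: category B root\n"
        "namespace: molecular_function\n"
        "\n[Term]\nid: GO:2000002\nname: function with shared annotation\n"
        "namespace: molecular_function\nis_a: GO:2000001\n"
        "\n[Term]\nid: GO:2000003\nname: planted function\n"
        "namespace: molecular_function\nis_a: GO:2000001\n")
    ann = out_dir / "annotations.tsv"
    ann.write_text(
        "g1\tGO:1000002\ng2\tGO:1000002\ng3\tGO:1000002\n"
        "g4\tGO:1000003\ng5\tGO:1000003\n"
        "g1\tGO:2000002\ng2\tGO:2000002\ng3\tGO:2000002\n"
        "g6\tGO:2000003\ng7\tGO:2000003\n")
    net = out_dir / "network.tsv"
    net.write_text(
        "# worked example network: g4..g7 form the planted module\n"
        "g4\tg5\t1.0\ng4\tg6\t1.0\ng4\tg7\t0.8\n"
        "g5\tg6\t0.9\ng5\tg7\t1.0\ng6\tg7\t1.0\n"
        "g1\tg2\t0.5\ng2\tg3\t0.5\n")
    gold = out_dir / "gold_standard.tsv"
    gold.write_text(
        "term1\tterm2\tlabel\n"
        "GO:1000003\tGO:2000003\tpositive\n"
        "GO:1000002\tGO:2000003\trandom\n")
    return SyntheticBundle(
        obo=obo, annotations=ann, network=net, gold_standard=gold,
        planted_pairs=[("GO:1000003", "GO:2000003")],
        leaf_genes={"GO:1000002": ["g1", "g2", "g3"],
                    "GO:1000003": ["g4", "g5"],
                    "GO:2000002": ["g1", "g2", "g3"],
                    "GO:2000003": ["g6", "g7"]},
        spec=None)
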