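"""Evaluation protocol: ROC/AUC on a gold standard of positive vs random
cross-category term pairs, TP rate at fixed FP rates, and a network-density
robustness test (re-scoring after random edge deletion)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .diffusion import delete_random_edges, iterate_ranking, raw_association
from .ontology_io import OntologyDAG
from .pipeline import load_inputs
from .similarity import score_pair

log = logging.getLogger(__name__)

#: FP-rate levels at which TP rates are conventionally reported.
REPORT_FPR_LEVELS = (0.05, 0.10, 0.15)


@dataclass
class GoldStandard:
    """Known-related cross-category pairs (positives) plus a random set."""

    positive_pairs: list[tuple[str, str]]
    random_pairs: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        overlap = set(map(frozenset, self.positive_pairs)) & \
            set(map(frozenset, self.random_pairs))
        if overlap:
            raise ValueError(f"{len(overlap)} pairs appear in both classes")


@dataclass
class RocResult:
    """Tie-grouped ROC curve, its trapezoidal AUC, and TP rates at the
    conventional FP-rate levels (conservative step values, no interpolation)."""

    auc: float
    curve: list[tuple[float, float]]
    tpr_at_fpr: dict[float, float] = field(default_factory=dict)


def load_gold_standard(path: str | Path,
                       dag: OntologyDAG | None = None) -> GoldStandard:
    """Read a TSV ``term1 TAB term2 TAB label`` with label positive|random.

    Duplicates are dropped with a warning; if a dag is supplied, same-category
    rows are rejected (cross-category pairs only); unequal class sizes get a
    warning but remain usable.
    """
    path = Path(path)
    seen: set[frozenset] = set()
    pos: list[tuple[str, str]] = []
    rand: list[tuple[str, str]] = []
    n_dup = n_same_cat = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or \
                    line.lower().startswith("term1\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            t1, t2, label = fields[0], fields[1], fields[2].strip().lower()
            if dag is not None and t1 in dag and t2 in dag and \
                    dag.category(t1) == dag.category(t2):
                n_same_cat += 1
                continue
            key = frozenset((t1, t2))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            if label == "positive":
                pos.append((t1, t2))
            elif label == "random":
                rand.append((t1, t2))
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
    if n_dup:
        log.warning("%d duplicate gold-standard rows dropped", n_dup)
    if n_same_cat:
        log.warning("%d same-category rows rejected", n_same_cat)
    if len(pos) != len(rand):
        log.warning("unequal class sizes: %d positive vs %d random",
                    len(pos), len(rand))
    return GoldStandard(positive_pairs=pos, random_pairs=rand,
                        provenance=str(path))


def roc(scores_pos: list[float], scores_neg: list[float]) -> RocResult:
    """Threshold-sweep ROC with equal scores grouped into single steps."""
    if not scores_pos or not scores_neg:
        raise ValueError("both score lists must be nonempty")
    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(_trapezoid_auc(fpr, tpr))
    tpr_at = {}
    for level in REPORT_FPR_LEVELS:
        ok = fpr <= level + 1e-12
        tpr_at[level] = float(tpr[ok].max()) if ok.any() else 0.0
    return RocResult(auc=auc, curve=list(zip(fpr.tolist(), tpr.tolist())),
                     tpr_at_fpr=tpr_at)


def mann_whitney_auc(scores_pos: list[float], scores_neg: list[float]) -> float:
    """Brute-force AUC over all positive x negative pairs (ties count 0.5).

    Independent of the curve-based estimate; intended as a cross-check.
    """
    pos = np.asarray(scores_pos)[:, None]
    neg = np.asarray(scores_neg)[None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


def score_gold_standard(dag, ann, result, gold: GoldStandard) -> RocResult:
    """Score both gold-standard classes with the combined similarity and
    summarize as a ROC."""
    def sims(pairs):
        return [score_pair(t1, t2, ann, dag, result).sim for t1, t2 in pairs]
    return roc(sims(gold.positive_pairs), sims(gold.random_pairs))


def evaluate_files(obo: str | Path, annotations: str | Path,
                   network: str | Path, gold: str | Path, *,
                   alpha: float = 0.1, mode: str = "diffusion") -> RocResult:
    """End-to-end evaluation from the four input files."""
    dag, ann, net = load_inputs(obo, annotations, network)
    if mode == "diffusion":
        result = iterate_ranking(net, alpha)
    elif mode == "raw":
        result = raw_association(net)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    gs = load_gold_standard(gold, dag)
    return score_gold_standard(dag, ann, result, gs)


@dataclass
class RobustnessReport:
    auc_full: float
    auc_deleted: list[float]
    fraction: float
    seeds: list[int]

    @property
    def mean_auc_deleted(self) -> float:
        return float(np.mean(self.auc_deleted))


def robustness_test(obo: str | Path, annotations: str | Path,
                    network: str | Path, gold: str | Path, *,
                    fraction: float = 0.5, seeds: list[int] = (0, 1, 2, 3, 4),
                    alpha: float = 0.1) -> RobustnessReport:
    """Compare AUC on the intact network against the network with a random
    fraction of edges deleted, paired by seed."""
    dag, ann, net = load_inputs(obo, annotations, network)
    gs = load_gold_standard(gold, dag)
    full = score_gold_standard(dag, ann, iterate_ranking(net, alpha), gs)
    deleted_aucs = []
    for seed in seeds:
        thin = delete_random_edges(net, fraction, seed)
        res = iterate_ranking(thin, alpha)
        deleted_aucs.append(score_gold_standard(dag, ann, res, gs).auc)
    report = RobustnessReport(auc_full=full.auc, auc_deleted=deleted_aucs,
                              fraction=fraction, seeds=list(seeds))
    log.info("robustness: full AUC %.3f vs mean deleted AUC %.3f",
             report.auc_full, report.mean_auc_deleted)
    return report


def write_report(result: RocResult, path: str | Path, *,
                 curve_path: str | Path | None = None) -> None:
    """Write the AUC and TP-rate summary as TSV; optionally dump the curve."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"auc\t{result.auc:.6g}\n")
        for level, tpr in sorted(result.tpr_at_fpr.items()):
            fh.write(f"tpr_at_fpr_{level:g}\t{tpr:.6g}\n")
    if curve_path is not None:
        with open(curve_path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in result.curve:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
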