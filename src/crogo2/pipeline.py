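"""Shared input-loading glue used by the CLI and evaluation helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .diffusion import CoFunctionNetwork, load_network
from .ontology_io import AnnotationMap, OntologyDAG, parse_annotations, \
    parse_obo, propagate


def load_inputs(obo: str | Path, annotations: str | Path,
                network: str | Path, *,
                exclude_evidence: Iterable[str] = ()) -> \
        tuple[OntologyDAG, AnnotationMap, CoFunctionNetwork]:
    """Parse ontology, annotations (propagated), and co-function network."""
    dag = parse_obo(obo)
    ann = propagate(parse_annotations(annotations, dag,
                                      exclude_evidence=exclude_evidence), dag)
    net = load_network(network)
    return dag, ann, net
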