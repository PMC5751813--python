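import numpy as np
import pytest

from crogo2 import (closed_form_ranking, load_inputs, worked_example)
from crogo2.diffusion import CoFunctionNetwork
from crogo2.ontology_io import AnnotationMap, OntologyDAG


@pytest.fixture(scope="session")
def wex(tmp_path_factory):
    """The fixed worked-example bundle, parsed, with its exact association
    matrix from the closed-form solve."""
    bundle = worked_example(tmp_path_factory.mktemp("wex"))
    dag, ann, net = load_inputs(bundle.obo, bundle.annotations, bundle.network)
    return {"bundle": bundle, "dag": dag, "ann": ann, "net": net,
            "result": closed_form_ranking(net, alpha=0.1)}


@pytest.fixture
def two_category_dag():
    """Hand-built DAG: category A root with leaves a1, a2; category B root
    with a parent/child chain b1 <- b2 <- b3."""
    dag = OntologyDAG()
    dag.add_term("rootA", "A")
    dag.add_term("a1", "A")
    dag.add_term("a2", "A")
    dag.add_parent("a1", "rootA")
    dag.add_parent("a2", "rootA")
    dag.add_term("rootB", "B")
    for child, parent in [("b1", "rootB"), ("b2", "b1"), ("b3", "b2")]:
        dag.add_term(child, "B")
        dag.add_parent(child, parent)
    return dag


def make_annotation_map(propagated: dict[str, set[str]],
                        universe: dict[str, set[str]]) -> AnnotationMap:
    return AnnotationMap(direct={}, propagated=propagated, universe=universe)


def random_network(rng: np.random.Generator, n_nodes: int,
                   edge_prob: float = 0.3) -> CoFunctionNetwork:
    """Erdos-Renyi weighted network over n_nodes gene labels."""
    nodes = [f"g{i:03d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((i, j, float(rng.uniform(0.1, 1.0))))
    return CoFunctionNetwork(nodes=nodes, edges=edges)
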