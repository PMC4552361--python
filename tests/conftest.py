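import numpy as np
import pytest

import gogonet as gg
from gogonet.types import GoAnnotation


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small planted synthetic dataset shared across read-only tests."""
    cfg = gg.SyntheticConfig(
        n_genes=300,
        n_terms=40,
        seed=11,
        planted_temporal=(gg.PlantedBridge("GO:A", "GO:B", (2, 4)),),
        planted_coexpr=(
            gg.PlantedCoexpr(6, "treated", term_x="GO:CX", term_y="GO:CY"),
            gg.PlantedCoexpr(15, "treated"),
        ),
    )
    out = tmp_path_factory.mktemp("fixture")
    paths = gg.write_fixture(cfg, out)
    return cfg, paths


def random_instance(rng, n_genes=20, n_edges=30, n_terms=5, days=(2, 4)):
    """Random (graph edges, annotation, labeling) for oracle comparisons."""
    import networkx as nx

    genes = [f"g{i}" for i in range(n_genes)]
    g = nx.gnm_random_graph(n_genes, n_edges, seed=int(rng.integers(2**31)))
    edges = [(genes[a], genes[b]) for a, b in g.edges()]
    terms = [f"GO:{i}" for i in range(n_terms)]
    terms_of = {}
    for gene in genes:
        k = int(rng.integers(0, 3))  # 0-2 terms; some genes unannotated
        if k:
            terms_of[gene] = tuple(
                sorted(rng.choice(terms, size=k, replace=False))
            )
    day_of = {}
    for gene in genes:
        u = rng.random()
        if u < 0.3:
            day_of[gene] = days[0]
        elif u < 0.6:
            day_of[gene] = days[1]
        # else unlabeled
    return genes, edges, terms_of, day_of


def as_objects(genes, edges, terms_of, day_of, alpha=0.01):
    """Package a random instance into the library's domain types."""
    import networkx as nx

    net = nx.Graph()
    net.add_nodes_from(genes)
    net.add_edges_from(edges)
    annot = GoAnnotation({g: frozenset(t) for g, t in terms_of.items()})
    labeling = gg.FirstDayLabeling(gene_to_day=dict(day_of), alpha=alpha)
    return net, annot, labeling
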