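import pytest

from phenolink import (
    CurieId,
    DiseaseNode,
    KnowledgeGraph,
    SimulationConfig,
    simulate_knowledge_graph,
)


def curie(text: str) -> CurieId:
    from phenolink import normalize_curie

    return normalize_curie(text)


def make_graph(nodes, tree_edges=(), phenotype_edges=(), gene_edges=()):
    """Assemble a small validated graph from shorthand tuples:
    nodes as (id, xref-iterable), edges as CURIE-string tuples."""
    g = KnowledgeGraph()
    for node_id, xrefs in nodes:
        nid = curie(node_id)
        g.nodes[nid] = DiseaseNode(
            id=nid,
            name=f"disease {nid.local_id}",
            source=nid.prefix,
            xrefs=frozenset(curie(x) for x in xrefs),
        )
    for child, parent in tree_edges:
        c = curie(child)
        g.tree_edges.add((c, curie(parent), c.prefix))
    for subj, obj in phenotype_edges:
        g.phenotype_edges.add((curie(subj), curie(obj)))
    for subj, obj in gene_edges:
        g.gene_edges.add((curie(subj), curie(obj)))
    g.validate()
    return g


@pytest.fixture
def noise_free_config():
    """The planted-structure reference condition: 60 diseases, 5
    duplicate pairs, 5 subtype pairs, 4 sibling families of 4, no label
    noise, no collisions."""
    return SimulationConfig(
        seed=7,
        n_diseases=60,
        n_duplicate_pairs=5,
        n_subtype_pairs=5,
        n_sibling_families=4,
        family_size=4,
        label_noise=0.0,
        n_collision_pairs=0,
    )


@pytest.fixture
def noise_free_graph(noise_free_config):
    return simulate_knowledge_graph(noise_free_config)
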