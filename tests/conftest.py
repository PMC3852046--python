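import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dlrs
from dlrs.trees import GeneFamily, PlantedTree, TimedSpeciesTree

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def species2() -> TimedSpeciesTree:
    """Two species, split at age 1, planted root at age 2."""
    return TimedSpeciesTree.from_newick("(A:1,B:1):1;")


@pytest.fixture
def species3() -> TimedSpeciesTree:
    """Three species ((A,B),C): splits at ages 1 and 2, planted at 3."""
    return TimedSpeciesTree.from_newick("((A:1,B:1):1,C:2):1;")


@pytest.fixture
def species4() -> TimedSpeciesTree:
    """Balanced four species, splits at ages 1 and 2, planted at 3."""
    return TimedSpeciesTree.from_newick("((A:1,B:1):1,(C:1,D:1):1):1;")


def species_leaves(S: TimedSpeciesTree) -> dict[str, int]:
    return {S.topology.label[v]: v for v in S.topology.leaves()}


def build_gene_tree(shape, species: TimedSpeciesTree, lengths=None):
    """GeneFamily from a nested-tuple shape whose leaves are species letters."""
    from _oracles import family_from_shape

    fam = family_from_shape(shape, species_leaves(species))
    if lengths is not None:
        fam = GeneFamily(fam.gene_tree, dict(lengths), fam.leaf_map, fam.alignment)
    return fam


def congruent_family(S: TimedSpeciesTree, rate: float = 1.0) -> GeneFamily:
    """One gene per species, topology congruent with S, lengths = rate x span."""
    top = S.topology
    G = PlantedTree()
    mapping: dict[int, int] = {}
    leaf_map: dict[int, int] = {}

    def build(sv: int, parent):
        if top.is_leaf(sv):
            g = G.add_vertex(parent=parent, label=top.label[sv].lower() + "1")
            leaf_map[g] = sv
        else:
            g = G.add_vertex(parent=parent)
            for c in top.children[sv]:
                build(c, g)
        mapping[sv] = g
        return g

    planted = G.add_vertex()
    build(top.root, planted)
    lengths = {}
    for sv, g in mapping.items():
        span = S.time[top.parent[sv]] - S.time[sv]
        lengths[g] = rate * span
    return GeneFamily(G, lengths, leaf_map)


def random_tiny_instance(rng: np.random.Generator):
    """A random small (family, params, S') triple amenable to enumeration."""
    from _oracles import all_gene_topologies, family_from_shape

    S = (
        TimedSpeciesTree.from_newick("(A:1,B:1):1;")
        if rng.random() < 0.5
        else TimedSpeciesTree.from_newick("((A:1,B:1):1,C:2):1;")
    )
    letters = [S.topology.label[v] for v in S.topology.leaves()]
    n_leaves = int(rng.integers(2, 5))
    labels = [letters[int(rng.integers(len(letters)))] for _ in range(n_leaves)]
    shapes = all_gene_topologies(labels)
    shape = shapes[int(rng.integers(len(shapes)))]
    fam = family_from_shape(shape, species_leaves(S))
    lengths = {e: float(rng.uniform(0.2, 2.0)) for e in fam.gene_tree.edges()}
    fam = GeneFamily(fam.gene_tree, lengths, fam.leaf_map)
    params = dlrs.ModelParams(
        lam=float(rng.uniform(0.1, 0.8)),
        mu=float(rng.uniform(0.1, 0.8)),
        rate_mean=1.0,
        rate_var=float(rng.uniform(0.3, 0.8)),
    )
    k = int(rng.integers(1, 4))
    sd = dlrs.discretize(S, k)
    return fam, params, sd
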