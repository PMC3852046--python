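"""Most parsimonious reconciliation and distances between reconciliations.

The MPR is the classical LCA mapping: a gene vertex u is a duplication iff
sigma(u) equals sigma of one of its children; duplications are placed on the
species edge immediately above sigma(u), speciations at sigma(u) itself.

Distances between two reconciliations of the same (G, S) are built from an
atomary distance between species-tree objects a, b in V(S) u E(S):

    d(a, b) = l + 1 - |{a,b} n V(S)|/2 - |{a,b} n E(S)|

where l is the edge-length of the minimum-length path of S containing both
objects (an edge is contained when both its endpoints are).  The max distance
takes the maximum of d(gamma(u), gamma'(u)) over V(G); the average distance
sums over all of V(G) but divides by the number of internal vertices (leaf
terms vanish because both reconciliations fix the leaves).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .realization import Reconciliation, SpeciesObj
from .trees import GeneFamily, PlantedTree


@dataclass(frozen=True)
class MPRResult:
    reconciliation: Reconciliation
    duplication_count: int


def mpr(family: GeneFamily, species_tree: PlantedTree) -> MPRResult:
    """The most parsimonious (LCA) reconciliation of the family with S."""
    G = family.gene_tree
    sig = family.sigma_map(species_tree)
    gamma: dict[int, SpeciesObj] = {}
    dups = 0
    for u in G.vertices():
        if u == G.planted_root:
            gamma[u] = ("vertex", species_tree.planted_root)
        elif G.is_leaf(u):
            gamma[u] = ("vertex", sig[u])
        else:
            if any(sig[c] == sig[u] for c in G.children[u]):
                gamma[u] = ("edge", sig[u])  # edge above sigma(u)
                dups += 1
            else:
                gamma[u] = ("vertex", sig[u])
    return MPRResult(Reconciliation.from_dict(gamma), dups)


def min_discretization_for_mpr(family: GeneFamily, species_tree: PlantedTree) -> int:
    """Smallest k such that S' can host the MPR's stacked duplications.

    Ancestor-descendant duplications placed on the same species edge need
    distinct interior vertices, so k must be at least the longest such chain.
    """
    gamma = mpr(family, species_tree).reconciliation.as_dict()
    G = family.gene_tree
    depth: dict[int, int] = {}
    best = 1
    for u in G.postorder()[::-1]:  # parents first
        obj = gamma.get(u)
        if obj is None or obj[0] != "edge":
            continue
        par = G.parent[u]
        depth[u] = depth.get(par, 0) + 1 if gamma.get(par) == obj else 1
        best = max(best, depth[u])
    return best


def _endpoints(S: PlantedTree, obj: SpeciesObj) -> tuple[int, ...]:
    kind, ident = obj
    if kind == "vertex":
        return (ident,)
    if kind == "edge":
        return (ident, S.parent[ident])
    raise ValueError(f"unknown object kind {kind!r}")


def _tree_path(S: PlantedTree, a: int, b: int) -> list[int]:
    anc = S.lca(a, b)
    up_a, v = [], a
    while v != anc:
        up_a.append(v)
        v = S.parent[v]
    up_b, v = [], b
    while v != anc:
        up_b.append(v)
        v = S.parent[v]
    return up_a + [anc] + up_b[::-1]


def atomary_distance(S: PlantedTree, a: SpeciesObj, b: SpeciesObj) -> float:
    """The elementary distance between two vertices/edges of the species tree."""
    req = set(_endpoints(S, a)) | set(_endpoints(S, b))
    for v in req:
        if v < 0 or v >= S.n_vertices:
            raise ValueError("objects do not belong to this species tree")
    best = None
    for x, y in product(_endpoints(S, a), _endpoints(S, b)):
        path = _tree_path(S, x, y)
        if req.issubset(path):
            ln = len(path) - 1
            best = ln if best is None else min(best, ln)
    if best is None:
        raise ValueError("objects of S do not lie on a common path")
    # objects counted with multiplicity, so identical objects get distance 0
    n_vertices = (a[0] == "vertex") + (b[0] == "vertex")
    n_edges = (a[0] == "edge") + (b[0] == "edge")
    return best + 1 - n_vertices / 2 - n_edges


def _paired_mappings(gamma: Reconciliation, gamma2: Reconciliation):
    d1, d2 = gamma.as_dict(), gamma2.as_dict()
    if set(d1) != set(d2):
        raise ValueError("reconciliations are not over the same gene tree")
    return d1, d2


def distance_max(S: PlantedTree, gamma: Reconciliation, gamma2: Reconciliation) -> float:
    d1, d2 = _paired_mappings(gamma, gamma2)
    return max(atomary_distance(S, d1[u], d2[u]) for u in d1)


def distance_avg(
    S: PlantedTree, G: PlantedTree, gamma: Reconciliation, gamma2: Reconciliation
) -> float:
    d1, d2 = _paired_mappings(gamma, gamma2)
    total = sum(atomary_distance(S, d1[u], d2[u]) for u in d1)
    internal = [
        u for u in G.vertices()
        if not G.is_leaf(u) and u != G.planted_root
    ]
    if not internal:
        raise ValueError("gene tree has no internal vertices")
    return total / len(internal)
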