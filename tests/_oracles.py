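"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP tables: realizations are enumerated
explicitly and their densities are computed as direct products of local model
factors along species-tree paths, so that agreement with the DP is a real
cross-check of the sum-product structure.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from dlrs.birth_death import BDTables, build_bd_tables
from dlrs.model import ModelParams
from dlrs.rates import rate_density
from dlrs.realization import DRealization, Reconciliation, SpeciesObj
from dlrs.trees import DiscretizedSpeciesTree, GeneFamily, PlantedTree


def edge_factor(
    sd: DiscretizedSpeciesTree,
    bdt: BDTables,
    params: ModelParams,
    length: float,
    x: int,
    y: int,
) -> float:
    """Density factor of a gene edge realized from S'-vertex x down to y.

    One p11 per S' segment on the path, one sibling-extinction factor per
    speciation vertex passed through (strictly between x and y), and a single
    relaxed-clock density over the full span.
    """
    path = []
    v = y
    while v != x:
        path.append(v)
        v = sd.parent[v]
        if v == -1:
            raise ValueError("x is not an ancestor of y")
    path.append(x)
    path.reverse()  # x ... y
    f = 1.0
    for a, b in zip(path, path[1:]):
        f *= bdt.p11[(a, b)]
    for q, b in zip(path[1:-1], path[2:]):
        if sd.is_speciation(q):
            f *= bdt.eps_bar(q, b)
    f *= rate_density(length / sd.t(x, y), params.rates)
    return f


def realization_density(
    alpha: dict[int, int],
    family: GeneFamily,
    params: ModelParams,
    sd: DiscretizedSpeciesTree,
    bdt: BDTables | None = None,
) -> float:
    """p(G, l, alpha | theta, S) as an explicit product over gene edges/events."""
    bdt = bdt or build_bd_tables(sd, params.bd)
    G = family.gene_tree
    dens = 1.0
    for u in G.vertices():
        if u == G.planted_root:
            continue
        dens *= edge_factor(
            sd, bdt, params, family.lengths[u], alpha[G.parent[u]], alpha[u]
        )
        if not G.is_leaf(u) and not sd.is_species(alpha[u]):
            dens *= 2.0 * params.lam * sd.slice[alpha[u]]
    return dens


def enumerate_realizations(
    family: GeneFamily, params: ModelParams, sd: DiscretizedSpeciesTree
) -> list[tuple[DRealization, float]]:
    """All sound d-realizations with their densities (zero-density included)."""
    G = family.gene_tree
    sig = family.sigma_map(sd.base.topology)
    bdt = build_bd_tables(sd, params.bd)
    paths = {
        u: sd.ancestors_path(sd.of_species[sig[u]])
        for u in G.vertices()
        if u != G.planted_root
    }

    def options(u: int, parent_pos: int) -> list[int]:
        below = [
            v for v in paths[u]
            if v != parent_pos and parent_pos in sd.ancestors_path(v)
        ]
        if G.is_leaf(u):
            return [v for v in below if v == sd.of_species[sig[u]]]
        out = []
        for v in below:
            if sd.is_species(v):
                if v == sd.of_species[sig[u]] and sd.is_speciation(v):
                    out.append(v)
            else:
                out.append(v)
        return out

    results: list[tuple[DRealization, float]] = []
    order = [u for u in G.postorder()[::-1] if u != G.planted_root]

    def rec(i: int, alpha: dict[int, int]) -> None:
        if i == len(order):
            full = dict(alpha)
            full[G.planted_root] = sd.planted_root
            results.append(
                (
                    DRealization.from_dict(full),
                    realization_density(full, family, params, sd, bdt),
                )
            )
            return
        u = order[i]
        ppos = alpha[G.parent[u]] if G.parent[u] in alpha else sd.planted_root
        for v in options(u, ppos):
            alpha[u] = v
            rec(i + 1, alpha)
            del alpha[u]

    rec(0, {})
    return results


def enumerate_reconciliations(
    family: GeneFamily, params: ModelParams, sd: DiscretizedSpeciesTree
) -> dict[Reconciliation, float]:
    """Reconciliation densities as sums over their associated d-realizations."""
    out: dict[Reconciliation, float] = {}
    for alpha, dens in enumerate_realizations(family, params, sd):
        gamma = alpha.project(sd)
        out[gamma] = out.get(gamma, 0.0) + dens
    return out


def brute_force_min_duplications(family: GeneFamily, S: PlantedTree) -> int:
    """Minimum duplication count over all sound reconciliations, by search."""
    G = family.gene_tree
    sig = family.sigma_map(S)

    def edges_above(s_vertex: int) -> list[int]:
        out, v = [], s_vertex
        while S.parent[v] != -1:
            out.append(v)  # edge keyed by child
            v = S.parent[v]
        return out

    def below(bound: SpeciesObj, obj: SpeciesObj) -> bool:
        kb, vb = bound
        ko, vo = obj
        if kb == "vertex" and ko == "vertex":
            return vb != vo and S.is_ancestor(vb, vo)
        if kb == "vertex" and ko == "edge":
            return S.is_ancestor(vb, S.parent[vo])
        if kb == "edge" and ko == "vertex":
            return S.is_ancestor(vb, vo)
        return bound == obj or S.is_ancestor(vb, S.parent[vo])

    @lru_cache(maxsize=None)
    def best(u: int, bound: SpeciesObj) -> float:
        if G.is_leaf(u):
            return 0.0 if below(bound, ("vertex", sig[u])) else math.inf
        opts: list[tuple[SpeciesObj, int]] = []
        sv = ("vertex", sig[u])
        if S.children[sig[u]] and below(bound, sv):
            opts.append((sv, 0))
        for e in edges_above(sig[u]):
            obj = ("edge", e)
            if below(bound, obj):
                opts.append((obj, 1))
        out = math.inf
        for obj, cost in opts:
            sub = cost + sum(best(c, obj) for c in G.children[u])
            out = min(out, sub)
        return out

    res = best(G.root, ("vertex", S.planted_root))
    best.cache_clear()
    if math.isinf(res):
        raise ValueError("no sound reconciliation found (should not happen)")
    return int(res)


def all_gene_topologies(labels: list[str]) -> list:
    """All rooted binary leaf-labeled shapes over the multiset of labels.

    Returned as nested tuples; deduplicated up to child order.
    """

    def canon(t):
        if isinstance(t, str):
            return t
        a, b = canon(t[0]), canon(t[1])
        return (a, b) if repr(a) <= repr(b) else (b, a)

    def rec(items: tuple) -> set:
        if len(items) == 1:
            return {items[0]}
        out = set()
        n = len(items)
        for mask in range(1, 2 ** (n - 1)):
            left = tuple(x for i, x in enumerate(items) if mask >> i & 1)
            right = tuple(x for i, x in enumerate(items) if not mask >> i & 1)
            for lt in rec(left):
                for rt in rec(right):
                    out.add(canon((lt, rt)))
        return out

    return sorted(rec(tuple(labels)), key=repr)


def family_from_shape(shape, species_map: dict[str, int], lengths_value: float = 0.5):
    """Build a GeneFamily (no alignment) from a nested-tuple leaf-label shape."""
    G = PlantedTree()
    planted = G.add_vertex()
    counter: dict[str, int] = {}

    def build(t, parent: int) -> int:
        if isinstance(t, str):
            counter[t] = counter.get(t, 0) + 1
            return G.add_vertex(parent=parent, label=f"{t.lower()}{counter[t]}")
        v = G.add_vertex(parent=parent)
        build(t[0], v)
        build(t[1], v)
        return v

    build(shape, planted)
    G.validate()
    lengths = {v: lengths_value for v in G.edges()}
    leaf_map = {
        u: species_map[G.label[u][0].upper()] for u in G.leaves()
    }
    return GeneFamily(G, lengths, leaf_map)
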