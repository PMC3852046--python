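"""Sampling and MAP computation of d-realizations; reconciliations.

A d-realization alpha maps gene-tree vertices to vertices of the discretized
species tree S'; its projection through the R-map (species vertex -> itself,
interior vertex -> its species edge) is the associated reconciliation gamma.
Realizations are sampled exactly from p(alpha | G, l, theta, S) by drawing the
gene-root placement from its normalized marginal and then each child's
placement conditional on its parent's, using the s-table rows.  The MAP
d-realization replaces sums by maxima (the m-table) and traces backpointers;
ties break towards the leafmost discretization vertex, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp import DPContext, DPTable
from .model import ModelParams
from .trees import DiscretizedSpeciesTree, GeneFamily

SpeciesObj = tuple[str, int]  # ('vertex', s_vertex) or ('edge', child_s_vertex)


@dataclass(frozen=True)
class DRealization:
    """Mapping of gene-tree vertices to S' vertices (planted root included)."""

    mapping: tuple[tuple[int, int], ...]  # sorted (gene vertex, S' vertex) pairs

    @classmethod
    def from_dict(cls, d: dict[int, int]) -> "DRealization":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[int, int]:
        return dict(self.mapping)

    def project(self, sd: DiscretizedSpeciesTree) -> "Reconciliation":
        return Reconciliation(
            tuple(sorted((u, sd.project(v)) for u, v in self.mapping))
        )


@dataclass(frozen=True)
class Reconciliation:
    """Mapping of gene-tree vertices to species-tree vertices or edges."""

    mapping: tuple[tuple[int, SpeciesObj], ...]

    @classmethod
    def from_dict(cls, d: dict[int, SpeciesObj]) -> "Reconciliation":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[int, SpeciesObj]:
        return dict(self.mapping)

    def duplication_count(self) -> int:
        return sum(1 for _, (kind, _) in self.mapping if kind == "edge")


def check_realization_sound(
    alpha: dict[int, int], family: GeneFamily, sd: DiscretizedSpeciesTree
) -> None:
    """Raise ValueError if alpha is not a sound d-realization."""
    G = family.gene_tree
    sig = family.sigma_map(sd.base.topology)
    if alpha.get(G.planted_root) != sd.planted_root:
        raise ValueError("the planted root of G must map to the planted root of S")
    for u in G.vertices():
        if u == G.planted_root:
            continue
        if u not in alpha:
            raise ValueError(f"gene vertex {u} unmapped")
        pu = G.parent[u]
        if alpha[u] == alpha[pu]:
            raise ValueError("a vertex and its parent cannot map to the same S' vertex")
        anc = sd.ancestors_path(alpha[u])
        if alpha[pu] not in anc:
            raise ValueError("unsound realization: child mapped above its parent")
        if G.is_leaf(u) and alpha[u] != sd.of_species[sig[u]]:
            raise ValueError("gene leaves must map to their species leaves")


def sample_drealization(
    table: DPTable, rng: np.random.Generator | int
) -> DRealization:
    """Draw one d-realization from p(alpha | G, l, theta, S).

    ``rng`` may be a Generator or an integer seed; the draw is deterministic
    given the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if table.mode != "sum":
        raise ValueError("sampling requires an s-table (mode='sum')")
    ctx = table.ctx
    G = ctx.family.gene_tree
    alpha: dict[int, int] = {G.planted_root: ctx.sd.planted_root}

    def draw(u: int, row: int) -> None:
        weights = table.s_matrix(u)[row, :row]
        tot = weights.sum()
        if tot <= 0.0:
            raise RuntimeError(
                "all-zero placement conditional: inconsistent s-table"
            )
        j = int(np.searchsorted(np.cumsum(weights), rng.random() * tot, side="right"))
        j = min(j, row - 1)
        alpha[u] = ctx.path[u][j]
        if not G.is_leaf(u):
            for c in G.children[u]:
                draw(c, j + ctx.offset[c])

    r = ctx.root
    draw(r, len(ctx.path[r]) - 1)
    return DRealization.from_dict(alpha)


def compute_m_table(
    family: GeneFamily, params: ModelParams, sd: DiscretizedSpeciesTree
) -> DPTable:
    """The max-product analogue of the s-table, with backpointers."""
    return DPTable(DPContext(family, sd), params, mode="max")


def map_drealization(table: DPTable) -> tuple[DRealization, float]:
    """Trace the MAP d-realization and return it with its probability density."""
    if table.mode != "max":
        raise ValueError("MAP traceback requires an m-table (mode='max')")
    ctx = table.ctx
    G = ctx.family.gene_tree
    best = table.total()
    if best <= 0.0:
        raise RuntimeError("zero MAP probability: no sound realization has support")
    alpha: dict[int, int] = {G.planted_root: ctx.sd.planted_root}

    def trace(u: int, row: int) -> None:
        j = int(table.argmax[u][row])
        alpha[u] = ctx.path[u][j]
        if not G.is_leaf(u):
            for c in G.children[u]:
                trace(c, j + ctx.offset[c])

    r = ctx.root
    trace(r, len(ctx.path[r]) - 1)
    return DRealization.from_dict(alpha), best


def to_reconciliation(alpha: DRealization, sd: DiscretizedSpeciesTree) -> Reconciliation:
    """The unique reconciliation associated with a d-realization."""
    return alpha.project(sd)


def _object_above(S, a: SpeciesObj, b: SpeciesObj) -> bool:
    """True if object a may host an ancestor of a gene vertex hosted by b.

    Vertices may not repeat along a gene lineage; an edge may host several.
    """
    ka, va = a
    kb, vb = b
    if ka == "vertex" and kb == "vertex":
        return va != vb and S.is_ancestor(va, vb)
    if ka == "vertex" and kb == "edge":
        return S.is_ancestor(va, S.parent[vb])
    if ka == "edge" and kb == "vertex":
        return S.is_ancestor(va, vb)
    return a == b or S.is_ancestor(va, S.parent[vb])


def check_reconciliation_sound(
    gamma: dict[int, SpeciesObj], family: GeneFamily, sd: DiscretizedSpeciesTree
) -> None:
    """Raise ValueError if gamma is not a sound reconciliation for (G, S)."""
    S = sd.base.topology
    G = family.gene_tree
    sig = family.sigma_map(S)
    if gamma.get(G.planted_root) != ("vertex", S.planted_root):
        raise ValueError("the planted root of G must map to the planted root of S")
    for u in G.vertices():
        if u not in gamma:
            raise ValueError(f"gene vertex {u} unmapped")
        kind, ident = gamma[u]
        if G.is_leaf(u) and u != G.planted_root:
            if gamma[u] != ("vertex", sig[u]):
                raise ValueError("gene leaves must map to their species leaves")
        if kind == "vertex" and not S.is_ancestor(ident, sig[u]):
            raise ValueError("vertex placement below sigma(u) is unsound")
        if kind == "edge" and not S.is_ancestor(ident, sig[u]):
            raise ValueError("edge placement below sigma(u) is unsound")
        if u != G.planted_root and not _object_above(S, gamma[G.parent[u]], gamma[u]):
            raise ValueError("unsound reconciliation: child placed above its parent")


def species_object_name(sd: DiscretizedSpeciesTree, obj: SpeciesObj) -> str:
    S = sd.base.topology
    kind, ident = obj
    if kind == "vertex":
        if ident == S.planted_root:
            return "planted_root"
        return S.label[ident] if S.is_leaf(ident) else f"({S.leafset_id(ident)})"
    return f"edge_above:({S.leafset_id(ident)})"


def _gene_vertex_name(G, u: int) -> str:
    return "planted_root" if u == G.planted_root else G.leafset_id(u)


def realization_to_tsv(
    alpha: DRealization, family: GeneFamily, sd: DiscretizedSpeciesTree
) -> str:
    """TSV serialization; gene vertices named by their sorted subtree leaf sets.

    Columns: gene vertex, event kind, species vertex/edge, discretization
    point (index within the edge, 0 = leafmost; empty at species vertices).
    """
    G = family.gene_tree
    lines = ["gene_vertex\tkind\tspecies_position\tdiscretization_point"]
    for u, v in alpha.mapping:
        obj = sd.project(v)
        kind = "duplication" if obj[0] == "edge" else ("leaf" if G.is_leaf(u) else "speciation")
        point = "" if obj[0] == "vertex" else str(sd.edge_points[obj[1]].index(v))
        lines.append(
            f"{_gene_vertex_name(G, u)}\t{kind}\t{species_object_name(sd, obj)}\t{point}"
        )
    return "\n".join(lines) + "\n"


def reconciliation_to_tsv(
    gamma: Reconciliation, family: GeneFamily, sd: DiscretizedSpeciesTree
) -> str:
    G = family.gene_tree
    lines = ["gene_vertex\tkind\tspecies_position\tdiscretization_point"]
    for u, obj in gamma.mapping:
        kind = "duplication" if obj[0] == "edge" else ("leaf" if G.is_leaf(u) else "speciation")
        lines.append(f"{_gene_vertex_name(G, u)}\t{kind}\t{species_object_name(sd, obj)}\t")
    return "\n".join(lines) + "\n"


def reconciliation_probability(
    family: GeneFamily,
    params: ModelParams,
    sd: DiscretizedSpeciesTree,
    gamma: Reconciliation | dict[int, SpeciesObj],
) -> float:
    """p(G, l, gamma | theta, S): the gamma-restricted generation density.

    The s-recursion with every placement sum intersected with R(gamma(.)).
    Raises for an unsound gamma.
    """
    gd = gamma.as_dict() if isinstance(gamma, Reconciliation) else dict(gamma)
    check_reconciliation_sound(gd, family, sd)
    ctx = DPContext(family, sd)
    masks: dict[int, np.ndarray] = {}
    for u in ctx.order:
        allowed = set(sd.R(gd[u]))
        m = np.array([1.0 if v in allowed else 0.0 for v in ctx.path[u]])
        masks[u] = m
    table = DPTable(ctx, params, mode="sum", event_mask=masks)
    return table.total()
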