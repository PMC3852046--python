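"""The core DLRS dynamic program over the discretized species tree.

For every gene vertex u the table s(x, y, u) holds the probability (density in
the edge lengths) that a single gene lineage starting at S'-vertex x generates
the planted gene subtree G^u with its lengths, with the event of u realized at
S'-vertex y.  Events live on the path from sigma(u) up to the planted root of
S', so per u the table is a lower-triangular matrix indexed by path positions
(0 = sigma(u), increasing rootwards).

The recursion, evaluated bottom-up over G and over S' positions:

* leaf u at its species leaf: s = 1;
* speciation: u realized at sigma(u) (an internal species vertex) combines the
  two children's placement sums, one per side of the speciation;
* duplication: u realized at an interior discretization vertex y contributes
  2 * lambda * dt(y) (dt(y) = the time slice owned by y) times the two
  children's sums over proper descendants of y;
* chaining: s(x, y, u) for x above y multiplies one p11 factor per S' segment
  on the path, one sibling-extinction factor eps(z, zbar) for every speciation
  vertex z the edge passes *through* (strictly between x and y), and a single
  relaxed-clock density rho(l(p(u), u) / t(x, y)) for the edge's full span
  (the per-step rho ratios of the raw recursion telescope to this).

The generation probability p(G, l | theta, S) is the sum over placements of
the gene root strictly below the planted root of S.

Because the chain factors depend only on (S', lambda, mu) and on the path -
which is determined by sigma(u) - they are cached per sigma vertex and can be
shared across the gene vertices of a family and across whole cohorts; the
sum-mode table works on flattened lower-triangular arrays for speed.
"""

from __future__ import annotations

import math

import numpy as np

from .birth_death import BDTables, build_bd_tables
from .model import ModelParams
from .rates import rate_density
from .trees import DiscretizedSpeciesTree, GeneFamily


class DPContext:
    """Per-family precomputation shared by every parameter value.

    Holds, for every non-planted gene vertex u: the S' path from sigma'(u) to
    the planted root, the pairwise time spans along it (dense and flattened
    over the strict lower triangle), flags marking interior
    (duplication-capable) positions, and the index offset into each child's
    (longer) path.
    """

    def __init__(self, family: GeneFamily, sd: DiscretizedSpeciesTree) -> None:
        self.family = family
        self.sd = sd
        G = family.gene_tree
        S = sd.base.topology
        self.sigma = family.sigma_map(S)
        self.order = [u for u in G.postorder() if u != G.planted_root]
        self.root = G.root
        self.path: dict[int, list[int]] = {}
        self.tdiff: dict[int, np.ndarray] = {}
        self.interior: dict[int, np.ndarray] = {}
        self.dupw: dict[int, np.ndarray] = {}  # 2*dt slice weights at interior pos
        self.offset: dict[int, int] = {}       # child-path index offset vs parent path
        self.fi: dict[int, np.ndarray] = {}    # flattened strict-lower row index
        self.fj: dict[int, np.ndarray] = {}    # flattened strict-lower col index
        self.td_flat: dict[int, np.ndarray] = {}
        path_cache: dict[int, tuple] = {}
        for u in self.order:
            sp = sd.of_species[self.sigma[u]]
            if sp not in path_cache:
                p = sd.ancestors_path(sp)
                t = np.array([sd.time[v] for v in p])
                td = t[:, None] - t[None, :]
                fi, fj = np.tril_indices(len(p), k=-1)
                path_cache[sp] = (p, td, fi, fj, td[fi, fj],
                                  np.array([not sd.is_species(v) for v in p]),
                                  np.array([2.0 * sd.slice[v] for v in p]))
            p, td, fi, fj, tdf, inter, dupw = path_cache[sp]
            self.path[u] = p
            self.tdiff[u] = td
            self.fi[u], self.fj[u], self.td_flat[u] = fi, fj, tdf
            self.interior[u] = inter
            self.dupw[u] = dupw
        for u in self.order:
            par = G.parent[u]
            if par == G.planted_root:
                continue
            self.offset[u] = len(self.path[u]) - len(self.path[par])

    def index_of(self, u: int, sprime: int) -> int:
        return self.path[u].index(sprime)


def chain_matrix(
    sd: DiscretizedSpeciesTree, bdt: BDTables, path: list[int]
) -> np.ndarray:
    """C[i, j] (i > j): product of p11 steps and pass-through eps factors."""
    A = len(path)
    C = np.zeros((A, A))
    step = np.empty(A)
    passf = np.ones(A)
    for i in range(1, A):
        step[i] = bdt.p11[(path[i], path[i - 1])]
    for q in range(1, A - 1):
        if sd.is_speciation(path[q]):
            passf[q] = bdt.eps_bar(path[q], path[q - 1])
    for i in range(1, A):
        if i >= 2:
            C[i, : i - 1] = step[i] * passf[i - 1] * C[i - 1, : i - 1]
        C[i, i - 1] = step[i]
    return C


def _gamma_logconst(mean: float, var: float) -> tuple[float, float, float]:
    a = mean * mean / var
    s = var / mean
    return a, s, -math.lgamma(a) - a * math.log(s)


class DPTable:
    """The s-table (mode='sum') or m-table (mode='max') for one gene family.

    ``agg[u][i]`` is the sum (max) over all placements of u strictly below
    path position i; ``argmax[u]`` records backpointers in max mode.  Use
    ``s_matrix(u)`` for the dense placement matrix of one gene vertex.
    """

    def __init__(
        self,
        ctx: DPContext,
        params: ModelParams,
        mode: str = "sum",
        event_mask: dict[int, np.ndarray] | None = None,
        reuse: "DPTable | None" = None,
        bdt: BDTables | None = None,
        chain_cache: dict[int, np.ndarray] | None = None,
    ) -> None:
        if mode not in ("sum", "max"):
            raise ValueError("mode must be 'sum' or 'max'")
        self.ctx = ctx
        self.params = params
        self.mode = mode
        sd = ctx.sd
        G = ctx.family.gene_tree

        if reuse is not None and reuse.params.bd == params.bd:
            self.bdt = reuse.bdt
            self._chain = reuse._chain
        else:
            self.bdt = bdt if bdt is not None and bdt.bd == params.bd else \
                build_bd_tables(sd, params.bd)
            self._chain = chain_cache if chain_cache is not None else {}
        chain = self._chain
        for u in ctx.order:
            key = ctx.path[u][0]
            if key not in chain:
                chain[key] = chain_matrix(sd, self.bdt, ctx.path[u])

        if reuse is not None and reuse.params.rates == params.rates:
            self.Rflat = reuse.Rflat
        else:
            a, s, logc = _gamma_logconst(params.rate_mean, params.rate_var)
            self.Rflat = {}
            for u in ctx.order:
                r = ctx.family.lengths[u] / ctx.td_flat[u]
                self.Rflat[u] = np.exp(logc + (a - 1.0) * np.log(r) - r / s)

        self.e: dict[int, np.ndarray] = {}
        self.agg: dict[int, np.ndarray] = {}
        self.argmax: dict[int, np.ndarray] = {}
        self._Sflat: dict[int, np.ndarray] = {}
        lam = params.lam
        for u in ctx.order:
            A = len(ctx.path[u])
            e = np.zeros(A)
            if G.is_leaf(u):
                e[0] = 1.0  # sigma(u) is a species leaf
            else:
                v, w = G.children[u]
                av, aw = self.agg[v], self.agg[w]
                ov, ow = ctx.offset[v], ctx.offset[w]
                # duplications at interior vertices strictly above sigma(u)
                idx = np.nonzero(ctx.interior[u])[0]
                e[idx] = lam * ctx.dupw[u][idx] * av[idx + ov] * aw[idx + ow]
                # speciation at sigma(u) itself, if it is an internal S vertex
                if sd.is_speciation(ctx.path[u][0]):
                    e[0] = av[ov] * aw[ow]
            if event_mask is not None and u in event_mask:
                e = e * event_mask[u]
            self.e[u] = e
            fi, fj = ctx.fi[u], ctx.fj[u]
            Sflat = chain[ctx.path[u][0]][fi, fj] * self.Rflat[u] * e[fj]
            self._Sflat[u] = Sflat
            if mode == "sum":
                self.agg[u] = np.bincount(fi, weights=Sflat, minlength=A)
            else:
                M = np.zeros((A, A))
                M[fi, fj] = Sflat
                self.agg[u] = M.max(axis=1, initial=0.0)
                self.argmax[u] = M.argmax(axis=1)

    # -- accessors ---------------------------------------------------------
    def s_matrix(self, u: int) -> np.ndarray:
        """Dense placement matrix: entry (i, j) = s(path[i], path[j], u), i > j."""
        cache = getattr(self, "_dense", None)
        if cache is None:
            cache = self._dense = {}
        if u not in cache:
            A = len(self.ctx.path[u])
            M = np.zeros((A, A))
            M[self.ctx.fi[u], self.ctx.fj[u]] = self._Sflat[u]
            cache[u] = M
        return cache[u]

    # -- results ----------------------------------------------------------
    def total(self) -> float:
        """Sum (or max) over gene-root placements below the planted root of S."""
        r = self.ctx.root
        return float(self.agg[r][len(self.ctx.path[r]) - 1])

    def value(self, x: int, y: int, u: int) -> float:
        """s(x, y, u) for S' vertices x, y; 0 outside the structural support."""
        p = self.ctx.path[u]
        if x not in p or y not in p:
            return 0.0
        i, j = p.index(x), p.index(y)
        if i < j:
            return 0.0
        if i == j:
            return float(self.e[u][i])
        return float(self.s_matrix(u)[i, j])

    def dump_rows(self):
        """(x, y, u, value) tuples of all structurally reachable entries."""
        for u in self.ctx.order:
            p = self.ctx.path[u]
            M = self.s_matrix(u)
            for i in range(len(p)):
                for j in range(i + 1):
                    v = self.e[u][i] if i == j else M[i, j]
                    if v != 0.0:
                        yield p[i], p[j], u, float(v)


def compute_s_table(
    family: GeneFamily, params: ModelParams, sd: DiscretizedSpeciesTree
) -> DPTable:
    """Build the s-table (cases 1-6) for one gene family."""
    return DPTable(DPContext(family, sd), params, mode="sum")


def generation_probability(
    family: GeneFamily,
    params: ModelParams,
    sd: DiscretizedSpeciesTree,
    table: DPTable | None = None,
) -> float:
    """p(G, l | theta, S): the DLRS generation density of (G, l)."""
    if table is None:
        table = compute_s_table(family, params, sd)
    return table.total()
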