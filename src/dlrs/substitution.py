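"""Amino-acid sequence evolution: empirical CTMC models and the pruning likelihood.

The sequence component of the model is a standard empirical amino-acid
replacement chain (JTT by default; any PAML-format ``.dat`` matrix can be
plugged in).  The rate matrix is built from the symmetric exchangeabilities
and stationary frequencies, normalized to one expected substitution per unit
branch length, and exponentiated via the symmetric eigendecomposition.  The
likelihood P(D | G, l) is computed with Felsenstein's pruning algorithm; the
planted edge of G carries a length and contributes a transition, with the
stationary distribution placed at the planted root.  Gaps and ambiguity codes
are treated as missing data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .trees import GeneFamily, PlantedTree

AA = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA)}


def _read_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    nums = [float(x) for x in text.split()]
    if len(nums) < 190 + 20:
        raise ValueError("PAML dat file must contain 190 exchangeabilities and 20 frequencies")
    S = np.zeros((20, 20))
    it = iter(nums)
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    pi = np.array([next(it) for _ in range(20)])
    pi = pi / pi.sum()
    return S, pi


@dataclass
class SubstModel:
    """Empirical amino-acid model with a normalized, reversible rate matrix."""

    name: str = "JTT"
    exchangeability: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    Q: np.ndarray = field(init=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.exchangeability is None or self.frequencies is None:
            ref = importlib.resources.files("dlrs.data") / f"{self.name.lower()}.dat"
            S, pi = _read_paml_dat(ref.read_text())
            self.exchangeability = S if self.exchangeability is None else self.exchangeability
            self.frequencies = pi if self.frequencies is None else self.frequencies
        S, pi = self.exchangeability, self.frequencies
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize: one expected substitution per unit branch length
        Q = Q / (-(pi * np.diag(Q)).sum())
        self.Q = Q
        # reversible: pi^1/2 Q pi^-1/2 is symmetric -> real eigendecomposition
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (w, U * (1.0 / sq)[:, None], U * sq[:, None])

    def transition_matrix(self, length: float) -> np.ndarray:
        """P(l) = exp(Q l); rows sum to 1."""
        if length < 0:
            raise ValueError("branch lengths must be nonnegative")
        w, L, R = self._eig
        P = (L * np.exp(w * length)[None, :]) @ R.T
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)


def transition_matrix(model: SubstModel, length: float) -> np.ndarray:
    return model.transition_matrix(length)


def _leaf_partials(seq: str) -> np.ndarray:
    """Per-site partial likelihood vectors; non-standard symbols = missing data."""
    L = np.zeros((len(seq), 20))
    for i, c in enumerate(seq):
        j = AA_INDEX.get(c)
        if j is None:
            L[i, :] = 1.0
        else:
            L[i, j] = 1.0
    return L


def felsenstein_loglik(
    gene_tree: PlantedTree,
    lengths: dict[int, float],
    alignment: dict[int, str],
    model: SubstModel,
) -> float:
    """log P(D | G, l) by pruning, summed over columns.

    The planted edge's transition is applied above the root and the result is
    marginalized against the stationary frequencies at the planted root.
    """
    if not alignment:
        raise ValueError("alignment is empty")
    ncol = len(next(iter(alignment.values())))
    if ncol == 0:
        raise ValueError("alignment has zero columns")
    scale_log = 0.0
    partial: dict[int, np.ndarray] = {}
    for u in gene_tree.postorder():
        if gene_tree.is_leaf(u):
            partial[u] = _leaf_partials(alignment[u])
        else:
            prod = np.ones((ncol, 20))
            for c in gene_tree.children[u]:
                P = model.transition_matrix(lengths[c])
                prod *= partial[c] @ P.T
            if u != gene_tree.planted_root:
                # rescale to dodge underflow on deep trees
                m = prod.max(axis=1, keepdims=True)
                m[m == 0.0] = 1.0
                prod /= m
                scale_log += float(np.log(m).sum())
            partial[u] = prod
    site = partial[gene_tree.planted_root] @ model.frequencies
    if np.any(site <= 0.0):
        return -np.inf
    return float(np.log(site).sum()) + scale_log


def simulate_alignment(
    gene_tree: PlantedTree,
    lengths: dict[int, float],
    model: SubstModel,
    n_sites: int,
    rng: np.random.Generator,
) -> dict[int, str]:
    """Simulate sequences down the planted gene tree (root state from pi)."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    states: dict[int, np.ndarray] = {}
    pr = gene_tree.planted_root
    states[pr] = rng.choice(20, size=n_sites, p=model.frequencies)
    for u in gene_tree.postorder()[::-1]:
        if u == pr:
            continue
        P = model.transition_matrix(lengths[u])
        parent_states = states[gene_tree.parent[u]]
        cum = P.cumsum(axis=1)
        draws = rng.random(n_sites)
        states[u] = (draws[:, None] > cum[parent_states]).sum(axis=1)
    return {
        u: "".join(AA[s] for s in states[u])
        for u in gene_tree.leaves()
    }
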