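"""Linear birth-death transition machinery on the discretized species tree.

A gene lineage evolving down a species-tree edge undergoes a linear
birth-death process with duplication rate lambda and loss rate mu.  Over a
segment of duration t, the number of descendant lineages at the bottom is
0 with probability p0 and otherwise geometric with parameter q (Kendall's
classical solution).  With extinction probability D below the segment bottom,
the two quantities every DP recursion needs are

* ``extinct``      -- p0 + (1-p0)(1-q) D / (1 - qD): no extant descendant at all;
* ``p11``          -- (1-p0)(1-q) / (1 - qD)^2: exactly one bottom lineage
                      continues (sum over n of P(N=n) * n * D^(n-1)); the
                      survival of that one lineage is *not* included, because
                      the DP factor it multiplies accounts for it.

Both are exact for the linear process, continuous in (lambda, mu, t), and
well defined at lambda = mu (via expm1) and at lambda or mu = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import DiscretizedSpeciesTree


@dataclass(frozen=True)
class BDParams:
    lam: float  # duplication (birth) rate, events per time unit
    mu: float   # loss (death) rate, events per time unit

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("birth-death rates must be nonnegative")


def bd_segment(lam: float, mu: float, t: float) -> tuple[float, float, float]:
    """Classical linear birth-death quantities over a segment of duration t.

    Returns ``(p_extinct, p_one_to_one_raw, q)`` where ``p_extinct`` = P(0
    lineages at t), ``p_one_to_one_raw`` = P(exactly 1 lineage at t) and ``q``
    is the geometric offspring parameter.  The lambda = mu limit is handled
    exactly.
    """
    if t < 0:
        raise ValueError("segment duration must be nonnegative")
    if t == 0:
        return 0.0, 1.0, 0.0
    d = lam - mu
    if d == 0.0:
        if lam == 0.0:
            return 0.0, 1.0, 0.0
        x = lam * t / (1.0 + lam * t)
        p0 = q = x
    else:
        em = math.expm1(d * t)
        denom = lam * em + d
        p0 = mu * em / denom
        q = lam * em / denom
    p0 = min(max(p0, 0.0), 1.0)
    q = min(max(q, 0.0), 1.0)
    return p0, (1.0 - p0) * (1.0 - q), q


def extinct_through(p0: float, q: float, below: float) -> float:
    """Overall extinction across a segment given extinction prob. below it."""
    val = p0 + (1.0 - p0) * (1.0 - q) * below / (1.0 - q * below)
    return min(max(val, 0.0), 1.0)


def p11_through(p0: float, q: float, below: float) -> float:
    """One-to-one passage across a segment given extinction prob. below it."""
    val = (1.0 - p0) * (1.0 - q) / (1.0 - q * below) ** 2
    return min(max(val, 0.0), 1.0)


class BDTables:
    """Per-vertex extinction and per-adjacent-pair one-to-one probabilities on S'.

    ``extinct[v]`` is the probability that a single lineage at S'-vertex v
    leaves no extant descendant.  ``p11[(x, z)]`` is defined for S'-adjacent
    pairs (parent x, child z).  ``eps_side[(x, z)]``, defined at speciation
    vertices x for each S'-child z, is the extinction probability of the copy
    sent from x into the edge starting at z; ``eps_bar(x, z)`` is the sibling
    value, written epsilon(x, z-bar) in the DLRS recursions.
    """

    def __init__(self, sd: DiscretizedSpeciesTree, bd: BDParams) -> None:
        self.sd = sd
        self.bd = bd
        self.extinct: dict[int, float] = {}
        self.single: dict[int, float] = {}   # exactly one extant descendant
        self.p11: dict[tuple[int, int], float] = {}
        self.eps_side: dict[tuple[int, int], float] = {}
        order = sorted(range(sd.n_vertices), key=lambda v: sd.time[v])
        for v in order:
            kids = sd.children[v]
            if not kids:  # species leaf
                self.extinct[v] = 0.0
                self.single[v] = 1.0
                continue
            side_e, side_s = [], []
            for z in kids:
                p0, _, q = bd_segment(bd.lam, bd.mu, sd.t(v, z))
                ez = extinct_through(p0, q, self.extinct[z])
                pass_one = p11_through(p0, q, self.extinct[z])
                self.p11[(v, z)] = pass_one
                self.eps_side[(v, z)] = ez
                side_e.append(ez)
                side_s.append(pass_one * self.single[z])
            self.extinct[v] = math.prod(side_e)
            if len(kids) == 1:
                self.single[v] = side_s[0]
            else:
                self.single[v] = (
                    side_s[0] * side_e[1] + side_e[0] * side_s[1]
                )

    def eps_bar(self, x: int, z: int) -> float:
        """Extinction of the copy sent into the sibling edge at speciation x.

        Vacuously 1 when x has a single S'-child (the planted root).
        """
        kids = self.sd.children[x]
        if len(kids) == 1:
            return 1.0
        (other,) = [c for c in kids if c != z]
        return self.eps_side[(x, other)]


    def prob_degenerate(self) -> float:
        """P(a family started at the planted root leaves < 2 extant genes).

        Used to condition likelihoods on a family being observable, mirroring
        the removal of extinct and single-gene families from real datasets.
        """
        p = self.sd.planted_root
        return min(1.0, self.extinct[p] + self.single[p])


def build_bd_tables(sd: DiscretizedSpeciesTree, bd: BDParams) -> BDTables:
    return BDTables(sd, bd)
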