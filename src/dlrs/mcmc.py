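"""Metropolis-Hastings sampling of p(G, l, theta | D, S).

The target factorizes as P(D | G, l) * p(G, l | theta, S) * p(theta): the
pruning likelihood, the DLRS generation density, and independent Gamma priors
on the positive parameters.  One move class is chosen per iteration:

* topology: rooted NNI (swap a vertex's sibling with one of its children) or
  rooted SPR (prune a subtree, regraft above another edge), with Hastings
  corrections from the move counts on both sides; edge lengths travel with
  their child vertex;
* lengths: a log-normal multiplier on one random edge length;
* parameters: a log-scale Gaussian random walk on one of lambda, mu, m, v.

The species tree and its divergence times are fixed throughout.  A cohort
variant (`run_mcmc_params`) holds every family's (G, l) fixed and samples
theta from the product of generation densities - the natural estimator for
duplication/loss rates from reconciled trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dp import DPContext, DPTable
from .model import ModelParams
from .substitution import felsenstein_loglik
from .trees import (
    DiscretizedSpeciesTree,
    GeneFamily,
    PlantedTree,
    TimedSpeciesTree,
    discretize,
    write_newick_planted,
)

PARAM_NAMES = ("lam", "mu", "rate_mean", "rate_var")


@dataclass
class MCMCConfig:
    iterations: int = 5000
    burn_in_frac: float = 0.25
    thin: int = 1
    discretization_k: int = 5
    fix_topology: bool = False
    fix_lengths: bool = False
    sample_params: tuple[str, ...] = PARAM_NAMES
    length_sigma: float = 0.4
    param_sigma: float = 0.4
    p_topology: float = 0.3
    p_spr: float = 0.3          # share of topology moves that are SPR
    priors: dict = field(
        default_factory=lambda: {n: (1.0, 10.0) for n in PARAM_NAMES}
    )
    # condition each family's generation density on being observable
    # (>= 2 extant genes), matching how cohorts are assembled
    condition_on_observation: bool = False
    target_override: object = None  # callable(state) -> float, for diagnostics


@dataclass
class MCMCState:
    gene_tree: PlantedTree
    lengths: dict[int, float]
    params: ModelParams


@dataclass
class Trace:
    samples: list[dict]
    n_iterations: int
    n_burn_in: int
    accept: dict[str, list[int]]

    def param_array(self, name: str) -> np.ndarray:
        return np.array([s[name] for s in self.samples])

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.param_array(name)
        lo = (1.0 - level) / 2.0
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (sum(v) / len(v) if v else float("nan"))
            for k, v in self.accept.items()
        }

    def to_tsv(self) -> str:
        header = "iteration\tlog_target\tlam\tmu\trate_mean\trate_var\tgene_tree\n"
        rows = [
            f"{s['iteration']}\t{s['log_target']:.6f}\t{s['lam']:.6g}\t"
            f"{s['mu']:.6g}\t{s['rate_mean']:.6g}\t{s['rate_var']:.6g}\t{s['newick']}\n"
            for s in self.samples
        ]
        return header + "".join(rows)


# -- tree moves -------------------------------------------------------------

def copy_tree(tree: PlantedTree) -> PlantedTree:
    out = PlantedTree()
    out.parent = list(tree.parent)
    out.children = [list(c) for c in tree.children]
    out.label = dict(tree.label)
    return out


def nni_moves(tree: PlantedTree) -> list[tuple[int, int]]:
    """All (w, c) pairs: swap w's sibling with w's child c."""
    out = []
    pr = tree.planted_root
    for w in tree.vertices():
        if tree.is_leaf(w) or w == pr:
            continue
        pw = tree.parent[w]
        if pw == -1 or pw == pr:
            continue
        for c in tree.children[w]:
            out.append((w, c))
    return out


def apply_nni(tree: PlantedTree, move: tuple[int, int]) -> None:
    w, c = move
    pw = tree.parent[w]
    (s,) = [x for x in tree.children[pw] if x != w]
    tree.children[pw][tree.children[pw].index(s)] = c
    tree.children[w][tree.children[w].index(c)] = s
    tree.parent[s] = w
    tree.parent[c] = pw


def spr_moves(tree: PlantedTree) -> list[tuple[int, int]]:
    """All (prune vertex v, regraft edge child c2) pairs."""
    out = []
    pr = tree.planted_root
    for v in tree.vertices():
        pv = tree.parent[v]
        if pv in (-1, pr):
            continue
        sub = set()
        stack = [v]
        while stack:
            x = stack.pop()
            sub.add(x)
            stack.extend(tree.children[x])
        (s,) = [x for x in tree.children[pv] if x != v]
        for c2 in tree.vertices():
            if tree.parent[c2] == -1 or c2 in sub or c2 in (pv, s):
                continue
            out.append((v, c2))
    return out


def apply_spr(tree: PlantedTree, move: tuple[int, int]) -> None:
    v, c2 = move
    pv = tree.parent[v]
    gp = tree.parent[pv]
    (s,) = [x for x in tree.children[pv] if x != v]
    # detach pv, splice sibling up
    tree.children[gp][tree.children[gp].index(pv)] = s
    tree.parent[s] = gp
    # reinsert pv above c2
    g2 = tree.parent[c2]
    tree.children[g2][tree.children[g2].index(c2)] = pv
    tree.parent[pv] = g2
    tree.children[pv] = [v, c2]
    tree.parent[c2] = pv


# -- targets ----------------------------------------------------------------

def _log_prior(params: ModelParams, config: MCMCConfig) -> float:
    lp = 0.0
    for name in config.sample_params:
        a0, s0 = config.priors[name]
        x = getattr(params, name)
        if x <= 0:
            return -math.inf
        lp += (a0 - 1.0) * math.log(x) - x / s0 - math.lgamma(a0) - a0 * math.log(s0)
    return lp


def log_target(
    state: MCMCState,
    family: GeneFamily,
    sd: DiscretizedSpeciesTree,
    config: MCMCConfig | None = None,
) -> float:
    """log [ P(D|G,l) p(G,l|theta,S) p(theta) ] for a full state."""
    config = config or MCMCConfig()
    fam = GeneFamily(state.gene_tree, state.lengths, family.leaf_map, family.alignment)
    ll = _seq_loglik(fam, state.params)
    lg = _gen_loglik(fam, state.params, sd, config.condition_on_observation)
    return ll + lg + _log_prior(state.params, config)


def _seq_loglik(fam: GeneFamily, params: ModelParams) -> float:
    if not fam.alignment:
        return 0.0
    return felsenstein_loglik(
        fam.gene_tree, fam.lengths, fam.alignment, params.substitution()
    )


def _gen_loglik(
    fam: GeneFamily, params: ModelParams, sd: DiscretizedSpeciesTree,
    condition: bool = False,
) -> float:
    table = DPTable(DPContext(fam, sd), params, mode="sum")
    p = table.total()
    if p <= 0.0:
        return -math.inf
    lg = math.log(p)
    if condition:
        p_obs = 1.0 - table.bdt.prob_degenerate()
        lg -= math.log(p_obs) if p_obs > 0.0 else -math.inf
    return lg


# -- the sampler ------------------------------------------------------------

def run_mcmc(
    family: GeneFamily,
    species_tree: TimedSpeciesTree,
    config: MCMCConfig,
    seed: int,
    init_params: ModelParams | None = None,
) -> Trace:
    """MH sampling over (G, l, theta) for one gene family.

    ``family`` provides the data (alignment, leaf map) and the initial gene
    tree and lengths.  Requires at least 3 gene leaves unless the topology is
    fixed.
    """
    G0 = family.gene_tree
    if len(G0.leaves()) < 3 and not config.fix_topology:
        raise ValueError("topology sampling needs at least 3 gene leaves")
    rng = np.random.default_rng(seed)
    sd = discretize(species_tree, config.discretization_k)
    params = init_params or ModelParams(0.5, 0.5, 1.0, 0.5)
    state = MCMCState(copy_tree(G0), dict(family.lengths), params)

    override = config.target_override

    def full_target(st: MCMCState) -> tuple[float, float, float]:
        if override is not None:
            t = float(override(st))
            return t, t, 0.0
        fam = GeneFamily(st.gene_tree, st.lengths, family.leaf_map, family.alignment)
        ll = _seq_loglik(fam, st.params)
        lg = _gen_loglik(fam, st.params, sd, config.condition_on_observation)
        return ll + lg + _log_prior(st.params, config), ll, lg

    cur_target, cur_ll, cur_lg = full_target(state)
    if not math.isfinite(cur_target):
        raise ValueError("initial state has zero posterior density; choose another start")

    burn = int(config.iterations * config.burn_in_frac)
    samples: list[dict] = []
    accept: dict[str, list[int]] = {"topology": [], "length": [], "param": []}

    move_kinds = []
    if not config.fix_topology:
        move_kinds.append(("topology", config.p_topology))
    if not config.fix_lengths:
        move_kinds.append(("length", 1.0))
    if config.sample_params:
        move_kinds.append(("param", 1.0))
    if not move_kinds:
        raise ValueError("nothing to sample: all components fixed")
    kinds = [k for k, _ in move_kinds]
    wts = np.array([w for _, w in move_kinds])
    wts = wts / wts.sum()

    for it in range(config.iterations):
        kind = kinds[int(rng.choice(len(kinds), p=wts))]
        hastings = 0.0
        if kind == "topology":
            new_tree = copy_tree(state.gene_tree)
            use_spr = rng.random() < config.p_spr
            moves = spr_moves(new_tree) if use_spr else nni_moves(new_tree)
            if not moves:
                continue
            mv = moves[int(rng.integers(len(moves)))]
            n_fwd = len(moves)
            (apply_spr if use_spr else apply_nni)(new_tree, mv)
            n_rev = len(spr_moves(new_tree) if use_spr else nni_moves(new_tree))
            hastings = math.log(n_fwd) - math.log(n_rev)
            prop = MCMCState(new_tree, dict(state.lengths), state.params)
        elif kind == "length":
            e = int(rng.choice(state.gene_tree.edges()))
            mult = math.exp(config.length_sigma * rng.standard_normal())
            new_lengths = dict(state.lengths)
            new_lengths[e] = state.lengths[e] * mult
            hastings = math.log(mult)
            prop = MCMCState(state.gene_tree, new_lengths, state.params)
        else:
            name = config.sample_params[int(rng.integers(len(config.sample_params)))]
            x = getattr(state.params, name)
            mult = math.exp(config.param_sigma * rng.standard_normal())
            hastings = math.log(mult)
            prop = MCMCState(
                state.gene_tree, state.lengths, state.params.replace(**{name: x * mult})
            )
        prop_target, prop_ll, prop_lg = full_target(prop)
        ok = math.log(rng.random()) < (prop_target - cur_target) + hastings
        accept[kind if kind != "topology" else "topology"].append(int(ok))
        if ok:
            state, cur_target = prop, prop_target
        if it >= burn and (it - burn) % config.thin == 0:
            samples.append(
                {
                    "iteration": it,
                    "log_target": cur_target,
                    "lam": state.params.lam,
                    "mu": state.params.mu,
                    "rate_mean": state.params.rate_mean,
                    "rate_var": state.params.rate_var,
                    "newick": write_newick_planted(state.gene_tree, state.lengths),
                    "gene_tree": copy_tree(state.gene_tree),
                    "lengths": dict(state.lengths),
                }
            )
    return Trace(samples, config.iterations, burn, accept)


def run_mcmc_params(
    families: list[GeneFamily],
    species_tree: TimedSpeciesTree,
    config: MCMCConfig,
    seed: int,
    init_params: ModelParams | None = None,
) -> Trace:
    """Parameter-only MH with every family's (G, l) held fixed.

    Targets prod_i p(G_i, l_i | theta, S) * p(theta); sequence data drop out
    because (G, l) is conditioned on.  DP contexts are precomputed once per
    family and the birth-death / rate factor caches are reused whenever a
    proposal leaves (lambda, mu) or (m, v) untouched.
    """
    rng = np.random.default_rng(seed)
    sd = discretize(species_tree, config.discretization_k)
    params = init_params or ModelParams(0.5, 0.5, 1.0, 0.5)
    ctxs = [DPContext(f, sd) for f in families]

    def tables_and_target(p: ModelParams, prev: list[DPTable] | None):
        # birth-death tables and chain-factor caches are shared across families
        tabs, lp = [], _log_prior(p, config)
        shared_bdt, shared_chain = None, None
        for i, ctx in enumerate(ctxs):
            t = DPTable(
                ctx, p, mode="sum",
                reuse=None if prev is None else prev[i],
                bdt=shared_bdt, chain_cache=shared_chain,
            )
            shared_bdt, shared_chain = t.bdt, t._chain
            tabs.append(t)
            val = t.total()
            if val <= 0.0:
                return tabs, -math.inf
            lp += math.log(val)
        if config.condition_on_observation and shared_bdt is not None:
            p_obs = 1.0 - shared_bdt.prob_degenerate()
            if p_obs <= 0.0:
                return tabs, -math.inf
            lp -= len(ctxs) * math.log(p_obs)
        return tabs, lp

    cur_tabs, cur_target = tables_and_target(params, None)
    if not math.isfinite(cur_target):
        raise ValueError("initial parameters have zero density on this cohort")
    burn = int(config.iterations * config.burn_in_frac)
    samples: list[dict] = []
    accept: dict[str, list[int]] = {"param": []}
    for it in range(config.iterations):
        name = config.sample_params[int(rng.integers(len(config.sample_params)))]
        x = getattr(params, name)
        mult = math.exp(config.param_sigma * rng.standard_normal())
        prop = params.replace(**{name: x * mult})
        prop_tabs, prop_target = tables_and_target(prop, cur_tabs)
        ok = math.log(rng.random()) < (prop_target - cur_target) + math.log(mult)
        accept["param"].append(int(ok))
        if ok:
            params, cur_tabs, cur_target = prop, prop_tabs, prop_target
        if it >= burn and (it - burn) % config.thin == 0:
            samples.append(
                {
                    "iteration": it,
                    "log_target": cur_target,
                    "lam": params.lam,
                    "mu": params.mu,
                    "rate_mean": params.rate_mean,
                    "rate_var": params.rate_var,
                    "newick": "",
                }
            )
    return Trace(samples, config.iterations, burn, accept)
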