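"""Generative DLRS simulator: gene families evolving inside a species tree.

One gene lineage enters the species tree at the planted root.  Along every
species edge it experiences exponential waiting times at rate lambda + mu;
an event is a duplication (probability lambda/(lambda+mu)), which splits the
lineage in place, or a loss, which kills it.  At a speciation the lineage
splits into one copy per descendant edge.  Lineages reaching species leaves
become extant genes.  Pruning all all-loss subtrees yields the observed gene
tree; each pruned-tree edge then receives an iid Gamma(m, v) substitution
rate, its length is rate x time span, and sequences are simulated under the
substitution model.  The true (continuous-time) duplication events are
recorded and can be snapped to the nearest discretization vertex for
comparison with inferred d-realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams
from .rates import RateParams
from .substitution import SubstModel, simulate_alignment
from .trees import (
    DiscretizedSpeciesTree,
    GeneFamily,
    PlantedTree,
    TimedSpeciesTree,
)


@dataclass
class _RawVertex:
    kind: str            # 'start' | 'dup' | 'spec' | 'loss' | 'extant'
    time: float
    s_vertex: int | None      # species vertex (spec/extant) ...
    s_edge: int | None        # ... or species edge (dup/loss), by child S vertex
    children: list[int] = field(default_factory=list)


@dataclass
class SimulatedFamily:
    """A simulated gene family with its full generative ground truth."""

    family: GeneFamily | None          # pruned observable family (None if degenerate)
    species_tree: TimedSpeciesTree
    n_extant: int
    true_rates: dict[int, float]       # pruned-tree edge -> rate
    true_events: list[dict]            # per pruned internal vertex: kind/time/position
    n_raw_vertices: int
    degenerate: bool

    def true_drealization(self, sd: DiscretizedSpeciesTree) -> dict[int, int]:
        """Snap true event positions to nearest S' vertices (ties leafward)."""
        if self.family is None:
            raise ValueError("degenerate family has no realization")
        out: dict[int, int] = {}
        G = self.family.gene_tree
        out[G.planted_root] = sd.planted_root
        sig = self.family.sigma_map(sd.base.topology)
        events = {ev["vertex"]: ev for ev in self.true_events}
        # longest chain of same-edge duplications below each duplication: room
        # that must stay free under its snapped position
        chain_below: dict[int, int] = {}
        for u in G.postorder():
            if u in events and events[u]["kind"] == "dup":
                e = events[u]["s_edge"]
                chain_below[u] = max(
                    (
                        chain_below[c] + 1
                        for c in G.children[u]
                        if c in events
                        and events[c]["kind"] == "dup"
                        and events[c]["s_edge"] == e
                    ),
                    default=0,
                )
        for u in G.postorder()[::-1]:  # parents before children
            if u == G.planted_root:
                continue
            if G.is_leaf(u):
                out[u] = sd.of_species[sig[u]]
                continue
            ev = events[u]
            if ev["kind"] == "spec":
                out[u] = sd.of_species[ev["s_vertex"]]
                continue
            pts = sd.edge_points[ev["s_edge"]]  # leafward -> rootward
            parent_pos = out[G.parent[u]]
            hi = pts.index(parent_pos) if parent_pos in pts else len(pts)
            allowed = pts[chain_below[u]: hi]
            if not allowed:
                raise ValueError(
                    "discretization too coarse to host the true realization"
                )
            diffs = [abs(sd.time[p] - ev["time"]) for p in allowed]
            best = min(range(len(allowed)), key=lambda i: (diffs[i], sd.time[allowed[i]]))
            out[u] = allowed[best]
        return out


def simulate_family(
    species_tree: TimedSpeciesTree,
    params: ModelParams,
    seq_length: int = 100,
    seed: int | np.random.Generator = 0,
    with_sequences: bool = True,
) -> SimulatedFamily:
    """Simulate one gene family by the DLRS generative process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = species_tree.topology
    lam, mu = params.lam, params.mu
    raw: list[_RawVertex] = []

    def new(kind, time, s_vertex=None, s_edge=None) -> int:
        raw.append(_RawVertex(kind, time, s_vertex, s_edge))
        return len(raw) - 1

    def evolve_edge(parent_raw: int, s_child: int, t_now: float) -> None:
        """A lineage at time t_now on the species edge above s_child."""
        t_end = species_tree.time[s_child]
        rate = lam + mu
        while True:
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t_now - wait <= t_end:
                break
            t_now -= wait
            if rng.random() < (lam / rate if rate > 0 else 0.0):
                v = new("dup", t_now, s_edge=s_child)
                raw[parent_raw].children.append(v)
                evolve_edge(v, s_child, t_now)
                evolve_edge(v, s_child, t_now)
                return
            v = new("loss", t_now, s_edge=s_child)
            raw[parent_raw].children.append(v)
            return
        if not S.children[s_child]:
            v = new("extant", t_end, s_vertex=s_child)
            raw[parent_raw].children.append(v)
            return
        v = new("spec", t_end, s_vertex=s_child)
        raw[parent_raw].children.append(v)
        for c in S.children[s_child]:
            evolve_edge(v, c, t_end)

    start = new("start", species_tree.time[S.planted_root], s_vertex=S.planted_root)
    evolve_edge(start, S.root, species_tree.time[S.planted_root])

    # prune: keep vertices with extant descendants; suppress unary vertices
    alive = [False] * len(raw)
    for i in range(len(raw) - 1, -1, -1):
        v = raw[i]
        if v.kind == "extant":
            alive[i] = True
        else:
            alive[i] = any(alive[c] for c in v.children)

    extant = [i for i, v in enumerate(raw) if v.kind == "extant"]
    if len(extant) < 2:
        return SimulatedFamily(
            family=None, species_tree=species_tree, n_extant=len(extant),
            true_rates={}, true_events=[], n_raw_vertices=len(raw),
            degenerate=True,
        )

    # build pruned planted tree with event bookkeeping
    G = PlantedTree()
    g_planted = G.add_vertex()
    event_time: dict[int, float] = {g_planted: species_tree.time[S.planted_root]}
    events: list[dict] = []
    leaf_map: dict[int, int] = {}
    species_counter: dict[int, int] = {}

    def build(i: int, g_parent: int) -> None:
        v = raw[i]
        live = [c for c in v.children if alive[c]]
        if v.kind == "extant":
            sv = v.s_vertex
            species_counter[sv] = species_counter.get(sv, 0) + 1
            label = f"{S.label[sv]}_{species_counter[sv]}"
            g = G.add_vertex(parent=g_parent, label=label)
            event_time[g] = 0.0
            leaf_map[g] = sv
            return
        if len(live) >= 2:  # visible bifurcation (dup or speciation)
            g = G.add_vertex(parent=g_parent)
            event_time[g] = v.time
            events.append(
                {"vertex": g, "kind": "spec" if v.kind == "spec" else "dup",
                 "time": v.time, "s_vertex": v.s_vertex, "s_edge": v.s_edge}
            )
            for c in live:
                build(c, g)
        else:  # pass through invisible events
            build(live[0], g_parent)

    build(start, g_planted)
    G.validate()

    rates: dict[int, float] = {}
    lengths: dict[int, float] = {}
    rp: RateParams = params.rates
    for u in G.edges():
        span = event_time[G.parent[u]] - event_time[u]
        r = float(rng.gamma(rp.shape, rp.scale))
        while r <= 0.0:  # numerically zero draws are invalid lengths
            r = float(rng.gamma(rp.shape, rp.scale))
        rates[u] = r
        lengths[u] = max(r * span, 1e-12)

    alignment: dict[int, str] = {}
    if with_sequences:
        model = params.substitution()
        alignment = simulate_alignment(G, lengths, model, seq_length, rng)

    family = GeneFamily(G, lengths, leaf_map, alignment)
    return SimulatedFamily(
        family=family, species_tree=species_tree, n_extant=len(extant),
        true_rates=rates, true_events=events, n_raw_vertices=len(raw),
        degenerate=False,
    )


@dataclass
class CohortManifest:
    n_requested: int
    n_degenerate: int
    rows: list[dict]

    def to_tsv(self) -> str:
        header = "family\tn_leaves\tn_duplications\tseed\n"
        return header + "".join(
            f"{r['family']}\t{r['n_leaves']}\t{r['n_duplications']}\t{r['seed']}\n"
            for r in self.rows
        )


def simulate_cohort(
    species_tree: TimedSpeciesTree,
    params: ModelParams,
    n_families: int,
    seq_length: int = 100,
    seed: int = 0,
    with_sequences: bool = True,
    keep_degenerate: bool = False,
) -> tuple[list[SimulatedFamily], CohortManifest]:
    """n independent families; degenerate ones (< 2 extant genes) are dropped
    by default and counted in the manifest."""
    rng = np.random.default_rng(seed)
    out: list[SimulatedFamily] = []
    rows: list[dict] = []
    n_degenerate = 0
    produced = 0
    attempt = 0
    while produced < n_families and attempt < 50 * max(n_families, 1) + 50:
        attempt += 1
        fam_seed = int(rng.integers(0, 2**31 - 1))
        fam = simulate_family(
            species_tree, params, seq_length, np.random.default_rng(fam_seed),
            with_sequences=with_sequences,
        )
        if fam.degenerate:
            n_degenerate += 1
            if not keep_degenerate:
                continue
        out.append(fam)
        rows.append(
            {
                "family": f"fam{produced:04d}",
                "n_leaves": fam.n_extant,
                "n_duplications": sum(1 for e in fam.true_events if e["kind"] == "dup"),
                "seed": fam_seed,
            }
        )
        produced += 1
    return out, CohortManifest(n_families, n_degenerate, rows)
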