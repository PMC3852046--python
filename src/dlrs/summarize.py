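"""Duplication heatmaps over the species tree and MPR-distance summaries.

The heatmap estimates, per discretization vertex of S', the expected number
of duplications across gene families under the posterior over realizations:
each family's sampled realizations contribute their duplication placements
with weight 1/#samples, summed over families.  Counts are then binned into 11
levels (0..10) for display, either globally, globally minus a set of excluded
edges, or within each species edge independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import distance_avg, distance_max, mpr
from .realization import DRealization, Reconciliation
from .trees import DiscretizedSpeciesTree, GeneFamily, PlantedTree


def accumulate_duplications(
    samples_per_family: list[list[DRealization]],
    sd: DiscretizedSpeciesTree,
) -> dict[int, float]:
    """Expected duplication counts per S' vertex, summed over families."""
    counts: dict[int, float] = {v: 0.0 for v in range(sd.n_vertices)}
    for realizations in samples_per_family:
        if not realizations:
            continue
        w = 1.0 / len(realizations)
        for alpha in realizations:
            for _, v in alpha.mapping:
                if v >= sd.n_vertices:
                    raise ValueError("realization refers to a different S'")
                if not sd.is_species(v):
                    counts[v] += w
    return counts


def normalize_heatmap(
    counts: dict[int, float],
    sd: DiscretizedSpeciesTree,
    mode: str = "global",
    excluded_edges: set[int] | None = None,
) -> dict[int, int]:
    """Bin duplication counts into 11 equal-width levels (max -> 10, 0 -> 0).

    ``mode``: 'global', 'global-excluding' (drop ``excluded_edges``, re-bin the
    rest) or 'per-edge' (normalize within each species edge; a constant
    positive edge maps to level 10).  Returns levels for interior S' vertices
    in the normalization domain.
    """
    if mode not in ("global", "global-excluding", "per-edge"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    excluded = excluded_edges or set()

    def bin_levels(vs: list[int]) -> dict[int, int]:
        mx = max((counts.get(v, 0.0) for v in vs), default=0.0)
        if mx <= 0.0:
            return {v: 0 for v in vs}
        return {
            v: min(10, int(np.floor(counts.get(v, 0.0) / mx * 11.0)))
            for v in vs
        }

    if mode == "per-edge":
        out: dict[int, int] = {}
        for edge, pts in sd.edge_points.items():
            if edge in excluded:
                continue
            vals = [counts.get(v, 0.0) for v in pts]
            if len(set(vals)) == 1:  # degenerate constant edge
                lvl = 10 if vals[0] > 0 else 0
                out.update({v: lvl for v in pts})
            else:
                out.update(bin_levels(pts))
        return out
    domain = [
        v for edge, pts in sd.edge_points.items() if edge not in excluded
        for v in pts
    ]
    if mode == "global" and excluded:
        raise ValueError("use mode='global-excluding' to exclude edges")
    return bin_levels(domain)


def heatmap_table(
    counts: dict[int, float], levels: dict[int, int], sd: DiscretizedSpeciesTree
) -> pd.DataFrame:
    S = sd.base.topology
    rows = []
    for edge, pts in sd.edge_points.items():
        for i, v in enumerate(pts):
            if v not in levels:
                continue
            rows.append(
                {
                    "edge": f"({S.leafset_id(edge)})",
                    "point": i,
                    "age": sd.time[v],
                    "count": counts.get(v, 0.0),
                    "level": levels[v],
                }
            )
    return pd.DataFrame(rows)


def heatmap_newick(levels: dict[int, int], sd: DiscretizedSpeciesTree) -> str:
    """Species tree Newick with per-edge level strings as comments."""
    S = sd.base.topology

    def fmt(v: int) -> str:
        if S.is_leaf(v):
            s = S.label[v]
        else:
            s = "(" + ",".join(fmt(c) for c in S.children[v]) + ")"
        span = sd.base.time[S.parent[v]] - sd.base.time[v]
        lv = ",".join(str(levels.get(p, "")) for p in sd.edge_points[v])
        return f"{s}:{span:.10g}[&levels={lv}]"

    return fmt(S.root) + ";"


@dataclass
class FamilySamples:
    """Posterior reconciliation samples for one family.

    Each entry pairs a sampled gene family (its topology may vary across MCMC
    samples) with the sampled reconciliation; the MPR is recomputed per entry
    against its own gene tree.
    """

    name: str
    entries: list[tuple[GeneFamily, Reconciliation]]


def mpr_summary(
    cohort: list[FamilySamples], species_tree: PlantedTree
) -> pd.DataFrame:
    """Per-family expected avg/max distance to MPR and MPR-identity fractions.

    The cohort-level fraction of all samples differing from MPR is attached
    as DataFrame attrs ('fraction_differing', 'n_samples').
    """
    rows = []
    total, identical = 0, 0
    for famsam in cohort:
        if not famsam.entries:
            continue
        avg_d, max_d, same = [], [], 0
        for fam, gamma in famsam.entries:
            m = mpr(fam, species_tree)
            avg_d.append(distance_avg(species_tree, fam.gene_tree, gamma, m.reconciliation))
            max_d.append(distance_max(species_tree, gamma, m.reconciliation))
            if gamma == m.reconciliation:
                same += 1
        n = len(famsam.entries)
        total += n
        identical += same
        rows.append(
            {
                "family": famsam.name,
                "n_samples": n,
                "expected_avg_distance": float(np.mean(avg_d)),
                "expected_max_distance": float(np.mean(max_d)),
                "fraction_identical_mpr": same / n,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_samples"] = total
    df.attrs["fraction_differing"] = (1.0 - identical / total) if total else 0.0
    return df


def map_reconciliation_estimates(
    family: GeneFamily,
    params,
    sd: DiscretizedSpeciesTree,
    n_samples: int = 1000,
    seed: int = 0,
):
    """Two MAP-reconciliation estimators, clearly labeled.

    'most_frequent': the modal projected reconciliation over sampled
    d-realizations (maximizes the summed realization posterior, approximately);
    'map_projection': the projection of the single MAP d-realization.  The two
    can differ because a reconciliation aggregates many realizations.
    """
    from .dp import compute_s_table
    from .realization import (  # local import to avoid a module cycle
        compute_m_table,
        map_drealization,
        sample_drealization,
    )

    table = compute_s_table(family, params, sd)
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(n_samples):
        g = sample_drealization(table, rng).project(sd)
        counts[g] = counts.get(g, 0) + 1
    modal = max(counts, key=counts.get)
    alpha, _ = map_drealization(compute_m_table(family, params, sd))
    return {
        "most_frequent": modal,
        "most_frequent_support": counts[modal] / n_samples,
        "map_projection": alpha.project(sd),
    }


def plot_heatmap(levels: dict[int, int], sd: DiscretizedSpeciesTree, path: str) -> None:
    """Optional thin rendering layer (11-color per-edge strips)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    S = sd.base.topology
    leaves = S.leaves()
    ypos = {v: i for i, v in enumerate(leaves)}
    for v in S.postorder():
        if v not in ypos:
            kids = S.children[v]
            ypos[v] = float(np.mean([ypos[c] for c in kids])) if kids else 0.0
    cmap = plt.get_cmap("inferno", 11)
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(leaves) + 2))
    for edge, pts in sd.edge_points.items():
        y = ypos[edge]
        p = S.parent[edge]
        ax.plot([sd.base.time[p], sd.base.time[edge]], [ypos[p], y], c="0.8", lw=1, zorder=0)
        for v in pts:
            if v in levels:
                ax.scatter(sd.time[v], y, c=[cmap(levels[v])], s=60, zorder=2)
    for leaf in leaves:
        ax.text(-0.02 * sd.base.time[S.planted_root], ypos[leaf], S.label[leaf],
                ha="right", va="center")
    ax.set_xlabel("age before present")
    ax.invert_xaxis()
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
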