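"""Planted trees, timed species trees, discretization and the sigma (LCA) map.

All trees in this package are *planted* binary trees: a rooted binary tree
augmented with a degree-1 planted root above the root, so that the root itself
has an incoming edge.  Vertices are small integers; every edge is identified by
its child vertex.  Species-tree vertices carry divergence times ("age before
present": leaves at 0, strictly increasing towards the planted root).  The
discretized species tree S' augments every edge of S (including the planted
edge) with k equidistant interior vertices; these interior vertices are the
only places where duplications can be realized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy


class TreeFormatError(ValueError):
    """Raised for malformed Newick input (non-binary vertices, duplicate labels)."""


class MappingError(ValueError):
    """Raised when a gene leaf cannot be mapped to a species leaf."""


class PlantedTree:
    """Rooted binary tree with a planted root (a single-child top vertex).

    Vertices are integers ``0..n-1``.  ``parent[v]`` is the parent of ``v``
    (``-1`` for the planted root), ``children[v]`` the ordered children list
    (two for internal vertices, one for the planted root, none for leaves).
    """

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.children: list[list[int]] = []
        self.label: dict[int, str] = {}

    # -- construction -----------------------------------------------------
    def add_vertex(self, parent: int | None = None, label: str | None = None) -> int:
        v = len(self.parent)
        self.parent.append(-1 if parent is None else parent)
        self.children.append([])
        if parent is not None:
            self.children[parent].append(v)
        if label is not None:
            self.label[v] = label
        return v

    # -- structure queries ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def planted_root(self) -> int:
        for v in range(self.n_vertices):
            if self.parent[v] == -1:
                return v
        raise ValueError("tree has no planted root")

    @property
    def root(self) -> int:
        """The true root: the single child of the planted root."""
        return self.children[self.planted_root][0]

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_vertices) if self.is_leaf(v)]

    def vertices(self) -> list[int]:
        return list(range(self.n_vertices))

    def edges(self) -> list[int]:
        """Edges identified by their child vertex (includes the planted edge)."""
        return [v for v in range(self.n_vertices) if self.parent[v] != -1]

    def postorder(self) -> list[int]:
        out: list[int] = []
        stack = [self.planted_root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        out.reverse()
        return out

    def subtree_leaves(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            w = stack.pop()
            if self.is_leaf(w):
                out.append(w)
            else:
                stack.extend(self.children[w])
        return out

    def depth(self, v: int) -> int:
        d = 0
        while self.parent[v] != -1:
            v = self.parent[v]
            d += 1
        return d

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is an ancestor of or equal to ``b``."""
        while b != -1:
            if a == b:
                return True
            b = self.parent[b]
        return False

    def lca(self, a: int, b: int) -> int:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a, da = self.parent[a], da - 1
        while db > da:
            b, db = self.parent[b], db - 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def leafset_id(self, v: int) -> str:
        """Stable vertex name: sorted leaf labels of the subtree, comma-joined."""
        return ",".join(sorted(self.label[w] for w in self.subtree_leaves(v)))

    def validate(self) -> None:
        pr = self.planted_root
        if len(self.children[pr]) != 1:
            raise TreeFormatError("planted root must have exactly one child")
        for v in range(self.n_vertices):
            if v == pr:
                continue
            nc = len(self.children[v])
            if nc not in (0, 2):
                raise TreeFormatError(
                    f"vertex {self.label.get(v, v)!r} has {nc} children; "
                    "trees must be binary"
                )
        labels = [self.label[v] for v in self.leaves()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeFormatError(f"duplicate leaf labels: {sorted(dupes)}")


def read_newick_planted(
    text: str, branch_attr: bool = True
) -> tuple[PlantedTree, dict[int, float]]:
    """Parse a binary Newick string and plant it.

    A planted root is added above the Newick root.  Returns the tree and a
    dict of branch lengths keyed by child vertex (the Newick root's own
    branch length, if present, becomes the planted edge's length).  Branch
    lengths default to 0.0 when absent.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy's reader errors (incl. duplicate taxa)
        raise TreeFormatError(f"malformed Newick: {exc}") from exc
    seed = dtree.seed_node
    # Collapse a top-level unifurcation around an internal child: "((A,B):1);"
    # denotes the rooted tree (A,B) with a stem of length 1 (the planted edge).
    if len(seed.child_nodes()) == 1 and seed.child_nodes()[0].child_nodes():
        seed = seed.child_nodes()[0]
    tree = PlantedTree()
    planted = tree.add_vertex()
    lengths: dict[int, float] = {}

    def build(node, parent: int) -> None:
        label = None
        if not node.child_nodes():
            if node.taxon is not None:
                label = node.taxon.label
            elif node.label:
                label = node.label
            if label is None:
                raise TreeFormatError("unlabeled leaf in Newick input")
        v = tree.add_vertex(parent=parent, label=label)
        lengths[v] = float(node.edge.length) if node.edge.length is not None else 0.0
        for ch in node.child_nodes():
            build(ch, v)

    build(seed, planted)
    tree.validate()
    return tree, lengths


def write_newick_planted(tree: PlantedTree, lengths: dict[int, float] | None = None) -> str:
    """Serialize the tree below the planted root as Newick.

    The planted edge's length, if given, is written as the root's branch length.
    """

    def fmt(v: int) -> str:
        if tree.is_leaf(v):
            s = tree.label[v]
        else:
            s = "(" + ",".join(fmt(c) for c in tree.children[v]) + ")"
        if lengths is not None and v in lengths:
            s += f":{lengths[v]:.10g}"
        return s

    return fmt(tree.root) + ";"


@dataclass
class TimedSpeciesTree:
    """A planted binary species tree with divergence times (ages; leaves at 0)."""

    topology: PlantedTree
    time: dict[int, float]

    def __post_init__(self) -> None:
        t = self.topology
        for leaf in t.leaves():
            if abs(self.time[leaf]) > 1e-12:
                raise ValueError("species tree must be ultrametric: leaves at age 0")
        for v in t.edges():
            if self.time[t.parent[v]] <= self.time[v]:
                raise ValueError("vertex times must strictly increase towards the root")

    @classmethod
    def from_newick(cls, text: str, planted_stem: float | None = None) -> "TimedSpeciesTree":
        """Read a species tree whose branch lengths are time spans.

        Ages are reconstructed bottom-up from the spans.  The planted root's age
        is root age + the Newick root's branch length if one was given, else
        root age + ``planted_stem`` (default: the root age itself, doubling it).
        """
        tree, spans = read_newick_planted(text)
        time: dict[int, float] = {}

        # leaf ages 0; internal age = child age + child span (take first child;
        # ultrametry is validated afterwards)
        def age(v: int) -> float:
            if v in time:
                return time[v]
            if tree.is_leaf(v):
                time[v] = 0.0
            else:
                c = tree.children[v][0]
                time[v] = age(c) + spans.get(c, 0.0)
            return time[v]

        for v in tree.vertices():
            age(v)
        root = tree.root
        for leaf in tree.leaves():
            # recompute each leaf's implied root age to catch non-ultrametric input
            acc, v = 0.0, leaf
            while v != root:
                acc += spans.get(v, 0.0)
                v = tree.parent[v]
            if abs(acc - time[root]) > 1e-6 * max(1.0, time[root]):
                raise ValueError("species tree branch lengths are not ultrametric")
        stem = spans.get(root, 0.0)
        if stem <= 0:
            stem = planted_stem if planted_stem is not None else max(time[root], 1.0)
        time[tree.planted_root] = time[root] + stem
        return cls(tree, time)

    def to_newick(self) -> str:
        t = self.topology
        spans = {v: self.time[t.parent[v]] - self.time[v] for v in t.edges()}
        return write_newick_planted(t, spans)


class DiscretizedSpeciesTree:
    """The species tree S' with k equidistant interior vertices per edge.

    S'-vertices are integers; species vertices keep a reference to their S
    vertex, interior vertices to the S edge (keyed by its child S-vertex)
    they subdivide.  ``R`` maps species vertices to themselves and species
    edges to their interior vertex lists (ordered leafward to rootward).
    """

    def __init__(self, base: TimedSpeciesTree, k: int) -> None:
        if k < 1:
            raise ValueError("discretization requires k >= 1 interior points per edge")
        self.base = base
        self.k = k
        S = base.topology
        n = 0
        self.time: list[float] = []
        self.parent: list[int] = []
        self.children: list[list[int]] = []
        self.species_vertex: list[int | None] = []   # S vertex id, or None
        self.edge_child: list[int | None] = []       # S edge (child S-vertex), or None
        self.of_species: dict[int, int] = {}         # S vertex -> S' vertex
        self.edge_points: dict[int, list[int]] = {}  # S edge -> interior S' ids

        def new_vertex(time: float, sv: int | None, ec: int | None, parent: int | None) -> int:
            nonlocal n
            v = n
            n += 1
            self.time.append(time)
            self.parent.append(-1 if parent is None else parent)
            self.children.append([])
            if parent is not None:
                self.children[parent].append(v)
            self.species_vertex.append(sv)
            self.edge_child.append(ec)
            return v

        def build(sv: int, parent_prime: int | None) -> int:
            v = new_vertex(base.time[sv], sv, None, parent_prime)
            self.of_species[sv] = v
            for c in S.children[sv]:
                top, bot = base.time[sv], base.time[c]
                prev = v
                pts: list[int] = []
                for i in range(1, k + 1):
                    t = top - (top - bot) * i / (k + 1)
                    prev = new_vertex(t, None, c, prev)
                    pts.append(prev)
                self.edge_points[c] = list(reversed(pts))  # leafward -> rootward
                build(c, prev)
            return v

        build(S.planted_root, None)
        self.n_vertices = n
        # slice width owned by each interior vertex of an edge
        self.slice: list[float] = [0.0] * n
        for c, pts in self.edge_points.items():
            dur = base.time[S.parent[c]] - base.time[c]
            for p in pts:
                self.slice[p] = dur / (k + 1)

    # -- queries -----------------------------------------------------------
    def is_species(self, v: int) -> bool:
        return self.species_vertex[v] is not None

    def is_speciation(self, v: int) -> bool:
        """Internal species vertex of S (two children); excludes planted root."""
        sv = self.species_vertex[v]
        if sv is None:
            return False
        S = self.base.topology
        return len(S.children[sv]) == 2

    @property
    def planted_root(self) -> int:
        return self.of_species[self.base.topology.planted_root]

    def ancestors_path(self, v: int) -> list[int]:
        """S' vertices from ``v`` (inclusive) up to the planted root."""
        out = [v]
        while self.parent[out[-1]] != -1:
            out.append(self.parent[out[-1]])
        return out

    def R(self, obj: tuple[str, int]) -> list[int]:
        """R-map: ('vertex', s) -> [its S' id]; ('edge', child_s) -> interior ids."""
        kind, ident = obj
        if kind == "vertex":
            return [self.of_species[ident]]
        if kind == "edge":
            return list(self.edge_points[ident])
        raise ValueError(f"unknown species-tree object kind {kind!r}")

    def project(self, v: int) -> tuple[str, int]:
        """R-preimage of an S' vertex: the species vertex or species edge."""
        sv = self.species_vertex[v]
        if sv is not None:
            return ("vertex", sv)
        return ("edge", self.edge_child[v])

    def t(self, x: int, y: int) -> float:
        """Time span between S' vertices (x a proper ancestor of y)."""
        return self.time[x] - self.time[y]


def discretize(species_tree: TimedSpeciesTree, k: int) -> DiscretizedSpeciesTree:
    """Augment every edge of S (planted edge included) with k equidistant points."""
    return DiscretizedSpeciesTree(species_tree, k)


def sigma(
    gene_tree: PlantedTree, species_tree: PlantedTree, leaf_map: dict[int, int]
) -> dict[int, int]:
    """The LCA map: sigma(u) = LCA in S of the species hosting the genes of G_u.

    ``leaf_map`` maps gene-leaf vertices to species-leaf vertices.  The map is
    extended bottom-up; the planted root of G maps to the planted root of S.
    """
    sig: dict[int, int] = {}
    for u in gene_tree.postorder():
        if gene_tree.is_leaf(u):
            if u not in leaf_map:
                raise MappingError(
                    f"gene leaf {gene_tree.label.get(u, u)!r} has no species mapping"
                )
            sig[u] = leaf_map[u]
        elif u == gene_tree.planted_root:
            sig[u] = species_tree.planted_root
        else:
            c1, c2 = gene_tree.children[u]
            sig[u] = species_tree.lca(sig[c1], sig[c2])
    return sig


@dataclass
class GeneFamily:
    """A gene family: planted gene tree, edge lengths, leaf map and alignment.

    ``lengths`` are expected substitutions per site, keyed by child vertex
    (the planted edge included).  ``leaf_map`` maps gene leaves to species
    leaves of ``species_tree``.  ``alignment`` maps gene leaves to equal-length
    amino-acid strings (may be empty for sequence-free analyses).
    """

    gene_tree: PlantedTree
    lengths: dict[int, float]
    leaf_map: dict[int, int]
    alignment: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.gene_tree.edges():
            if v not in self.lengths:
                raise ValueError("every gene-tree edge (planted edge included) needs a length")
            if self.lengths[v] <= 0:
                raise ValueError("gene-tree edge lengths must be positive")
        if self.alignment:
            if set(self.alignment) != set(self.gene_tree.leaves()):
                raise ValueError("alignment keys must equal the gene-tree leaves")
            lens = {len(s) for s in self.alignment.values()}
            if len(lens) != 1:
                raise ValueError("alignment sequences must have equal length")
            if lens == {0}:
                raise ValueError("alignment has zero columns")

    def sigma_map(self, species_tree: PlantedTree) -> dict[int, int]:
        return sigma(self.gene_tree, species_tree, self.leaf_map)


# -- flat-file I/O ---------------------------------------------------------

def read_leaf_map(text: str) -> dict[str, str]:
    """Parse a two-column 'gene species' whitespace table; '#' starts a comment."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(io.StringIO(text), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MappingError(f"line {ln}: expected 'gene species', got {raw!r}")
        out[parts[0]] = parts[1]
    return out


def resolve_leaf_map(
    gene_tree: PlantedTree, species_tree: PlantedTree, names: dict[str, str]
) -> dict[int, int]:
    """Turn a name-level gene->species map into a vertex-level map."""
    sp_by_label = {species_tree.label[v]: v for v in species_tree.leaves()}
    out: dict[int, int] = {}
    for u in gene_tree.leaves():
        g = gene_tree.label[u]
        if g not in names:
            raise MappingError(f"gene leaf {g!r} missing from the mapping file")
        s = names[g]
        if s not in sp_by_label:
            raise MappingError(f"species {s!r} (for gene {g!r}) not in the species tree")
        out[u] = sp_by_label[s]
    return out


def read_fasta(text: str) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    }


def write_fasta(seqs: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in seqs.items())
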