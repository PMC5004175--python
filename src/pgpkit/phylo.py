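"""Distance-based protein phylogenetics.

Pipeline: gapped multiple alignment -> proportion of differing sites (p)
-> Poisson-corrected distance d = -ln(1 - p) -> Saitou-Nei neighbor joining
-> optional bootstrap support from column resampling -> Newick.

The Poisson correction converts an observed fraction of differing residues
into an expected number of substitutions per site under a model in which
substitutions hit sites as a Poisson process and every hit changes the
residue; it saturates (is undefined) at p = 1.

Neighbor joining here follows the standard Q-criterion formulation:
Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k), joining the pair
with minimal Q each round; limb lengths come from the usual closed forms,
and negative limbs are clamped to zero with the deficit moved to the sister
limb so path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = set("-.")


class PhyloError(ValueError):
    pass


class SaturationError(PhyloError):
    """p-distance reached 1: Poisson correction diverges."""


@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped protein alignment: unique taxa, equal-length rows."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 3:
            raise PhyloError("need at least 3 taxa")
        if len(self.taxa) != len(self.rows):
            raise PhyloError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise PhyloError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise PhyloError("alignment rows differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        """Bootstrap replicate: sample columns with replacement."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = tuple("".join(r[i] for i in idx) for r in self.rows)
        return MultipleAlignment(self.taxa, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise PhyloError("non-finite distances")
        if not np.allclose(d, d.T):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise PhyloError("nonzero diagonal")
        if np.any(d < 0):
            raise PhyloError("negative distances")
        object.__setattr__(self, "d", d)


@dataclass
class TreeNode:
    """Node of an (implicitly unrooted) tree; the root is the final
    trifurcation left by neighbor joining."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # on the edge above this node

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaf_names())

    # -- bipartitions -------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side *not*
        containing the alphabetically first taxon."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def _edges(self):
        """Yield (parent, child, length) over all edges."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                yield node, child, length
                stack.append(child)

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along tree branches."""
        adj: dict[int, list[tuple[int, float]]] = {}
        labels_at: dict[int, str] = {}
        for parent, child, length in self._edges():
            adj.setdefault(id(parent), []).append((id(child), length))
            adj.setdefault(id(child), []).append((id(parent), length))
            if child.is_leaf():
                labels_at[id(child)] = child.label
        if self.root.is_leaf():  # degenerate single-leaf tree
            labels_at[id(self.root)] = self.root.label
        labels = sorted(labels_at.values())
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        for node_id, lab in labels_at.items():
            # Dijkstra is overkill on a tree: DFS accumulating distance
            seen = {node_id}
            stack = [(node_id, 0.0)]
            while stack:
                cur, dist = stack.pop()
                if cur in labels_at and cur != node_id:
                    d[index[lab], index[labels_at[cur]]] = dist
                for nxt, w in adj.get(cur, []):
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append((nxt, dist + w))
        return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# distances

def p_distance(row_i: str, row_j: str,
               gap_mode: str = "pairwise-deletion",
               mask: np.ndarray | None = None) -> float:
    """Proportion of differing residues among comparable columns.

    ``pairwise-deletion`` drops columns gapped in either of the two rows;
    ``complete-deletion`` requires a precomputed ``mask`` of alignment-wide
    ungapped columns (supplied by :func:`build_distance_matrix`).
    """
    if len(row_i) != len(row_j):
        raise PhyloError("rows differ in length")
    comparable = diffs = 0
    for k, (a, b) in enumerate(zip(row_i, row_j)):
        if mask is not None and not mask[k]:
            continue
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        diffs += a != b
    if comparable == 0:
        raise PhyloError("no comparable (ungapped) columns between rows")
    return diffs / comparable


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p); requires 0 <= p < 1."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p-distance {p} outside [0, 1): saturated")
    return -float(np.log1p(-p))


def build_distance_matrix(aln: MultipleAlignment,
                          gap_mode: str = "pairwise-deletion") -> DistanceMatrix:
    """Poisson-corrected distances between all alignment rows."""
    if gap_mode not in ("pairwise-deletion", "complete-deletion"):
        raise PhyloError(f"unknown gap mode {gap_mode!r}")
    mask = None
    if gap_mode == "complete-deletion":
        mask = np.array([all(r[k] not in GAP_CHARS for r in aln.rows)
                         for k in range(aln.n_sites)])
        if not mask.any():
            raise PhyloError("complete deletion removed every column")
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.rows[i], aln.rows[j], gap_mode, mask)
            try:
                d[i, j] = d[j, i] = poisson_correct(p)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}"
                ) from exc
    return DistanceMatrix(tuple(aln.taxa), d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the label-sorted (i, j) index pair so the
    topology is reproducible. Negative limb lengths are clamped to zero and
    the deficit transferred to the sister limb (path lengths through the new
    node are preserved).
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("need at least 3 taxa")
    order = np.argsort(np.array(dm.labels))
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]
    limb_above: dict[int, float] = {}

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    node_of: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)  # index order is creation order = label order
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, pushing the deficit onto the sister limb
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(node_of[i], li), (node_of[j], lj)])
        u = next_id
        next_id += 1
        node_of[u] = new
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        dist[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    root = TreeNode(children=[(node_of[i], max(li, 0.0)),
                              (node_of[j], max(lj, 0.0)),
                              (node_of[k], max(lk, 0.0))])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    tree: PhyloTree
    n_replicates: int
    n_completed: int
    n_saturated: int


def bootstrap_support(aln: MultipleAlignment, b: int, seed: int,
                      gap_mode: str = "pairwise-deletion") -> BootstrapResult:
    """Column-resampling bootstrap support for the NJ tree of ``aln``.

    Support of an internal edge is the fraction of completed replicates whose
    NJ tree contains the same leaf bipartition. Replicates in which some pair
    saturates (p = 1) are dropped and counted; the denominator is the number
    of completed replicates.
    """
    if b < 1:
        raise PhyloError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(build_distance_matrix(aln, gap_mode))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    completed = saturated = 0
    for _ in range(b):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(build_distance_matrix(rep, gap_mode))
        except SaturationError:
            saturated += 1
            continue
        completed += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            counts[bp] += bp in rep_bps

    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)

    def annotate(node: TreeNode, below_root: bool) -> frozenset:
        if node.is_leaf():
            node.support = 1.0  # trivial bipartition
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c, False) for c, _ in node.children))
        if not below_root and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = counts[side] / completed if completed else float("nan")
        return below

    annotate(tree.root, True)
    return BootstrapResult(tree=tree, n_replicates=b,
                           n_completed=completed, n_saturated=saturated)


# ---------------------------------------------------------------------------
# Newick

def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}:;,'\" \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, *, support_as: str = "fraction") -> str:
    """Serialize with branch lengths; internal-node labels carry support
    (as a fraction, or percent when ``support_as='percent'``)."""
    if tree is None or tree.root is None:
        raise PhyloError("empty tree")

    def fmt_support(s: float | None) -> str:
        if s is None:
            return ""
        if support_as == "percent":
            return str(int(round(100 * s)))
        return format(s, "g")

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            return _quote(node.label)
        inner = ",".join(f"{render(c)}:{length:.10g}"
                         for c, length in node.children)
        return f"({inner}){fmt_support(node.support)}"

    return render(tree.root) + ";"


def read_alignment_fasta(path) -> MultipleAlignment:
    from Bio import SeqIO
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(tuple(taxa), tuple(rows))
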