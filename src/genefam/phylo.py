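"""Distance-based protein phylogeny with bootstrap support.

Progressive multiple alignment (delegated to biotite's BLOSUM62
progressive aligner), p-distance / Poisson-corrected distances with
pairwise gap deletion, Saitou–Nei neighbor joining with deterministic
tie-breaking, nonparametric bootstrap of alignment columns, and
support-threshold subfamily assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import biotite.sequence as bseq
import biotite.sequence.align as balign


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            len(self.rows), self.n_columns)

    def take_columns(self, cols: np.ndarray) -> "MultipleAlignment":
        arr = self.to_array()[:, cols]
        return MultipleAlignment(
            self.ids, [row.tobytes().decode() for row in arr])


def msa_proteins(seqs: dict[str, str]) -> MultipleAlignment:
    """Progressive multiple alignment of protein sequences (BLOSUM62)."""
    if not seqs:
        raise ValueError("no sequences to align")
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    cleaned = [seqs[i].upper().rstrip("*") for i in ids]
    bios = [bseq.ProteinSequence(s) for s in cleaned]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alignment, *_ = balign.align_multiple(bios, matrix, gap_penalty=(-10, -1))
    return MultipleAlignment(ids, alignment.get_gapped_sequences())


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal; np.inf marks saturation

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m


def _pair_masks(msa: MultipleAlignment):
    """Per-pair (valid-column, mismatch) boolean masks for fast resampling."""
    arr = msa.to_array()
    gap = arr == b"-"
    n = len(msa.ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), msa.n_columns), dtype=bool)
    diff = np.empty_like(valid)
    for k, (i, j) in enumerate(pairs):
        valid[k] = ~gap[i] & ~gap[j]
        diff[k] = valid[k] & (arr[i] != arr[j])
    return pairs, valid, diff


def _distances_from_masks(pairs, valid, diff, n, model, cols=None):
    if cols is not None:
        valid, diff = valid[:, cols], diff[:, cols]
    shared = valid.sum(axis=1)
    mism = diff.sum(axis=1)
    if np.any(shared == 0):
        raise ValueError("a sequence pair shares no ungapped columns")
    p = mism / shared
    if model == "p":
        d = p
    elif model == "poisson":
        with np.errstate(divide="ignore"):
            d = np.where(p < 1.0, -np.log(np.clip(1.0 - p, 1e-300, None)), np.inf)
            d = np.where(p >= 1.0, np.inf, d)
    else:
        raise ValueError(f"unknown distance model {model!r}")
    m = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        m[i, j] = m[j, i] = d[k]
    return m


def protein_distance(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    p-distance is mismatches / shared ungapped columns; the Poisson
    correction is d = -ln(1 - p), with p -> 1 flagged as saturated
    (infinite distance).
    """
    pairs, valid, diff = _pair_masks(msa)
    m = _distances_from_masks(pairs, valid, diff, len(msa.ids), model)
    return DistanceMatrix(msa.ids, m)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Rooted representation of the (unrooted) NJ tree; the top node is a
    trifurcation for n >= 3 taxa."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.17g}"
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if with_support and node.support is not None and not top:
                label = str(node.support)
            suffix = "" if top else f":{node.length:.17g}"
            return f"({inner}){label}{suffix}"

        return fmt(self, True) + ";"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Q-criterion agglomeration with ties broken toward the lowest taxon
    index pair; negative branch lengths are clamped to zero with the
    deficit transferred to the sibling edge.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("saturated (infinite) distances cannot be joined")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first occurrence: lowest pair
        ai, aj = sorted((best[0], best[1]))
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for a in active:
            if a in (i, j):
                continue
            d[k, a] = d[a, k] = 0.5 * (d[i, a] + d[j, a] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def tree_splits(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Nontrivial bipartitions of the unrooted tree, canonicalized.

    Each internal edge is keyed by the smaller side of its split (ties
    broken lexicographically) so rootings compare equal.
    """
    all_leaves = tree.leaf_names()
    splits: dict[frozenset, TreeNode] = {}
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits[key] = node
    return splits


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances through the tree."""
    ids = sorted(tree.leaf_names())
    index = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    m = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {index[node.name]: 0.0}
        below: dict[int, float] = {}
        for child in node.children:
            sub = {k: v + child.length for k, v in walk(child).items()}
            for a, da in sub.items():
                for b, db in below.items():
                    m[a, b] = m[b, a] = da + db
            below.update(sub)
        return below

    walk(tree)
    return DistanceMatrix(ids, m)


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree on the full alignment, with bootstrap supports.

    Columns are resampled with replacement n_reps times; the support of
    each internal edge is the percentage of replicate trees containing
    the same bipartition.  n_reps = 0 leaves supports at 0.
    """
    pairs, valid, diff = _pair_masks(msa)
    n = len(msa.ids)
    full = DistanceMatrix(
        msa.ids, _distances_from_masks(pairs, valid, diff, n, model))
    tree = nj_tree(full)
    splits = tree_splits(tree)
    counts = {key: 0 for key in splits}
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        try:
            dm = DistanceMatrix(
                msa.ids, _distances_from_masks(pairs, valid, diff, n, model, cols))
            rep = nj_tree(dm)
        except ValueError:
            continue
        rep_splits = tree_splits(rep)
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = round(100.0 * counts[key] / n_reps) if n_reps else 0
    return tree


def assign_subfamilies(tree: TreeNode, support_threshold: int = 50) -> dict[str, str]:
    """Label leaves by maximal well-supported clades.

    Clades whose subtending edge support exceeds the threshold (and with
    at least 2 leaves) become groups I, II, ...; all remaining leaves
    are labeled 'ungrouped'.
    """
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
              "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII"]
    labels = {leaf.name: "ungrouped" for leaf in tree.leaves()}
    counter = 0

    def descend(node: TreeNode) -> None:
        nonlocal counter
        for child in node.children:
            if (not child.is_leaf and child.support is not None
                    and child.support > support_threshold
                    and len(child.leaves()) >= 2):
                name = romans[counter] if counter < len(romans) else f"G{counter + 1}"
                counter += 1
                for leaf in child.leaves():
                    labels[leaf.name] = name
            else:
                descend(child)

    descend(tree)
    return labels


def midpoint_rooted_newick(tree: TreeNode) -> str:
    """Midpoint-rooted Newick string, for display only."""
    import dendropy

    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    t.reroot_at_midpoint(update_bipartitions=False)
    return t.as_string(schema="newick").strip()
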