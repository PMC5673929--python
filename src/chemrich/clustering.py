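"""Chemical similarity tree construction and decomposition.

The pairwise Tanimoto matrix is converted to the dissimilarity
``d = 1 - T`` and clustered with average linkage.  The dendrogram is then
decomposed with an adaptive (dynamic) tree cut: branches are split
top-down wherever the separation between two sub-branches clearly
exceeds their internal spread, small straggler branches are re-attached
to their nearest cluster (PAM-like), and any pair of clusters whose
between-cluster similarity reaches their within-cluster similarity is
re-merged.  Compounds without ontology annotation are rescued into
existing classes by nearest-neighbor Tanimoto similarity (> 0.90, then
> 0.75), and whole new clusters are discovered among the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .fingerprints import (
    Fingerprint,
    SimilarityMatrix,
    compute_fingerprint,
    similarity_matrix,
    tanimoto,
)
from .ontology import ChemSet

__all__ = [
    "Dendrogram",
    "TreeCutResult",
    "build_tree",
    "dynamic_cut",
    "assign_unmapped",
    "detect_new_clusters",
    "tree_order",
    "export_newick",
    "T_HIGH",
    "T_LOW",
]

T_HIGH = 0.90
T_LOW = 0.75

# separation threshold of the adaptive cut per deep-split level (0 = most
# conservative); a branch is split when between-branch spread exceeds
# within-branch spread by at least this much (on the 0..1 distance scale)
_SPLIT_GAP = {0: 0.25, 1: 0.15, 2: 0.10, 3: 0.05}


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labelled leaves (heights = 1 - T)."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)

    def __post_init__(self):
        z = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if z.shape != (n - 1, 4):
            raise ValueError("merge list must have n-1 rows")
        self.merges = z

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self, node: int) -> tuple[int, int] | None:
        n = self.n_leaves
        if node < n:
            return None
        a, b = self.merges[node - n, 0], self.merges[node - n, 1]
        return int(a), int(b)

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.merges[node - n, 2])

    def leaves_of(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            kids = self._children(cur)
            if kids is None:
                out.append(cur)
            else:
                stack.extend(kids)
        return sorted(out)

    def _min_label(self, node: int, memo: dict[int, str]) -> str:
        if node in memo:
            return memo[node]
        kids = self._children(node)
        if kids is None:
            val = self.labels[node]
        else:
            val = min(self._min_label(kids[0], memo), self._min_label(kids[1], memo))
        memo[node] = val
        return val

    def canonical_leaf_order(self) -> list[str]:
        """Leaf order with the smaller-minimum-label child left at each merge.

        This makes the displayed order, the tree positions of sets and the
        Newick export independent of the input row order.
        """
        memo: dict[int, str] = {}
        root = 2 * self.n_leaves - 2
        order: list[str] = []

        def visit(node: int) -> None:
            kids = self._children(node)
            if kids is None:
                order.append(self.labels[node])
                return
            a, b = kids
            if self._min_label(a, memo) > self._min_label(b, memo):
                a, b = b, a
            visit(a)
            visit(b)

        visit(root)
        return order


def build_tree(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage dendrogram of the dissimilarity ``1 - T``."""
    if len(sim.labels) < 2:
        raise ValueError("need at least 2 compounds to build a tree")
    d = sim.distance()
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=list(sim.labels), merges=z)


@dataclass
class TreeCutResult:
    """Cluster memberships from the adaptive tree cut (0 = unassigned)."""

    clusters: dict[str, int]
    min_cluster_size: int
    deep_split: int
    cut_method: str = "adaptive_hybrid"

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, cid in self.clusters.items():
            if cid > 0:
                out.setdefault(cid, []).append(label)
        return out


def dynamic_cut(
    tree: Dendrogram,
    dist: np.ndarray,
    min_cluster_size: int = 3,
    deep_split: int = 2,
) -> TreeCutResult:
    """Adaptive decomposition of the dendrogram into clusters.

    Top-down, a node is split into its two branches when the mean
    between-branch distance exceeds the larger of the two mean
    within-branch distances by more than the deep-split dependent gap.
    Branches smaller than ``min_cluster_size`` become stragglers and are
    re-attached to the closest cluster when they fall inside its radius;
    cluster pairs whose between similarity reaches their within similarity
    are re-merged.  Cluster ids are numbered along the canonical leaf
    order; id 0 marks unassigned compounds.
    """
    if deep_split not in _SPLIT_GAP:
        raise ValueError(f"deep_split must be one of {sorted(_SPLIT_GAP)}")
    gap = _SPLIT_GAP[deep_split]
    n = tree.n_leaves
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match tree")
    if n < min_cluster_size:
        return TreeCutResult(
            {l: 0 for l in tree.labels}, min_cluster_size, deep_split
        )

    def mean_within(leaves: list[int]) -> float:
        if len(leaves) < 2:
            return 0.0
        sub = dist[np.ix_(leaves, leaves)]
        return float(sub[np.triu_indices(len(leaves), 1)].mean())

    def mean_between(a: list[int], b: list[int]) -> float:
        return float(dist[np.ix_(a, b)].mean())

    clusters: list[list[int]] = []
    stragglers: list[int] = []

    def visit(node: int) -> None:
        leaves = tree.leaves_of(node)
        if len(leaves) < min_cluster_size:
            stragglers.extend(leaves)
            return
        kids = tree._children(node)
        if kids is not None:
            la, lb = tree.leaves_of(kids[0]), tree.leaves_of(kids[1])
            between = mean_between(la, lb)
            within = max(mean_within(la), mean_within(lb))
            small = min(len(la), len(lb)) < min_cluster_size
            if between - within > gap:
                if small:
                    # shed the small branch, keep descending the large one
                    keep, shed = (la, lb) if len(la) >= len(lb) else (lb, la)
                    stragglers.extend(shed)
                    visit(kids[0] if keep is la else kids[1])
                else:
                    visit(kids[0])
                    visit(kids[1])
                return
        clusters.append(leaves)

    visit(2 * n - 2)

    # PAM-like re-attachment of stragglers to the nearest cluster
    for leaf in sorted(stragglers):
        if not clusters:
            break
        avg = [float(dist[leaf, c].mean()) for c in clusters]
        best = int(np.argmin(avg))
        radius = mean_within(clusters[best]) + 3 * gap
        if avg[best] <= radius:
            clusters[best].append(leaf)

    # merge cluster pairs whose separation collapsed
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                within = max(mean_within(clusters[i]), mean_within(clusters[j]))
                if mean_between(clusters[i], clusters[j]) <= within + 1e-12:
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break

    clusters = [sorted(c) for c in clusters if len(c) >= min_cluster_size]

    # number clusters along the canonical leaf order
    order = {label: pos for pos, label in enumerate(tree.canonical_leaf_order())}
    clusters.sort(key=lambda c: min(order[tree.labels[i]] for i in c))
    result = {l: 0 for l in tree.labels}
    for k, c in enumerate(clusters, start=1):
        for leaf in c:
            result[tree.labels[leaf]] = k
    return TreeCutResult(result, min_cluster_size, deep_split)


def assign_unmapped(
    record,
    annotated_refs: list[tuple[Fingerprint, str]],
    t_high: float = T_HIGH,
    t_low: float = T_LOW,
    fingerprint: Fingerprint | None = None,
) -> tuple[str, str] | None:
    """Nearest-neighbor similarity rescue of an unannotated compound.

    Returns ``(set_label, provenance)`` where provenance records which
    cutoff fired (strictly > 0.90 -> ``similarity_090``, else strictly
    > 0.75 -> ``similarity_075``), or None when no reference is similar
    enough.  Ties at the maximum are broken by the class with more
    reference members, then by label.
    """
    if not annotated_refs:
        raise ValueError("no annotated reference compounds")
    fp = fingerprint or compute_fingerprint(record.smiles)
    best_by_label: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for ref_fp, label in annotated_refs:
        t = tanimoto(fp, ref_fp)
        sizes[label] = sizes.get(label, 0) + 1
        if t > best_by_label.get(label, -1.0):
            best_by_label[label] = t
    t_max = max(best_by_label.values())
    tied = [l for l, t in best_by_label.items() if t >= t_max - 1e-12]
    label = sorted(tied, key=lambda l: (-sizes[l], l))[0]
    if t_max > t_high:
        return label, "similarity_090"
    if t_max > t_low:
        return label, "similarity_075"
    return None


def detect_new_clusters(
    records: list,
    sim: SimilarityMatrix | None = None,
    min_cluster_size: int = 3,
    deep_split: int = 2,
    named_refs: dict[str, list[Fingerprint]] | None = None,
    naming_threshold: float = 0.5,
) -> tuple[list[ChemSet], list[str]]:
    """Discover novel compound classes among unassigned compounds.

    Builds a similarity tree restricted to the unassigned compounds and
    cuts it; each resulting cluster becomes a new set with provenance
    ``tree_cut_new``.  New sets are labelled ``Cluster_<k>``, suffixed
    with ``near <label>`` when the most similar named reference class
    reaches the naming threshold.  Returns the new sets and the leftover
    compound ids (future singletons).
    """
    ids = [r.compound_id for r in records]
    if len(ids) < min_cluster_size:
        return [], ids
    sim = similarity_matrix(records) if sim is None else sim.subset(ids)
    tree = build_tree(sim)
    cut = dynamic_cut(tree, sim.distance(), min_cluster_size, deep_split)
    sets: list[ChemSet] = []
    for k, members in sorted(cut.groups().items()):
        label = f"Cluster_{k}"
        if named_refs:
            best_label, best_t = None, -1.0
            for ref_label, fps in sorted(named_refs.items()):
                for cid in members:
                    for fp in fps:
                        t = tanimoto(sim.fingerprints[cid], fp)
                        if t > best_t:
                            best_label, best_t = ref_label, t
            if best_label is not None and best_t >= naming_threshold:
                label = f"Cluster_{k}: near {best_label}"
        sets.append(ChemSet(label, sorted(members), provenance="tree_cut_new"))
    assigned = {cid for s in sets for cid in s.compound_ids}
    leftovers = [cid for cid in ids if cid not in assigned]
    return sets, leftovers


def tree_order(tree: Dendrogram, assignment) -> list[str]:
    """Set labels ordered by the median leaf position of their members.

    Position is taken in the canonical leaf ordering, so the result is
    independent of input row order; ties are broken by label.
    """
    pos = {label: i for i, label in enumerate(tree.canonical_leaf_order())}
    classes = assignment.classes() if hasattr(assignment, "classes") else assignment
    medians = []
    for label, members in classes.items():
        positions = sorted(pos[cid] for cid in members if cid in pos)
        if not positions:
            continue
        medians.append((float(np.median(positions)), label))
    return [label for _, label in sorted(medians)]


def export_newick(tree: Dendrogram) -> str:
    """Newick serialization with branch lengths from merge heights.

    Each branch length is the height difference between a node and its
    parent merge, so leaf-to-root path lengths reproduce merge heights.
    """
    memo: dict[int, str] = {}

    def name(label: str) -> str:
        if any(c in label for c in " ():;,'\t\n[]"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def visit(node: int, parent_height: float) -> str:
        length = parent_height - tree.height(node)
        kids = tree._children(node)
        if kids is None:
            return f"{name(tree.labels[node])}:{length:.10g}"
        a, b = kids
        if tree._min_label(a, memo) > tree._min_label(b, memo):
            a, b = b, a
        inner = f"({visit(a, tree.height(node))},{visit(b, tree.height(node))})"
        return f"{inner}:{length:.10g}"

    root = 2 * tree.n_leaves - 2
    kids = tree._children(root)
    a, b = kids
    if tree._min_label(a, memo) > tree._min_label(b, memo):
        a, b = b, a
    h = tree.height(root)
    return f"({visit(a, h)},{visit(b, h)});"
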