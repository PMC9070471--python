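"""Ward clustering with multiscale-bootstrap cluster-support values.

To ask whether the false-lumen cohort contains genuine sub-groups, samples
are clustered hierarchically (Ward linkage on Euclidean distances of their
TIC-normalized spectra) and every internal node of the dendrogram receives
an approximately unbiased (AU) p-value from multiscale bootstrap
resampling (Shimodaira): the m/z features are resampled with replacement at
a range of sample-size scales r (datasets of round(p*r) features), the
samples are re-clustered, and the bootstrap probability BP_r of each node —
the fraction of replicates whose dendrogram contains the node's exact leaf
set — is recorded per scale.  Fitting

    Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by weighted least squares across scales separates the signed distance v
from the curvature c of the cluster boundary, and AU = 1 - Phi(v - c)
corrects the ordinary bootstrap probability's bias.  Nodes with AU above a
threshold (0.90 here) are reported as genuine clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.stats import norm


@dataclass
class Dendrogram:
    """Ward merge tree: scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray
    leaf_labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def node_leaf_sets(self) -> list[frozenset]:
        """Leaf-index sets of the n-1 internal nodes, in merge order."""
        return _internal_leaf_sets(self.linkage_matrix, self.n_leaves)


@dataclass
class NodeSupport:
    """Per-node bootstrap support across scales and the fitted AU value."""

    leaf_set: frozenset
    bp_at_scale: np.ndarray
    scales: np.ndarray
    au: float
    bp: float  # ordinary bootstrap proportion (scale closest to 1)
    v: float
    c: float
    fit_ok: bool


@dataclass
class ClusterAssignment:
    """Disjoint AU-supported clusters; leaves outside any become singletons."""

    clusters: list[frozenset]
    singletons: list[int]
    au_threshold: float
    leaf_labels: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Per-leaf cluster id; singletons get ids after the real clusters."""
        n = len(self.leaf_labels) if self.leaf_labels else (
            sum(len(c) for c in self.clusters) + len(self.singletons)
        )
        out = np.full(n, -1, dtype=int)
        for cid, members in enumerate(self.clusters):
            for leaf in members:
                out[leaf] = cid
        next_id = len(self.clusters)
        for leaf in self.singletons:
            out[leaf] = next_id
            next_id += 1
        return out


def _internal_leaf_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    sets: list[frozenset] = []
    def members(node: int) -> frozenset:
        return frozenset([node]) if node < n else sets[node - n]
    for a, b in Z[:, :2].astype(int):
        sets.append(members(a) | members(b))
    return sets


def ward_cluster(X, leaf_labels=None) -> Dendrogram:
    """Agglomerative Ward clustering on Euclidean distances.

    Merge heights are non-decreasing; ties are resolved deterministically
    (lowest pair in condensed-distance order, i.e. lowest leaf indices).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    Z = linkage(X, method="ward")
    if leaf_labels is None:
        leaf_labels = list(range(X.shape[0]))
    return Dendrogram(Z, list(leaf_labels))


def au_from_bootstrap_proportions(
    bp_at_scale: np.ndarray,
    scales: np.ndarray,
    n_boot: int,
) -> tuple[float, float, float, bool]:
    """Fit the multiscale model to per-scale bootstrap proportions.

    Returns (au, v, c, fit_ok).  BP values are clipped to
    [1/(2 n_boot), 1 - 1/(2 n_boot)] before the probit transform; weights
    follow the delta-method binomial variance of BP.  A node saturated at
    the same bound across every scale is reported with AU at that bound and
    fit_ok = False.
    """
    bp = np.asarray(bp_at_scale, dtype=float)
    scales = np.asarray(scales, dtype=float)
    lo = 1.0 / (2.0 * n_boot)
    # scales where BP is saturated at 0 or 1 carry no information about how
    # the probit varies with r; the fit uses only informative scales
    use = (bp > 0.0) & (bp < 1.0)
    if use.sum() < 2:
        au = 1.0 if bp.mean() >= 0.5 else 0.0
        return au, 0.0, 0.0, False
    bp_c = np.clip(bp[use], lo, 1.0 - lo)
    r = scales[use]
    z = norm.ppf(1.0 - bp_c)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = n_boot * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, True


def multiscale_bootstrap(
    X,
    scales: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[Dendrogram, list[NodeSupport]]:
    """Multiscale bootstrap support for every internal node of the Ward tree.

    Features (columns of X — the m/z bins the samples are described by) are
    resampled with replacement at each scale r to datasets of round(p*r)
    features, the full sample set is re-clustered, and a node counts as
    recovered when some node of the replicate tree has exactly its leaf
    set.  Scales must bracket 1 so the probit regression can separate v
    from c.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if scales is None:
        scales = np.round(np.arange(0.5, 1.45, 0.1), 10)
    scales = np.asarray(scales, dtype=float)
    if scales.min() >= 1.0 or scales.max() <= 1.0:
        raise ValueError("scales must span values below and above 1")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    dendrogram = ward_cluster(X)
    node_sets = dendrogram.node_leaf_sets()
    counts = np.zeros((len(node_sets), scales.size), dtype=int)
    index_of = {s: i for i, s in enumerate(node_sets)}
    for si, r in enumerate(scales):
        p_r = max(2, int(round(p * r)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, size=p_r)
            Zb = linkage(X[:, cols], method="ward")
            for s in _internal_leaf_sets(Zb, n):
                i = index_of.get(s)
                if i is not None:
                    counts[i, si] += 1
    bp = counts / n_boot
    near_one = int(np.argmin(np.abs(scales - 1.0)))
    supports = []
    for i, leaf_set in enumerate(node_sets):
        au, v, c, ok = au_from_bootstrap_proportions(bp[i], scales, n_boot)
        supports.append(
            NodeSupport(
                leaf_set=leaf_set,
                bp_at_scale=bp[i],
                scales=scales,
                au=au,
                bp=float(bp[i, near_one]),
                v=v,
                c=c,
                fit_ok=ok,
            )
        )
    return dendrogram, supports


def stable_clusters(
    dendrogram: Dendrogram,
    supports: list[NodeSupport],
    threshold: float = 0.90,
) -> ClusterAssignment:
    """Maximal disjoint AU-supported nodes; uncovered leaves become singletons.

    The tree is walked from the root: the first node on each path whose AU
    strictly exceeds the threshold is taken as a cluster and its subtree is
    not descended further.  The root itself (all leaves; trivially
    recovered in every replicate) is never a candidate.
    """
    n = dendrogram.n_leaves
    Z = dendrogram.linkage_matrix.astype(int)
    au_of_node = {i + n: supports[i].au for i in range(len(supports))}
    root = n + len(supports) - 1
    clusters: list[frozenset] = []
    singletons: list[int] = []
    node_sets = dendrogram.node_leaf_sets()

    def descend(node: int, is_root: bool) -> None:
        if node < n:
            singletons.append(node)
            return
        if not is_root and au_of_node[node] > threshold:
            clusters.append(node_sets[node - n])
            return
        a, b = Z[node - n, 0], Z[node - n, 1]
        descend(a, False)
        descend(b, False)

    descend(root, True)
    return ClusterAssignment(
        clusters=clusters,
        singletons=sorted(singletons),
        au_threshold=threshold,
        leaf_labels=dendrogram.leaf_labels,
    )


def support_table(supports: list[NodeSupport], leaf_labels=None):
    """Tidy per-node support table (one row per internal node)."""
    import pandas as pd

    rows = []
    for i, s in enumerate(supports):
        members = sorted(s.leaf_set)
        if leaf_labels is not None:
            members = [leaf_labels[m] for m in members]
        rows.append(
            {
                "node": i,
                "n_leaves": len(s.leaf_set),
                "members": ";".join(str(m) for m in members),
                "au": s.au,
                "bp": s.bp,
                "v": s.v,
                "c": s.c,
                "fit_ok": s.fit_ok,
            }
        )
    return pd.DataFrame(rows)


def to_newick(dendrogram: Dendrogram, supports: list[NodeSupport] | None = None) -> str:
    """Newick text of the merge tree, internal nodes annotated with AU/BP."""
    n = dendrogram.n_leaves
    Z = dendrogram.linkage_matrix

    def label(i: int) -> str:
        return str(dendrogram.leaf_labels[i]).replace(",", "_").replace("(", "_").replace(")", "_")

    def render(node: int) -> str:
        if node < n:
            return label(node)
        i = node - n
        a, b = int(Z[i, 0]), int(Z[i, 1])
        ann = ""
        if supports is not None:
            ann = f"au{supports[i].au:.3f}_bp{supports[i].bp:.3f}"
        return f"({render(a)},{render(b)}){ann}:{Z[i, 2]:.6g}"

    return render(2 * n - 2) + ";"
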