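"""Phenotypic similarity clustering of probands.

Turns per-proband ontology term sets into a pairwise symmetric-Lin
similarity matrix, converts it to a distance matrix (``d = 1 - s``),
selects a cluster count with the gap statistic on Ward hierarchical
clustering, cuts the dendrogram and summarises cluster composition.

The Ward linkage here follows the Lance-Williams update on squared
distances (the ``ward.D2``-style criterion), with deterministic
tie-breaking on the lowest pair of current cluster indices after sorting
probands canonically by id, so results are invariant to input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as sch

from .ontology import (
    ICTable,
    OntologyError,
    OntologyGraph,
    annotation_closure,
    set_similarity,
)

__all__ = [
    "EmptyPhenotypeError",
    "SimilarityMatrix",
    "DistanceMatrix",
    "GapCurve",
    "ClusterAssignment",
    "apply_exclusions",
    "build_similarity_matrix",
    "similarity_to_distance",
    "ward_linkage",
    "gap_statistic",
    "select_k",
    "cut_clusters",
    "cluster_term_frequencies",
    "cocluster_count",
    "linkage_to_newick",
    "export_heatmap",
]


class EmptyPhenotypeError(OntologyError):
    """A proband lost every term to the exclusion list."""


@dataclass
class SimilarityMatrix:
    ids: list
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray  # symmetric, zero diagonal, non-negative

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class GapCurve:
    """Gap-statistic curve over k = 1..kmax.

    ``log_w`` is the observed log within-cluster dispersion, ``e_log_w``
    the reference mean, ``gap = e_log_w - log_w`` and ``se`` the reference
    standard error inflated by ``sqrt(1 + 1/B)``.
    """

    k: np.ndarray
    log_w: np.ndarray
    e_log_w: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    n_refs: int
    seed: int


@dataclass
class ClusterAssignment:
    labels: dict  # proband id -> cluster label in 1..k
    linkage: np.ndarray  # scipy-format (n-1, 4) merge list
    ids: list  # row order used for the linkage
    leaf_order: list = field(default_factory=list)  # ids in dendrogram order

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list:
        return [i for i, l in self.labels.items() if l == label]


# ---------------------------------------------------------------------------
# annotation preparation
# ---------------------------------------------------------------------------

def apply_exclusions(annotations, exclusions, g: OntologyGraph):
    """Drop excluded terms from raw annotation sets, then close.

    Exclusion entries may be term ids or exact labels.  Only the listed
    terms are removed; their ancestors may still be reached through other
    terms.  A proband left with no terms raises
    :class:`EmptyPhenotypeError` naming the proband.
    """
    excluded = {g.resolve(e) for e in exclusions}
    closed = {}
    for pid, terms in annotations.items():
        kept = {g.resolve(t) for t in terms} - excluded
        if not kept:
            raise EmptyPhenotypeError(
                f"proband {pid!r} has no terms left after exclusions; "
                "similarity is undefined"
            )
        closed[pid] = annotation_closure(kept, g)
    return closed


# ---------------------------------------------------------------------------
# similarity / distance
# ---------------------------------------------------------------------------

def build_similarity_matrix(annotations, ic: ICTable,
                            g: OntologyGraph) -> SimilarityMatrix:
    """Pairwise symmetric-Lin similarity between all probands.

    Probands are ordered canonically (sorted by id) so the downstream
    clustering is invariant to input order.
    """
    ids = sorted(annotations)
    if len(ids) < 2:
        raise OntologyError("similarity matrix requires at least 2 probands")
    n = len(ids)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = set_similarity(
                annotations[ids[i]], annotations[ids[j]], ic, g
            )
    return SimilarityMatrix(ids=ids, values=s)


def similarity_to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    """``d = 1 - s`` with the diagonal forced to zero."""
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(ids=list(s.ids), values=d)


# ---------------------------------------------------------------------------
# Ward linkage (Lance-Williams on squared distances, canonical ties)
# ---------------------------------------------------------------------------

def ward_linkage(d: np.ndarray) -> np.ndarray:
    """Ward agglomeration of a square distance matrix.

    Returns a scipy-format linkage matrix.  Ties in merge height are broken
    by the lowest pair of current cluster indices, which makes the merge
    sequence deterministic.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")

    d2 = d.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    cluster_id = np.arange(n)
    z = np.zeros((n - 1, 4))

    work = d2.copy()
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        np.fill_diagonal(masked, np.inf)
        m = masked.min()
        cand = np.argwhere(np.isclose(masked, m, rtol=0.0, atol=0.0))
        # deterministic tie-break: lowest (cluster_id_i, cluster_id_j)
        best = min(
            (tuple(sorted((cluster_id[i], cluster_id[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        ci, cj = sorted((cluster_id[i], cluster_id[j]))
        z[step] = [ci, cj, np.sqrt(m), sizes[i] + sizes[j]]

        si, sj = sizes[i], sizes[j]
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        sk = sizes[others]
        new = ((si + sk) * work[i, others] + (sj + sk) * work[j, others]
               - sk * m) / (si + sj + sk)
        work[i, others] = new
        work[others, i] = new
        active[j] = False
        sizes[i] = si + sj
        cluster_id[i] = n + step
    return z


def _labels_from_linkage(z: np.ndarray, n: int, k: int) -> np.ndarray:
    """Cut a linkage into exactly k clusters via the first n-k merges."""
    parent = list(range(n + len(z)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(z[step, 0]), int(z[step, 1])
        merged = n + step
        parent[find(a)] = merged
        parent[find(b)] = merged
    roots = [find(i) for i in range(n)]
    remap = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        out[i] = remap.setdefault(r, len(remap))
    return out


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

def _within_dispersion(d2: np.ndarray, labels: np.ndarray) -> float:
    """W = sum_r (1/n_r) * sum_{i<j in C_r} d_ij^2."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return w


def _log_w_curve(d: np.ndarray, kmax: int) -> np.ndarray:
    z = ward_linkage(d)
    d2 = d ** 2
    n = d.shape[0]
    out = np.empty(kmax)
    for k in range(1, kmax + 1):
        labels = _labels_from_linkage(z, n, k)
        out[k - 1] = np.log(max(_within_dispersion(d2, labels), 1e-12))
    return out


def _cmds_embed(d: np.ndarray, var_target: float = 0.95,
                max_dims: int = 10) -> np.ndarray:
    """Classical MDS coordinates covering >= 95% of positive eigen-mass."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if not pos.any():
        return np.zeros((n, 1))
    vals, vecs = vals[pos], vecs[:, pos]
    cum = np.cumsum(vals) / vals.sum()
    ndim = min(int(np.searchsorted(cum, var_target) + 1), max_dims, len(vals))
    return vecs[:, :ndim] * np.sqrt(vals[:ndim])


def gap_statistic(d: DistanceMatrix | np.ndarray, kmax: int = 15,
                  n_refs: int = 100, seed: int = 0) -> GapCurve:
    """Gap statistic over Ward cuts for k = 1..kmax.

    The reference distribution embeds the distance matrix with classical
    MDS (top components explaining >= 95% of positive eigen-mass, capped at
    10 dimensions) and samples points uniformly within the per-dimension
    bounding box; each reference set is clustered with the same Ward
    procedure.
    """
    mat = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    n = mat.shape[0]
    if kmax >= n:
        raise ValueError(f"kmax ({kmax}) must be smaller than n ({n})")
    if n_refs < 10:
        raise ValueError("need at least 10 reference datasets")

    log_w = _log_w_curve(mat, kmax)

    coords = _cmds_embed(mat)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    rng = np.random.default_rng(seed)
    ref = np.empty((n_refs, kmax))
    for b in range(n_refs):
        pts = rng.uniform(lo, hi, size=(n, coords.shape[1]))
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        ref[b] = _log_w_curve(dist, kmax)

    e_log_w = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    return GapCurve(
        k=np.arange(1, kmax + 1),
        log_w=log_w,
        e_log_w=e_log_w,
        gap=e_log_w - log_w,
        se=sd * np.sqrt(1.0 + 1.0 / n_refs),
        n_refs=n_refs,
        seed=seed,
    )


def select_k(curve: GapCurve, rule: str = "slope", override: int | None = None) -> int:
    """Choose the cluster count from a gap curve.

    ``rule='slope'`` (default) picks the k in [2, kmax-1] where the curve's
    slope decreases the most, i.e. the most negative second difference
    ``Gap(k+1) - 2 Gap(k) + Gap(k-1)``.  ``rule='one_se'`` applies the
    Tibshirani one-standard-error rule.  ``override`` forces a value.
    """
    if override is not None:
        return int(override)
    gap = curve.gap
    kmax = len(gap)
    if kmax < 3:
        raise ValueError("selecting k requires kmax >= 3")
    if rule == "one_se":
        for i in range(kmax - 1):
            if gap[i] >= gap[i + 1] - curve.se[i + 1]:
                return int(curve.k[i])
        return int(curve.k[-1])
    if rule != "slope":
        raise ValueError(f"unknown rule {rule!r}")
    second = gap[2:] - 2.0 * gap[1:-1] + gap[:-2]  # index i -> k = i + 2
    if np.allclose(second, second[0]):
        warnings.warn("gap curve has no distinct elbow; choosing smallest k")
        return int(curve.k[1])
    return int(curve.k[int(np.argmin(second)) + 1])


# ---------------------------------------------------------------------------
# cutting & summaries
# ---------------------------------------------------------------------------

def cut_clusters(z: np.ndarray, ids, k: int) -> ClusterAssignment:
    """Cut a linkage into exactly k clusters with stable 1..k labels.

    Labels are numbered by first appearance along the dendrogram leaf
    order, which also becomes the heatmap row/column order.
    """
    ids = list(ids)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = _labels_from_linkage(z, n, k)
    order = [int(i) for i in sch.leaves_list(z)] if n > 1 else [0]
    remap: dict = {}
    for idx in order:
        remap.setdefault(raw[idx], len(remap) + 1)
    labels = {ids[i]: remap[raw[i]] for i in range(n)}
    return ClusterAssignment(labels=labels, linkage=z, ids=ids,
                             leaf_order=[ids[i] for i in order])


def cluster_term_frequencies(assignment: ClusterAssignment, annotations):
    """Per-cluster fraction of members annotated with each term."""
    import pandas as pd

    missing = [p for p in assignment.labels if p not in annotations]
    if missing:
        raise KeyError(f"no annotations for probands: {missing}")
    rows = {}
    all_terms = sorted(set().union(*annotations.values()))
    for lab in sorted(set(assignment.labels.values())):
        members = assignment.members(lab)
        rows[lab] = {
            t: sum(t in annotations[m] for m in members) / len(members)
            for t in all_terms
        }
    return pd.DataFrame.from_dict(rows, orient="index")[all_terms]


def cocluster_count(assignment: ClusterAssignment, subset) -> int:
    """Largest number of the given probands sharing one cluster."""
    subset = list(subset)
    unknown = [p for p in subset if p not in assignment.labels]
    if unknown:
        raise KeyError(f"unknown proband id(s): {unknown}")
    if not subset:
        return 0
    counts: dict = {}
    for p in subset:
        lab = assignment.labels[p]
        counts[lab] = counts.get(lab, 0) + 1
    return max(counts.values())


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def linkage_to_newick(z: np.ndarray, ids) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    tree = sch.to_tree(z)
    ids = list(ids)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def export_heatmap(s: SimilarityMatrix, assignment: ClusterAssignment, path):
    """Similarity heatmap ordered by dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [s.ids.index(p) for p in assignment.leaf_order]
    mat = s.values[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(mat, cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    ax.set_xticklabels(assignment.leaf_order, rotation=90, fontsize=6)
    ax.set_yticklabels(assignment.leaf_order, fontsize=6)
    fig.colorbar(im, ax=ax, label="phenotypic similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return assignment.leaf_order
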