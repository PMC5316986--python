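"""UPGMA dendrograms with multiscale-bootstrap clade support (BP and AU).

UPGMA (average linkage) iteratively merges the closest pair of clusters; the
distance from any cluster C to the merged cluster A+B is the size-weighted
average (n_A d(C,A) + n_B d(C,B)) / (n_A + n_B), and the join height is half
the merge distance, giving an ultrametric tree. Ties are broken on the
lexicographically smallest pair of cluster representatives (a cluster is
represented by its smallest leaf label), so the tree is deterministic
regardless of input order.

Clade uncertainty is assessed by multiscale bootstrap: the variables
(compounds, wavelengths, chemicals — the observations feeding each pairwise
dissimilarity) are resampled with replacement at several sample-size scales
r = n'/n, the tree is rebuilt, and the bootstrap probability BP_r of each
reference clade is recorded per scale. Writing sigma = 1/sqrt(r) and
z_r = Phi^{-1}(1 - BP_r), the model z(sigma) = v*sigma + c/sigma is fitted by
weighted least squares, and the approximately unbiased p-value is
AU = 1 - Phi(v - c): the bias of the plain bootstrap probability is removed
through the curvature term c. BP at scale 1 is the ordinary bootstrap
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .trait_io import DistanceMatrix, TraitTable

__all__ = [
    "Dendrogram",
    "NodeSupport",
    "DEFAULT_SCALES",
    "upgma",
    "multiscale_bootstrap",
    "fit_au",
    "write_newick",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.4 + 1e-9, 0.1), 10))


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` is an ordered list of (left, right, height) where left/right
    are node indices: 0..n-1 the leaves, n+i the cluster created by merge i.
    ``height`` is the cophenetic level (merge distance / 2).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_clades(self) -> list[frozenset]:
        """Leaf-label set of every internal node, in merge order."""
        sets: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.leaves)
        }
        clades = []
        n = self.n_leaves
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
            clades.append(sets[n + k])
        return clades

    def cophenetic(self) -> DistanceMatrix:
        """Ultrametric distances implied by the tree (2 x join height)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        d = np.zeros((n, n))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    d[i, j] = d[j, i] = 2.0 * h
            members[n + k] = members[a] + members[b]
        return DistanceMatrix(d, self.leaves, "cophenetic")


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix."""
    n = d.n
    if n < 2:
        raise ValueError("need at least two leaves")
    # order clusters by representative (smallest leaf label) so the argmin
    # scan resolves ties lexicographically
    order = sorted(range(n), key=lambda i: d.labels[i])
    leaves = [d.labels[i] for i in order]
    D = d.d[np.ix_(order, order)].astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))  # node ids, ordered by representative
    sizes = {i: 1 for i in range(n)}
    reps = {i: leaves[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        m = len(active)
        sub = D[:m, :m]
        flat = np.argmin(sub)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dist = sub[i, j]
        a, b = active[i], active[j]
        na, nb = sizes[a], sizes[b]
        new_row = (na * sub[i, :m] + nb * sub[j, :m]) / (na + nb)
        # collapse j into i, then drop j
        keep = [k for k in range(m) if k != j]
        sub2 = sub[np.ix_(keep, keep)].copy()
        nr = new_row[keep]
        ii = keep.index(i)
        sub2[ii, :] = nr
        sub2[:, ii] = nr
        sub2[ii, ii] = np.inf
        merges.append((a, b, dist / 2.0))
        node = next_id
        next_id += 1
        sizes[node] = na + nb
        reps[node] = min(reps[a], reps[b])
        active = [active[k] for k in keep]
        active[ii] = node
        # re-sort by representative to keep lexicographic tie-breaking
        perm = sorted(range(len(active)), key=lambda k: reps[active[k]])
        active = [active[k] for k in perm]
        sub2 = sub2[np.ix_(perm, perm)]
        D = np.full_like(D, np.inf)
        D[: len(active), : len(active)] = sub2
    return Dendrogram(leaves, merges)


@dataclass
class NodeSupport:
    """Per-clade multiscale bootstrap record."""

    clade: frozenset
    scales: tuple[float, ...]
    bp_per_scale: np.ndarray
    n_boot: int
    v: float = np.nan
    c: float = np.nan
    AU: float = np.nan
    BP: float = np.nan  # bootstrap proportion at (nearest to) scale 1
    fit_residual: float = np.nan
    flag: str | None = None


def fit_au(
    bp_per_scale,
    scales,
    n_boot: int,
) -> tuple[float, float, float, float]:
    """Fit the multiscale model and return (v, c, AU, BP_at_scale_1).

    z_r = Phi^{-1}(1 - BP_r) is regressed on sigma = 1/sqrt(r) under the
    model z = v*sigma + c/sigma, with binomial-delta-method weights
    n_boot * phi(z_r)^2 / (BP_r (1 - BP_r)). Boundary BP values are clamped
    to 1/(2 n_boot) from 0 or 1 so the probit stays finite. AU = 1 - Phi(v-c).
    """
    bp = np.asarray(bp_per_scale, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if bp.shape != scales.shape:
        raise ValueError("one BP per scale required")
    eps = 1.0 / (2.0 * n_boot)
    interior = (bp > 0.0) & (bp < 1.0)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    if interior.sum() < 2:
        # degenerate support: all-saturated or all-dead curves
        if (bp >= 1.0 - 1e-12).all():
            return np.inf, 0.0, 1.0, 1.0
        if (bp <= 1e-12).all():
            return -np.inf, 0.0, 0.0, 0.0
    sigma = 1.0 / np.sqrt(scales)
    z = norm.ppf(1.0 - bp_c)
    w = n_boot * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    X = np.column_stack([sigma, 1.0 / sigma])
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - norm.cdf(v - c))
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    return v, c, au, float(bp[i1])


_METRICS = ("bray_curtis", "euclidean")


def _metric_matrix(values: np.ndarray, labels: list[str], metric: str) -> DistanceMatrix:
    from .multivariate_stats import bray_curtis_matrix, euclidean_matrix
    from .trait_io import TraitTable as _TT

    if metric == "bray_curtis":
        t = _TT(values, labels, [f"v{k}" for k in range(values.shape[1])])
        return bray_curtis_matrix(t)
    return euclidean_matrix(values, labels)


def multiscale_bootstrap(
    t: TraitTable,
    metric: str = "bray_curtis",
    scales=DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> tuple[Dendrogram, list[NodeSupport]]:
    """Reference UPGMA tree plus per-clade multiscale bootstrap supports.

    The bootstrap unit is the variable axis: at scale r, n' = round(r * n_vars)
    variable columns are drawn with replacement, distances and the tree are
    recomputed, and BP_r is the fraction of resampled trees containing each
    reference clade. Same seed => identical BP tables.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    scales = tuple(float(r) for r in scales)
    n_vars = t.n_variables
    for r in scales:
        if int(round(r * n_vars)) < 2:
            raise ValueError(f"scale {r} resamples fewer than 2 variables")
    ref = upgma(_metric_matrix(t.values, t.sample_ids, metric))
    ref_clades = ref.node_clades()
    # root clade (all leaves) is trivially present in every tree
    counts = {cl: np.zeros(len(scales)) for cl in ref_clades}
    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        n_prime = int(round(r * n_vars))
        for _ in range(n_boot):
            cols = rng.integers(0, n_vars, size=n_prime)
            vals = t.values[:, cols]
            try:
                tree = upgma(_metric_matrix(vals, t.sample_ids, metric))
            except ValueError:
                continue  # e.g. all-zero rows under Bray-Curtis resample
            boot_clades = set(tree.node_clades())
            for cl in ref_clades:
                if cl in boot_clades:
                    counts[cl][si] += 1
    supports = []
    for cl in ref_clades:
        bp = counts[cl] / n_boot
        ns = NodeSupport(cl, scales, bp, n_boot)
        if (bp == 0).all():
            ns.AU, ns.BP, ns.v, ns.c = 0.0, 0.0, -np.inf, 0.0
            ns.flag = "clade never observed at any scale"
        else:
            v, c, au, bp1 = fit_au(bp, scales, n_boot)
            ns.v, ns.c, ns.AU, ns.BP = v, c, au, bp1
            sigma = 1.0 / np.sqrt(np.asarray(scales))
            if np.isfinite(v):
                fitted = v * sigma + c / sigma
                eps = 1.0 / (2.0 * n_boot)
                z = norm.ppf(1.0 - np.clip(bp, eps, 1 - eps))
                ns.fit_residual = float(np.sqrt(np.mean((fitted - z) ** 2)))
        supports.append(ns)
    return ref, supports


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in ",();:'[] \t")


def _fmt_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: Dendrogram, supports: list[NodeSupport] | None = None
) -> str:
    """Newick string with branch lengths; internal nodes optionally annotated
    with ``[&AU=...,BP=...]`` comments keyed by clade."""
    by_clade = {}
    if supports:
        by_clade = {s.clade: s for s in supports}
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    text = {i: _fmt_label(lab) for i, lab in enumerate(tree.leaves)}
    sets: dict[int, frozenset] = {
        i: frozenset([lab]) for i, lab in enumerate(tree.leaves)
    }
    for k, (a, b, h) in enumerate(tree.merges):
        node = n + k
        la = h - heights[a]
        lb = h - heights[b]
        ann = ""
        cl = sets[a] | sets[b]
        s = by_clade.get(cl)
        if s is not None and np.isfinite(s.AU):
            ann = f"[&AU={s.AU:.4f},BP={s.BP:.4f}]"
        text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g}){ann}"
        heights[node] = h
        sets[node] = cl
    root = n + len(tree.merges) - 1
    return text[root] + ";"
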