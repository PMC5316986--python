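"""Distance-based permutation inference for trait tables.

perMANOVA partitions the total sum of squared dissimilarities among and
within groups,

    SS_T = (1/N) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_A = SS_T - SS_W
    F    = (SS_A / (a - 1)) / (SS_W / (N - a)),

and tests the pseudo-F against a null built by permuting group labels whole.
The permutation p-value uses the add-one convention
p = (1 + #{F* >= F_obs}) / (1 + n_perm); ties count as >=.  With
``exact=True`` all distinct label assignments are enumerated instead and
p is the exact fraction of assignments with F* >= F_obs.

Multivariate dispersion homogeneity embeds the distance matrix by principal
coordinates (Gower-centred -d^2/2), measures each sample's distance to its
own group centroid — subtracting the squared contribution of negative-
eigenvalue axes, as required for non-Euclidean dissimilarities such as
Bray-Curtis — and permutes those distances through a one-way ANOVA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .trait_io import DistanceMatrix, TraitTable

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "bray_curtis_matrix",
    "euclidean_matrix",
    "permanova",
    "pairwise_permanova",
    "dispersion_homogeneity",
]


def bray_curtis_matrix(t: TraitTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d_ij = sum|x_i - x_j| / sum(x_i + x_j)."""
    sums = t.values.sum(axis=1)
    if (sums <= 0).any():
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"sample {t.sample_ids[i]!r} is all-zero; Bray-Curtis undefined"
        )
    d = squareform(pdist(t.values, metric="braycurtis"))
    return DistanceMatrix(d, t.sample_ids, "bray_curtis")


def euclidean_matrix(points: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """Euclidean distances between rows of an n x k coordinate matrix."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    if labels is None:
        labels = [str(i) for i in range(pts.shape[0])]
    d = squareform(pdist(pts, metric="euclidean"))
    return DistanceMatrix(d, list(labels), "euclidean")


@dataclass
class PermanovaResult:
    SS_A: float
    SS_W: float
    SS_T: float
    df_between: int
    df_within: int
    F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None
    exact: bool = False
    warning: str | None = None

    def __str__(self) -> str:  # adonis-style one-liner
        return (
            f"perMANOVA: F_{self.df_between},{self.df_within} = {self.F:.4g}, "
            f"R2 = {self.R2:.3f}, p = {self.p:.4g} "
            f"({'exact' if self.exact else f'{self.n_perm} permutations'})"
        )


def _group_structure(groups):
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    return labels, codes, sizes


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    # one-hot trick: within-group sum of d^2 over unordered pairs = diag(G' D2 G)/2
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def _pseudo_f(d2, codes, n_groups, sizes, ss_t):
    N = codes.size
    ssw = _ss_within(d2, codes, n_groups)
    ssa = ss_t - ssw
    df_b, df_w = n_groups - 1, N - n_groups
    if ssw <= 0:
        return ssa, ssw, np.inf if ssa > 0 else 0.0
    return ssa, ssw, (ssa / df_b) / (ssw / df_w)


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exact: bool = False,
) -> PermanovaResult:
    """One-way perMANOVA on a distance matrix.

    ``groups`` is one label per sample in matrix order. ``seed`` is required
    for the sampled permutation test (identical seed => identical result);
    ``exact=True`` enumerates every distinct assignment of labels to samples
    and needs no seed.
    """
    groups = np.asarray(groups)
    if groups.size != d.n:
        raise ValueError("one group label per sample required")
    labels, codes, sizes = _group_structure(groups)
    a, N = labels.size, d.n
    if a < 2:
        raise ValueError("need at least two groups")
    if N <= a:
        raise ValueError("need more samples than groups")
    d2 = d.d ** 2
    ss_t = d2.sum() / (2.0 * N)
    ssa, ssw, f_obs = _pseudo_f(d2, codes, a, sizes, ss_t)
    warning = None
    if ss_t <= 0:
        # all samples identical: define F = 0, nothing to test
        return PermanovaResult(0.0, 0.0, 0.0, a - 1, N - a, 0.0, 0.0, 1.0,
                               0, seed, exact, "SS_T = 0; all samples identical")
    if ssw <= 0:
        warning = "SS_W = 0; F undefined, p from enumeration of SS_A"
        f_obs = np.inf

    stat_obs = ssa if ssw <= 0 else f_obs

    def stat(perm_codes):
        s_a, s_w, f = _pseudo_f(d2, perm_codes, a, sizes, ss_t)
        return s_a if ssw <= 0 else f

    if exact:
        total = 0
        seen_ge = 0
        for perm in _distinct_assignments(codes):
            total += 1
            if stat(perm) >= stat_obs - 1e-12:
                seen_ge += 1
        p = seen_ge / total
        n_used = total
    else:
        if seed is None:
            raise ValueError("seed required for sampled permutations")
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if stat(perm) >= stat_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        n_used = n_perm
    r2 = ssa / ss_t
    f_rep = 0.0 if not np.isfinite(f_obs) and ssa <= 0 else f_obs
    return PermanovaResult(
        ssa, ssw, ss_t, a - 1, N - a, float(f_rep), float(r2), float(p),
        n_used, seed, exact, warning,
    )


def _distinct_assignments(codes: np.ndarray):
    """Every distinct assignment of the label multiset to sample positions.

    Intended for small instances (<= ~10 samples); the count is the
    multinomial coefficient N! / prod(n_g!).
    """
    for perm in sorted(set(itertools.permutations(codes.tolist()))):
        yield np.array(perm)


@dataclass
class PairwisePermanovaRow:
    pair: tuple[str, str]
    F: float
    df_between: int
    df_within: int
    p_raw: float
    p_adjusted: float


def pairwise_permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    adjustment: str = "bonferroni",
) -> list[PairwisePermanovaRow]:
    """perMANOVA on every pair of groups, with Bonferroni adjustment.

    Each pair re-uses the full permutation budget. ``p_adjusted`` is
    min(1, p_raw * number_of_pairs).
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    pairs = list(itertools.combinations(labels.tolist(), 2))
    k = len(pairs)
    rows = []
    for j, (g1, g2) in enumerate(pairs):
        mask = (groups == g1) | (groups == g2)
        idx = np.flatnonzero(mask)
        sub = DistanceMatrix(
            d.d[np.ix_(idx, idx)], [d.labels[i] for i in idx], d.metric_name
        )
        sub_seed = None if seed is None else seed + j
        res = permanova(sub, groups[idx], n_perm=n_perm, seed=sub_seed)
        p_adj = res.p if adjustment == "none" else min(1.0, res.p * k)
        rows.append(
            PairwisePermanovaRow(
                (str(g1), str(g2)), res.F, res.df_between, res.df_within,
                res.p, p_adj,
            )
        )
    return rows


@dataclass
class DispersionResult:
    z: np.ndarray
    groups: np.ndarray
    F: float
    df_between: int
    df_within: int
    p: float
    n_perm: int
    seed: int | None

    def __str__(self) -> str:
        return (
            f"dispersion homogeneity: F_{self.df_between},{self.df_within} = "
            f"{self.F:.4g}, p = {self.p:.4g} ({self.n_perm} permutations)"
        )


def _anova_f(values: np.ndarray, codes: np.ndarray, a: int) -> float:
    N = values.size
    grand = values.mean()
    ssb = ssw = 0.0
    for g in range(a):
        v = values[codes == g]
        m = v.mean()
        ssb += v.size * (m - grand) ** 2
        ssw += ((v - m) ** 2).sum()
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (N - a))


def dispersion_homogeneity(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """betadisper-style test of multivariate dispersion homogeneity.

    Principal-coordinates embedding of d; z_i = distance of sample i to its
    group centroid with the squared negative-axis contribution subtracted
    (floored at 0); F = one-way ANOVA on z; p by permuting z among groups.
    """
    groups = np.asarray(groups)
    labels, codes, sizes = _group_structure(groups)
    a, N = labels.size, d.n
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    # Gower-centred double-centring of -d^2/2
    A = -0.5 * d.d ** 2
    J = np.eye(N) - np.ones((N, N)) / N
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    C_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    C_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    z = np.empty(N)
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        cp = C_pos[idx].mean(axis=0) if C_pos.size else np.zeros(0)
        cn = C_neg[idx].mean(axis=0) if C_neg.size else np.zeros(0)
        dz2 = ((C_pos[idx] - cp) ** 2).sum(axis=1) - (
            (C_neg[idx] - cn) ** 2
        ).sum(axis=1)
        if (dz2 < -1e-8 * max(1.0, d.d.max() ** 2)).any():
            raise ValueError("inconsistent embedding: squared distance < 0")
        z[idx] = np.sqrt(np.clip(dz2, 0.0, None))
    f_obs = _anova_f(z, codes, a)
    if seed is None:
        raise ValueError("seed required for the permutation test")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(z, perm, a) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DispersionResult(z, groups, float(f_obs), a - 1, N - a, float(p),
                            n_perm, seed)
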