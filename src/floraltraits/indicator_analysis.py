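"""Dufrene-Legendre indicator value (IndVal) analysis.

A variable (scent compound, sterol, amino acid) is a good indicator of a
group of samples when it is both specific to it and faithful within it.
For variable j and group k:

    A_jk = mean abundance of j in k / sum over groups of mean abundances
    B_jk = fraction of samples of k in which j is present (> 0)
    IndVal_jk = A_jk * B_jk

The indicator value of a variable is max_k IndVal_jk, attained at its best
group; significance comes from permuting sample group labels and comparing
the permuted max-IndVal to the observed one, per variable, with the add-one
p-value convention. Values are reported on the 0-1 scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trait_io import TraitTable

__all__ = ["IndvalResult", "indval", "indval_components"]


@dataclass
class IndvalResult:
    variable_ids: list[str]
    group_labels: list[str]
    A: np.ndarray  # (n_vars, n_groups) specificity
    B: np.ndarray  # (n_vars, n_groups) fidelity
    indval_matrix: np.ndarray  # A * B
    best_group: list[str]  # per variable
    indval: np.ndarray  # per variable, max over groups
    p: np.ndarray  # per-variable permutation p
    n_perm: int
    seed: int | None
    flags: list[str | None]

    def to_dataframe(self, full: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variable": self.variable_ids,
                "best_group": self.best_group,
                "A": self.A[np.arange(len(self.variable_ids)),
                            [self.group_labels.index(g) for g in self.best_group]],
                "B": self.B[np.arange(len(self.variable_ids)),
                            [self.group_labels.index(g) for g in self.best_group]],
                "indval": self.indval,
                "p": self.p,
            }
        )
        if full:
            for gi, g in enumerate(self.group_labels):
                df[f"indval_{g}"] = self.indval_matrix[:, gi]
        return df


def indval_components(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """(A, B, IndVal) matrices for an abundance matrix and coded groups."""
    n_vars = values.shape[1]
    means = np.empty((n_groups, n_vars))
    pres = np.empty((n_groups, n_vars))
    for g in range(n_groups):
        block = values[codes == g]
        means[g] = block.mean(axis=0)
        pres[g] = (block > 0).mean(axis=0)
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(total > 0, means / np.where(total > 0, total, 1.0), 0.0)
    iv = A * pres
    return A.T, pres.T, iv.T  # (n_vars, n_groups)


def indval(
    t: TraitTable,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    exact: bool = False,
    adjustment: str | None = None,
) -> IndvalResult:
    """Indicator-value analysis of every variable against a grouping.

    ``groups`` may be a metadata column name or one label per sample.
    p-values are per-variable with no multiplicity adjustment by default;
    ``adjustment="bonferroni"`` adds a Bonferroni-corrected column in the
    exported frame (factor = number of variables). ``exact=True`` enumerates
    all distinct label assignments (tiny n only).
    """
    if isinstance(groups, str):
        groups = t.groups(groups)
    groups = np.asarray(groups)
    if groups.size != t.n_samples:
        raise ValueError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    a = labels.size
    if a < 2:
        raise ValueError("need at least two groups")
    values = t.values
    A, B, iv = indval_components(values, codes, a)
    best_idx = iv.argmax(axis=1)
    obs = iv.max(axis=1)
    n_vars = t.n_variables

    if exact:
        perms = sorted(set(itertools.permutations(codes.tolist())))
        ge = np.zeros(n_vars)
        for perm in perms:
            _, _, iv_p = indval_components(values, np.array(perm), a)
            ge += iv_p.max(axis=1) >= obs - 1e-12
        p = ge / len(perms)
        n_used = len(perms)
    else:
        if seed is None:
            raise ValueError("seed required for sampled permutations")
        rng = np.random.default_rng(seed)
        ge = np.zeros(n_vars)
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            _, _, iv_p = indval_components(values, perm, a)
            ge += iv_p.max(axis=1) >= obs - 1e-12
        p = (1.0 + ge) / (1.0 + n_perm)
        n_used = n_perm

    flags: list[str | None] = [None] * n_vars
    absent = values.sum(axis=0) == 0
    for j in np.flatnonzero(absent):
        obs[j] = 0.0
        p[j] = 1.0
        flags[j] = "variable absent everywhere"
    res = IndvalResult(
        list(t.variable_ids),
        [str(x) for x in labels],
        A,
        B,
        iv,
        [str(labels[i]) for i in best_idx],
        obs,
        p,
        n_used,
        seed,
        flags,
    )
    if adjustment == "bonferroni":
        res.p_adjusted = np.minimum(1.0, p * n_vars)  # type: ignore[attr-defined]
    return res
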