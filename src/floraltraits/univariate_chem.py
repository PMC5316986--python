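"""Per-analyte one-way ANOVA with post-hoc compact letter displays.

Concentration tables (e.g. polypeptide, total/essential amino acid and
sterol content of pollen in mg/g, a few replicates per plant species) are
compared analyte by analyte: a classical one-way ANOVA, then all pairwise
post-hoc comparisons (Tukey HSD by default, Bonferroni-adjusted pooled-t as
an option), summarised as letters — two groups share a letter exactly when
their comparison is not significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "LetterDisplay",
    "one_way_anova",
    "pairwise_posthoc",
    "posthoc_letters",
    "letters_from_nonsig",
    "analyte_summary",
]


@dataclass
class AnovaResult:
    SS_between: float
    SS_within: float
    df_between: int
    df_within: int
    F: float
    p: float
    group_labels: list[str]
    group_means: np.ndarray
    group_sd: np.ndarray
    group_n: np.ndarray
    flag: str | None = None

    def __str__(self) -> str:
        return f"F_{self.df_between},{self.df_within} = {self.F:.2f}, p = {self.p:.3g}"


def _split(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()), key=str)
    parts = [values[groups == g] for g in labels]
    return [str(g) for g in labels], parts


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA decomposition on raw replicate data."""
    labels, parts = _split(values, groups)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least two groups")
    if any(p.size < 2 for p in parts):
        raise ValueError("every group needs at least two replicates")
    all_vals = np.concatenate(parts)
    grand = all_vals.mean()
    means = np.array([p.mean() for p in parts])
    sds = np.array([p.std(ddof=1) for p in parts])
    ns = np.array([p.size for p in parts])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((p - m) ** 2).sum() for p, m in zip(parts, means)))
    df_b, df_w = a - 1, all_vals.size - a
    flag = None
    if ssw <= 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        flag = "zero within-group variance"
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(ssb, ssw, df_b, df_w, float(f), float(p),
                       labels, means, sds, ns, flag)


def pairwise_posthoc(values, groups, method: str = "tukey_hsd") -> pd.DataFrame:
    """All pairwise post-hoc p-values (adjusted) as a tidy frame."""
    labels, parts = _split(values, groups)
    rows = []
    if method == "tukey_hsd":
        res = stats.tukey_hsd(*parts)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                rows.append((labels[i], labels[j], float(res.pvalue[i, j])))
    elif method == "bonferroni_t":
        # pooled-variance t tests with Bonferroni adjustment
        a = len(labels)
        df_w = sum(p.size for p in parts) - a
        msw = sum(((p - p.mean()) ** 2).sum() for p in parts) / df_w
        k = a * (a - 1) // 2
        for i in range(a):
            for j in range(i + 1, a):
                se = np.sqrt(msw * (1 / parts[i].size + 1 / parts[j].size))
                tstat = (parts[i].mean() - parts[j].mean()) / se
                p_raw = 2 * stats.t.sf(abs(tstat), df_w)
                rows.append((labels[i], labels[j], float(min(1.0, p_raw * k))))
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return pd.DataFrame(rows, columns=["group1", "group2", "p_adjusted"])


@dataclass
class LetterDisplay:
    group_labels: list[str]  # ascending group means
    letters: dict[str, str]
    alpha: float
    method: str

    def __str__(self) -> str:
        return ", ".join(f"{g}: {self.letters[g]}" for g in self.group_labels)


def letters_from_nonsig(
    order: list[str], nonsig: set[frozenset]
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    ``order`` lists groups by ascending mean; ``nonsig`` holds the unordered
    pairs that are NOT significantly different. Each maximal run of mutually
    non-distinct groups gets one letter; two groups share a letter iff their
    pair is in ``nonsig``.
    """
    sig = [
        (g, h)
        for i, g in enumerate(order)
        for h in order[i + 1:]
        if frozenset((g, h)) not in nonsig
    ]
    columns: list[set[str]] = [set(order)]
    for g, h in sig:
        new_cols: list[set[str]] = []
        for col in columns:
            if g in col and h in col:
                new_cols.append(col - {g})
                new_cols.append(col - {h})
            else:
                new_cols.append(col)
        # absorb: dedupe, then drop columns properly contained in another
        dedup: list[set[str]] = []
        for s in new_cols:
            if s and s not in dedup:
                dedup.append(s)
        columns = [s for s in dedup if not any(s < t for t in dedup)]
    uniq = columns
    uniq.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for k, s in enumerate(uniq):
        for g in order:
            if g in s:
                letters[g].append(alphabet[k % len(alphabet)])
    return {g: "".join(v) for g, v in letters.items()}


def posthoc_letters(
    values, groups, alpha: float = 0.05, method: str = "tukey_hsd"
) -> LetterDisplay:
    """Compact letter display from all-pairwise post-hoc tests at ``alpha``.

    Letters are assigned deterministically in order of ascending group means.
    """
    labels, parts = _split(values, groups)
    means = {g: p.mean() for g, p in zip(labels, parts)}
    order = sorted(labels, key=lambda g: means[g])
    ph = pairwise_posthoc(values, groups, method)
    nonsig = {
        frozenset((r.group1, r.group2))
        for r in ph.itertuples()
        if r.p_adjusted > alpha
    }
    return LetterDisplay(order, letters_from_nonsig(order, nonsig), alpha, method)


def analyte_summary(
    values, groups, alpha: float = 0.05, method: str = "tukey_hsd"
) -> pd.DataFrame:
    """Per-group n / mean / sd / letters table plus ANOVA header columns."""
    res = one_way_anova(values, groups)
    disp = posthoc_letters(values, groups, alpha, method)
    return pd.DataFrame(
        {
            "group": res.group_labels,
            "n": res.group_n,
            "mean": res.group_means,
            "sd": res.group_sd,
            "letters": [disp.letters[g] for g in res.group_labels],
            "F": res.F,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p": res.p,
        }
    )
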