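"""Permutation-based one-way ANOVA across experimental groups.

Per protein, the classical one-way F statistic is computed on the available
(non-missing) log2 intensities.  Its p-value is estimated by permuting the
group labels: the same random relabelling is applied to every protein in a
permutation round, which preserves the between-protein correlation
structure of the data.  Relabellings that reproduce the observed partition
of samples into groups (including swaps of equal-sized groups, which leave
F unchanged) are rejected and redrawn, so the permutation p-value is

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)

with a minimum attainable value of 1 / (n_perm + 1).  Welch (unequal
variance) t-tests for the three pairwise contrasts are computed alongside,
as the group sizes are typically unbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lfq import GROUPS, LFQMatrix

CONTRASTS = (
    ("mutant", "control"),
    ("mutant_drug", "mutant"),
    ("mutant_drug", "control"),
)


def oneway_f(values: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Vectorised one-way F statistic, NaN-aware.

    Parameters
    ----------
    values : (n_proteins, n_samples) array with NaN for missing.
    membership : (n_samples, n_groups) one-hot group indicator.

    Returns NaN where fewer than two groups have data or all values are
    identical; +inf where between-group variance exists but within-group
    variance is zero.
    """
    valid = ~np.isnan(values)
    x = np.nan_to_num(values)
    n_g = valid.astype(float) @ membership          # per-protein group sizes
    s_g = x @ membership
    ss_g = (x * x) @ membership
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = np.where(n_g > 0, s_g / np.where(n_g > 0, n_g, 1), np.nan)
        n_total = n_g.sum(axis=1)
        grand = s_g.sum(axis=1) / n_total
        k_eff = (n_g > 0).sum(axis=1)
        ssb = np.nansum(n_g * (mean_g - grand[:, None]) ** 2, axis=1)
        ssw = np.nansum(ss_g - n_g * mean_g**2, axis=1)
        ssw = np.maximum(ssw, 0.0)                  # numerical guard
        df_b = k_eff - 1
        df_w = n_total - k_eff
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where((df_b < 1) | (df_w < 1), np.nan, f)
    zero_w = (ssw <= 1e-12 * np.maximum(ssb, 1.0)) & (df_b >= 1) & (df_w >= 1)
    f = np.where(zero_w & (ssb > 0), np.inf, f)
    f = np.where(zero_w & (ssb <= 1e-12), np.nan, f)   # totally degenerate
    return f


@dataclass
class DiffResult:
    """Per-protein differential statistics for the three-group design."""

    table: pd.DataFrame
    alpha: float
    n_perm: int
    seed: int
    n_skipped: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def permutation_anova(
    matrix: LFQMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> DiffResult:
    """Run the permutation ANOVA plus Welch pairwise contrasts.

    Proteins without at least two groups of >= 2 valid values are skipped
    (statistics set to NaN, never significant) and counted in
    ``result.n_skipped``.  Deterministic for a given ``seed``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; permutation p-values will be coarse", stacklevel=2)
    log2 = matrix.log2()
    values = log2.to_numpy(dtype=float)
    groups_present = [g for g in GROUPS if (matrix.groups == g).any()]
    if len(groups_present) < 2:
        raise ValueError("permutation ANOVA needs at least two groups")
    labels = matrix.groups.to_numpy()
    membership = np.stack([(labels == g).astype(float) for g in groups_present], axis=1)

    valid = ~np.isnan(values)
    per_group_valid = valid.astype(int) @ membership.astype(int)
    testable = (per_group_valid >= 2).sum(axis=1) >= 2
    n_skipped = int((~testable).sum())

    f_obs = oneway_f(values, membership)
    f_obs = np.where(testable, f_obs, np.nan)

    def partition(lab: np.ndarray) -> frozenset:
        blocks: dict = {}
        for i, g in enumerate(lab):
            blocks.setdefault(g, []).append(i)
        return frozenset(frozenset(v) for v in blocks.values())

    observed_partition = partition(labels)
    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    exceed = np.zeros(values.shape[0], dtype=np.int64)
    finite_obs = np.where(np.isnan(f_obs), np.inf, f_obs)  # NaN rows never accumulate
    for _ in range(n_perm):
        for _try in range(1000):
            order = rng.permutation(n_samples)
            if partition(labels[order]) != observed_partition:
                break
        f_perm = oneway_f(values[:, order], membership)
        exceed += np.nan_to_num(f_perm, nan=-np.inf) >= finite_obs
    p_anova = (1.0 + exceed) / (1.0 + n_perm)
    # degenerate or skipped rows: no evidence against the null
    degenerate = np.isnan(f_obs)
    p_anova = np.where(degenerate, 1.0, p_anova)
    p_anova = np.where(testable, p_anova, np.nan)

    out = pd.DataFrame(index=log2.index)
    for g in groups_present:
        cols = matrix.group_samples(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"mean_{g}"] = np.nanmean(values[:, [log2.columns.get_loc(c) for c in cols]], axis=1)
    out["F"] = f_obs
    out["p_anova"] = p_anova
    out["significant"] = testable & (p_anova < alpha)

    for a, b in CONTRASTS:
        key = f"p_welch_{a}_vs_{b}"
        if a in groups_present and b in groups_present:
            xa = values[:, [log2.columns.get_loc(c) for c in matrix.group_samples(a)]]
            xb = values[:, [log2.columns.get_loc(c) for c in matrix.group_samples(b)]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.ttest_ind(xa, xb, axis=1, equal_var=False, nan_policy="omit")
            out[key] = np.asarray(res.pvalue, dtype=float)
            out[f"log2fc_{a}_vs_{b}"] = out[f"mean_{a}"] - out[f"mean_{b}"]
        else:
            out[key] = np.nan
            out[f"log2fc_{a}_vs_{b}"] = np.nan

    notes = []
    if n_skipped:
        notes.append(f"{n_skipped} proteins skipped: fewer than two groups with >= 2 valid values")
    return DiffResult(table=out, alpha=alpha, n_perm=n_perm, seed=seed,
                      n_skipped=n_skipped, notes=notes)
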