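"""Simulate label-free proteomics (LFQ) matrices with planted structure.

The generative model works in log2 intensity space.  Each protein has a
baseline abundance; a planted *differential* subset shifts its mean in the
mutant group by +/- ``effect_size`` log2 units relative to control.  Within
the differential subset, a *restored* fraction has its drug-treated group
mean returned to the control mean (full pharmacological rescue); the rest
keep the mutant mean under drug.  Samples add i.i.d. Gaussian noise, values
go missing completely at random, and a fraction of extra rows carries the
quality flags (contaminant / reverse / only-identified-by-site) that the
MaxQuant proteinGroups dialect marks with "+".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..proteomics.lfq import FLAG_COLUMNS, GROUPS, LFQMatrix


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Parameters of one simulated three-group LFQ experiment."""

    n_proteins: int = 1000
    group_sizes: tuple[int, int, int] = (3, 3, 2)   # control, mutant, mutant_drug
    frac_differential: float = 0.2
    frac_up_among_differential: float = 0.9
    frac_restored_among_differential: float = 0.5
    effect_size: float = 2.0        # log2 units
    noise_sd: float = 0.3           # log2 units
    missing_rate: float = 0.0
    frac_flagged: float = 0.0
    baseline_mean: float = 25.0     # log2 units
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_up_among_differential",
                     "frac_restored_among_differential", "frac_flagged"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.group_sizes[0] < 2 or self.group_sizes[1] < 2:
            raise ValueError(
                "control and mutant groups need >= 2 samples: the valid-value "
                "filter and two-group contrasts are undefined below that"
            )
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")


@dataclass
class ProteomeTruth:
    """Planted labels: which proteins are differential, their direction, and
    which are restored by the drug."""

    differential: pd.Index
    direction: pd.Series          # "up" / "down", indexed by differential ids
    restored: pd.Index
    flagged: pd.Index

    def __post_init__(self) -> None:
        assert self.restored.isin(self.differential).all()


def simulate_proteome(spec: ProteomeSimSpec) -> tuple[LFQMatrix, ProteomeTruth]:
    """Draw one LFQ matrix plus its ground-truth labels.

    Planted set sizes are deterministic (``round(fraction * count)``);
    membership is sampled.  Flags are planted on non-differential rows only,
    so flag filtering never removes planted signal.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    n_c, n_m, n_d = spec.group_sizes
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein")

    n_diff = round(spec.frac_differential * n)
    n_up = round(spec.frac_up_among_differential * n_diff)
    n_restored = round(spec.frac_restored_among_differential * n_diff)

    perm = rng.permutation(n)
    diff_idx = np.sort(perm[:n_diff])
    up_mask = np.zeros(n_diff, dtype=bool)
    up_mask[rng.permutation(n_diff)[:n_up]] = True
    restored_idx = np.sort(diff_idx[rng.permutation(n_diff)[:n_restored]])

    n_flag = round(spec.frac_flagged * n)
    non_diff = np.setdiff1d(perm[n_diff:], [])
    if n_flag > len(non_diff):
        raise ValueError("frac_flagged too large: not enough non-differential rows to flag")
    flag_idx = np.sort(rng.permutation(non_diff)[:n_flag])

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    shift = np.zeros(n)
    shift[diff_idx] = np.where(up_mask, spec.effect_size, -spec.effect_size)

    mean_c = baseline
    mean_m = baseline + shift
    mean_d = mean_m.copy()
    mean_d[restored_idx] = mean_c[restored_idx]     # full rescue to control level

    means = np.concatenate([
        np.repeat(mean_c[:, None], n_c, axis=1),
        np.repeat(mean_m[:, None], n_m, axis=1),
        np.repeat(mean_d[:, None], n_d, axis=1),
    ], axis=1)
    log2 = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
    if spec.missing_rate > 0:
        log2[rng.random(size=log2.shape) < spec.missing_rate] = np.nan

    samples = (
        [f"control_{i+1}" for i in range(n_c)]
        + [f"mutant_{i+1}" for i in range(n_m)]
        + [f"mutant_drug_{i+1}" for i in range(n_d)]
    )
    groups = pd.Series(
        [GROUPS[0]] * n_c + [GROUPS[1]] * n_m + [GROUPS[2]] * n_d,
        index=samples, name="group",
    )
    intensities = pd.DataFrame(np.exp2(log2), index=ids, columns=samples)

    flags = pd.DataFrame(False, index=ids, columns=list(FLAG_COLUMNS))
    which = rng.integers(0, len(FLAG_COLUMNS), size=len(flag_idx))
    for j, row in zip(which, flag_idx):
        flags.iloc[row, j] = True

    matrix = LFQMatrix(
        intensities=intensities,
        groups=groups,
        flags=flags,
        gene_names=pd.Series([f"GENE{i}" for i in range(n)], index=ids, name="gene"),
    )
    truth = ProteomeTruth(
        differential=ids[diff_idx],
        direction=pd.Series(np.where(up_mask, "up", "down"), index=ids[diff_idx]),
        restored=ids[restored_idx],
        flagged=ids[flag_idx],
    )
    return matrix, truth
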