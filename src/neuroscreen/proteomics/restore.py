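"""Classify dysregulated proteins and the drug-restored subset.

A protein is *dysregulated* when the three-group ANOVA is significant and
the mutant-vs-control Welch contrast rejects at the same level; its
direction is the sign of the mutant - control log2 mean difference.  It is
*restored* when, in addition, the drug-vs-mutant contrast rejects with the
opposite sign and the drug-group mean has returned at least a configurable
fraction of the way back to the control mean.  The restored set is a
subset of the dysregulated set by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import DiffResult


@dataclass
class RestorationResult:
    """Dysregulated / restored classification with summary counts."""

    table: pd.DataFrame             # per-protein: direction, dysregulated, restored
    alpha: float
    restore_fraction: float
    drug_group_present: bool = True

    @property
    def dysregulated(self) -> pd.Index:
        return self.table.index[self.table["dysregulated"]]

    @property
    def restored(self) -> pd.Index:
        return self.table.index[self.table["restored"]]

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        return {
            "n_differential": int(t["dysregulated"].sum()),
            "n_up": int((t["dysregulated"] & (t["direction"] == "up")).sum()),
            "n_down": int((t["dysregulated"] & (t["direction"] == "down")).sum()),
            "n_restored": int(t["restored"].sum()),
        }


def classify_restoration(
    diff: DiffResult,
    alpha: float | None = None,
    restore_fraction: float = 0.5,
    require_anova: bool = True,
    min_abs_log2fc: float = 0.5,
) -> RestorationResult:
    """Apply the dysregulation + restoration rules to ANOVA/contrast output.

    Parameters
    ----------
    diff : result of :func:`~neuroscreen.proteomics.anova.permutation_anova`.
    alpha : significance level for every test involved (defaults to the
        level the ANOVA was run with).
    restore_fraction : minimum fraction of the mutant-vs-control shift that
        the drug must undo; 0.5 means the drug mean lies at least halfway
        back to control.
    require_anova : additionally gate dysregulation on the permutation
        ANOVA being significant (the study-level multigroup test); disable
        to classify on the two-group contrast alone.
    min_abs_log2fc : minimum |mutant - control| log2 shift for a protein
        to count as dysregulated (volcano-plot style floor; at n = 3 a
        bare p-cutoff admits statistically significant but minuscule
        shifts).  Set to 0 to classify on significance alone.

    If the drug group is absent, only dysregulation is reported.
    """
    if alpha is None:
        alpha = diff.alpha
    if not (0 <= restore_fraction <= 1):
        raise ValueError("restore_fraction must be in [0, 1]")
    t = diff.table
    fc_mc = t["log2fc_mutant_vs_control"]
    p_mc = t["p_welch_mutant_vs_control"]

    dys = (p_mc < alpha).fillna(False)
    if min_abs_log2fc > 0:
        dys &= (fc_mc.abs() >= min_abs_log2fc).fillna(False)
    if require_anova:
        dys &= t["significant"]
    direction = pd.Series(
        np.where(fc_mc > 0, "up", "down"), index=t.index
    ).where(dys, other=pd.NA)

    drug_present = "mean_mutant_drug" in t.columns and t["mean_mutant_drug"].notna().any()
    if drug_present:
        p_dm = t["p_welch_mutant_drug_vs_mutant"]
        fc_dm = t["log2fc_mutant_drug_vs_mutant"]
        reversal = (p_dm < alpha).fillna(False) & (np.sign(fc_dm) == -np.sign(fc_mc))
        returned = (
            (t["mean_mutant_drug"] - t["mean_control"]).abs()
            <= (1 - restore_fraction) * fc_mc.abs()
        ).fillna(False)
        restored = dys & t["significant"] & reversal & returned
    else:
        restored = pd.Series(False, index=t.index)

    out = pd.DataFrame(
        {
            "direction": direction,
            "dysregulated": dys,
            "restored": restored,
        },
        index=t.index,
    )
    return RestorationResult(
        table=out,
        alpha=alpha,
        restore_fraction=restore_fraction,
        drug_group_present=drug_present,
    )
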