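"""Protein-group matrix container and quality filters.

Reads and writes the MaxQuant ``proteinGroups.txt`` tabular dialect:
tab-separated, one row per protein group, sample intensities in
``LFQ intensity <sample>`` columns, and the quality-flag columns
("Potential contaminant", "Reverse", "Only identified by site") using "+"
for flagged and empty otherwise.  Zero or blank intensities denote missing
values — a zero LFQ intensity means "not quantified", and its logarithm is
undefined, so it is represented as NaN internally and never as -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "mutant", "mutant_drug")

FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")
_FLAG_HEADERS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_identified_by_site": "Only identified by site",
}
_LFQ_PREFIX = "LFQ intensity "


@dataclass
class LFQMatrix:
    """Proteins x samples intensity matrix with design and quality flags.

    ``intensities`` holds raw (linear-scale) LFQ values with NaN for
    missing; ``groups`` maps each sample column to its experimental group.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    flags: pd.DataFrame
    gene_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.intensities.columns) != set(self.groups.index):
            raise ValueError("groups must label exactly the sample columns of the matrix")
        self.groups = self.groups.reindex(self.intensities.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.intensities.fillna(0) < 0).any().any():
            raise ValueError("intensities must be non-negative")
        self.flags = self.flags.reindex(index=self.intensities.index, columns=list(FLAG_COLUMNS), fill_value=False)

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def log2(self) -> pd.DataFrame:
        """log2-transformed intensities; missing stays NaN (never -inf)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log2(self.intensities.where(self.intensities > 0))
        return values

    def subset(self, index: pd.Index) -> "LFQMatrix":
        return replace(
            self,
            intensities=self.intensities.loc[index],
            flags=self.flags.loc[index],
            gene_names=None if self.gene_names is None else self.gene_names.loc[index],
        )

    # -- proteinGroups dialect I/O ----------------------------------------

    def to_protein_groups(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.intensities.index)
        out["Protein IDs"] = self.intensities.index
        out["Gene names"] = self.gene_names if self.gene_names is not None else self.intensities.index
        for sample in self.samples:
            out[_LFQ_PREFIX + sample] = self.intensities[sample].fillna(0.0)
        for key, header in _FLAG_HEADERS.items():
            out[header] = np.where(self.flags[key], "+", "")
        out.to_csv(path, sep="\t", index=False)

    def write_design(self, path: str | Path) -> None:
        pd.DataFrame({"sample": self.samples, "group": self.groups.values}).to_csv(path, index=False)


def read_design(path: str | Path) -> pd.Series:
    """Read a sample -> group design CSV with columns ``sample, group``."""
    design = pd.read_csv(path)
    if not {"sample", "group"} <= set(design.columns):
        raise ValueError("design file needs 'sample' and 'group' columns")
    return pd.Series(design["group"].values, index=design["sample"].values, name="group")


def parse_protein_groups(path: str | Path, design: pd.Series | str | Path) -> LFQMatrix:
    """Parse a proteinGroups-dialect TSV into an :class:`LFQMatrix`.

    ``design`` maps sample name (as it appears after "LFQ intensity ") to
    group label; it may be the Series itself or a path to a design CSV.
    """
    if not isinstance(design, pd.Series):
        design = read_design(design)
    table = pd.read_csv(path, sep="\t")
    lfq_cols = [c for c in table.columns if c.startswith(_LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"no '{_LFQ_PREFIX}<sample>' columns found: not a proteinGroups-dialect file")
    samples = [c[len(_LFQ_PREFIX):] for c in lfq_cols]
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")

    index = pd.Index(table["Protein IDs"].astype(str), name="protein")
    intensities = table[lfq_cols].astype(float)
    intensities.columns = samples
    intensities.index = index
    intensities = intensities.where(intensities > 0)  # 0/blank -> missing

    flags = pd.DataFrame(False, index=index, columns=list(FLAG_COLUMNS))
    for key, header in _FLAG_HEADERS.items():
        if header in table.columns:
            flags[key] = (table[header].fillna("").astype(str).str.strip() == "+").values

    gene_names = None
    if "Gene names" in table.columns:
        gene_names = pd.Series(table["Gene names"].values, index=index, name="gene")

    return LFQMatrix(
        intensities=intensities,
        groups=design.loc[samples],
        flags=flags,
        gene_names=gene_names,
    )


def filter_flags(matrix: LFQMatrix) -> tuple[LFQMatrix, dict[str, int]]:
    """Drop contaminant / reverse / only-identified-by-site protein groups.

    Returns the filtered matrix and a removal report with per-flag counts
    (a row with several flags counts once per flag but is removed once).
    """
    any_flag = matrix.flags.any(axis=1)
    report = {key: int(matrix.flags[key].sum()) for key in FLAG_COLUMNS}
    report["removed"] = int(any_flag.sum())
    report["kept"] = int((~any_flag).sum())
    return matrix.subset(matrix.intensities.index[~any_flag]), report


def valid_value_filter(matrix: LFQMatrix, min_valid: int = 2) -> LFQMatrix:
    """Keep proteins quantified in at least ``min_valid`` samples of at
    least one experimental group."""
    valid = matrix.intensities.notna()
    counts = valid.T.groupby(matrix.groups).sum().T
    keep = (counts >= min_valid).any(axis=1)
    return matrix.subset(matrix.intensities.index[keep])
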