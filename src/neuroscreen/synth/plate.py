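"""Simulate 384-well phenotypic screening plates.

Two fidelities are offered.  *Table* fidelity draws per-well summary
measurements (nuclei count, TH and TUJ1 intensities and their ratio)
directly from the generative model, which makes Monte-Carlo studies of the
hit-calling rules cheap: thousands of wells simulate in milliseconds.
*Image* fidelity renders actual multi-channel fields per well (with ground
truth attached) and exists to exercise the image-quantification operators
end to end.

Each compound's effect is summarised by two numbers: ``viability_fraction``
(multiplies the number of surviving cells; 1 = inert) and
``th_ratio_multiplier`` (multiplies the TH/TUJ1 intensity ratio; >1 = the
phenotype the screen selects for).  Vehicle (DMSO) wells have both equal
to 1 by definition and provide the null distribution for hit calling.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import OpticsParams
from .render import FieldImage, render_field
from .truth import FieldGroundTruth, make_field_truth

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
WELLS_PER_PLATE = len(ROWS) * N_COLS  # 384

SCREEN_TABLE_COLUMNS = [
    "plate", "well", "row", "col", "compound", "dose_um", "replicate", "role",
    "nuclei_count", "tuj1_intensity", "th_intensity", "th_tuj1_ratio",
]


@dataclass(frozen=True)
class CompoundEffect:
    """Ground-truth effect model of one library compound."""

    compound: str
    viability_fraction: float = 1.0
    th_ratio_multiplier: float = 1.0
    dose_um: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.viability_fraction <= 1):
            raise ValueError("viability_fraction must be in (0, 1]")
        if self.th_ratio_multiplier <= 0:
            raise ValueError("th_ratio_multiplier must be positive")


@dataclass
class PlateSpec:
    """Layout and generative parameters of a screening run.

    Compounds are dispensed in ``n_replicates`` adjacent wells; vehicle
    control wells (``dmso_per_plate``) head every plate.  Runs larger than
    one plate spill onto additional 384-well plates automatically.
    """

    compounds: list[CompoundEffect] = dc_field(default_factory=list)
    n_replicates: int = 2
    dmso_per_plate: int = 16
    cells_per_well: int = 2000
    baseline_ratio: float = 0.30
    ratio_cv: float = 0.10
    nuclei_cv: float = 0.05
    tuj1_intensity: float = 500.0
    fields_per_well: int = 15
    plate_shape: tuple[int, int] = (len(ROWS), N_COLS)
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.plate_shape) != (len(ROWS), N_COLS):
            raise ValueError("only the standard 384-well layout (16 rows A-P x 24 columns) is supported")
        if self.dmso_per_plate < 2:
            raise ValueError("need at least 2 DMSO wells per plate for null statistics")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ratio_cv < 0 or self.nuclei_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.baseline_ratio <= 0 or self.cells_per_well <= 0:
            raise ValueError("baseline_ratio and cells_per_well must be positive")

    @property
    def n_plates(self) -> int:
        per_plate = WELLS_PER_PLATE - self.dmso_per_plate
        need = len(self.compounds) * self.n_replicates
        return max(1, math.ceil(need / per_plate))


def well_name(index: int) -> tuple[str, str, int]:
    """Map a 0-based within-plate index to (well id, row letter, column)."""
    row, col = divmod(index, N_COLS)
    return f"{ROWS[row]}{col + 1:02d}", ROWS[row], col + 1


def plate_layout(spec: PlateSpec) -> pd.DataFrame:
    """Assign every well of every plate a role, compound and replicate id."""
    records = []
    capacity = WELLS_PER_PLATE - spec.dmso_per_plate
    slots = [(plate + 1, idx) for plate in range(spec.n_plates) for idx in range(WELLS_PER_PLATE)]
    cursor = {p: 0 for p in range(1, spec.n_plates + 1)}

    def take(plate: int) -> tuple[int, int]:
        idx = cursor[plate]
        cursor[plate] += 1
        return plate, idx

    for plate in range(1, spec.n_plates + 1):
        for i in range(spec.dmso_per_plate):
            p, idx = take(plate)
            well, row, col = well_name(idx)
            records.append((p, well, row, col, "DMSO", 0.0, i + 1, "DMSO"))

    plate = 1
    for comp in spec.compounds:
        if cursor[plate] + spec.n_replicates > WELLS_PER_PLATE:
            plate += 1
        for rep in range(1, spec.n_replicates + 1):
            p, idx = take(plate)
            well, row, col = well_name(idx)
            records.append((p, well, row, col, comp.compound, comp.dose_um, rep, "compound"))

    # unused wells receive vehicle: extra DMSO wells tighten the null
    # estimate the 2-SD rule depends on
    for plate in range(1, spec.n_plates + 1):
        extra = 0
        while cursor[plate] < WELLS_PER_PLATE:
            p, idx = take(plate)
            well, row, col = well_name(idx)
            extra += 1
            records.append((p, well, row, col, "DMSO", 0.0, spec.dmso_per_plate + extra, "DMSO"))

    return pd.DataFrame(
        records,
        columns=["plate", "well", "row", "col", "compound", "dose_um", "replicate", "role"],
    )


def _well_rng(spec: PlateSpec, plate: int, well: str) -> np.random.Generator:
    """Independent, reproducible random substream for one well."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(plate, zlib.crc32(well.encode())))
    return np.random.default_rng(ss)


def simulate_plate_table(spec: PlateSpec) -> pd.DataFrame:
    """Draw per-well summary measurements for the whole run (table fidelity).

    nuclei_count ~ round(cells_per_well * viability * exp(N(0, nuclei_cv)))
    th_tuj1_ratio ~ baseline_ratio * multiplier * (1 + N(0, ratio_cv))
    th_intensity is derived so that th/tuj1 reproduces the ratio exactly.
    """
    layout = plate_layout(spec)
    effects = {c.compound: c for c in spec.compounds}
    rows = []
    for rec in layout.itertuples(index=False):
        rng = _well_rng(spec, rec.plate, f"{rec.well}:{rec.replicate}:{rec.compound}")
        if rec.role == "DMSO":
            viability, multiplier = 1.0, 1.0
        else:
            eff = effects[rec.compound]
            viability, multiplier = eff.viability_fraction, eff.th_ratio_multiplier
        lognoise = math.exp(rng.normal(0.0, spec.nuclei_cv)) if spec.nuclei_cv > 0 else 1.0
        nuclei = int(round(spec.cells_per_well * viability * lognoise))
        ratio_noise = 1.0 + rng.normal(0.0, spec.ratio_cv) if spec.ratio_cv > 0 else 1.0
        ratio = max(0.0, spec.baseline_ratio * multiplier * ratio_noise)
        tuj1 = spec.tuj1_intensity
        rows.append(rec._asdict() | {
            "nuclei_count": nuclei,
            "tuj1_intensity": tuj1,
            "th_intensity": ratio * tuj1,
            "th_tuj1_ratio": ratio,
        })
    return pd.DataFrame(rows, columns=SCREEN_TABLE_COLUMNS)


def simulate_plate_images(
    spec: PlateSpec,
    optics: OpticsParams | None = None,
    cells_per_field: int = 20,
    wells: list[tuple[int, str]] | None = None,
) -> dict[tuple[int, str], list[tuple[FieldImage, FieldGroundTruth]]]:
    """Render fields for (a subset of) wells of the run (image fidelity).

    The compound's viability fraction scales the number of cells per field
    and its TH multiplier scales the TH channel gain.  Ground truth is
    returned alongside every rendered field.
    """
    optics = optics or OpticsParams()
    layout = plate_layout(spec)
    effects = {c.compound: c for c in spec.compounds}
    if wells is not None:
        keys = set(wells)
        layout = layout[[tuple(k) in keys for k in zip(layout["plate"], layout["well"])]]

    out: dict[tuple[int, str], list[tuple[FieldImage, FieldGroundTruth]]] = {}
    for rec in layout.itertuples(index=False):
        rng = _well_rng(spec, rec.plate, f"img:{rec.well}:{rec.replicate}:{rec.compound}")
        if rec.role == "DMSO":
            viability, multiplier = 1.0, 1.0
        else:
            eff = effects[rec.compound]
            viability, multiplier = eff.viability_fraction, eff.th_ratio_multiplier
        fields = []
        for _ in range(spec.fields_per_well):
            n = max(0, int(round(cells_per_field * viability)))
            truth = make_field_truth(
                n_cells=n, optics=optics, seed=int(rng.integers(0, 2**31 - 1)),
                frac_th=0.5, neurites_per_cell=2,
            )
            image = render_field_with_gains(truth, {"th": multiplier})
            fields.append((image, truth))
        out[(rec.plate, rec.well)] = fields
    return out


def render_field_with_gains(truth: FieldGroundTruth, gains: dict[str, float]) -> FieldImage:
    """Render a field, then scale selected channels' signal above background.

    Used by the plate simulator to apply compound effects (e.g. a TH boost)
    without altering the planted geometry.
    """
    image = render_field(truth)
    bg = truth.optics.background_level
    for name, gain in gains.items():
        if gain != 1.0:
            ch = image.channels[name]
            image.channels[name] = np.maximum(bg + (ch - bg) * gain, 0.0)
    return image


def write_screen_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(SCREEN_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return table
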