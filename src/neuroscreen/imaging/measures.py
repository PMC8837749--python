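"""Per-field and per-cell quantification of neuronal phenotypes.

Implements the image-derived readouts of the screen and of the follow-up
neuropathology assays: nuclei counts and the TH/TUJ1 intensity ratio,
total neurite length by skeletonisation, the axon degeneration index
(fragmented spots per unit neurite area), per-cell aggregate counts,
marker-positive cell fractions, per-cell mean intensities, and the
GFP/mCherry tandem-reporter autophagic-flux puncta ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, skeletonize, white_tophat

from .params import SegmentationParams, resolve_threshold
from .segment import segment_nuclei
from .skeleton import per_seed_lengths, skeleton_length_px


@dataclass
class WellMeasurement:
    """Summary readouts of one well (across its fields)."""

    nuclei_count: int
    tuj1_intensity: float
    th_intensity: float
    th_tuj1_ratio: float            # NaN when undefined (no TUJ1 signal anywhere)
    n_fields: int

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.th_tuj1_ratio)


@dataclass
class NeuriteMeasure:
    """Total and per-cell neurite length in micrometres."""

    total_length: float
    per_cell_lengths: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return 0 if self.per_cell_lengths is None else len(self.per_cell_lengths)


@dataclass
class DegenerationIndex:
    """Fragmented-axon spots per 10^3 um^2 of neurite-positive area."""

    n_spots: int
    tuj1_area_um2: float
    index: float                    # NaN when no TUJ1+ area


@dataclass
class FluxResult:
    """Tandem-reporter puncta counts and GFP+/mCherry+ ratio per cell."""

    per_cell: pd.DataFrame          # index: cell label; n_gfp, n_mcherry, ratio
    excluded_cells: list[int] = field(default_factory=list)  # no mCherry+ puncta

    @property
    def mean_ratio(self) -> float:
        valid = self.per_cell["ratio"].dropna()
        return float(valid.mean()) if len(valid) else float("nan")


# ---------------------------------------------------------------------------

def _mean_over_own_mask(channel: np.ndarray, setting) -> tuple[float, bool]:
    """Mean supra-threshold intensity of a channel over its own mask.

    Returns (mean, mask_nonempty); an empty mask yields mean 0 (no signal).
    """
    thr = resolve_threshold(channel, setting)
    mask = channel > thr
    if not mask.any():
        return 0.0, False
    return float(channel[mask].mean()), True


def measure_well(
    fields: list,
    params: SegmentationParams | None = None,
    ratio_mode: str = "per_field",
) -> WellMeasurement:
    """Aggregate nuclei counts and the TH/TUJ1 intensity ratio over the
    fields of one well.

    Each channel is thresholded independently (its own mask) and the mean
    supra-threshold intensity taken.  ``per_field`` computes the ratio per
    field and averages across fields with TUJ1 signal; ``pooled`` averages
    the intensities across fields first and takes one ratio.  The ratio is
    NaN when no field has TUJ1 signal.
    """
    if not fields:
        raise ValueError("need at least one field")
    if ratio_mode not in ("per_field", "pooled"):
        raise ValueError("ratio_mode must be 'per_field' or 'pooled'")
    params = params or SegmentationParams()

    total_nuclei = 0
    tuj1_means: list[float] = []
    th_means: list[float] = []
    ratios: list[float] = []
    for fi in fields:
        _, n = segment_nuclei(fi["nuclei"], params)
        total_nuclei += n
        tuj1, tuj1_ok = _mean_over_own_mask(fi["tuj1"], params.neurite_threshold)
        th, _ = _mean_over_own_mask(fi["th"], params.neurite_threshold)
        tuj1_means.append(tuj1)
        th_means.append(th)
        if tuj1_ok:
            ratios.append(th / tuj1)

    tuj1_mean = float(np.mean(tuj1_means))
    th_mean = float(np.mean(th_means))
    if ratio_mode == "per_field":
        ratio = float(np.mean(ratios)) if ratios else float("nan")
    else:
        ratio = th_mean / tuj1_mean if tuj1_mean > 0 else float("nan")
    return WellMeasurement(
        nuclei_count=total_nuclei,
        tuj1_intensity=tuj1_mean,
        th_intensity=th_mean,
        th_tuj1_ratio=ratio,
        n_fields=len(fields),
    )


def measure_neurites(
    channel: np.ndarray,
    seeds: np.ndarray | None,
    params: SegmentationParams | None = None,
    pixel_size: float = 1.0,
) -> NeuriteMeasure:
    """Total (and per-cell) neurite length by skeletonising the marker mask.

    The mask is thresholded, skeletonised, and its arc length counted with
    diagonal steps weighted sqrt(2); connected pieces whose skeleton is no
    longer than ``branch_cutoff_px`` (isolated blebs, bare somata) are not
    neurites and are excluded.  With ``seeds`` given, each skeleton edge is
    credited to the nearest seed, yielding per-cell lengths.
    """
    params = params or SegmentationParams()
    thr = resolve_threshold(channel, params.neurite_threshold)
    mask = channel > thr
    if not mask.any():
        per_cell = np.zeros(len(seeds)) if seeds is not None and len(seeds) else None
        return NeuriteMeasure(total_length=0.0, per_cell_lengths=per_cell)

    skel = skeletonize(mask)
    # drop skeleton components too short to be neurites
    comp = cc_label(skel, connectivity=2)
    keep = np.zeros_like(skel, dtype=bool)
    for region in regionprops(comp):
        sub = comp[region.slice] == region.label
        if skeleton_length_px(sub) > params.branch_cutoff_px:
            keep[region.slice] |= sub
    skel = keep

    total = skeleton_length_px(skel) * pixel_size
    per_cell = None
    if seeds is not None and len(seeds):
        per_cell = per_seed_lengths(skel, np.asarray(seeds)) * pixel_size
    return NeuriteMeasure(total_length=float(total), per_cell_lengths=per_cell)


def degeneration_index(
    channel: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size: float = 1.0,
) -> DegenerationIndex:
    """Axon degeneration index: fragmented spots per 10^3 um^2 TUJ1+ area.

    Spots are connected supra-threshold components whose pixel area falls
    inside the configured window and whose skeleton is no longer than the
    branch cutoff (i.e. blebs, not intact neurites or somata).  The area
    denominator is the *total* marker-positive area of the field.
    """
    params = params or SegmentationParams()
    thr = resolve_threshold(channel, params.neurite_threshold)
    mask = channel > thr
    area_um2 = float(mask.sum()) * pixel_size**2
    if area_um2 == 0:
        return DegenerationIndex(n_spots=0, tuj1_area_um2=0.0, index=float("nan"))

    labels = cc_label(mask, connectivity=2)
    n_spots = 0
    for region in regionprops(labels):
        if not (params.spot_min_area <= region.area <= params.spot_max_area):
            continue
        sub_mask = labels[region.slice] == region.label
        if skeleton_length_px(skeletonize(sub_mask)) <= params.branch_cutoff_px:
            n_spots += 1
    return DegenerationIndex(
        n_spots=n_spots,
        tuj1_area_um2=area_um2,
        index=1e3 * n_spots / area_um2,
    )


def count_aggregates(
    channel: np.ndarray,
    rois: np.ndarray,
    params: SegmentationParams | None = None,
) -> pd.Series:
    """Count supra-threshold particles of at least ``aggregate_min_area``
    per cell ROI; particles are assigned to the ROI under their centroid.

    Returns a count per ROI label (zeros included).  An empty ROI image
    yields an empty series.
    """
    params = params or SegmentationParams()
    roi_ids = np.unique(rois)
    roi_ids = roi_ids[roi_ids > 0]
    counts = pd.Series(0, index=pd.Index(roi_ids, name="cell"), dtype=int)
    if len(roi_ids) == 0:
        return counts
    thr = resolve_threshold(channel, params.aggregate_threshold)
    mask = channel > thr
    if not mask.any():
        return counts
    labels = cc_label(mask, connectivity=2)
    for region in regionprops(labels):
        if region.area < params.aggregate_min_area:
            continue
        r, c = (int(round(x)) for x in region.centroid)
        owner = int(rois[r, c])
        if owner > 0:
            counts.loc[owner] += 1
    return counts


def group_mean_sem(counts: pd.Series) -> tuple[float, float]:
    """Mean and standard error of per-cell counts."""
    vals = counts.to_numpy(dtype=float)
    if len(vals) == 0:
        return float("nan"), float("nan")
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sem


def mean_intensity_per_cell(channel: np.ndarray, rois: np.ndarray) -> pd.Series:
    """Arithmetic mean pixel intensity of a channel inside each ROI label."""
    roi_ids = np.unique(rois)
    roi_ids = roi_ids[roi_ids > 0]
    means = ndimage.mean(channel, labels=rois, index=roi_ids) if len(roi_ids) else []
    return pd.Series(means, index=pd.Index(roi_ids, name="cell"), dtype=float)


def positive_fraction(
    channel: np.ndarray,
    nuclei_labels: np.ndarray,
    threshold: float,
) -> float:
    """Percent of cells whose mean marker intensity reaches ``threshold``."""
    means = mean_intensity_per_cell(channel, nuclei_labels)
    if len(means) == 0:
        return float("nan")
    return 100.0 * float((means >= threshold).mean())


def flux_ratio(
    gfp_channel: np.ndarray,
    mcherry_channel: np.ndarray,
    rois: np.ndarray,
    params: SegmentationParams | None = None,
) -> FluxResult:
    """GFP+/mCherry+ puncta ratio of the tandem autophagy reporter.

    mCherry+ puncta are detected on a white top-hat of the mCherry channel
    (prominence threshold + size window); each punctum is GFP+ when the
    GFP top-hat signal on its own footprint reaches the same prominence.
    The per-cell ratio n_gfp / n_mcherry is therefore <= 1 by construction
    (colocalisation is required).  Cells without any mCherry+ punctum have
    an undefined ratio and are excluded (listed in ``excluded_cells``).
    A ratio near 1 means autophagosomes are not maturing; a low ratio
    means efficient acidification, i.e. higher autophagic flux.
    """
    params = params or SegmentationParams()
    footprint = disk(3)
    tophat_m = white_tophat(mcherry_channel, footprint=footprint)
    tophat_g = white_tophat(gfp_channel, footprint=footprint)

    roi_ids = [int(i) for i in np.unique(rois) if i > 0]
    n_mch = dict.fromkeys(roi_ids, 0)
    n_gfp = dict.fromkeys(roi_ids, 0)

    mask = tophat_m > params.puncta_prominence
    labels = cc_label(mask, connectivity=2)
    for region in regionprops(labels):
        if not (params.puncta_min_area <= region.area <= params.puncta_max_area):
            continue
        r, c = (int(round(x)) for x in region.centroid)
        owner = int(rois[r, c])
        if owner <= 0:
            continue
        n_mch[owner] += 1
        footprint_mask = labels[region.slice] == region.label
        if float(tophat_g[region.slice][footprint_mask].max()) > params.puncta_prominence:
            n_gfp[owner] += 1

    rows = []
    excluded = []
    for cell in roi_ids:
        m, g = n_mch[cell], n_gfp[cell]
        if m == 0:
            excluded.append(cell)
            rows.append((cell, g, m, float("nan")))
        else:
            rows.append((cell, g, m, g / m))
    per_cell = pd.DataFrame(rows, columns=["cell", "n_gfp", "n_mcherry", "ratio"]).set_index("cell")
    return FluxResult(per_cell=per_cell, excluded_cells=excluded)
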