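"""Quantification operators: hand-built arrays and planted-field oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from neuroscreen.imaging import (
    SegmentationParams,
    cell_rois,
    count_aggregates,
    degeneration_index,
    flux_ratio,
    group_mean_sem,
    mean_intensity_per_cell,
    measure_neurites,
    measure_well,
    positive_fraction,
    segment_nuclei,
)
from neuroscreen.synth import make_field_truth, render_field


def _disc(img, center, radius, amp):
    rr, cc = draw_disk(center, radius, shape=img.shape)
    img[rr, cc] = amp
    return img


# ---------------------------------------------------------------- measure_well

def _field(tuj1_amp=80.0, th_amp=40.0, shape=(96, 96)):
    nuclei = _disc(np.zeros(shape), (30, 30), 5, 100.0)
    tuj1 = _disc(np.zeros(shape), (30, 30), 10, tuj1_amp) if tuj1_amp else np.zeros(shape)
    th = _disc(np.zeros(shape), (30, 30), 10, th_amp) if th_amp else np.zeros(shape)
    return {"nuclei": nuclei, "tuj1": tuj1, "th": th}


def test_well_ratio_flat_discs(params):
    m = measure_well([_field()], params)
    assert m.nuclei_count == 1
    assert m.tuj1_intensity == pytest.approx(80.0)
    assert m.th_intensity == pytest.approx(40.0)
    assert m.th_tuj1_ratio == pytest.approx(0.5)
    assert m.ratio_defined


def test_well_ratio_no_th_signal(params):
    m = measure_well([_field(th_amp=0.0)], params)
    assert m.th_tuj1_ratio == pytest.approx(0.0)


def test_well_ratio_undefined_without_tuj1(params):
    m = measure_well([_field(tuj1_amp=0.0, th_amp=0.0)], params)
    assert math.isnan(m.th_tuj1_ratio)
    assert not m.ratio_defined


def test_well_aggregates_fields(params):
    m = measure_well([_field(), _field(th_amp=80.0)], params)
    assert m.n_fields == 2
    assert m.nuclei_count == 2
    assert m.th_tuj1_ratio == pytest.approx((0.5 + 1.0) / 2)
    pooled = measure_well([_field(), _field(th_amp=80.0)], params, ratio_mode="pooled")
    assert pooled.th_tuj1_ratio == pytest.approx(60.0 / 80.0)


def test_well_requires_fields(params):
    with pytest.raises(ValueError):
        measure_well([], params)
    with pytest.raises(ValueError):
        measure_well([_field()], params, ratio_mode="bogus")


# ------------------------------------------------------------------- neurites

def test_neurite_length_straight_line(params):
    img = np.zeros((64, 128))
    img[30, 10:110] = 100.0                      # 100 px, 1 px wide
    m = measure_neurites(img, None, params, pixel_size=0.5)
    assert m.total_length == pytest.approx(99 * 0.5, rel=0.02)


def test_short_components_are_not_neurites(params):
    img = np.zeros((64, 64))
    img[30, 30:34] = 100.0                       # skeleton ~3 px <= cutoff 6
    m = measure_neurites(img, None, params, pixel_size=1.0)
    assert m.total_length == 0.0


def test_neurite_per_cell_assignment(params):
    img = np.zeros((64, 128))
    img[20, 5:55] = 100.0
    img[40, 75:125] = 100.0
    seeds = np.array([[20.0, 5.0], [40.0, 124.0]])
    m = measure_neurites(img, seeds, params, pixel_size=1.0)
    assert m.n_cells == 2
    assert m.per_cell_lengths[0] == pytest.approx(49.0)
    assert m.per_cell_lengths[1] == pytest.approx(49.0)
    assert m.per_cell_lengths.sum() == pytest.approx(m.total_length)


# ------------------------------------------------------- degeneration index

def test_degeneration_index_hand_example():
    """4 small spots + 2000 px^2 of intact arbor at 1 um/px:
    index = 1000 * 4 / 2024."""
    img = np.zeros((256, 256))
    for i in range(10):                          # intact arbor: 10 long lines
        img[20 + 10 * i, 20:220] = 100.0         # each 200 px, skeleton 199 > cutoff
    for j, (r, c) in enumerate([(150, 10), (170, 10), (190, 10), (210, 10)]):
        img[r:r + 2, c:c + 3] = 100.0            # 2x3 px spots (6 px^2)
    res = degeneration_index(img, SegmentationParams(), pixel_size=1.0)
    assert res.n_spots == 4
    assert res.tuj1_area_um2 == pytest.approx(10 * 200 + 4 * 6)
    assert res.index == pytest.approx(1e3 * 4 / 2024)


def test_degeneration_index_empty_field():
    res = degeneration_index(np.zeros((64, 64)), SegmentationParams(), 1.0)
    assert res.n_spots == 0
    assert math.isnan(res.index)


def test_degeneration_index_pixel_size_covariance():
    img = np.zeros((128, 128))
    img[20, 10:110] = 100.0
    img[60:62, 60:63] = 100.0
    at1 = degeneration_index(img, SegmentationParams(), pixel_size=1.0)
    at2 = degeneration_index(img, SegmentationParams(), pixel_size=2.0)
    assert at1.n_spots == at2.n_spots == 1
    assert at2.tuj1_area_um2 == pytest.approx(4 * at1.tuj1_area_um2)
    assert at2.index == pytest.approx(at1.index / 4)


# ------------------------------------------------------------- aggregates

def test_aggregate_counts_and_size_filter(params):
    rois = np.zeros((64, 64), dtype=int)
    rois[:, :32] = 1
    rois[:, 32:] = 2
    img = np.zeros((64, 64))
    _disc(img, (10, 10), 2, 100.0)               # cell 1
    _disc(img, (40, 20), 2, 100.0)               # cell 1
    _disc(img, (30, 50), 2, 100.0)               # cell 2
    img[55, 5] = 100.0                           # 1 px < aggregate_min_area (4)
    counts = count_aggregates(img, rois, params)
    assert counts.to_dict() == {1: 2, 2: 1}


def test_aggregates_empty_inputs(params):
    assert len(count_aggregates(np.zeros((32, 32)), np.zeros((32, 32), dtype=int), params)) == 0
    rois = np.ones((32, 32), dtype=int)
    counts = count_aggregates(np.zeros((32, 32)), rois, params)
    assert counts.to_dict() == {1: 0}


def test_group_mean_sem_hand_values():
    mean, sem = group_mean_sem(pd.Series([2.0, 4.0, 6.0]))
    assert mean == pytest.approx(4.0)
    assert sem == pytest.approx(2.0 / math.sqrt(3))
    mean1, sem1 = group_mean_sem(pd.Series([5.0]))
    assert mean1 == 5.0 and math.isnan(sem1)


# ------------------------------------------- marker fractions / intensities

def test_positive_fraction_half():
    labels = np.zeros((64, 64), dtype=int)
    rr, cc = draw_disk((20, 20), 4)
    labels[rr, cc] = 1
    rr, cc = draw_disk((40, 40), 4)
    labels[rr, cc] = 2
    channel = np.zeros((64, 64))
    channel[labels == 1] = 100.0
    assert positive_fraction(channel, labels, threshold=50.0) == pytest.approx(50.0)
    assert math.isnan(positive_fraction(channel, np.zeros_like(labels), 50.0))


def test_mean_intensity_per_cell_exact():
    labels = np.zeros((32, 32), dtype=int)
    labels[5:10, 5:10] = 1
    channel = np.full((32, 32), 3.0)
    channel[5:10, 5:10] = 17.0
    means = mean_intensity_per_cell(channel, labels)
    assert means.to_dict() == {1: 17.0}


# ----------------------------------------------------------------- flux

def _flux_scene():
    shape = (96, 96)
    rois = np.zeros(shape, dtype=int)
    rois[:, :48] = 1
    rois[48:, 48:] = 2                           # cell 2 has no puncta
    mch = np.zeros(shape)
    gfp = np.zeros(shape)
    _disc(mch, (20, 20), 2, 100.0)
    _disc(mch, (30, 35), 2, 100.0)
    _disc(gfp, (20, 20), 2, 100.0)               # colocalises with 1st punctum
    return gfp, mch, rois


def test_flux_ratio_half_and_exclusion(params):
    gfp, mch, rois = _flux_scene()
    res = flux_ratio(gfp, mch, rois, params)
    assert res.per_cell.loc[1, "n_mcherry"] == 2
    assert res.per_cell.loc[1, "n_gfp"] == 1
    assert res.per_cell.loc[1, "ratio"] == pytest.approx(0.5)
    assert res.excluded_cells == [2]
    assert res.mean_ratio == pytest.approx(0.5)


def test_flux_ratio_never_exceeds_one(params):
    gfp, mch, rois = _flux_scene()
    # GFP blazing everywhere still cannot beat colocalisation counting
    res = flux_ratio(np.full_like(gfp, 0.0) + gfp * 10, mch, rois, params)
    assert (res.per_cell["ratio"].dropna() <= 1.0).all()


def test_flux_zero_when_gfp_dark(params):
    _, mch, rois = _flux_scene()
    res = flux_ratio(np.zeros_like(mch), mch, rois, params)
    assert res.per_cell.loc[1, "ratio"] == pytest.approx(0.0)


# ----------------------------------------- planted-field oracle equivalence

def test_planted_field_counts_recovered(params, planted_field):
    truth, image = planted_field
    planted = truth.planted_counts()

    labels, n = segment_nuclei(image["nuclei"], params)
    assert n == planted["cells"]

    frac = positive_fraction(image["th"], labels, params.positive_marker_threshold)
    assert frac == pytest.approx(100.0 * planted["th_positive"] / planted["cells"])

    rois = cell_rois(labels, params.roi_radius)
    agg = count_aggregates(image["aggregate"], rois, params)
    assert int(agg.sum()) == planted["aggregates"]

    flux = flux_ratio(image["gfp"], image["mcherry"], rois, params)
    assert int(flux.per_cell["n_mcherry"].sum()) == planted["mcherry_puncta"]
    assert int(flux.per_cell["n_gfp"].sum()) == planted["gfp_puncta"]

    deg = degeneration_index(image["tuj1"], params, truth.optics.pixel_size)
    assert deg.n_spots == planted["fragments"]


def test_planted_neurite_length_within_tolerance(params, planted_field):
    truth, image = planted_field
    m = measure_neurites(image["tuj1"], truth.seeds(), params, truth.optics.pixel_size)
    planted = sum(c.total_neurite_length for c in truth.cells)
    assert m.total_length == pytest.approx(planted, rel=0.03)
    assert m.per_cell_lengths.sum() == pytest.approx(m.total_length)
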