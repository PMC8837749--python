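"""Nuclei segmentation and cell ROI construction."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

from .params import SegmentationParams, resolve_threshold


def segment_nuclei(
    nuclei_channel: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, int]:
    """Segment nuclei by global threshold + area filter, optionally
    splitting touching nuclei with a distance-transform watershed.

    Returns (label image, nuclei count).  An empty or featureless channel
    yields zero nuclei, not an error.
    """
    params = params or SegmentationParams()
    thr = resolve_threshold(nuclei_channel, params.nuclei_threshold)
    mask = nuclei_channel > thr
    mask = ndimage.binary_fill_holes(mask)
    # max_size semantics: removes objects of area <= value, keeping >= min_area
    mask = remove_small_objects(mask, max_size=params.nuclei_min_area - 1)
    if not mask.any():
        return np.zeros_like(nuclei_channel, dtype=np.int32), 0

    if params.split_touching:
        distance = ndimage.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance,
            min_distance=params.watershed_min_distance,
            labels=cc_label(mask),
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < params.nuclei_min_area)
    small = small[small > 0]
    if len(small):
        labels[np.isin(labels, small)] = 0
    labels, n = _relabel(labels)
    return labels, n


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out, len(ids)


def cell_rois(nuclei_labels: np.ndarray, radius: float = 10.0) -> np.ndarray:
    """Approximate per-cell regions by expanding nuclei labels outward up
    to ``radius`` pixels (nearest-nucleus assignment, regions disjoint)."""
    return expand_labels(nuclei_labels, distance=radius)
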