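"""Render ground-truth fields into multi-channel fluorescence images.

Channel model
-------------
``nuclei``    Hoechst-like stain: one 2-D Gaussian per cell.
``tuj1``      pan-neuronal marker: soma disc + neurite polylines + any
              planted degeneration fragments (isolated blebs).
``th``        dopaminergic marker: soma + neurites of TH+ cells only.
``marker``    generic nuclear/somatic marker (e.g. Ki67): soma discs of
              marker-positive cells.
``cellbody``  somatic stain whose amplitude is each cell's planted
              ``soma_intensity`` (for per-cell intensity measurements).
``aggregate`` protein-aggregate stain: small bright discs.
``gfp`` / ``mcherry``  tandem autophagy reporter puncta; GFP renders only
              the dual-positive (non-acidified) subset.

Signal is additive over objects on a constant background; optional Gaussian
blur, Poisson shot noise and Gaussian read noise follow, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .truth import (
    AGGREGATE_RADIUS,
    NUCLEUS_SIGMA,
    PUNCTA_RADIUS,
    SOMA_RADIUS,
    SPOT_RADIUS,
    FieldGroundTruth,
)

CHANNELS = ("nuclei", "tuj1", "th", "marker", "cellbody", "aggregate", "gfp", "mcherry")

NUCLEUS_AMP = 100.0
TUJ1_AMP = 80.0
TH_AMP = 90.0
MARKER_AMP = 90.0
MARKER_SOMA_RADIUS = 5.0   # soma discs of marker channels cover the whole nucleus mask
AGGREGATE_AMP = 120.0
PUNCTA_AMP = 100.0


@dataclass
class FieldImage:
    """Multi-channel raster of one microscope field."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def to_tiff(self, path: str | Path) -> None:
        """Write as a multi-page TIFF, one page per channel."""
        names = list(self.channels)
        stack = np.stack([self.channels[n].astype(np.float32) for n in names])
        tifffile.imwrite(
            path,
            stack,
            metadata={"axes": "CYX", "channels": names, "pixel_size_um": self.pixel_size},
        )

    @classmethod
    def from_tiff(cls, path: str | Path) -> "FieldImage":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        names = meta.get("channels") or [f"ch{i}" for i in range(stack.shape[0])]
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        return cls(channels=dict(zip(names, stack)), pixel_size=pixel_size)


def _add_gaussian(img: np.ndarray, center: tuple[float, float], sigma: float, amp: float) -> None:
    h, w = img.shape
    r0, c0 = center
    ext = int(np.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


def _add_disc(img: np.ndarray, center: tuple[float, float], radius: float, amp: float) -> None:
    h, w = img.shape
    r0, c0 = center
    ext = int(np.ceil(radius)) + 1
    rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    region = img[rlo:rhi, clo:chi]
    region[inside] = np.maximum(region[inside], amp)


def _add_polyline(img: np.ndarray, points_px: np.ndarray, amp: float) -> None:
    """Anti-aliased polyline; overlapping strokes take the maximum."""
    h, w = img.shape
    pts = np.round(points_px).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        np.maximum.at(img, (rr, cc), amp * val)


def render_field(truth: FieldGroundTruth) -> FieldImage:
    """Render every channel of a ground-truth field.

    Deterministic: the noise stream is seeded from ``truth.seed``, so the
    same truth always renders to bit-identical images.
    """
    optics = truth.optics
    ps = optics.pixel_size
    signal = {name: np.zeros(optics.shape, dtype=float) for name in CHANNELS}

    for cell in truth.cells:
        _add_gaussian(signal["nuclei"], cell.centroid, NUCLEUS_SIGMA, NUCLEUS_AMP)
        _add_disc(signal["tuj1"], cell.centroid, SOMA_RADIUS, TUJ1_AMP)
        _add_disc(signal["cellbody"], cell.centroid, SOMA_RADIUS, cell.soma_intensity)
        for poly_um in cell.neurites:
            _add_polyline(signal["tuj1"], poly_um / ps, TUJ1_AMP)
        if cell.is_th:
            _add_disc(signal["th"], cell.centroid, MARKER_SOMA_RADIUS, TH_AMP)
            for poly_um in cell.neurites:
                _add_polyline(signal["th"], poly_um / ps, TH_AMP)
        if cell.is_marker_positive:
            _add_disc(signal["marker"], cell.centroid, MARKER_SOMA_RADIUS, MARKER_AMP)
        for center in cell.fragment_centers:
            _add_disc(signal["tuj1"], tuple(center), SPOT_RADIUS, TUJ1_AMP)
        for center in cell.aggregate_centers:
            _add_disc(signal["aggregate"], tuple(center), AGGREGATE_RADIUS, AGGREGATE_AMP)
        for i, center in enumerate(cell.mcherry_centers):
            _add_disc(signal["mcherry"], tuple(center), PUNCTA_RADIUS, PUNCTA_AMP)
            if i < cell.n_gfp_puncta:
                _add_disc(signal["gfp"], tuple(center), PUNCTA_RADIUS, PUNCTA_AMP)

    rng = np.random.default_rng(truth.seed)
    out: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        img = signal[name]
        if optics.psf_sigma > 0:
            img = gaussian_filter(img, optics.psf_sigma)
        img = img + optics.background_level
        if optics.shot_noise:
            img = rng.poisson(np.maximum(img, 0)).astype(float)
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
        out[name] = np.maximum(img, 0.0)
    return FieldImage(channels=out, pixel_size=ps)
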