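"""Ground-truth field models for synthetic neuronal cultures.

A :class:`FieldGroundTruth` records every planted object — somata, neurite
polylines, degeneration fragments, aggregates, and tandem-reporter puncta —
so that downstream image measurements can be validated against exactly known
quantities.  Object geometry is frozen at construction time; rendering adds
only optics (blur, background, noise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .optics import OpticsParams

# Rendered object geometry (pixels).  These are the smallest footprints that
# survive the segmentation operators downstream.
NUCLEUS_SIGMA = 3.0
SOMA_RADIUS = 3.0
SPOT_RADIUS = 1.4       # degeneration fragments
AGGREGATE_RADIUS = 1.4
PUNCTA_RADIUS = 1.4

_EDGE_MARGIN = 14.0      # keep somata clear of the field border
_DRAW_MARGIN = 3.0       # everything rendered stays this far inside bounds


def polyline_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (k, 2) array of vertices."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class CellGroundTruth:
    """One planted cell: soma position, identity flags and planted objects.

    Neurite polylines are stored in micrometres (field coordinates); object
    centres are stored in pixels.  The first ``n_gfp_puncta`` entries of
    ``mcherry_centers`` are dual-positive (rendered in both reporter
    channels); the remainder are mCherry-only, i.e. acidified autolysosomes
    in which GFP is quenched.
    """

    centroid: tuple[float, float]                 # (row, col) px
    is_th: bool = False
    is_marker_positive: bool = False
    soma_intensity: float = 50.0
    neurites: list[np.ndarray] = field(default_factory=list)   # um coords
    fragment_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    aggregate_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    mcherry_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    n_gfp_puncta: int = 0

    def __post_init__(self) -> None:
        self.fragment_centers = np.atleast_2d(np.asarray(self.fragment_centers, dtype=float)).reshape(-1, 2)
        self.aggregate_centers = np.atleast_2d(np.asarray(self.aggregate_centers, dtype=float)).reshape(-1, 2)
        self.mcherry_centers = np.atleast_2d(np.asarray(self.mcherry_centers, dtype=float)).reshape(-1, 2)
        if self.n_gfp_puncta < 0:
            raise ValueError("puncta counts must be non-negative")
        if self.n_gfp_puncta > self.n_mcherry_puncta:
            raise ValueError(
                "n_gfp_puncta cannot exceed n_mcherry_puncta: every GFP+ "
                "punctum of the tandem reporter is also mCherry+"
            )

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_centers)

    @property
    def n_aggregates(self) -> int:
        return len(self.aggregate_centers)

    @property
    def n_mcherry_puncta(self) -> int:
        return len(self.mcherry_centers)

    @property
    def total_neurite_length(self) -> float:
        """Summed arc length of all neurites, micrometres."""
        return float(sum(polyline_length(p) for p in self.neurites))


@dataclass
class FieldGroundTruth:
    """All planted cells of one field plus the optics used to render it."""

    cells: list[CellGroundTruth]
    optics: OpticsParams
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.optics.shape
        for cell in self.cells:
            r, c = cell.centroid
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"cell centroid {cell.centroid} outside field bounds {self.optics.shape}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def seeds(self) -> np.ndarray:
        """Cell centroids as an (n, 2) pixel array (seed points for assignment)."""
        return np.array([c.centroid for c in self.cells], dtype=float).reshape(-1, 2)

    def planted_counts(self) -> dict[str, int]:
        return {
            "cells": self.n_cells,
            "th_positive": sum(c.is_th for c in self.cells),
            "marker_positive": sum(c.is_marker_positive for c in self.cells),
            "fragments": sum(c.n_fragments for c in self.cells),
            "aggregates": sum(c.n_aggregates for c in self.cells),
            "mcherry_puncta": sum(c.n_mcherry_puncta for c in self.cells),
            "gfp_puncta": sum(c.n_gfp_puncta for c in self.cells),
        }

    # -- JSON sidecar ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "optics": {
                "shape": list(self.optics.shape),
                "pixel_size": self.optics.pixel_size,
                "background_level": self.optics.background_level,
                "noise_sd": self.optics.noise_sd,
                "psf_sigma": self.optics.psf_sigma,
                "shot_noise": self.optics.shot_noise,
            },
            "cells": [
                {
                    "centroid": list(c.centroid),
                    "is_th": c.is_th,
                    "is_marker_positive": c.is_marker_positive,
                    "soma_intensity": c.soma_intensity,
                    "neurites": [p.tolist() for p in c.neurites],
                    "fragment_centers": c.fragment_centers.tolist(),
                    "aggregate_centers": c.aggregate_centers.tolist(),
                    "mcherry_centers": c.mcherry_centers.tolist(),
                    "n_gfp_puncta": c.n_gfp_puncta,
                }
                for c in self.cells
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FieldGroundTruth":
        payload = json.loads(Path(path).read_text())
        o = payload["optics"]
        optics = OpticsParams(
            shape=tuple(o["shape"]),
            pixel_size=o["pixel_size"],
            background_level=o["background_level"],
            noise_sd=o["noise_sd"],
            psf_sigma=o["psf_sigma"],
            shot_noise=o["shot_noise"],
        )
        cells = [
            CellGroundTruth(
                centroid=tuple(c["centroid"]),
                is_th=c["is_th"],
                is_marker_positive=c["is_marker_positive"],
                soma_intensity=c["soma_intensity"],
                neurites=[np.asarray(p, dtype=float) for p in c["neurites"]],
                fragment_centers=np.asarray(c["fragment_centers"], dtype=float).reshape(-1, 2),
                aggregate_centers=np.asarray(c["aggregate_centers"], dtype=float).reshape(-1, 2),
                mcherry_centers=np.asarray(c["mcherry_centers"], dtype=float).reshape(-1, 2),
                n_gfp_puncta=c["n_gfp_puncta"],
            )
            for c in payload["cells"]
        ]
        return cls(cells=cells, optics=optics, seed=payload["seed"])


def _as_range(value: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return int(lo), int(hi)
    return int(value), int(value)


def _sample_count(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    lo, hi = _as_range(value)
    if lo == hi:
        return lo
    return int(rng.integers(lo, hi + 1))


def _place_points(
    rng: np.random.Generator,
    center: tuple[float, float],
    n: int,
    r_min: float,
    r_max: float,
    min_sep: float,
    shape: tuple[int, int],
    forbidden: np.ndarray | None = None,
    clearance: float = 0.0,
    max_tries: int = 400,
) -> np.ndarray:
    """Rejection-sample ``n`` points in an annulus around ``center``.

    Points keep ``min_sep`` between themselves, stay inside the field margin
    and, when a ``forbidden`` boolean mask is given, keep ``clearance``
    pixels away from any set pixel of it.
    """
    h, w = shape
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        ok = False
        for _try in range(max_tries):
            radius = math.sqrt(rng.uniform(r_min**2, r_max**2))
            theta = rng.uniform(0, 2 * math.pi)
            r = center[0] + radius * math.sin(theta)
            c = center[1] + radius * math.cos(theta)
            if not (_DRAW_MARGIN <= r < h - _DRAW_MARGIN and _DRAW_MARGIN <= c < w - _DRAW_MARGIN):
                continue
            if placed and np.min(np.hypot(*(np.array(placed) - (r, c)).T)) < min_sep:
                continue
            if forbidden is not None and clearance > 0:
                rr0 = int(max(0, math.floor(r - clearance)))
                rr1 = int(min(h, math.ceil(r + clearance) + 1))
                cc0 = int(max(0, math.floor(c - clearance)))
                cc1 = int(min(w, math.ceil(c + clearance) + 1))
                if forbidden[rr0:rr1, cc0:cc1].any():
                    continue
            placed.append((r, c))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place {n} objects with separation {min_sep} in "
                f"annulus [{r_min}, {r_max}] around {center}; reduce counts "
                "or enlarge the placement radius"
            )
    return np.array(placed, dtype=float).reshape(-1, 2)


# the 8 principal lattice directions (45 degree multiples) and their step length
_DIRECTIONS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def _grow_neurite(
    rng: np.random.Generator,
    start_px: tuple[float, float],
    length_um: float,
    pixel_size: float,
    shape: tuple[int, int],
    n_segments: int = 3,
    max_tries: int = 60,
) -> np.ndarray:
    """Random polyline of roughly the requested arc length, inside the field.

    Segments run along the 8 principal lattice directions (45-degree
    multiples) with integer-pixel vertices, so the rasterised chain length
    equals the recorded arc length exactly — digitisation of arbitrary
    angles would otherwise bias chain-code length estimates by several
    percent.  Consecutive segments turn by at most 45 degrees.  Returns
    vertices in micrometres; if no in-bounds path is found the target
    length is shortened geometrically until one fits.
    """
    h, w = shape
    margin = _DRAW_MARGIN
    target_px = length_um / pixel_size
    start = (int(round(start_px[0])), int(round(start_px[1])))
    for attempt in range(max_tries):
        d = int(rng.integers(0, 8))
        pts = [start]
        seg_px = target_px / n_segments
        ok = True
        for _ in range(n_segments):
            dr, dc = _DIRECTIONS[d]
            step = math.hypot(dr, dc)
            n_steps = max(3, int(round(seg_px / step)))
            r = pts[-1][0] + n_steps * dr
            c = pts[-1][1] + n_steps * dc
            if not (margin <= r < h - margin and margin <= c < w - margin):
                ok = False
                break
            pts.append((r, c))
            d = (d + int(rng.integers(-1, 2))) % 8
        if ok:
            return np.array(pts, dtype=float) * pixel_size
        if attempt % 10 == 9:
            target_px *= 0.75
    raise RuntimeError("could not fit a neurite inside the field")


def _dilate2(mask: np.ndarray) -> np.ndarray:
    """Binary dilation by a 5x5 square (2-pixel clearance)."""
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, structure=np.ones((5, 5), dtype=bool))


def rasterize_polyline_px(points_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean occupancy mask of a polyline (1-px Bresenham strokes)."""
    from skimage.draw import line

    mask = np.zeros(shape, dtype=bool)
    pts = np.round(points_px).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def make_field_truth(
    n_cells: int,
    optics: OpticsParams | None = None,
    seed: int = 0,
    frac_th: float = 0.5,
    frac_marker_positive: float = 0.2,
    neurites_per_cell: int | tuple[int, int] = 2,
    neurite_length_um: float | tuple[float, float] = (40.0, 70.0),
    n_fragments: int | tuple[int, int] = 0,
    n_aggregates: int | tuple[int, int] = 0,
    n_mcherry_puncta: int | tuple[int, int] = 0,
    n_gfp_puncta: int | tuple[int, int] | None = None,
    soma_intensity: float | tuple[float, float] = 50.0,
    min_separation_px: float = 26.0,
    object_radius_px: float = 10.0,
) -> FieldGroundTruth:
    """Sample a ground-truth field of ``n_cells`` well-separated neurons.

    Cell bodies are placed with at least ``min_separation_px`` between
    centroids so that every planted sub-cellular object (aggregates, puncta,
    all within ``object_radius_px`` of their soma) unambiguously belongs to
    its cell.  Degeneration fragments are placed clear of every rendered
    neurite so they form isolated spots in the pan-neuronal channel.

    ``n_gfp_puncta`` defaults to all mCherry puncta (no quenching); it is
    clipped per cell so the reporter invariant GFP+ <= mCherry+ always holds.
    """
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)
    h, w = optics.shape

    if 2 * object_radius_px + 4 > min_separation_px:
        raise ValueError("object_radius_px too large for the requested cell separation")

    # soma positions
    centroids: list[tuple[float, float]] = []
    for _ in range(n_cells):
        for _try in range(2000):
            r = rng.uniform(_EDGE_MARGIN, h - _EDGE_MARGIN)
            c = rng.uniform(_EDGE_MARGIN, w - _EDGE_MARGIN)
            if not centroids or np.min(np.hypot(*(np.array(centroids) - (r, c)).T)) >= min_separation_px:
                centroids.append((r, c))
                break
        else:
            raise RuntimeError(f"could not place {n_cells} cells at separation {min_separation_px}")

    # neurite arbors + occupancy mask (somata included) for fragment clearance
    occupancy = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    all_neurites: list[list[np.ndarray]] = []
    for r, c in centroids:
        occupancy |= (rr - r) ** 2 + (cc - c) ** 2 <= (SOMA_RADIUS + 1) ** 2
    for r, c in centroids:
        k = _sample_count(rng, neurites_per_cell)
        arbors = []
        own_soma = (rr - r) ** 2 + (cc - c) ** 2 <= (SOMA_RADIUS + 3) ** 2
        for _ in range(k):
            if isinstance(neurite_length_um, (tuple, list)):
                length = rng.uniform(*neurite_length_um)
            else:
                length = float(neurite_length_um)
            # candidate arbors must keep clear of existing structures:
            # near-parallel strokes would fuse into one ribbon and break the
            # planted-length bookkeeping
            best, best_overlap = None, None
            for _attempt in range(40):
                poly = _grow_neurite(rng, (r, c), length, optics.pixel_size, optics.shape)
                stroke = rasterize_polyline_px(poly / optics.pixel_size, optics.shape)
                test = stroke & ~own_soma
                overlap = int((_dilate2(test) & occupancy).sum())
                if overlap == 0:
                    best = poly
                    break
                if best_overlap is None or overlap < best_overlap:
                    best, best_overlap = poly, overlap
            arbors.append(best)
            occupancy |= rasterize_polyline_px(best / optics.pixel_size, optics.shape)
        all_neurites.append(arbors)

    cells: list[CellGroundTruth] = []
    for (r, c), arbors in zip(centroids, all_neurites):
        frag = _place_points(
            rng, (r, c), _sample_count(rng, n_fragments),
            r_min=SOMA_RADIUS + 5, r_max=min_separation_px,
            min_sep=2 * SPOT_RADIUS + 3, shape=optics.shape,
            forbidden=occupancy, clearance=SPOT_RADIUS + 2.5,
            max_tries=1200,
        )
        for fr, fc in frag:  # future fragments must also avoid this one
            occupancy |= (rr - fr) ** 2 + (cc - fc) ** 2 <= (SPOT_RADIUS + 2) ** 2
        agg = _place_points(
            rng, (r, c), _sample_count(rng, n_aggregates),
            r_min=0.0, r_max=object_radius_px - 2,
            min_sep=2 * AGGREGATE_RADIUS + 2, shape=optics.shape,
        )
        n_mch = _sample_count(rng, n_mcherry_puncta)
        puncta = _place_points(
            rng, (r, c), n_mch,
            r_min=2.0, r_max=object_radius_px,
            min_sep=2 * PUNCTA_RADIUS + 2, shape=optics.shape,
        )
        if n_gfp_puncta is None:
            n_gfp = n_mch
        else:
            n_gfp = min(_sample_count(rng, n_gfp_puncta), n_mch)
        if isinstance(soma_intensity, (tuple, list)):
            intensity = float(rng.uniform(*soma_intensity))
        else:
            intensity = float(soma_intensity)
        cells.append(
            CellGroundTruth(
                centroid=(r, c),
                is_th=bool(rng.random() < frac_th),
                is_marker_positive=bool(rng.random() < frac_marker_positive),
                soma_intensity=intensity,
                neurites=arbors,
                fragment_centers=frag,
                aggregate_centers=agg,
                mcherry_centers=puncta,
                n_gfp_puncta=n_gfp,
            )
        )

    return FieldGroundTruth(cells=cells, optics=optics, seed=int(rng.integers(0, 2**31 - 1)))
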