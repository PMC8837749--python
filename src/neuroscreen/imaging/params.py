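"""Segmentation and detection parameters for field quantification.

Every intensity threshold can be the string ``"auto"`` (Otsu's global
threshold on the channel) or a fixed number in image intensity units.
Areas are in square pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

Threshold = float | str


@dataclass(frozen=True)
class SegmentationParams:
    nuclei_threshold: Threshold = "auto"
    nuclei_min_area: int = 20
    split_touching: bool = True
    watershed_min_distance: int = 5

    neurite_threshold: Threshold = "auto"
    branch_cutoff_px: float = 6.0       # skeletons at or below this length are spots, not neurites

    spot_min_area: int = 3
    spot_max_area: int = 60

    aggregate_threshold: Threshold = "auto"
    aggregate_min_area: int = 4

    puncta_min_area: int = 2
    puncta_max_area: int = 40
    puncta_prominence: float = 30.0

    positive_marker_threshold: float = 50.0
    roi_radius: float = 10.0            # cell ROI = nuclei labels expanded this far

    def __post_init__(self) -> None:
        for name in ("nuclei_min_area", "aggregate_min_area", "spot_min_area", "puncta_min_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spot_max_area <= self.spot_min_area:
            raise ValueError("spot_max_area must exceed spot_min_area")
        if self.puncta_max_area <= self.puncta_min_area:
            raise ValueError("puncta_max_area must exceed puncta_min_area")


def resolve_threshold(channel: np.ndarray, setting: Threshold) -> float:
    """Turn a threshold setting into a number for this channel.

    ``"auto"`` uses Otsu; a featureless (constant) channel gets an
    unreachable threshold so the mask comes out empty instead of arbitrary.
    """
    if setting == "auto":
        if np.ptp(channel) <= 1e-9:
            return np.inf
        return float(threshold_otsu(channel))
    return float(setting)
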