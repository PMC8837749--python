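"""Acquisition parameters for synthetic microscope fields."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class OpticsParams:
    """Geometry and noise model of a simulated wide-field acquisition.

    Attributes
    ----------
    shape : (int, int)
        Field size in pixels (rows, cols). Minimum 64 x 64.
    pixel_size : float
        Lateral sampling in micrometres per pixel.
    background_level : float
        Constant background intensity (arbitrary units) added to every channel.
    noise_sd : float
        Standard deviation of Gaussian read noise added after shot noise.
    psf_sigma : float
        Sigma (pixels) of an optional Gaussian blur applied to each channel
        before noise; 0 disables it.
    shot_noise : bool
        Apply Poisson shot noise on the (blurred) signal before read noise.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.65
    background_level: float = 10.0
    noise_sd: float = 2.0
    psf_sigma: float = 0.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.shape) != 2 or min(self.shape) < 64:
            raise ValueError("field must be at least 64 x 64 pixels")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")

    def noise_free(self) -> "OpticsParams":
        """Copy of these optics with all stochastic corruption disabled."""
        return replace(self, noise_sd=0.0, shot_noise=False)
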