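"""Core data containers shared across the pipeline.

Coordinate convention: images are 2D arrays indexed ``[row, col]``. Pixel
indices are 0-based; the *center* of pixel ``(i, j)`` sits at physical
position ``x = (j + 0.5) * a``, ``y = (i + 0.5) * a`` nanometers, where ``a``
is the pixel size. All continuous positions are reported in nm in this frame,
with x running along columns and y along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class NanofishError(Exception):
    """Base class for errors raised by this package."""


class PositionError(NanofishError):
    """An emitter or query point lies outside the valid region."""


class EdgeError(NanofishError):
    """A region of interest would cross the image boundary."""


class UnfittableSpotError(NanofishError):
    """A spot has no signal above background and cannot be fitted."""


@dataclass(frozen=True)
class FrameGeometry:
    """Camera frame geometry: size in pixels and physical pixel pitch.

    ``pixel_size_nm`` is the back-projected pixel size *a* in the sample
    plane (nm per pixel).
    """

    width_px: int
    height_px: int
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("frame must be at least 8x8 pixels")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def width_nm(self) -> float:
        return self.width_px * self.pixel_size_nm

    @property
    def height_nm(self) -> float:
        return self.height_px * self.pixel_size_nm

    def x_edges_nm(self) -> np.ndarray:
        """Physical x coordinates of the column boundaries (length w+1)."""
        return np.arange(self.width_px + 1) * self.pixel_size_nm

    def y_edges_nm(self) -> np.ndarray:
        return np.arange(self.height_px + 1) * self.pixel_size_nm


@dataclass(frozen=True)
class OpticsModel:
    """Emission wavelength (nm) and objective numerical aperture."""

    wavelength_nm: float
    numerical_aperture: float

    def __post_init__(self) -> None:
        if not (300 <= self.wavelength_nm <= 900):
            raise ValueError("wavelength_nm must lie in [300, 900]")
        if not (0 < self.numerical_aperture <= 1.7):
            raise ValueError("numerical_aperture must lie in (0, 1.7]")


@dataclass(frozen=True)
class NoiseModel:
    """Camera and background model.

    ``background_photons_per_px`` is the *mean* background level b in
    photons/pixel (realized as Poisson counts); ``read_noise_e`` is the
    Gaussian read noise standard deviation in electrons (applied on the
    count scale after gain); ``gain_counts_per_photon`` converts detected
    photons to camera counts.
    """

    background_photons_per_px: float = 0.0
    read_noise_e: float = 0.0
    gain_counts_per_photon: float = 1.0

    def __post_init__(self) -> None:
        if self.background_photons_per_px < 0:
            raise ValueError("background must be non-negative")
        if self.read_noise_e < 0:
            raise ValueError("read noise must be non-negative")
        if self.gain_counts_per_photon <= 0:
            raise ValueError("gain must be positive")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class Emitter:
    """A point source at a continuous position with an expected photon yield."""

    x_nm: float
    y_nm: float
    photons: float
    channel_id: str = "A"

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be positive")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm])


@dataclass
class Image:
    """A 2D grid of camera counts with acquisition metadata."""

    data: np.ndarray
    frame: FrameGeometry
    optics: OpticsModel
    camera: NoiseModel = field(default_factory=NoiseModel)
    channel_id: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (self.frame.height_px, self.frame.width_px):
            raise ValueError(
                f"data shape {self.data.shape} does not match frame "
                f"({self.frame.height_px}, {self.frame.width_px})"
            )


@dataclass
class ROI:
    """A square pixel block cut from a parent image.

    ``anchor`` is the (row, col) index of the top-left pixel in the parent
    image, so physical coordinates of ROI pixels remain expressed in the
    parent frame.
    """

    data: np.ndarray
    anchor: tuple[int, int]
    pixel_size_nm: float
    gain: float = 1.0
    optics: Optional[OpticsModel] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("ROI must be a square 2D block")
        if self.data.shape[0] < 5:
            raise ValueError("ROI side must be at least 5 px")

    @property
    def side(self) -> int:
        return self.data.shape[0]

    def x_edges_nm(self) -> np.ndarray:
        """Column boundaries in parent-frame nm (length side+1)."""
        j0 = self.anchor[1]
        return (j0 + np.arange(self.side + 1)) * self.pixel_size_nm

    def y_edges_nm(self) -> np.ndarray:
        i0 = self.anchor[0]
        return (i0 + np.arange(self.side + 1)) * self.pixel_size_nm

    def x_centers_nm(self) -> np.ndarray:
        j0 = self.anchor[1]
        return (j0 + np.arange(self.side) + 0.5) * self.pixel_size_nm

    def y_centers_nm(self) -> np.ndarray:
        i0 = self.anchor[0]
        return (i0 + np.arange(self.side) + 0.5) * self.pixel_size_nm

    def perimeter_values(self) -> np.ndarray:
        """Counts of the outermost ring of pixels, row-major order."""
        d = self.data
        return np.concatenate([d[0, :], d[-1, :], d[1:-1, 0], d[1:-1, -1]])

    def contains_nm(self, x_nm: float, y_nm: float) -> bool:
        xe, ye = self.x_edges_nm(), self.y_edges_nm()
        return xe[0] <= x_nm <= xe[-1] and ye[0] <= y_nm <= ye[-1]
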