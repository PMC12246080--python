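"""Core data containers shared by the STED and MINFLUX pipelines.

Coordinate convention (fixed throughout the package): images are indexed
``grid[row, col]`` with the origin at the top-left corner; the *center* of
pixel ``(i, j)`` sits at physical position ``x = (j + 0.5) * pitch`` and
``y = (i + 0.5) * pitch`` in nanometers.  Coordinates in files are always
nanometers; pixel indices are never serialized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PixelImage:
    """A 2D photon-count raster with physical pixel pitch.

    Parameters
    ----------
    grid : ndarray
        2D array of intensities (photon counts; may be negative after
        background subtraction).
    pitch : float
        Pixel pitch in nm (STED rasters in this study use 20 nm).
    channel : str, optional
        Species / channel label (e.g. ``"MT-ND1"``).
    origin_nm : tuple of float
        Physical position of the top-left image corner, used by images
        derived from point data so that absolute positions survive.
    """

    grid: np.ndarray
    pitch: float
    channel: str | None = None
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError(f"image grid must be 2D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image grid contains non-finite values")
        if not self.pitch > 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def with_grid(self, grid: np.ndarray) -> "PixelImage":
        """Return a copy carrying a new grid but the same geometry."""
        return PixelImage(grid=grid, pitch=self.pitch, channel=self.channel,
                          origin_nm=self.origin_nm)


@dataclass
class SpotCallParams:
    """Parameters of the STED spot-calling and mask pipeline.

    Defaults implement the study's published analysis settings: 25 nm FWHM
    smoothing, 210 nm FWHM background estimate, spots at local maxima that
    are at least 100 nm from the image edge and reach at least 3 counts
    after background subtraction; the mitochondrial mask grows 6 px disks
    (120 nm at 20 nm pitch) around maxima, drops components below 200 px,
    applies a 5x5 majority vote (threshold 12.5 of 25) and fills holes
    below 200 px.
    """

    smooth_fwhm: float = 25.0          # nm
    background_fwhm: float = 210.0     # nm
    edge_margin: float = 100.0         # nm
    min_counts: float = 3.0            # counts after background subtraction
    disk_radius_px: int = 6
    min_component_px: int = 200
    majority_kernel: int = 5           # side length in px
    majority_threshold: float = 12.5
    min_hole_px: int = 200

    def __post_init__(self) -> None:
        for name in ("smooth_fwhm", "background_fwhm", "edge_margin",
                     "min_counts", "disk_radius_px", "min_component_px",
                     "majority_kernel", "majority_threshold", "min_hole_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.background_fwhm > self.smooth_fwhm:
            raise ValueError("background_fwhm must exceed smooth_fwhm")


@dataclass
class Spot:
    """A detected mRNA/protein/mtDNA spot (local maximum)."""

    x_nm: float
    y_nm: float
    row: int
    col: int
    peak_value: float          # counts after background subtraction
    channel: str | None = None
    fwhm_nm: float | None = None


@dataclass
class SpotSet:
    """Detected spots of one channel together with the source geometry."""

    spots: list[Spot]
    shape: tuple[int, int]
    pitch: float
    channel: str | None = None
    source: str | None = None

    def __len__(self) -> int:
        return len(self.spots)

    def positions_nm(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in nm."""
        if not self.spots:
            return np.empty((0, 2))
        return np.array([[s.x_nm, s.y_nm] for s in self.spots])

    def pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) pixel indices."""
        if not self.spots:
            return np.empty((0, 2), dtype=int)
        return np.array([[s.row, s.col] for s in self.spots], dtype=int)


@dataclass
class MitoMask:
    """Binary mitochondrial-area mask congruent with its source image."""

    grid: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * (self.pitch / 1000.0) ** 2


@dataclass
class DistanceSummary:
    """Order statistics plus a Gaussian KDE of a distance sample.

    The KDE bandwidth follows the 1D Scott rule, h = sigma_hat * n**(-1/5)
    with sigma_hat the sample standard deviation (ddof=1).  For samples with
    fewer than two points or zero spread the KDE fields are ``None``.
    """

    distances: np.ndarray
    median: float
    q1: float
    q3: float
    bandwidth: float | None = None
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(np.asarray(self.distances).size)

    def as_dict(self) -> dict:
        """JSON-serializable summary (omits the KDE curve)."""
        return {
            "n": self.n,
            "median": float(self.median),
            "q1": float(self.q1),
            "q3": float(self.q3),
            "bandwidth": None if self.bandwidth is None else float(self.bandwidth),
        }


@dataclass
class DensityResult:
    """Spot count inside the mitochondrial mask, per area."""

    count: int
    area_px: int
    area_um2: float
    per_um2: float
    per_px: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
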