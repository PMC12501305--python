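"""Cartesian imaging grid with circular support mask.

The reconstruction unknowns live on a p x p lattice of pixel centres
spanning [-r, +r]^2 (pixel pitch 2r/p, centres offset half a pixel from the
edges). Pixels are ordered row-major with the image convention: row index
runs down the +y -> -y direction, column index runs along -x -> +x, so the
pixel array displays correctly with ``imshow``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImagingGrid:
    """Square pixel lattice for the scatterer map.

    Parameters
    ----------
    n_side : int
        Pixels per side (p = q).
    imaging_radius : float
        Half-width of the imaged square and radius of the circular support
        mask, metres.
    """

    n_side: int = 64
    imaging_radius: float = 0.08

    def __post_init__(self) -> None:
        if self.n_side < 1:
            raise ValueError(f"n_side must be >= 1, got {self.n_side}")
        if self.imaging_radius <= 0:
            raise ValueError("imaging_radius must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.n_side * self.n_side

    @property
    def pitch(self) -> float:
        """Pixel pitch 2r/p, metres."""
        return 2.0 * self.imaging_radius / self.n_side

    @property
    def axis_coords(self) -> np.ndarray:
        """The p ascending pixel-centre coordinates shared by both axes."""
        r, p = self.imaging_radius, self.n_side
        return -r + (np.arange(p) + 0.5) * self.pitch

    def pixel_centers(self) -> np.ndarray:
        """(p*q, 2) array of (x, y) centres in row-major pixel order."""
        c = self.axis_coords
        xx, yy = np.meshgrid(c, c[::-1])  # row 0 at +y (image convention)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def mask(self) -> np.ndarray:
        """Boolean (p*q,) support mask: centre within the imaging radius."""
        xy = self.pixel_centers()
        return np.hypot(xy[:, 0], xy[:, 1]) <= self.imaging_radius

    def pixel_index(self, x: float, y: float) -> int:
        """Row-major index of the pixel whose centre is nearest (x, y)."""
        c = self.axis_coords
        j = int(np.argmin(np.abs(c - x)))
        i = int(np.argmin(np.abs(c[::-1] - y)))
        return i * self.n_side + j

    def index_to_xy(self, k: int) -> tuple[float, float]:
        """Centre coordinates of row-major pixel ``k``."""
        i, j = divmod(int(k), self.n_side)
        c = self.axis_coords
        return float(c[j]), float(c[::-1][i])
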