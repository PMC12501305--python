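"""Linear inverse model: SVD pseudo-inverse back-projection.

The stacked measurement vector S relates to the per-pixel scatterer map P
through the sensitivity matrix, S = J P. With more measurements than
pixels J is tall, and the minimum-norm least-squares solution is

    P = J^+ S,    J^+ = V diag(1/s_i) U^H

from the singular value decomposition J = U diag(s_i) V^H, with singular
values below ``rtol * s_max`` treated as zero. The Hermitian transpose is
essential for complex data: it makes J^+ the true Moore-Penrose inverse
and P the least-squares minimizer of ||J P - S||_2.

The solved map is complex; images display its magnitude, on a linear or a
peak-normalized dB scale, optionally bilinearly upsampled for presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import maximum_filter

from .forward import SensitivityMatrix, stack_measurements
from .grid import ImagingGrid

DB_FLOOR = -120.0
"""Background value (dB) assigned to masked or zero pixels in dB images."""


class InverseModelError(ValueError):
    """Invalid inverse-model input (shape mismatch, rank collapse...)."""


def _as_matrix(J: SensitivityMatrix | np.ndarray) -> np.ndarray:
    return J.matrix if isinstance(J, SensitivityMatrix) else np.asarray(J)


def default_rtol(J: SensitivityMatrix | np.ndarray) -> float:
    """max(m, n) * machine epsilon — the conventional pseudo-inverse cutoff."""
    m = _as_matrix(J)
    return max(m.shape) * np.finfo(float).eps


def pinv_svd(J: SensitivityMatrix | np.ndarray, rtol: float | None = None) -> np.ndarray:
    """Moore-Penrose pseudo-inverse via SVD with relative tolerance cutoff.

    Singular values below ``rtol * s_max`` are zeroed (dropped from the
    reconstruction subspace). ``rtol=None`` uses :func:`default_rtol`.
    """
    m = _as_matrix(J)
    if not np.all(np.isfinite(m)):
        raise InverseModelError("sensitivity matrix contains non-finite entries")
    if rtol is None:
        rtol = default_rtol(m)
    if rtol < 0:
        raise InverseModelError("rtol must be >= 0")
    u, s, vh = np.linalg.svd(m, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise InverseModelError("matrix has no nonzero singular values")
    keep = s >= rtol * s[0]
    if not np.any(keep):
        raise InverseModelError(
            f"all singular values fall below rtol*s_max = {rtol * s[0]:.3e}"
        )
    inv_s = np.zeros_like(s)
    inv_s[keep] = 1.0 / s[keep]
    return (vh.conj().T * inv_s) @ u.conj().T


@dataclass(frozen=True)
class ScattererMap:
    """Complex per-pixel backscatter solution P on an imaging grid."""

    values: np.ndarray
    grid: ImagingGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex).ravel()
        if v.size != self.grid.n_pixels:
            raise InverseModelError(
                f"solution length {v.size} != grid pixel count {self.grid.n_pixels}"
            )
        object.__setattr__(self, "values", v)

    def as_image_array(self) -> np.ndarray:
        """Complex p x p array in image orientation."""
        return self.values.reshape(self.grid.n_side, self.grid.n_side)


def solve_scatterer_map(
    s_vec: np.ndarray,
    J: SensitivityMatrix,
    rtol: float | None = None,
    pinv: np.ndarray | None = None,
) -> ScattererMap:
    """Least-squares scatterer map P = J^+ S for a stacked measurement vector.

    ``s_vec`` may be the stacked vector or the (M, N) sinogram matrix, which
    is stacked with the same ordering the sensitivity matrix uses. Pass a
    precomputed ``pinv`` to reuse one factorization across many solves.
    """
    s_vec = np.asarray(s_vec)
    if s_vec.ndim == 2:
        s_vec = stack_measurements(s_vec)
    if s_vec.size != J.matrix.shape[0]:
        raise InverseModelError(
            f"measurement vector length {s_vec.size} != J row count "
            f"{J.matrix.shape[0]} (rows: {J.row_ordering}; cols: {J.col_ordering})"
        )
    if pinv is None:
        pinv = pinv_svd(J, rtol)
    return ScattererMap(pinv @ s_vec, J.grid)


@dataclass(frozen=True)
class ReconstructedImage:
    """Real-valued magnitude image of a scatterer map."""

    values: np.ndarray
    grid: ImagingGrid
    scale: str = "linear"
    presentation: np.ndarray | None = field(default=None, compare=False)


def assemble_image(
    P: ScattererMap, grid: ImagingGrid | None = None, scale: str = "linear"
) -> ReconstructedImage:
    """Magnitude image |P| on the grid, linear or peak-normalized dB.

    Pixels outside the circular support mask carry the background value
    (0 on the linear scale, the dB floor on the dB scale).
    """
    grid = P.grid if grid is None else grid
    if scale not in ("linear", "db"):
        raise InverseModelError(f"scale must be 'linear' or 'db', got {scale!r}")
    mag = np.abs(P.values).astype(float)
    mask = grid.mask()
    if scale == "linear":
        img = np.where(mask, mag, 0.0)
    else:
        peak = mag[mask].max() if np.any(mask) else 0.0
        if peak == 0.0:
            warnings.warn("all-zero scatterer map; dB image set to the floor value")
            img = np.full(mag.shape, DB_FLOOR)
        else:
            with np.errstate(divide="ignore"):
                db = 20.0 * np.log10(mag / peak)
            img = np.where(mask, np.maximum(db, DB_FLOOR), DB_FLOOR)
    return ReconstructedImage(img.reshape(grid.n_side, grid.n_side), grid, scale)


def interpolate_presentation(
    img: ReconstructedImage, n_out: int = 2401
) -> ReconstructedImage:
    """Bilinearly upsample the pixel-centre lattice to n_out x n_out.

    The output lattice spans the same pixel-centre extent; values at the
    original nodes are preserved by the bilinear interpolant.
    """
    p = img.grid.n_side
    if n_out < p:
        raise InverseModelError(f"n_out ({n_out}) must be >= grid side ({p})")
    c = img.grid.axis_coords
    # rows run +y -> -y; flip to ascending for the interpolator
    interp = RegularGridInterpolator(
        (c, c), img.values[::-1, :].T, method="linear", bounds_error=True
    )
    out_c = np.linspace(c[0], c[-1], n_out)
    xx, yy = np.meshgrid(out_c, out_c[::-1])
    big = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(n_out, n_out)
    return ReconstructedImage(img.values, img.grid, img.scale, presentation=big)


def localize_peaks(
    img: ReconstructedImage, k: int = 1, min_separation: int = 2
) -> list[tuple[int, int]]:
    """Strongest local maxima of the image, as (row, col) pixel coordinates.

    A peak must strictly exceed its 8 neighbours; peaks are greedily
    selected in decreasing magnitude with a minimum Chebyshev separation.
    Returns fewer than ``k`` peaks (with a warning) if the image does not
    contain them.
    """
    if k < 1:
        raise InverseModelError("k must be >= 1")
    v = img.values
    padded = np.pad(v, 1, constant_values=-np.inf)
    neigh = maximum_filter(padded, size=3)[1:-1, 1:-1]
    # strict local max: value equals the 3x3 max and exceeds all neighbours
    strict = np.zeros_like(v, dtype=bool)
    rows, cols = np.nonzero(v >= neigh)
    for r, c in zip(rows, cols):
        window = padded[r : r + 3, c : c + 3].copy()
        window[1, 1] = -np.inf
        if v[r, c] > window.max():
            strict[r, c] = True
    cand = np.argwhere(strict)
    if cand.size == 0:
        if k > 0:
            warnings.warn("no strict local maxima found; returning empty peak list")
        return []
    order = np.argsort(-v[cand[:, 0], cand[:, 1]])
    chosen: list[tuple[int, int]] = []
    for i in order:
        r, c = int(cand[i, 0]), int(cand[i, 1])
        if all(max(abs(r - r0), abs(c - c0)) >= min_separation for r0, c0 in chosen):
            chosen.append((r, c))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(f"found only {len(chosen)} of {k} requested peaks")
    return chosen


def peak_positions_xy(
    img: ReconstructedImage, k: int = 1, min_separation: int = 2
) -> list[tuple[float, float]]:
    """Cartesian (x, y) centres of the strongest peaks, metres."""
    out = []
    for r, c in localize_peaks(img, k, min_separation):
        out.append(img.grid.index_to_xy(r * img.grid.n_side + c))
    return out
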