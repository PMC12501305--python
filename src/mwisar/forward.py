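"""Frequency-domain bistatic forward model and sensitivity matrix.

A scene of point scatterers inside a water-filled container is interrogated
by a fixed transmit/receive antenna pair while the scene rotates on a
turntable. For each frequency ``f`` and rotation step the complex
transmission coefficient (S21) of a single scatterer with radar
cross-section ``sigma`` is

    S = A0 * sqrt(G(delta1) * G(delta2) * sigma) / (d1 * d2)
          * exp(+j * (omega * sqrt(eps_r) / c0) * (d1 + d2))

where ``A0 = sqrt(Z0*Pt/4pi) * lambda/(4pi)`` is the effective aperture of
the receive antenna, ``d1``/``d2`` the target-to-Rx / target-to-Tx
distances, ``delta1``/``delta2`` the off-boresight angles and ``eps_r`` the
relative permittivity of the coupling medium. Scatterers superpose
linearly (Born-type approximation, single scattering only).

The sinogram is the M x N matrix of these responses over the frequency
sweep (rows) and turntable positions (columns); the sensitivity matrix
stacks the unit-RCS response of every imaging-grid pixel into the columns
of the linear system solved by the inverse model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import get_window

from .constants import C0, PHASE_SIGN, Z0
from .geometry import AntennaConfig, GeometryError, ScenePoint, antenna_positions
from .grid import ImagingGrid


class ForwardModelError(ValueError):
    """Invalid forward-model configuration or scene."""


@dataclass(frozen=True)
class FrequencySweep:
    """Uniform frequency grid f_start..f_stop with n_points bins."""

    f_start: float
    f_stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0 < self.f_start < self.f_stop:
            raise ForwardModelError("need 0 < f_start < f_stop")
        if self.n_points < 2:
            raise ForwardModelError("need at least 2 frequency points")

    @property
    def frequencies(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_stop, self.n_points)

    @property
    def df(self) -> float:
        return (self.f_stop - self.f_start) / (self.n_points - 1)

    @property
    def bandwidth(self) -> float:
        return self.f_stop - self.f_start


@dataclass(frozen=True)
class AngularSweep:
    """Uniform turntable positions covering [0, 360) degrees."""

    n_positions: int

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ForwardModelError("need at least 1 angular position")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_positions) * (360.0 / self.n_positions)


@dataclass(frozen=True)
class Scatterer:
    """Point scatterer: position in the scene plane and RCS in m^2."""

    position: ScenePoint
    rcs: float = 1.0

    def __post_init__(self) -> None:
        if self.rcs <= 0:
            raise ForwardModelError(f"rcs must be > 0, got {self.rcs}")


@dataclass(frozen=True)
class Scene:
    """Point-scatterer scene in a homogeneous coupling medium."""

    scatterers: tuple[Scatterer, ...]
    medium_eps_r: float = 80.0
    container_radius: float = 0.085
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scatterers", tuple(self.scatterers))
        if np.real(self.medium_eps_r) <= 0:
            raise ForwardModelError("medium_eps_r must have positive real part")
        if self.container_radius <= 0:
            raise ForwardModelError("container_radius must be > 0")
        for s in self.scatterers:
            if s.position.radius >= self.container_radius:
                raise ForwardModelError(
                    f"scatterer at radius {s.position.radius} m lies outside "
                    f"the container (radius {self.container_radius} m)"
                )


def gain_isotropic() -> Callable[[np.ndarray], np.ndarray]:
    """Unit gain in all directions."""

    def g(delta: np.ndarray) -> np.ndarray:
        return np.ones_like(np.asarray(delta, dtype=float))

    g.label = "isotropic"  # type: ignore[attr-defined]
    return g


def gain_cosine_power(n: float) -> Callable[[np.ndarray], np.ndarray]:
    """cos^n pattern, clipped to zero behind the antenna."""
    if n < 0:
        raise ForwardModelError("cosine power must be >= 0")

    def g(delta: np.ndarray) -> np.ndarray:
        return np.clip(np.cos(np.asarray(delta, dtype=float)), 0.0, None) ** n

    g.label = f"cosine_power({n})"  # type: ignore[attr-defined]
    return g


def gain_gaussian(beamwidth_deg: float) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian beam with the given half-power beamwidth (degrees)."""
    if beamwidth_deg <= 0:
        raise ForwardModelError("beamwidth must be > 0")
    bw = np.deg2rad(beamwidth_deg)

    def g(delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        return np.exp(-4.0 * np.log(2.0) * (d / bw) ** 2)

    g.label = f"gaussian({beamwidth_deg} deg)"  # type: ignore[attr-defined]
    return g


@dataclass(frozen=True)
class ForwardConfig:
    """Acquisition configuration: antennas, sweeps, power and gain model."""

    antenna: AntennaConfig
    sweep: FrequencySweep
    rotation: AngularSweep
    tx_power: float = 1.0
    z0: float = Z0
    gain: Callable[[np.ndarray], np.ndarray] = field(default_factory=gain_isotropic)

    def __post_init__(self) -> None:
        if self.tx_power <= 0 or self.z0 <= 0:
            raise ForwardModelError("tx_power and z0 must be > 0")


@dataclass(frozen=True)
class Sinogram:
    """Complex S21 matrix: frequency rows x turntable-angle columns."""

    values: np.ndarray
    sweep: FrequencySweep
    rotation: AngularSweep
    medium_eps_r: float = 80.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        object.__setattr__(self, "values", v)
        expected = (self.sweep.n_points, self.rotation.n_positions)
        if v.shape != expected:
            raise ForwardModelError(f"sinogram shape {v.shape} != {expected}")
        if not np.all(np.isfinite(v)):
            raise ForwardModelError("sinogram contains non-finite entries")

    @property
    def n_measurements(self) -> int:
        return self.values.size


def stack_measurements(values: np.ndarray) -> np.ndarray:
    """Vectorize an (M, N) measurement matrix into the shared row ordering.

    Angle-major blocks with frequency varying fastest: element (m, n) lands
    at index n*M + m. The sensitivity matrix uses the identical ordering, so
    ``J @ weights`` and a stacked sinogram are directly comparable.
    """
    values = np.asarray(values)
    return values.flatten(order="F")


def unstack_measurements(vec: np.ndarray, n_freq: int) -> np.ndarray:
    """Inverse of :func:`stack_measurements`."""
    vec = np.asarray(vec)
    if vec.size % n_freq:
        raise ForwardModelError("vector length not divisible by n_freq")
    return vec.reshape(n_freq, vec.size // n_freq, order="F")


@dataclass(frozen=True)
class RangeProfileSet:
    """Per-angle complex range (delay) profiles after range compression."""

    values: np.ndarray
    delays: np.ndarray
    angles_deg: np.ndarray
    window: str

    @property
    def delay_bin(self) -> float:
        return float(self.delays[1] - self.delays[0])


def effective_aperture(tx_power: float, wavelength: float, z0: float = Z0) -> float:
    """Effective aperture A0 = sqrt(Z0*Pt/4pi) * lambda/(4pi) of the receiver."""
    if tx_power <= 0 or wavelength <= 0 or z0 <= 0:
        raise ForwardModelError("tx_power, wavelength and z0 must be > 0")
    return np.sqrt(z0 * tx_power / (4.0 * np.pi)) * wavelength / (4.0 * np.pi)


def _rotate_xy(xy: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Rotate points by adding ``angles_deg`` to their azimuth.

    xy: (K, 2); angles_deg: (N,). Returns (N, K, 2). In cartesian terms the
    azimuth convention (phi from +y toward +x) makes this the clockwise
    rotation x' = x cos + y sin, y' = -x sin + y cos.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))[:, None]
    x, y = xy[:, 0][None, :], xy[:, 1][None, :]
    ca, sa = np.cos(a), np.sin(a)
    return np.stack([x * ca + y * sa, -x * sa + y * ca], axis=-1)


def _response_kernel(
    xy: np.ndarray,
    rcs: np.ndarray,
    eps_r: float,
    cfg: ForwardConfig,
) -> np.ndarray:
    """Complex response of each scatterer at each (frequency, angle).

    Returns an (M, N, K) array for K scatterers at cartesian positions
    ``xy`` (already in unrotated scene coordinates); the turntable rotation
    of the sweep is applied internally.
    """
    tx, rx = antenna_positions(cfg.antenna)
    rot = _rotate_xy(xy, cfg.rotation.angles_deg)  # (N, K, 2)

    vec1 = rot - rx  # target -> offset from Rx
    vec2 = rot - tx
    d1 = np.linalg.norm(vec1, axis=-1)  # (N, K)
    d2 = np.linalg.norm(vec2, axis=-1)
    if np.any(d1 == 0) or np.any(d2 == 0):
        raise GeometryError("scatterer coincides with an antenna position")

    # off-boresight angles: boresight is antenna -> origin
    def offaxis(vec: np.ndarray, ant: np.ndarray, d: np.ndarray) -> np.ndarray:
        bore = -ant / np.linalg.norm(ant)
        c = (vec @ bore) / d
        return np.arccos(np.clip(c, -1.0, 1.0))

    g = np.sqrt(cfg.gain(offaxis(vec1, rx, d1)) * cfg.gain(offaxis(vec2, tx, d2)))

    f = cfg.sweep.frequencies  # (M,)
    lam = C0 / (f * np.sqrt(eps_r))  # in-medium wavelength
    a0 = np.sqrt(cfg.z0 * cfg.tx_power / (4.0 * np.pi)) * lam / (4.0 * np.pi)
    k = PHASE_SIGN * 1j * (2.0 * np.pi * f * np.sqrt(eps_r) / C0)  # (M,)

    amp = g * np.sqrt(rcs)[None, :] / (d1 * d2)  # (N, K)
    path = d1 + d2
    return a0[:, None, None] * amp[None, :, :] * np.exp(k[:, None, None] * path[None, :, :])


def point_response(
    s: Scatterer,
    f: float,
    rotation_angle_deg: float,
    scene: Scene,
    cfg: ForwardConfig,
) -> complex:
    """Single-scatterer S21 at one frequency and turntable angle."""
    if not (cfg.sweep.f_start <= f <= cfg.sweep.f_stop):
        raise ForwardModelError(f"frequency {f} outside the sweep")
    p = s.position.rotated(rotation_angle_deg)
    tx, rx = antenna_positions(cfg.antenna)
    xy = p.xy
    vec1, vec2 = xy - rx, xy - tx
    d1, d2 = float(np.linalg.norm(vec1)), float(np.linalg.norm(vec2))
    if d1 == 0 or d2 == 0:
        raise GeometryError("scatterer coincides with an antenna position")

    def offax(vec: np.ndarray, ant: np.ndarray, d: float) -> float:
        bore = -ant / np.linalg.norm(ant)
        return float(np.arccos(np.clip(np.dot(vec, bore) / d, -1.0, 1.0)))

    g = np.sqrt(
        float(cfg.gain(np.array(offax(vec1, rx, d1))))
        * float(cfg.gain(np.array(offax(vec2, tx, d2))))
    )
    eps_r = scene.medium_eps_r
    lam = C0 / (f * np.sqrt(eps_r))
    a0 = effective_aperture(cfg.tx_power, lam, cfg.z0)
    phase = PHASE_SIGN * 1j * (2.0 * np.pi * f * np.sqrt(eps_r) / C0) * (d1 + d2)
    return complex(a0 * g * np.sqrt(s.rcs) / (d1 * d2) * np.exp(phase))


def simulate_sinogram(scene: Scene, cfg: ForwardConfig) -> Sinogram:
    """Synthesize the full S21 sinogram of a scene (superposition of points)."""
    M, N = cfg.sweep.n_points, cfg.rotation.n_positions
    if not scene.scatterers:
        values = np.zeros((M, N), dtype=complex)
    else:
        xy = np.array([s.position.xy for s in scene.scatterers])
        rcs = np.array([s.rcs for s in scene.scatterers], dtype=float)
        values = _response_kernel(xy, rcs, scene.medium_eps_r, cfg).sum(axis=-1)
    meta = {
        "medium_eps_r": scene.medium_eps_r,
        "container_radius_m": scene.container_radius,
        "ring_radius_m": cfg.antenna.ring_radius,
        "gain_model": getattr(cfg.gain, "label", "custom"),
    }
    return Sinogram(values, cfg.sweep, cfg.rotation, scene.medium_eps_r, meta)


_WINDOWS = {"rect": "boxcar", "hann": "hann", "hamming": "hamming"}


def range_compress(sg: Sinogram, window: str = "hann") -> RangeProfileSet:
    """Transform the frequency sweep into per-angle delay (range) profiles.

    A unitary forward-sign DFT (matching the exp(+j*omega*tau) propagation
    convention) maps the windowed spectrum of each angle onto a delay axis
    with bin width 1/(M*df), starting at zero. Windowing (default Hann)
    trades main-lobe width for sidelobe suppression.
    """
    if window not in _WINDOWS:
        raise ForwardModelError(
            f"unknown window {window!r}; choose from {sorted(_WINDOWS)}"
        )
    M = sg.sweep.n_points
    w = get_window(_WINDOWS[window], M, fftbins=False)
    spec = sg.values * w[:, None]
    # forward-sign DFT: profile_k = (1/sqrt(M)) sum_m X_m exp(-j 2 pi f_m tau_k)
    prof = np.fft.fft(spec, axis=0) / np.sqrt(M)
    delays = np.arange(M) / (M * sg.sweep.df)
    prof = prof * np.exp(-2j * np.pi * sg.sweep.f_start * delays)[:, None]
    return RangeProfileSet(prof, delays, sg.rotation.angles_deg, window)


@dataclass(frozen=True)
class SensitivityMatrix:
    """Linear map from per-pixel unit-RCS weights to stacked measurements.

    Rows follow :func:`stack_measurements` ordering (angle-major blocks,
    frequency fastest); columns follow the grid's row-major pixel order.
    Pixels outside the container have identically-zero columns.
    """

    matrix: np.ndarray
    grid: ImagingGrid
    sweep: FrequencySweep
    rotation: AngularSweep
    medium_eps_r: float
    row_ordering: str = "angle-major (frequency fastest)"
    col_ordering: str = "grid row-major"

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_sensitivity(
    grid: ImagingGrid,
    medium_eps_r: float,
    cfg: ForwardConfig,
    container_radius: float | None = None,
    chunk_pixels: int = 256,
) -> SensitivityMatrix:
    """Assemble the sensitivity matrix of unit-RCS pixel responses.

    Requires at least as many measurements as pixels (M*N >= p*q), the
    solvability condition of the linear inverse model. Built in pixel
    chunks to bound peak memory at full acquisition scale.
    """
    M, N = cfg.sweep.n_points, cfg.rotation.n_positions
    npix = grid.n_pixels
    if M * N < npix:
        raise ForwardModelError(
            f"under-determined system: {M}*{N} = {M * N} measurements for "
            f"{npix} pixels; need (freq x angle) >= (p x q)"
        )
    rmax = cfg.antenna.ring_radius if container_radius is None else container_radius
    centers = grid.pixel_centers()
    inside = np.hypot(centers[:, 0], centers[:, 1]) < rmax

    J = np.zeros((M * N, npix), dtype=complex)
    idx = np.flatnonzero(inside)
    for start in range(0, idx.size, chunk_pixels):
        cols = idx[start : start + chunk_pixels]
        resp = _response_kernel(
            centers[cols], np.ones(cols.size), medium_eps_r, cfg
        )  # (M, N, k)
        J[:, cols] = resp.reshape(M * N, cols.size, order="F")
    if not np.any(inside):
        warnings.warn("no grid pixel lies inside the container; J is all zero")
    return SensitivityMatrix(J, grid, cfg.sweep, cfg.rotation, medium_eps_r)
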