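"""Rod-based calibration of the coupling-medium permittivity.

A thin metal rod at a known position gives, after range compression, one
peak delay per turntable angle. Over all angles and rod positions the
delay is proportional to the bistatic path length:

    tau = sqrt(eps_r) / c0 * (d1 + d2)

so a zero-intercept least-squares fit of measured peak delays against
geometric path lengths estimates sqrt(eps_r)/c0, hence the relative
permittivity of the liquid. Peak delays are sharpened below the delay-bin
quantization by parabolic interpolation of the magnitude profile around
the per-angle maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import C0
from .forward import RangeProfileSet, Sinogram, range_compress
from .geometry import AntennaConfig, ScenePoint, bistatic_distances
from .io import MeasurementSet


class CalibrationError(ValueError):
    """Insufficient or degenerate calibration data."""


def peak_delays(rps: RangeProfileSet) -> np.ndarray:
    """Sub-bin peak delay per angle via parabolic interpolation of |profile|."""
    mag = np.abs(rps.values)
    k = np.argmax(mag, axis=0)
    delays = rps.delays[k].astype(float)
    M = mag.shape[0]
    for j, kj in enumerate(k):
        if 0 < kj < M - 1:
            y0, y1, y2 = mag[kj - 1, j], mag[kj, j], mag[kj + 1, j]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:  # proper maximum
                delays[j] += 0.5 * (y0 - y2) / denom * rps.delay_bin
    return delays


@dataclass(frozen=True)
class CalibrationResult:
    """Estimated medium permittivity and fit diagnostics."""

    eps_r: float
    slope_s_per_m: float
    rms_residual_s: float
    n_points: int


def calibrate_medium(
    rod_sets: list[tuple[MeasurementSet | Sinogram, ScenePoint]],
    antenna: AntennaConfig,
    window: str = "hann",
) -> CalibrationResult:
    """Estimate the coupling medium's eps_r from rod sweeps at known positions.

    Each entry pairs a measurement (or simulated sinogram) of a single rod
    with the rod's position. At least two distinct rod positions are
    required so the fit spans a range of path lengths.
    """
    if len(rod_sets) < 2:
        raise CalibrationError(
            f"need at least 2 rod positions for calibration, got {len(rod_sets)}"
        )
    paths: list[np.ndarray] = []
    taus: list[np.ndarray] = []
    for ms, pos in rod_sets:
        sg = ms.to_sinogram() if isinstance(ms, MeasurementSet) else ms
        rps = range_compress(sg, window=window)
        taus.append(peak_delays(rps))
        d = np.array(
            [
                sum(bistatic_distances(pos.rotated(a), antenna))
                for a in sg.rotation.angles_deg
            ]
        )
        paths.append(d)
    path = np.concatenate(paths)
    tau = np.concatenate(taus)
    if np.ptp(path) < 1e-9:
        raise CalibrationError("rod positions give indistinguishable path lengths")
    slope = float(np.dot(path, tau) / np.dot(path, path))
    if slope <= 0:
        raise CalibrationError("non-physical (non-positive) delay/path slope")
    resid = tau - slope * path
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > 0.2 * float(np.mean(tau)):
        warnings.warn(
            "calibration fit residuals exceed 20% of the mean delay; "
            "check rod positions and range-compression settings"
        )
    return CalibrationResult(
        eps_r=float((slope * C0) ** 2),
        slope_s_per_m=slope,
        rms_residual_s=rms,
        n_points=int(path.size),
    )
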