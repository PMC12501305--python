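"""Dielectric properties of tissues and matching media.

Covers the single-frequency quantities needed to size a water-coupled
microwave imaging link: loss tangent and in-medium wavelength of a lossy
dielectric, Cole-Cole dispersion of the coupling liquid, layered dB loss
budgets, and the range/cross-range resolution of a swept-frequency system.

Sign conventions: complex permittivity is written eps_r*(1 - j*tan_delta)
under the exp(+j*omega*t) time convention, so lossy media have a negative
imaginary part; dB loss terms are negative numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import C0, EPS0


class DielectricError(ValueError):
    """Invalid dielectric parameter (non-physical frequency, permittivity...)."""


def loss_tangent(sigma: float, eps_r: float, f: float) -> float:
    """Loss tangent sigma / (2*pi*f*eps0*eps_r) of a conductive dielectric."""
    if f <= 0:
        raise DielectricError(f"frequency must be > 0, got {f}")
    if eps_r <= 0:
        raise DielectricError(f"eps_r must be > 0, got {eps_r}")
    if sigma < 0:
        raise DielectricError(f"conductivity must be >= 0, got {sigma}")
    return sigma / (2.0 * np.pi * f * EPS0 * eps_r)


def wavelength_lossy(eps_r: float, tan_delta: float, f: float) -> float:
    """In-medium wavelength of a lossy dielectric, metres.

    lambda = c0 / (f * Re{sqrt(eps_r * (1 - j*tan_delta))}). Reduces to
    c0/(f*sqrt(eps_r)) when tan_delta = 0 and shrinks as the loss grows.
    """
    if f <= 0 or eps_r <= 0:
        raise DielectricError("f and eps_r must be > 0")
    if tan_delta < 0:
        raise DielectricError("tan_delta must be >= 0")
    n_re = np.sqrt(eps_r * (1.0 - 1j * tan_delta)).real
    return C0 / (f * n_re)


def attenuation_loss(thickness_cm: float, coeff_db_per_cm: float, passes: int = 2) -> float:
    """Signed dB loss of a tissue layer: -(thickness * passes * coefficient).

    ``passes`` is 1 for one-way, 2 for the out-and-back radar path.
    """
    if thickness_cm < 0 or coeff_db_per_cm < 0:
        raise DielectricError("thickness and attenuation coefficient must be >= 0")
    if passes not in (1, 2):
        raise DielectricError(f"passes must be 1 or 2, got {passes}")
    return -(thickness_cm * passes * coeff_db_per_cm)


@dataclass(frozen=True)
class LossBudget:
    """Ordered list of (label, dB) loss terms and their arithmetic total."""

    terms: tuple[tuple[str, float], ...]
    total_db: float

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.terms), columns=["term", "dB"])
        return pd.concat(
            [df, pd.DataFrame([{"term": "Total", "dB": self.total_db}])],
            ignore_index=True,
        )


def total_budget(terms: Iterable[tuple[str, float] | float]) -> LossBudget:
    """Sum signed dB terms into a LossBudget; bare floats get numeric labels."""
    norm: list[tuple[str, float]] = []
    for i, t in enumerate(terms):
        label, val = t if isinstance(t, tuple) else (f"term_{i + 1}", t)
        val = float(val)
        if not np.isfinite(val):
            raise DielectricError(f"non-finite budget term {label!r}: {val}")
        norm.append((label, val))
    return LossBudget(terms=tuple(norm), total_db=float(sum(v for _, v in norm)))


@dataclass(frozen=True)
class ColeColeParams:
    """Single-pole Cole-Cole dispersion parameters.

    eps(omega) = eps_inf + (eps_static - eps_inf) / (1 + (j*omega*tau)^(1-alpha))
                 - j * ionic_conductivity / (omega * eps0)

    alpha = 0 recovers the Debye relaxation. ``ionic_conductivity`` adds the
    low-frequency conduction loss of saline solutions.
    """

    eps_inf: float
    eps_static: float
    tau: float
    alpha: float = 0.0
    ionic_conductivity: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_static < self.eps_inf:
            raise DielectricError("eps_static must be >= eps_inf")
        if self.tau <= 0:
            raise DielectricError("tau must be > 0")
        if not 0.0 <= self.alpha < 1.0:
            raise DielectricError("alpha must lie in [0, 1)")
        if self.ionic_conductivity < 0:
            raise DielectricError("ionic_conductivity must be >= 0")


#: Named matching-medium presets. Tap water near 25 C: single Debye pole with
#: static permittivity 78.4, infinite-frequency limit 5.2 and relaxation time
#: 8.27 ps, giving roughly 78 - j4 at 1 GHz — the regime where water works as
#: a coupling liquid. Ionic conductivity is left at zero (low-salinity tap
#: water); raise it for saline media.
COLE_COLE_PRESETS: dict[str, ColeColeParams] = {
    "tap_water_25C": ColeColeParams(
        eps_inf=5.2, eps_static=78.4, tau=8.27e-12, alpha=0.0, ionic_conductivity=0.0
    ),
}


def cole_cole(f: float | np.ndarray, params: ColeColeParams) -> complex | np.ndarray:
    """Complex relative permittivity at frequency ``f`` (Hz).

    Follows the exp(+j*omega*t) convention: the imaginary part is <= 0 for a
    passive medium.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DielectricError("frequency must be > 0")
    omega = 2.0 * np.pi * f
    jwt = (1j * omega * params.tau) ** (1.0 - params.alpha)
    eps = params.eps_inf + (params.eps_static - params.eps_inf) / (1.0 + jwt)
    if params.ionic_conductivity > 0:
        eps = eps - 1j * params.ionic_conductivity / (omega * EPS0)
    eps = np.asarray(eps, dtype=complex)
    return complex(eps) if eps.ndim == 0 else eps


def propagation_speed(eps_r: float) -> float:
    """Phase velocity c0/sqrt(eps_r) in a lossless medium, m/s."""
    if eps_r <= 0:
        raise DielectricError(f"eps_r must be > 0, got {eps_r}")
    return C0 / np.sqrt(eps_r)


def range_resolution(bandwidth: float, eps_r: float = 1.0) -> float:
    """Range resolution v/(2B) = c0/(2*B*sqrt(eps_r)), metres."""
    if bandwidth <= 0:
        raise DielectricError(f"bandwidth must be > 0, got {bandwidth}")
    return propagation_speed(eps_r) / (2.0 * bandwidth)


def cross_range_resolution(
    center_frequency: float, aperture_deg: float, eps_r: float = 1.0
) -> float:
    """Cross-range resolution estimate for a rotational synthetic aperture.

    Uses the standard turntable-ISAR form lambda / (4*sin(aperture/2)) with
    the in-medium wavelength at the centre frequency. Treat as an
    order-of-magnitude figure: real apertures are tapered by the antenna
    pattern and windowing.
    """
    if center_frequency <= 0 or not 0 < aperture_deg <= 360:
        raise DielectricError("need center_frequency > 0 and aperture in (0, 360]")
    lam = propagation_speed(eps_r) / center_frequency
    return lam / (4.0 * np.sin(np.deg2rad(aperture_deg) / 2.0))


@dataclass(frozen=True)
class TissueDielectric:
    """Dielectric working point of one tissue at one frequency."""

    name: str
    frequency: float
    conductivity: float
    eps_r: float
    tan_delta: float = field(default=float("nan"))
    wavelength: float = field(default=float("nan"))

    @classmethod
    def from_sigma_eps(
        cls, name: str, frequency: float, conductivity: float, eps_r: float
    ) -> "TissueDielectric":
        """Populate the derived columns (tan_delta, wavelength) from (sigma, eps_r)."""
        td = loss_tangent(conductivity, eps_r, frequency)
        lam = wavelength_lossy(eps_r, td, frequency)
        return cls(name, frequency, conductivity, eps_r, td, lam)


#: Head-tissue working points at 1 GHz (conductivity S/m, relative
#: permittivity), after Gabriel's compilation — the inputs to the loss-tangent
#: and wavelength columns of the tissue table.
TISSUES_1GHZ: dict[str, tuple[float, float]] = {
    "blood": (1.580, 61.07),
    "bone_cortical": (0.160, 12.36),
    "csf": (2.460, 68.44),
    "grey_matter": (0.990, 52.28),
    "white_matter": (0.620, 38.58),
}


def tissue_table(
    tissues: dict[str, tuple[float, float]] | None = None, frequency: float = 1e9
) -> pd.DataFrame:
    """DataFrame of tissue dielectrics with derived loss tangent and wavelength."""
    tissues = TISSUES_1GHZ if tissues is None else tissues
    rows = [
        TissueDielectric.from_sigma_eps(name, frequency, sig, eps)
        for name, (sig, eps) in tissues.items()
    ]
    return pd.DataFrame(
        {
            "name": [r.name for r in rows],
            "f_Hz": [r.frequency for r in rows],
            "sigma_Sm": [r.conductivity for r in rows],
            "eps_r": [r.eps_r for r in rows],
            "tan_delta": [r.tan_delta for r in rows],
            "lambda_m": [r.wavelength for r in rows],
        }
    )


#: Two-way link-budget terms for a bleed 5 cm under the scalp at 1 GHz,
#: water-coupled: skull (1 cm at 1 dB/cm), grey matter (3 cm at 2.1 dB/cm),
#: the grey-matter/blood interface return loss, coupling losses, the RCS of a
#: 3 cm blood sphere, and spreading loss.
HEAD_BUDGET_1GHZ: tuple[tuple[str, float], ...] = (
    ("skull bone, 1 cm, two-way", attenuation_loss(1.0, 1.0, 2)),
    ("grey matter, 3 cm path, two-way", attenuation_loss(3.0, 2.1, 2)),
    ("return loss grey matter to blood", -13.0),
    ("additional transmission coupling losses", -2.0),
    ("RCS of blood section (3 cm sphere)", -30.0),
    ("spreading loss at 5 cm", -8.0),
)


def head_budget_1ghz() -> LossBudget:
    """The default water-coupled head link budget at 1 GHz (total -67.6 dB)."""
    return total_budget(HEAD_BUDGET_1GHZ)


def read_tissue_csv(path) -> pd.DataFrame:
    """Read a tissue table CSV (columns name, f_Hz, sigma_Sm, eps_r, ...)."""
    df = pd.read_csv(path)
    required = {"name", "f_Hz", "sigma_Sm", "eps_r"}
    missing = required - set(df.columns)
    if missing:
        raise DielectricError(f"tissue CSV missing columns: {sorted(missing)}")
    return df


def write_tissue_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
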