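"""Polar-plane bistatic acquisition geometry.

The scene lives in a 2-D polar plane centred on the rotation axis of the
turntable. Azimuth ``phi`` is measured in degrees from the +y axis toward
the +x axis, so a point at radius ``Ri`` and azimuth ``phi`` has cartesian
coordinates ``(Ri*sin(phi), Ri*cos(phi))``. The transmit and receive
antennas sit on a ring of radius ``R0`` just outside the container, each
making an angle ``theta`` with the +y axis. Two placements are supported:

* ``adjacent`` (default) — a side-by-side bistatic pair straddling the +y
  axis, separated by 2w = 2*R0*sin(theta):

      Tx = ( R0*sin(theta), R0*cos(theta))
      Rx = (-R0*sin(theta), R0*cos(theta))

  This is the quasi-monostatic radar arrangement of a turntable ISAR rig
  (two-way propagation into the scene and back to the same side).

* ``opposed`` — the antennas diametrically opposite (Rx = -Tx), a pure
  transmission geometry. Note that this placement cannot distinguish a
  scatterer from its point reflection through the origin: swapping
  d1 <-> d2 and delta1 <-> delta2 leaves the symmetric bistatic response
  unchanged, so every target has an exact antipodal ghost and the imaging
  operator loses half its rank. Use it for transmission studies, not for
  unambiguous localization.

Each antenna's boresight points at the origin. ``delta1``/``delta2`` are
the angles between the receive/transmit boresight and the direction from
that antenna to the target — the off-axis angles that enter the gain
pattern of the bistatic radar equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C0


class GeometryError(ValueError):
    """Invalid acquisition geometry (bad configuration or target placement)."""


@dataclass(frozen=True)
class ScenePoint:
    """A position in the polar imaging plane.

    Parameters
    ----------
    radius : float
        Distance from the plane centre, metres (>= 0).
    azimuth_deg : float
        Azimuth in degrees, measured from +y toward +x; normalised to
        [0, 360).
    """

    radius: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise GeometryError(f"radius must be >= 0, got {self.radius}")
        object.__setattr__(self, "azimuth_deg", float(self.azimuth_deg) % 360.0)

    @property
    def xy(self) -> np.ndarray:
        """Cartesian (x, y) coordinates in metres."""
        a = np.deg2rad(self.azimuth_deg)
        return np.array([self.radius * np.sin(a), self.radius * np.cos(a)])

    @classmethod
    def from_xy(cls, x: float, y: float) -> "ScenePoint":
        r = float(np.hypot(x, y))
        az = float(np.rad2deg(np.arctan2(x, y))) % 360.0
        return cls(r, az)

    def rotated(self, delta_deg: float) -> "ScenePoint":
        """Return the point rotated about the origin by ``delta_deg``."""
        return ScenePoint(self.radius, (self.azimuth_deg + delta_deg) % 360.0)


@dataclass(frozen=True)
class AntennaConfig:
    """Bistatic antenna ring: radius, opening angle, placement.

    The default opening angle of 20 degrees puts the adjacent pair about
    5.8 cm apart on an 8.5 cm ring — the footprint of two planar UWB
    antenna housings side by side. ``element_halfspacing`` (the half of the
    2w separation) is carried as metadata only; for the adjacent placement
    it is geometrically R0*sin(theta), but it does not enter the
    scattering model.
    """

    ring_radius: float
    opening_angle_deg: float = 20.0
    element_halfspacing: float = 0.0
    placement: str = "adjacent"

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise GeometryError(f"ring_radius must be > 0, got {self.ring_radius}")
        if self.element_halfspacing < 0:
            raise GeometryError("element_halfspacing must be >= 0")
        if self.placement not in ("adjacent", "opposed"):
            raise GeometryError(
                f"placement must be 'adjacent' or 'opposed', got {self.placement!r}"
            )


@dataclass(frozen=True)
class BistaticGeometry:
    """Distances and boresight off-axis angles for one target/antenna pair.

    ``d1``/``delta1`` refer to the receive antenna, ``d2``/``delta2`` to the
    transmit antenna. Angles are radians in [0, pi].
    """

    d1: float
    d2: float
    delta1: float
    delta2: float


def antenna_positions(cfg: AntennaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian (Tx, Rx) positions on the antenna ring.

    Tx sits at ``(R0 sin(theta), R0 cos(theta))``; Rx mirrors it about the
    +y axis for the adjacent placement, or sits diametrically opposite for
    the opposed placement.
    """
    t = np.deg2rad(cfg.opening_angle_deg)
    tx = np.array([cfg.ring_radius * np.sin(t), cfg.ring_radius * np.cos(t)])
    if cfg.placement == "adjacent":
        return tx, np.array([-tx[0], tx[1]])
    return tx, -tx


def bistatic_distances(p: ScenePoint, cfg: AntennaConfig) -> tuple[float, float]:
    """Euclidean distances (d1 to Rx, d2 to Tx) for a target inside the ring.

    Raises
    ------
    GeometryError
        If the target is on or outside the antenna ring (``Ri >= R0``).
    """
    if p.radius >= cfg.ring_radius:
        raise GeometryError(
            f"target radius {p.radius} m is outside the container "
            f"(ring radius {cfg.ring_radius} m)"
        )
    tx, rx = antenna_positions(cfg)
    xy = p.xy
    d1 = float(np.linalg.norm(xy - rx))
    d2 = float(np.linalg.norm(xy - tx))
    return d1, d2


def boresight_angles(p: ScenePoint, cfg: AntennaConfig) -> tuple[float, float]:
    """Off-boresight angles (delta1 at Rx, delta2 at Tx), radians in [0, pi].

    Each boresight points from the antenna to the origin; the returned angle
    is between that boresight and the antenna-to-target direction. The target
    at the origin gives (0, 0) by definition.
    """
    if p.radius >= cfg.ring_radius:
        raise GeometryError("target must be strictly inside the container")
    tx, rx = antenna_positions(cfg)
    xy = p.xy

    def angle_at(ant: np.ndarray) -> float:
        to_target = xy - ant
        if np.linalg.norm(to_target) == 0.0:
            raise GeometryError("target coincides with an antenna position")
        boresight = -ant  # antenna -> origin
        # atan2 form: exact at 0 and pi, unlike arccos of the unit dot product
        cross = boresight[0] * to_target[1] - boresight[1] * to_target[0]
        dot = float(np.dot(boresight, to_target))
        return float(np.arctan2(abs(cross), dot))

    return angle_at(rx), angle_at(tx)


def bistatic_geometry(p: ScenePoint, cfg: AntennaConfig) -> BistaticGeometry:
    """Bundle distances and boresight angles for one target."""
    d1, d2 = bistatic_distances(p, cfg)
    a1, a2 = boresight_angles(p, cfg)
    return BistaticGeometry(d1=d1, d2=d2, delta1=a1, delta2=a2)


def path_delay(d1: float, d2: float, eps_r: float) -> float:
    """Two-way propagation delay (s) over the bistatic path in a medium.

    delay = (d1 + d2) * sqrt(eps_r) / c0; this is the factor multiplying
    ``j*omega`` in the forward-model phase term.
    """
    if d1 < 0 or d2 < 0:
        raise GeometryError("distances must be >= 0")
    if eps_r <= 0:
        raise GeometryError(f"eps_r must be > 0, got {eps_r}")
    return (d1 + d2) * np.sqrt(eps_r) / C0
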