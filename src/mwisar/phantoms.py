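"""Synthetic scenes and measurement noise for inverse-problem testing.

Presets mirror the canonical test scenarios of a turntable ISAR rig with a
17 cm water-filled container (eps_r = 80): a single off-centre point
target, a nine-point constellation spanning all quadrants, an extended
ellipse phantom with cylindrical inserts (a vegetable surrogate with wooden
rods), and a thin metal rod used for medium calibration. Extended objects
are modelled as dense point-scatterer clouds with region-wise RCS contrast,
consistent with the constant-RCS linearization of the inverse model — not
as dielectric volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import C0
from .forward import ForwardModelError, Scatterer, Scene, Sinogram
from .geometry import ScenePoint

DEFAULT_CONTAINER_RADIUS = 0.085
DEFAULT_EPS_R = 80.0

#: lambda/4 in water at 4.8 GHz — the default discretization pitch for
#: extended phantoms (~0.87 mm).
DEFAULT_PITCH = C0 / (4.8e9 * math.sqrt(DEFAULT_EPS_R)) / 4.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description for config-driven runs."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def single_point_scene(
    radius: float = 0.06,
    azimuth_deg: float = 180.0,
    rcs: float = 1.0,
    medium_eps_r: float = DEFAULT_EPS_R,
    container_radius: float = DEFAULT_CONTAINER_RADIUS,
) -> Scene:
    """One unit-RCS point target 6 cm from centre at 180 deg (i.e. (0, -6 cm))."""
    return Scene(
        (Scatterer(ScenePoint(radius, azimuth_deg), rcs),),
        medium_eps_r,
        container_radius,
        metadata={"phantom": "single_point"},
    )


def nine_point_scene(
    r_x: float = 0.07,
    r_y: float = 0.06,
    r_diag: float = 0.045,
    medium_eps_r: float = DEFAULT_EPS_R,
    container_radius: float = DEFAULT_CONTAINER_RADIUS,
) -> Scene:
    """Nine unit scatterers: +-x pair, +-y pair, four diagonals, one centre.

    The x-axis pair sits farthest out, the y-axis pair next, the diagonal
    four closest to the centre (r_x > r_y > r_diag), reproducing the
    distance ordering of the standard multi-target test constellation.
    """
    if not (r_x > r_y > r_diag > 0):
        raise ForwardModelError(
            f"need r_x > r_y > r_diag > 0, got ({r_x}, {r_y}, {r_diag})"
        )
    if r_x >= container_radius:
        raise ForwardModelError("r_x must be inside the container")
    pts = [
        ScenePoint(r_x, 90.0),  # +x
        ScenePoint(r_x, 270.0),  # -x
        ScenePoint(r_y, 0.0),  # +y
        ScenePoint(r_y, 180.0),  # -y
        ScenePoint(r_diag, 45.0),
        ScenePoint(r_diag, 135.0),
        ScenePoint(r_diag, 225.0),
        ScenePoint(r_diag, 315.0),
        ScenePoint(0.0, 0.0),  # centre
    ]
    return Scene(
        tuple(Scatterer(p, 1.0) for p in pts),
        medium_eps_r,
        container_radius,
        metadata={"phantom": "nine_point"},
    )


def ellipse_with_inserts_scene(
    a: float = 0.04,
    b: float = 0.06,
    insert_positions: tuple[tuple[float, float], ...] = ((0.018, 0.0), (-0.018, 0.0)),
    insert_diameter: float = 0.01,
    contrasts: dict | None = None,
    pitch: float = DEFAULT_PITCH,
    medium_eps_r: float = DEFAULT_EPS_R,
    container_radius: float = DEFAULT_CONTAINER_RADIUS,
) -> Scene:
    """Extended elliptical phantom (semi-axes a, b) with cylindrical inserts.

    Emulates a vegetable surrogate: a high-contrast boundary ring (the
    skin), a weak interior fill, and distinct-contrast insert disks, all as
    point scatterers on a lattice of the given pitch. Contrast values are
    RCS multipliers per region (keys 'boundary', 'interior', 'insert').
    """
    contrasts = {"boundary": 1.0, "interior": 0.05, "insert": 0.5, **(contrasts or {})}
    if a <= 0 or b <= 0 or insert_diameter <= 0 or pitch <= 0:
        raise ForwardModelError("a, b, insert_diameter and pitch must be > 0")
    if max(a, b) >= container_radius:
        raise ForwardModelError("ellipse does not fit inside the container")
    r_ins = insert_diameter / 2.0
    for cx, cy in insert_positions:
        if (cx / (a - r_ins)) ** 2 + (cy / (b - r_ins)) ** 2 > 1.0:
            raise ForwardModelError(
                f"insert at ({cx}, {cy}) does not fit inside the ellipse"
            )

    scatterers: list[Scatterer] = []
    # boundary ring: points along the perimeter at ~pitch spacing
    perimeter = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    n_ring = max(8, int(round(perimeter / pitch)))
    t = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    for x, y in zip(a * np.cos(t), b * np.sin(t)):
        scatterers.append(Scatterer(ScenePoint.from_xy(x, y), contrasts["boundary"]))
    # interior fill on a square lattice
    nx = int(a // pitch)
    ny = int(b // pitch)
    xs = np.arange(-nx, nx + 1) * pitch
    ys = np.arange(-ny, ny + 1) * pitch
    for x in xs:
        for y in ys:
            if (x / a) ** 2 + (y / b) ** 2 >= 1.0:
                continue
            rcs = contrasts["interior"]
            for cx, cy in insert_positions:
                if (x - cx) ** 2 + (y - cy) ** 2 <= r_ins**2:
                    rcs = contrasts["insert"]
                    break
            scatterers.append(Scatterer(ScenePoint.from_xy(x, y), rcs))
    return Scene(
        tuple(scatterers),
        medium_eps_r,
        container_radius,
        metadata={
            "phantom": "ellipse_with_inserts",
            "semi_axes_m": (a, b),
            "insert_diameter_m": insert_diameter,
            "pitch_m": pitch,
        },
    )


def rod_calibration_scene(
    position: ScenePoint,
    rcs: float = 1.0,
    diameter: float = 0.005,
    medium_eps_r: float = DEFAULT_EPS_R,
    container_radius: float = DEFAULT_CONTAINER_RADIUS,
) -> Scene:
    """A thin metal rod (default 5 mm diameter) as a single strong scatterer.

    Used by the medium-calibration workflow: known rod positions give known
    bistatic path lengths, and the range-compressed peak delays fit the
    propagation speed of the coupling liquid.
    """
    return Scene(
        (Scatterer(position, rcs),),
        medium_eps_r,
        container_radius,
        metadata={"phantom": "rod", "rod_diameter_m": diameter},
    )


def add_noise(sg: Sinogram, snr_db: float, seed: int) -> Sinogram:
    """Add circular complex white Gaussian noise at the given mean SNR.

    Noise power is set so (mean signal power)/(noise power) = 10^(snr/10);
    an infinite SNR returns an identical sinogram. Reproducible for a fixed
    seed.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return Sinogram(
            sg.values.copy(), sg.sweep, sg.rotation, sg.medium_eps_r, dict(sg.metadata)
        )
    rng = np.random.default_rng(seed)
    p_sig = float(np.mean(np.abs(sg.values) ** 2))
    p_noise = p_sig / (10.0 ** (snr_db / 10.0))
    scale = math.sqrt(p_noise / 2.0)
    noise = scale * (
        rng.standard_normal(sg.values.shape) + 1j * rng.standard_normal(sg.values.shape)
    )
    meta = dict(sg.metadata)
    meta.update({"noise_snr_db": snr_db, "noise_seed": seed})
    return Sinogram(sg.values + noise, sg.sweep, sg.rotation, sg.medium_eps_r, meta)


_PHANTOM_BUILDERS = {
    "single_point": single_point_scene,
    "nine_point": nine_point_scene,
    "ellipse_with_inserts": ellipse_with_inserts_scene,
    "potato": ellipse_with_inserts_scene,
    "rod": rod_calibration_scene,
}


def make_scene(spec: PhantomSpec) -> Scene:
    """Build the scene named by a :class:`PhantomSpec` (pure in spec + seed)."""
    if spec.kind not in _PHANTOM_BUILDERS:
        raise ForwardModelError(
            f"unknown phantom kind {spec.kind!r}; choose from {sorted(_PHANTOM_BUILDERS)}"
        )
    params = dict(spec.params)
    if spec.kind == "rod" and "position" in params and not isinstance(
        params["position"], ScenePoint
    ):
        r, az = params["position"]
        params["position"] = ScenePoint(r, az)
    return _PHANTOM_BUILDERS[spec.kind](**params)


def scene_to_csv(scene: Scene, path) -> None:
    """Export a scene as CSV columns (x_m, y_m, rcs_m2)."""
    import pandas as pd

    rows = [
        {"x_m": s.position.xy[0], "y_m": s.position.xy[1], "rcs_m2": s.rcs}
        for s in scene.scatterers
    ]
    pd.DataFrame(rows, columns=["x_m", "y_m", "rcs_m2"]).to_csv(path, index=False)
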