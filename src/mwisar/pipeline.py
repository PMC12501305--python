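"""Run configuration and the end-to-end simulate -> invert pipeline.

A run is described by a single YAML mapping with sections geometry, sweep,
rotation, medium, grid, phantom, solver and output. Unknown sections or
keys are rejected up front so typos fail before any computation. All
randomness (noise injection) flows from the single top-level seed.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forward import (
    AngularSweep,
    ForwardConfig,
    ForwardModelError,
    FrequencySweep,
    Scene,
    build_sensitivity,
    gain_cosine_power,
    gain_gaussian,
    gain_isotropic,
    range_compress,
    simulate_sinogram,
    stack_measurements,
)
from .geometry import AntennaConfig
from .grid import ImagingGrid
from .inverse import (
    assemble_image,
    interpolate_presentation,
    localize_peaks,
    pinv_svd,
    solve_scatterer_map,
)
from .io import range_profiles_to_csv, save_sinogram_npz, write_sinogram_csv
from .phantoms import PhantomSpec, add_noise, make_scene


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


_SCHEMA: dict[str, dict[str, object]] = {
    "seed": None,
    "geometry": {
        "ring_radius_m": 0.085,
        "opening_angle_deg": 20.0,
        "element_halfspacing_m": 0.0,
        "placement": "adjacent",
    },
    "sweep": {"f_start_hz": 0.1e9, "f_stop_hz": 4.8e9, "n_points": 64},
    "rotation": {"n_positions": 90},
    "medium": {"eps_r": 80.0, "container_radius_m": 0.085},
    "grid": {"n_side": 32, "imaging_radius_m": 0.08},
    "phantom": {"kind": "single_point", "params": {}, "snr_db": math.inf},
    "solver": {"rtol": None, "window": "hann", "gain_model": "isotropic", "gain_param": None},
    "output": {"upsample": 0, "scale": "linear", "n_peaks": 1},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    geometry: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    rotation: dict = field(default_factory=dict)
    medium: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sections: dict = {}
        for name, defaults in _SCHEMA.items():
            if name == "seed":
                continue
            got = raw.get(name, {}) or {}
            if not isinstance(got, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            bad = set(got) - set(defaults)
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            sections[name] = {**defaults, **got}
        return cls(seed=int(raw.get("seed", 0)), **sections)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
        return cls.from_dict(raw)

    # --- object builders -------------------------------------------------
    def antenna(self) -> AntennaConfig:
        g = self.geometry
        return AntennaConfig(
            g["ring_radius_m"],
            g["opening_angle_deg"],
            g["element_halfspacing_m"],
            g["placement"],
        )

    def forward_config(self) -> ForwardConfig:
        s, r, sol = self.sweep, self.rotation, self.solver
        gains = {
            "isotropic": lambda p: gain_isotropic(),
            "cosine_power": lambda p: gain_cosine_power(2.0 if p is None else p),
            "gaussian": lambda p: gain_gaussian(60.0 if p is None else p),
        }
        if sol["gain_model"] not in gains:
            raise ConfigError(f"unknown gain_model {sol['gain_model']!r}")
        return ForwardConfig(
            antenna=self.antenna(),
            sweep=FrequencySweep(s["f_start_hz"], s["f_stop_hz"], int(s["n_points"])),
            rotation=AngularSweep(int(r["n_positions"])),
            gain=gains[sol["gain_model"]](sol["gain_param"]),
        )

    def imaging_grid(self) -> ImagingGrid:
        return ImagingGrid(int(self.grid["n_side"]), self.grid["imaging_radius_m"])

    def scene(self) -> Scene:
        p = self.phantom
        params = dict(p["params"])
        params.setdefault("medium_eps_r", self.medium["eps_r"])
        params.setdefault("container_radius", self.medium["container_radius_m"])
        return make_scene(PhantomSpec(p["kind"], params, self.seed))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate, reconstruct and report; returns the run report dict.

    Writes sinogram (npz + csv), range profiles (csv), reconstructed images
    (png, linear and dB) and report.json into ``outdir``. Deterministic for
    a fixed config seed; wall-clock timings live under the 'timings' key
    and are the only non-deterministic content.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    cfg = config.forward_config()
    grid = config.imaging_grid()
    n_meas = cfg.sweep.n_points * cfg.rotation.n_positions
    if n_meas < grid.n_pixels:
        raise ConfigError(
            f"solvability condition violated: (freq x angle) = {n_meas} < "
            f"(p x q) = {grid.n_pixels}"
        )
    scene = config.scene()

    sg = simulate_sinogram(scene, cfg)
    snr = config.phantom["snr_db"]
    if snr is not None and not (isinstance(snr, float) and math.isinf(snr)):
        sg = add_noise(sg, float(snr), config.seed)
    t_fwd = time.perf_counter()

    save_sinogram_npz(sg, outdir / "sinogram.npz")
    write_sinogram_csv(sg, outdir / "sinogram.csv")
    rps = range_compress(sg, window=config.solver["window"])
    range_profiles_to_csv(rps, outdir / "range_profiles.csv")

    J = build_sensitivity(
        grid, scene.medium_eps_r, cfg, container_radius=scene.container_radius
    )
    t_sens = time.perf_counter()
    pinv = pinv_svd(J, config.solver["rtol"])
    P = solve_scatterer_map(stack_measurements(sg.values), J, pinv=pinv)
    t_inv = time.perf_counter()

    img_lin = assemble_image(P, scale="linear")
    img_db = assemble_image(P, scale="db")
    _write_png(img_lin.values, outdir / "image_linear.png")
    _write_png(img_db.values, outdir / "image_db.png")
    upsample = int(config.output["upsample"])
    if upsample:
        pres = interpolate_presentation(img_lin, upsample)
        _write_png(pres.presentation, outdir / "image_presentation.png")

    n_peaks = int(config.output["n_peaks"])
    peaks = localize_peaks(img_lin, k=n_peaks)
    peak_xy = [img_lin.grid.index_to_xy(r * grid.n_side + c) for r, c in peaks]

    report = {
        "config": {
            "seed": config.seed,
            "geometry": config.geometry,
            "sweep": config.sweep,
            "rotation": config.rotation,
            "medium": config.medium,
            "grid": config.grid,
            "phantom": {k: v for k, v in config.phantom.items() if k != "snr_db"}
            | {"snr_db": None if snr is None or math.isinf(snr) else snr},
            "solver": config.solver,
        },
        "n_scatterers": len(scene.scatterers),
        "sinogram_shape": list(sg.values.shape),
        "sensitivity_shape": list(J.shape),
        "rtol_used": config.solver["rtol"],
        "peaks_pixel": [[int(r), int(c)] for r, c in peaks],
        "peaks_xy_m": [[float(x), float(y)] for x, y in peak_xy],
        "timings": {
            "forward_s": t_fwd - t0,
            "sensitivity_s": t_sens - t_fwd,
            "inverse_s": t_inv - t_sens,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _write_png(array: np.ndarray, path) -> None:
    """Save a real image as an 8-bit grayscale PNG (peak-normalized)."""
    from PIL import Image

    a = np.asarray(array, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)
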