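"""Measurement ingestion and persistence.

Supports two VNA export dialects:

* ``touchstone_per_angle`` — one two-port Touchstone ``.s2p`` file per
  turntable position, the angle encoded as a zero-padded integer-degree
  filename suffix (``..._a237.s2p``). RI and MA data formats are accepted;
  the forward-transmission term (S21) is extracted.
* ``csv_matrix`` — a single CSV with header column ``f_Hz`` followed by
  interleaved ``re_<angle>`` / ``im_<angle>`` column pairs, one pair per
  angle in degrees; one row per frequency point.

Sinograms are also persisted as compressed ``.npz`` containers with named
fields (values, f_Hz, angles_deg, eps_r, R0_m) for lossless round trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import AngularSweep, ForwardModelError, FrequencySweep, RangeProfileSet, Sinogram


class MeasurementIOError(ValueError):
    """Malformed or inconsistent measurement files."""


@dataclass(frozen=True)
class MeasurementSet:
    """Per-angle complex S21 spectra on a shared frequency grid."""

    frequencies: np.ndarray
    angles_deg: np.ndarray
    s21: np.ndarray  # (n_freq, n_angles)
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        s = np.asarray(self.s21, dtype=complex)
        if s.shape != (f.size, a.size):
            raise MeasurementIOError(
                f"S21 shape {s.shape} inconsistent with {f.size} frequencies "
                f"and {a.size} angles"
            )
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "s21", s)

    def to_sinogram(self, medium_eps_r: float = 80.0) -> Sinogram:
        """Lossless conversion onto the forward model's Sinogram container."""
        sweep = FrequencySweep(
            float(self.frequencies[0]), float(self.frequencies[-1]), self.frequencies.size
        )
        rotation = AngularSweep(self.angles_deg.size)
        return Sinogram(self.s21, sweep, rotation, medium_eps_r, dict(self.metadata))


_ANGLE_RE = re.compile(r"_a(\d+)\.s2p$", re.IGNORECASE)
_UNIT_SCALE = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _parse_touchstone_s2p(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse one .s2p file; return (frequencies_Hz, s21 complex array)."""
    unit, fmt = "GHZ", "MA"
    freqs: list[float] = []
    s21: list[complex] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = [t.upper() for t in line[1:].split()]
                for t in toks:
                    if t in _UNIT_SCALE:
                        unit = t
                    elif t in ("RI", "MA", "DB"):
                        fmt = t
                continue
            parts = line.split()
            if len(parts) != 9:
                raise MeasurementIOError(
                    f"{path.name}:{lineno}: expected 9 columns (f + 4 S-parameter "
                    f"pairs), got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise MeasurementIOError(f"{path.name}:{lineno}: {exc}") from exc
            freqs.append(vals[0] * _UNIT_SCALE[unit])
            a, b = vals[3], vals[4]  # third pair = S21 in standard s2p order
            if fmt == "RI":
                s21.append(complex(a, b))
            elif fmt == "MA":
                s21.append(a * np.exp(1j * np.deg2rad(b)))
            else:  # DB
                s21.append(10.0 ** (a / 20.0) * np.exp(1j * np.deg2rad(b)))
    if not freqs:
        raise MeasurementIOError(f"{path.name}: no data records found")
    return np.asarray(freqs), np.asarray(s21)


def read_measurements(path, dialect: str = "touchstone_per_angle") -> MeasurementSet:
    """Load a measurement set from a directory of .s2p files or a CSV matrix."""
    path = Path(path)
    if dialect == "touchstone_per_angle":
        files = sorted(p for p in path.iterdir() if _ANGLE_RE.search(p.name))
        if not files:
            raise MeasurementIOError(f"no *_a<deg>.s2p files found in {path}")
        entries = []
        for p in files:
            ang = float(_ANGLE_RE.search(p.name).group(1))
            f, s = _parse_touchstone_s2p(p)
            entries.append((ang, p.name, f, s))
        entries.sort(key=lambda e: e[0])
        f0 = entries[0][2]
        bad = [name for _, name, f, _ in entries if not np.array_equal(f, f0)]
        if bad:
            raise MeasurementIOError(
                f"inconsistent frequency grids across files: {bad}"
            )
        return MeasurementSet(
            f0,
            np.array([e[0] for e in entries]),
            np.column_stack([e[3] for e in entries]),
            {"source": str(path), "dialect": dialect},
        )
    if dialect == "csv_matrix":
        return read_sinogram_csv(path)
    raise MeasurementIOError(
        f"unknown dialect {dialect!r}; use 'touchstone_per_angle' or 'csv_matrix'"
    )


def write_touchstone_per_angle(
    ms: MeasurementSet, directory, prefix: str = "meas", fmt: str = "RI"
) -> list[Path]:
    """Write one .s2p per angle (S21 carries the data; S11/S12/S22 zero)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("RI", "MA"):
        raise MeasurementIOError("fmt must be 'RI' or 'MA'")
    out = []
    for j, ang in enumerate(ms.angles_deg):
        p = directory / f"{prefix}_a{int(round(ang)):03d}.s2p"
        with open(p, "w") as fh:
            fh.write(f"! angle {ang} deg\n# HZ S {fmt} R 50\n")
            for f, s in zip(ms.frequencies, ms.s21[:, j]):
                if fmt == "RI":
                    pair = f"{s.real:.12e} {s.imag:.12e}"
                else:
                    pair = f"{abs(s):.12e} {np.rad2deg(np.angle(s)):.10f}"
                fh.write(f"{f:.17g} 0 0 {pair} 0 0 0 0\n")
        out.append(p)
    return out


def write_sinogram_csv(sg: Sinogram | MeasurementSet, path) -> None:
    """Write the CSV matrix dialect (f_Hz + interleaved re/im per angle)."""
    if isinstance(sg, Sinogram):
        freqs, angles, vals = sg.sweep.frequencies, sg.rotation.angles_deg, sg.values
    else:
        freqs, angles, vals = sg.frequencies, sg.angles_deg, sg.s21
    cols: dict[str, np.ndarray] = {"f_Hz": freqs}
    for j, a in enumerate(angles):
        cols[f"re_{a:g}"] = vals[:, j].real
        cols[f"im_{a:g}"] = vals[:, j].imag
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_sinogram_csv(path) -> MeasurementSet:
    """Read the CSV matrix dialect back into a MeasurementSet."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "f_Hz" not in df.columns:
        raise MeasurementIOError("CSV matrix must have an 'f_Hz' column")
    angles, data = [], []
    for col in df.columns:
        if col.startswith("re_"):
            ang = col[3:]
            im_col = f"im_{ang}"
            if im_col not in df.columns:
                raise MeasurementIOError(f"missing imaginary column {im_col!r}")
            angles.append(float(ang))
            data.append(df[col].to_numpy() + 1j * df[im_col].to_numpy())
    if not angles:
        raise MeasurementIOError("no re_<angle>/im_<angle> column pairs found")
    return MeasurementSet(
        df["f_Hz"].to_numpy(float),
        np.array(angles),
        np.column_stack(data),
        {"source": str(path), "dialect": "csv_matrix"},
    )


def save_sinogram_npz(sg: Sinogram, path, container_radius: float | None = None) -> None:
    """Compressed array container: values, f_Hz, angles_deg, eps_r, R0_m."""
    np.savez_compressed(
        path,
        values=sg.values,
        f_Hz=sg.sweep.frequencies,
        angles_deg=sg.rotation.angles_deg,
        eps_r=np.asarray(sg.medium_eps_r),
        R0_m=np.asarray(
            sg.metadata.get("ring_radius_m", np.nan)
            if container_radius is None
            else container_radius
        ),
    )


def load_sinogram_npz(path) -> Sinogram:
    with np.load(path) as z:
        f = z["f_Hz"]
        sweep = FrequencySweep(float(f[0]), float(f[-1]), f.size)
        rotation = AngularSweep(z["angles_deg"].size)
        eps = complex(z["eps_r"]) if np.iscomplexobj(z["eps_r"]) else float(z["eps_r"])
        meta = {"ring_radius_m": float(z["R0_m"])} if np.isfinite(z["R0_m"]) else {}
        return Sinogram(z["values"], sweep, rotation, eps, meta)


def subtract_reference(ms: MeasurementSet, ref: MeasurementSet) -> MeasurementSet:
    """Elementwise complex difference against an empty-tank reference sweep."""
    if not np.array_equal(ms.frequencies, ref.frequencies) or not np.array_equal(
        ms.angles_deg, ref.angles_deg
    ):
        raise MeasurementIOError(
            "measurement and reference grids differ "
            f"({ms.frequencies.size}x{ms.angles_deg.size} vs "
            f"{ref.frequencies.size}x{ref.angles_deg.size})"
        )
    meta = dict(ms.metadata)
    meta["reference"] = ref.metadata.get("source", "in-memory reference")
    return MeasurementSet(ms.frequencies, ms.angles_deg, ms.s21 - ref.s21, meta)


def range_profiles_to_csv(rps: RangeProfileSet, path) -> None:
    """Export range profiles: delay_s column + |profile| per angle."""
    cols: dict[str, np.ndarray] = {"delay_s": rps.delays}
    for j, a in enumerate(rps.angles_deg):
        cols[f"mag_{a:g}"] = np.abs(rps.values[:, j])
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
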