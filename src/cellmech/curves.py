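"""Force-curve data model and plain-text I/O.

A force curve is the record of cantilever deflection versus piezo (sample)
position acquired while an AFM tip approaches a surface.  Curves are stored
as tab-separated text: ``# key: value`` header lines carrying the probe
metadata, a column-name line, then two numeric columns — piezo position in
meters and deflection in meters (``deflection_m``) or photodetector volts
(``deflection_V``).  Values are written with ``repr`` so a write/read round
trip is bitwise exact.

Directory layout for a study::

    <group>/reference.tsv              # rigid-substrate calibration curve
    <group>/<cell_id>/curve_<gx>_<gy>.tsv
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ForceCurve",
    "CurveSet",
    "CurveFormatError",
    "read_curve",
    "write_curve",
    "load_curve_set",
    "write_curve_set",
]

MIN_SAMPLES = 50

_MANDATORY_KEYS = (
    "spring_constant_N_per_m",
    "half_angle_deg",
    "segment",
    "grid_x",
    "grid_y",
    "cell_id",
)


class CurveFormatError(ValueError):
    """Raised for malformed force-curve files (message carries line numbers)."""


@dataclass
class ForceCurve:
    """Raw deflection-vs-position record with probe metadata.

    Parameters
    ----------
    z : ndarray
        Piezo positions in meters, strictly monotonic, increasing toward the
        sample for approach segments.
    deflection : ndarray
        Cantilever deflection, meters or volts according to ``unit``.
    unit : {"m", "V"}
        Unit tag of ``deflection``.
    spring_constant : float
        Cantilever stiffness in N/m (converts deflection to force).
    sensitivity : float or None
        Deflection sensitivity in m/V; required to interpret volt curves.
    half_angle : float
        Opening half-angle of the conical tip, radians.
    """

    z: np.ndarray
    deflection: np.ndarray
    unit: str = "m"
    segment: str = "approach"
    spring_constant: float = 0.03
    sensitivity: float | None = None
    half_angle: float = math.radians(36.0)
    grid_x: int = 0
    grid_y: int = 0
    cell_id: str = ""
    group: str = ""
    baseline: tuple[float, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.ndim != 1 or self.deflection.ndim != 1:
            raise ValueError("z and deflection must be 1-D arrays")
        if len(self.z) != len(self.deflection):
            raise ValueError(
                f"length mismatch: {len(self.z)} z values vs "
                f"{len(self.deflection)} deflection values"
            )
        if len(self.z) < MIN_SAMPLES:
            raise ValueError(
                f"too few samples: {len(self.z)} < {MIN_SAMPLES} required"
            )
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotonic within a segment")
        if self.unit not in ("m", "V"):
            raise ValueError(f"unknown deflection unit tag {self.unit!r}")
        if self.segment not in ("approach", "retract"):
            raise ValueError(f"unknown segment {self.segment!r}")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")
        if not 0 < self.half_angle < math.pi / 2:
            raise ValueError("half_angle must lie in (0, pi/2) radians")

    def __len__(self) -> int:
        return len(self.z)

    def with_deflection(self, deflection: np.ndarray, **kw) -> "ForceCurve":
        """Copy of the curve with a new deflection array (metadata kept)."""
        return replace(self, deflection=np.asarray(deflection, float), **kw)


@dataclass
class CurveSet:
    """A group's curves plus its rigid-substrate reference curve."""

    curves: list[ForceCurve]
    reference: ForceCurve | None = None
    provenance: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[ForceCurve]:
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)

    def by_cell(self) -> dict[str, list[ForceCurve]]:
        out: dict[str, list[ForceCurve]] = {}
        for c in self.curves:
            out.setdefault(c.cell_id, []).append(c)
        return out


def write_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write ``curve`` in the TSV dialect with repr-exact float precision."""
    path = Path(path)
    lines = [
        f"# spring_constant_N_per_m: {curve.spring_constant!r}",
        f"# half_angle_deg: {math.degrees(curve.half_angle)!r}",
        f"# segment: {curve.segment}",
        f"# grid_x: {curve.grid_x}",
        f"# grid_y: {curve.grid_y}",
        f"# cell_id: {curve.cell_id}",
    ]
    if curve.sensitivity is not None:
        lines.insert(2, f"# sensitivity_m_per_V: {curve.sensitivity!r}")
    if curve.group:
        lines.append(f"# group: {curve.group}")
    defl_col = "deflection_m" if curve.unit == "m" else "deflection_V"
    lines.append(f"z_m\t{defl_col}")
    for z, d in zip(curve.z, curve.deflection):
        lines.append(f"{float(z)!r}\t{float(d)!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_curve(path: str | Path) -> ForceCurve:
    """Read a TSV force curve, validating headers and every data row."""
    path = Path(path)
    header: dict[str, str] = {}
    z_vals: list[float] = []
    d_vals: list[float] = []
    unit: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise CurveFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, val = body.split(":", 1)
                header[key.strip()] = val.strip()
            elif line.startswith("z_m"):
                cols = line.split("\t")
                if len(cols) < 2 or cols[1] not in ("deflection_m", "deflection_V"):
                    raise CurveFormatError(
                        f"{path}:{lineno}: unrecognized column line {line!r}"
                    )
                unit = "m" if cols[1] == "deflection_m" else "V"
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CurveFormatError(
                        f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                try:
                    z_vals.append(float(parts[0]))
                    d_vals.append(float(parts[1]))
                except ValueError as exc:
                    raise CurveFormatError(f"{path}:{lineno}: {exc}") from None
    if unit is None:
        raise CurveFormatError(f"{path}: missing column-name line (z_m ...)")
    for key in _MANDATORY_KEYS:
        if key not in header:
            raise CurveFormatError(f"{path}: missing mandatory header key {key!r}")
    sens = header.get("sensitivity_m_per_V")
    try:
        return ForceCurve(
            z=np.array(z_vals),
            deflection=np.array(d_vals),
            unit=unit,
            segment=header["segment"],
            spring_constant=float(header["spring_constant_N_per_m"]),
            sensitivity=float(sens) if sens is not None else None,
            half_angle=math.radians(float(header["half_angle_deg"])),
            grid_x=int(header["grid_x"]),
            grid_y=int(header["grid_y"]),
            cell_id=header["cell_id"],
            group=header.get("group", ""),
        )
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from None


def write_curve_set(cs: CurveSet, group_dir: str | Path) -> Path:
    """Write a group's curves under ``<group>/<cell_id>/curve_<gx>_<gy>.tsv``."""
    group_dir = Path(group_dir)
    if cs.reference is not None:
        write_curve(cs.reference, group_dir / "reference.tsv")
    for c in cs.curves:
        cell = c.cell_id or "cell"
        write_curve(c, group_dir / cell / f"curve_{c.grid_x}_{c.grid_y}.tsv")
    return group_dir


def load_curve_set(group_dir: str | Path) -> CurveSet:
    """Load every curve (and the reference, if present) of one group."""
    group_dir = Path(group_dir)
    if not group_dir.is_dir():
        raise FileNotFoundError(f"no such group directory: {group_dir}")
    curves, prov = [], []
    ref = None
    ref_path = group_dir / "reference.tsv"
    if ref_path.exists():
        ref = read_curve(ref_path)
        prov.append(str(ref_path))
    for p in sorted(group_dir.glob("*/curve_*_*.tsv")):
        curves.append(read_curve(p))
        prov.append(str(p))
    return CurveSet(curves=curves, reference=ref, provenance=prov)
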