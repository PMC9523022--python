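"""Study orchestration: simulate -> calibrate -> fit -> aggregate -> compare.

A :class:`StudyConfig` (YAML-loadable) names the groups — each either a
directory of recorded curves or a simulation spec — the depth windows and
probe constants, and a seed.  :func:`run_mechanics` processes every curve
through baseline correction, contact detection, calibration subtraction and
the Hertz-Sneddon fit at each window, aggregates map points to cells and
cells to groups, and runs all pairwise Mann-Whitney comparisons per window.
Outputs are plain CSVs plus a JSON run manifest (config hash, version,
seed); a fixed seed reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import ldh_viability, mts_relative
from .calibrate import fit_sensitivity, prepare_curve, to_force_indentation
from .curves import CurveSet, load_curve_set
from .hertz import DEFAULT_WINDOWS, aggregate_cell, aggregate_group, fit_modulus
from .morphometry import MaskPair, compute_morphometry, read_mask
from .stats import mann_whitney
from .synthetic import (
    AcquisitionProtocol,
    GroupSpec,
    simulate_cell_population,
    simulate_mask_pair,
    simulate_plate,
)

log = logging.getLogger("cellmech")

__all__ = ["StudyConfig", "MechanicsResults", "run_mechanics", "run_morphometry", "run_assays"]


@dataclass
class GroupConfig:
    label: str
    curves_dir: str | None = None
    simulate: dict | None = None  # GroupSpec fields (moduli in Pa) + n_cells

    def __post_init__(self) -> None:
        if (self.curves_dir is None) == (self.simulate is None):
            raise ValueError(
                f"group {self.label!r}: exactly one of curves_dir or simulate "
                "must be given"
            )


@dataclass
class StudyConfig:
    """Everything one mechanics/morphometry/assay run needs."""

    groups: list[GroupConfig]
    depth_windows: tuple[float, ...] = DEFAULT_WINDOWS
    half_angle_deg: float = 36.0
    poisson: float = 0.5
    spring_constant: float = 0.03
    n_samples: int = 512
    output_dir: str = "cellmech_out"
    seed: int = 0
    images_dir: str | None = None
    pixel_size_um: float = 0.5
    plates: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        windows = tuple(float(w) for w in self.depth_windows)
        if any(w <= 0 for w in windows) or list(windows) != sorted(windows):
            raise ValueError("depth_windows must be positive and ascending")
        self.depth_windows = windows

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        groups = [GroupConfig(**g) for g in raw.pop("groups", [])]
        return cls(groups=groups, **raw)

    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            n_samples=self.n_samples,
            spring_constant=self.spring_constant,
            half_angle=math.radians(self.half_angle_deg),
            poisson=self.poisson,
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "groups": [vars(g) for g in self.groups],
                "depth_windows": list(self.depth_windows),
                "half_angle_deg": self.half_angle_deg,
                "poisson": self.poisson,
                "spring_constant": self.spring_constant,
                "n_samples": self.n_samples,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class MechanicsResults:
    curves: pd.DataFrame
    cells: pd.DataFrame
    groups: pd.DataFrame
    comparisons: pd.DataFrame
    n_flagged: int
    n_failed: int


def _acquire_group(
    gc: GroupConfig, config: StudyConfig, group_index: int
) -> CurveSet:
    if gc.curves_dir is not None:
        cs = load_curve_set(gc.curves_dir)
        if not cs.curves:
            raise ValueError(f"group {gc.label!r}: empty group")
        return cs
    spec_kw = dict(gc.simulate)
    n_cells = int(spec_kw.pop("n_cells", 60))
    spec = GroupSpec(label=gc.label, **spec_kw)
    # disjoint per-group seed streams, extensible in group count
    group_seed = config.seed + 100_000 * (group_index + 1)
    cs, _ = simulate_cell_population(
        spec, n_cells=n_cells, protocol=config.protocol(), seed=group_seed
    )
    return cs


def run_mechanics(config: StudyConfig, write: bool = True) -> MechanicsResults:
    """Run the full mechanics pipeline and (optionally) write the CSV bundle."""
    outdir = Path(config.output_dir)
    curve_rows: list[dict] = []
    cell_rows: list[dict] = []
    group_rows: list[dict] = []
    per_group_cells: dict[str, list] = {}
    n_flagged = n_failed = 0

    for gi, gc in enumerate(config.groups):
        cs = _acquire_group(gc, config, gi)
        if cs.reference is None:
            raise ValueError(f"group {gc.label!r} has no reference curve")
        cal = fit_sensitivity(cs.reference)
        cells_mech = []
        for cell_id, curves in cs.by_cell().items():
            estimates = []
            for curve in curves:
                try:
                    cur, z0 = prepare_curve(curve)
                    ic = to_force_indentation(cur, cal=cal, contact_point=z0)
                    for w in config.depth_windows:
                        est = fit_modulus(
                            ic,
                            w,
                            half_angle=math.radians(config.half_angle_deg),
                            poisson=config.poisson,
                        )
                        estimates.append(est)
                        n_flagged += est.flagged
                        curve_rows.append(
                            {
                                "group": gc.label,
                                "cell_id": cell_id,
                                "grid_x": curve.grid_x,
                                "grid_y": curve.grid_y,
                                "window_nm": w * 1e9,
                                "modulus_kpa": est.modulus / 1e3,
                                "n_points": est.n_points,
                                "fit_rms_n": est.fit_rms,
                                "contact_point_m": z0,
                                "flagged": est.flagged,
                            }
                        )
                except (ValueError, RuntimeError) as exc:
                    n_failed += 1
                    log.warning(
                        "curve (%s, %d, %d) failed: %s",
                        cell_id, curve.grid_x, curve.grid_y, exc,
                    )
            cm = aggregate_cell(estimates)
            cells_mech.append(cm)
            row = {"group": gc.label, "cell_id": cell_id}
            for w in config.depth_windows:
                row[f"mean_kpa_{w * 1e9:.0f}nm"] = cm.mean[w] / 1e3
                row[f"median_kpa_{w * 1e9:.0f}nm"] = cm.median[w] / 1e3
                row[f"n_flagged_{w * 1e9:.0f}nm"] = cm.n_flagged[w]
            cell_rows.append(row)
        per_group_cells[gc.label] = cells_mech
        for w in config.depth_windows:
            gs = aggregate_group(cells_mech, w, label=gc.label)
            group_rows.append(
                {
                    "group": gc.label,
                    "window_nm": w * 1e9,
                    "n_cells": gs.n,
                    "mean_kpa": gs.mean / 1e3,
                    "median_kpa": gs.median / 1e3,
                    "sd_kpa": gs.sd / 1e3,
                    "p25_kpa": gs.p25 / 1e3,
                    "p75_kpa": gs.p75 / 1e3,
                }
            )

    comp_rows = []
    labels = [gc.label for gc in config.groups]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            for w in config.depth_windows:
                a = [c.mean[w] for c in per_group_cells[labels[i]]]
                b = [c.mean[w] for c in per_group_cells[labels[j]]]
                gcmp = mann_whitney(a, b, label_a=labels[i], label_b=labels[j])
                comp_rows.append(
                    {
                        "group_a": labels[i],
                        "group_b": labels[j],
                        "window_nm": w * 1e9,
                        "n_a": gcmp.n_a,
                        "n_b": gcmp.n_b,
                        "u_statistic": gcmp.u_statistic,
                        "p_value": gcmp.p_value,
                        "percent_change": gcmp.percent_change,
                        "stars": gcmp.stars,
                    }
                )

    results = MechanicsResults(
        curves=pd.DataFrame(curve_rows),
        cells=pd.DataFrame(cell_rows),
        groups=pd.DataFrame(group_rows),
        comparisons=pd.DataFrame(comp_rows),
        n_flagged=n_flagged,
        n_failed=n_failed,
    )
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        results.curves.to_csv(outdir / "curves.csv", index=False)
        results.cells.to_csv(outdir / "cells.csv", index=False)
        results.groups.to_csv(outdir / "groups.csv", index=False)
        results.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        _write_manifest(config, outdir)
        log.info(
            "mechanics run complete: %d curve fits (%d flagged, %d failed)",
            len(results.curves), n_flagged, n_failed,
        )
    return results


def run_morphometry(
    config: StudyConfig, write: bool = True, min_size_px: int = 30
) -> pd.DataFrame:
    """Morphometry over an image directory of ``<id>_cell/_nucleus`` pairs."""
    if config.images_dir is None:
        raise ValueError("config.images_dir not set")
    imdir = Path(config.images_dir)
    cell_paths = sorted(
        p for ext in ("png", "tif", "tiff") for p in imdir.glob(f"*_cell.{ext}")
    )
    if not cell_paths:
        raise ValueError(f"no *_cell.<png|tif> images found in {imdir}")
    rows = []
    for cp in cell_paths:
        stem = cp.name[: -len("_cell" + cp.suffix)]
        np_path = cp.with_name(f"{stem}_nucleus{cp.suffix}")
        if not np_path.exists():
            raise FileNotFoundError(f"missing nucleus mask for {cp}")
        pair = MaskPair(
            cell_mask=read_mask(cp),
            nucleus_mask=read_mask(np_path),
            pixel_size=config.pixel_size_um,
            image_id=stem,
        )
        res = compute_morphometry(pair, min_size_px=min_size_px)
        rows.append(
            {
                "image_id": stem,
                "group": res.group,
                "total_cell_area_um2": res.total_cell_area,
                "nucleus_count": res.nucleus_count,
                "sa_um2": res.sa,
                "nc_ratio": res.nc_ratio,
            }
        )
    df = pd.DataFrame(rows)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "morphometry.csv", index=False)
    return df


def run_assays(config: StudyConfig, write: bool = True) -> pd.DataFrame:
    """MTS normalization and LDH viability over the configured plate files.

    Each entry of ``config.plates`` is
    ``{path, assay: MTS|LDH, control: <condition>}`` — for LDH, ``control``
    names the maximum-release condition (maxLDH).
    """
    if not config.plates:
        raise ValueError("config.plates is empty")
    rows = []
    for spec in config.plates:
        plate = pd.read_csv(spec["path"])
        assay = spec.get("assay", "MTS").upper()
        if assay == "MTS":
            rel = mts_relative(plate, spec["control"])
            for cond, sub in rel.groupby("condition"):
                rows.append(
                    {
                        "plate": spec["path"],
                        "assay": "MTS",
                        "condition": cond,
                        "value": float(sub["relative"].mean()),
                        "sd": float(sub["relative"].std(ddof=1))
                        if len(sub) > 1
                        else 0.0,
                        "n": len(sub),
                    }
                )
        elif assay == "LDH":
            maxsel = plate.loc[plate["condition"] == spec["control"], "od"]
            if maxsel.empty:
                raise ValueError(
                    f"maxLDH condition {spec['control']!r} not in plate"
                )
            max_mean = float(maxsel.mean())
            max_sd = float(maxsel.std(ddof=1)) if len(maxsel) > 1 else 0.0
            for cond, sub in plate.groupby("condition"):
                if cond == spec["control"]:
                    continue
                v = ldh_viability(
                    float(sub["od"].mean()),
                    max_mean,
                    float(sub["od"].std(ddof=1)) if len(sub) > 1 else 0.0,
                    max_sd,
                )
                rows.append(
                    {
                        "plate": spec["path"],
                        "assay": "LDH",
                        "condition": cond,
                        "value": v.viability_percent,
                        "sd": v.max_error_percent,
                        "n": len(sub),
                    }
                )
        else:
            raise ValueError(f"unknown assay {assay!r}")
    df = pd.DataFrame(rows)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "assays.csv", index=False)
    return df


def simulate_study(config: StudyConfig, outdir: str | Path | None = None) -> Path:
    """Write a synthetic study (curves + masks + plate) to disk for the CLI."""
    from .curves import write_curve_set
    from .morphometry import write_mask

    outdir = Path(outdir or config.output_dir)
    for gi, gc in enumerate(config.groups):
        if gc.simulate is None:
            continue
        cs = _acquire_group(gc, config, gi)
        write_curve_set(cs, outdir / "curves" / gc.label)
    cell_mask, nucleus_mask, _ = simulate_mask_pair(
        n_cells=8, seed=config.seed, image_shape=(384, 384)
    )
    write_mask(cell_mask, outdir / "images" / "sim00_cell.png")
    write_mask(nucleus_mask, outdir / "images" / "sim00_nucleus.png")
    plate = simulate_plate(
        {"control": 1.0, "treated": 0.8}, noise_sd=0.03, seed=config.seed
    )
    (outdir / "plates").mkdir(parents=True, exist_ok=True)
    plate.to_csv(outdir / "plates" / "mts.csv", index=False)
    _write_manifest(config, outdir)
    return outdir


def _write_manifest(config: StudyConfig, outdir: Path) -> None:
    manifest = {
        "tool": "cellmech",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
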