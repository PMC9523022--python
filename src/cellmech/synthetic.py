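"""Synthetic data with known ground truth for every pipeline stage.

Force curves are generated by *inverting* the Hertz–Sneddon cone contact law
through the cantilever compliance.  For a rigid cone of half-angle ``alpha``
indenting an incompressible elastic half-space, the load force is

    F(delta) = (2 tan(alpha) / pi) * E / (1 - mu^2) * delta^2

With cantilever stiffness ``k``, the measured deflection ``d`` at piezo
travel ``s = z - z0`` past the contact point solves the force balance

    k * d = F(s - d)

which is quadratic in ``d`` and solved in closed form, so generated curves
are exact to machine precision (noise-free) and independent of sampling
density.

Depth-dependent stiffness is modelled as a two-layer fixture: the modulus is
``modulus_shallow`` down to ``transition_depth`` and ``modulus_deep`` below
it, with the *force* kept continuous at the transition by integrating the
piecewise stiffness:

    F(delta) = C_s * delta^2                               delta <= t
    F(delta) = C_s * t^2 + C_d * (delta^2 - t^2)           delta >  t

This is a verification device for depth-windowed fitting, not a physical
claim about cell architecture.  The effective (secant) modulus recovered by
an origin-constrained fit at depth ``delta`` is given by
:func:`effective_modulus`.

The module also fabricates fluorescence-style mask pairs (disk-shaped cells
with concentric nuclei, exact pixel areas returned) and ELISA-style plate
tables with known condition means, so morphometry and assay arithmetic have
exact oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import ForceCurve, CurveSet

__all__ = [
    "MechanicalGroundTruth",
    "AcquisitionProtocol",
    "GroupSpec",
    "MaskGroundTruth",
    "cone_prefactor",
    "hertz_force",
    "effective_modulus",
    "simulate_force_curve",
    "simulate_reference_curve",
    "draw_cell_moduli",
    "simulate_cell_population",
    "simulate_mask_pair",
    "simulate_plate",
]


def cone_prefactor(modulus: float, half_angle: float, poisson: float) -> float:
    """Prefactor C of the cone contact law F = C * delta**2 (units Pa)."""
    return 2.0 * math.tan(half_angle) / math.pi * modulus / (1.0 - poisson**2)


@dataclass(frozen=True)
class MechanicalGroundTruth:
    """Generator truth for one simulated sample point.

    ``modulus_shallow``/``modulus_deep`` in Pa; equal values give a
    homogeneous sample.  ``baseline_offset`` (m) and ``baseline_slope``
    (m deflection per m travel) describe an additive optical baseline,
    ``noise_sd`` (m) white Gaussian deflection noise.
    """

    modulus_shallow: float
    modulus_deep: float | None = None
    transition_depth: float = 600e-9
    contact_point: float = 4e-6
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modulus_deep is None:
            object.__setattr__(self, "modulus_deep", self.modulus_shallow)
        if not self.modulus_shallow > 0 or not self.modulus_deep > 0:
            raise ValueError("moduli must be > 0")
        if not self.transition_depth > 0:
            raise ValueError("transition_depth must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def homogeneous(self) -> bool:
        return self.modulus_shallow == self.modulus_deep


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Instrument settings shared by every curve of an acquisition.

    Defaults follow a soft-cantilever cell-indentation setup: nominal spring
    constant 0.03 N/m, conical tip of 36 deg half-angle, incompressible
    sample (Poisson ratio 0.5), a 10 um ramp sampled at 512 points.  A deep
    ramp relative to the analysis windows is deliberate: on soft cells the
    contact point is identified by the curvature of the deep contact
    region, so generous post-contact travel is what makes shallow-window
    moduli reliable.  ``sensitivity`` set to a value in m/V makes
    the generator emit volt-unit curves as a real photodetector would.
    """

    z_start: float = 0.0
    z_end: float = 10e-6
    n_samples: int = 512
    spring_constant: float = 0.03
    sensitivity: float | None = None
    half_angle: float = math.radians(36.0)
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")
        if not 0 < self.half_angle < math.pi / 2:
            raise ValueError("half_angle must lie in (0, pi/2)")
        if not 0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")
        if not self.z_end > self.z_start:
            raise ValueError("z_end must exceed z_start")

    def z_grid(self) -> np.ndarray:
        return np.linspace(self.z_start, self.z_end, self.n_samples)


def hertz_force(
    delta: np.ndarray | float,
    truth: MechanicalGroundTruth,
    half_angle: float,
    poisson: float,
) -> np.ndarray:
    """Ground-truth force at indentation ``delta`` (two-layer aware)."""
    delta = np.asarray(delta, dtype=float)
    c_s = cone_prefactor(truth.modulus_shallow, half_angle, poisson)
    c_d = cone_prefactor(truth.modulus_deep, half_angle, poisson)
    t = truth.transition_depth
    shallow = c_s * delta**2
    deep = c_s * t**2 + c_d * (delta**2 - t**2)
    return np.where(delta <= t, shallow, deep)


def effective_modulus(truth: MechanicalGroundTruth, delta: float) -> float:
    """Secant modulus an origin-constrained quadratic fit sees at ``delta``.

    Equals ``modulus_shallow`` within the first layer; beyond the transition
    it is the depth-weighted mixture
    ``(E_s * t**2 + E_d * (delta**2 - t**2)) / delta**2``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    t = truth.transition_depth
    if delta <= t:
        return truth.modulus_shallow
    return (
        truth.modulus_shallow * t**2
        + truth.modulus_deep * (delta**2 - t**2)
    ) / delta**2


def _solve_deflection(
    s: np.ndarray,
    truth: MechanicalGroundTruth,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Closed-form deflection for piezo travel ``s >= 0`` past contact.

    Solves k*d = F(s - d) per sample; the shallow-branch root uses the
    numerically stable form (no cancellation for soft samples).
    """
    k = protocol.spring_constant
    c_s = cone_prefactor(truth.modulus_shallow, protocol.half_angle, protocol.poisson)
    c_d = cone_prefactor(truth.modulus_deep, protocol.half_angle, protocol.poisson)
    t = truth.transition_depth

    s = np.asarray(s, dtype=float)
    # shallow branch: c_s*d^2 - (2 c_s s + k) d + c_s s^2 = 0, smaller root
    d = 2.0 * c_s * s**2 / (2.0 * c_s * s + k + np.sqrt(k**2 + 4.0 * c_s * k * s))
    delta = s - d
    past = delta > t
    if np.any(past) and c_d != c_s:
        # deep branch in delta: c_d*delta^2 + k*delta + (c_s - c_d)*t^2 - k*s = 0
        sp = s[past]
        disc = k**2 - 4.0 * c_d * ((c_s - c_d) * t**2 - k * sp)
        delta_deep = (-k + np.sqrt(disc)) / (2.0 * c_d)
        d = d.copy()
        d[past] = sp - delta_deep
    return d


def simulate_force_curve(
    truth: MechanicalGroundTruth,
    protocol: AcquisitionProtocol,
    *,
    cell_id: str = "synthetic",
    group: str = "",
    grid_x: int = 0,
    grid_y: int = 0,
    rng: np.random.Generator | None = None,
) -> ForceCurve:
    """Generate one approach curve on an elastic sample.

    Deflection past contact satisfies the compliance-coupled contact law
    exactly (noise-free); before contact it is the baseline alone.  Baseline
    and Gaussian noise are added to the whole record, as an instrument's
    optics would.  Same seed, same curve, bit for bit.
    """
    z = protocol.z_grid()
    z0 = truth.contact_point
    if z0 >= z[-1]:
        raise ValueError(
            "no contact region: contact point lies at or beyond the piezo travel"
        )
    s = np.clip(z - z0, 0.0, None)
    d = _solve_deflection(s, truth, protocol)
    d = d + truth.baseline_offset + truth.baseline_slope * z
    if truth.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        d = d + rng.normal(0.0, truth.noise_sd, size=d.shape)
    unit = "m"
    if protocol.sensitivity is not None:
        d = d / protocol.sensitivity
        unit = "V"
    return ForceCurve(
        z=z,
        deflection=d,
        unit=unit,
        segment="approach",
        spring_constant=protocol.spring_constant,
        sensitivity=protocol.sensitivity,
        half_angle=protocol.half_angle,
        grid_x=grid_x,
        grid_y=grid_y,
        cell_id=cell_id,
        group=group,
    )


def simulate_reference_curve(
    protocol: AcquisitionProtocol,
    contact_point: float,
    noise_sd: float = 0.0,
    *,
    group: str = "",
    seed: int = 0,
) -> ForceCurve:
    """Rigid-substrate calibration curve (Petri-dish bottom).

    Past contact the deflection tracks the piezo travel one-to-one (slope 1
    in meters, 1/sensitivity in volts); before contact it is flat.  The
    contact point is snapped to the nearest sample of the piezo grid so the
    recorded kink coincides with a sample.
    """
    z = protocol.z_grid()
    if contact_point >= z[-1]:
        raise ValueError("no contact region: contact point beyond piezo travel")
    z0 = float(z[np.argmin(np.abs(z - contact_point))])
    d = np.where(z > z0, z - z0, 0.0)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, size=d.shape)
    unit = "m"
    if protocol.sensitivity is not None:
        d = d / protocol.sensitivity
        unit = "V"
    return ForceCurve(
        z=z,
        deflection=d,
        unit=unit,
        segment="approach",
        spring_constant=protocol.spring_constant,
        sensitivity=protocol.sensitivity,
        half_angle=protocol.half_angle,
        cell_id="reference",
        group=group,
    )


@dataclass(frozen=True)
class GroupSpec:
    """Population-level truth for one experimental group.

    Cell-to-cell apparent moduli are drawn from a log-normal parametrized by
    its *linear-space* mean and SD (moduli are positive and right-skewed).
    ``within_cell_cv`` scatters the 36 map points of a cell around the cell
    modulus (log-normal, unit mean); 0 makes every map point identical.
    ``deep_ratio`` scales the deep-layer modulus relative to the shallow one
    (1.0 = homogeneous cells).
    """

    label: str
    mean_modulus: float = 2400.0
    sd_modulus: float = 1310.0
    within_cell_cv: float = 0.0
    deep_ratio: float = 1.0
    transition_depth: float = 600e-9
    noise_sd: float = 0.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_modulus > 0 or not self.sd_modulus >= 0:
            raise ValueError("mean_modulus must be > 0 and sd_modulus >= 0")
        if self.within_cell_cv < 0 or self.noise_sd < 0:
            raise ValueError("within_cell_cv and noise_sd must be >= 0")
        if not self.deep_ratio > 0:
            raise ValueError("deep_ratio must be > 0")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log so the linear-space mean and SD are as given."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def draw_cell_moduli(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` per-cell moduli (Pa) from the group log-normal."""
    mu, sigma = _lognormal_params(mean, sd)
    if sigma == 0:
        return np.full(n, mean)
    return rng.lognormal(mu, sigma, size=n)


def simulate_cell_population(
    group_spec: GroupSpec,
    n_cells: int,
    protocol: AcquisitionProtocol | None = None,
    grid: tuple[int, int] = (6, 6),
    seed: int = 0,
) -> tuple[CurveSet, pd.DataFrame]:
    """Simulate a group: ``n_cells`` cells x one force map of ``grid`` curves.

    Per-cell sub-seeds are ``seed + cell_index`` so extending ``n_cells``
    never reshuffles previously generated cells.  Returns the curves (with a
    noise-free rigid reference) and the ground-truth table, one row per
    curve, with cell- and point-level moduli in Pa.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if protocol is None:
        protocol = AcquisitionProtocol()
    gx_n, gy_n = grid
    cell_rng = np.random.default_rng(seed)
    cell_moduli = draw_cell_moduli(
        group_spec.mean_modulus, group_spec.sd_modulus, n_cells, cell_rng
    )
    curves: list[ForceCurve] = []
    rows: list[dict] = []
    for ci in range(n_cells):
        cell_id = f"{group_spec.label}_cell{ci:03d}"
        sub = np.random.default_rng(seed + ci + 1)
        e_cell = float(cell_moduli[ci])
        for gy in range(gy_n):
            for gx in range(gx_n):
                if group_spec.within_cell_cv > 0:
                    mu, sg = _lognormal_params(1.0, group_spec.within_cell_cv)
                    e_point = e_cell * float(sub.lognormal(mu, sg))
                else:
                    e_point = e_cell
                truth = MechanicalGroundTruth(
                    modulus_shallow=e_point,
                    modulus_deep=e_point * group_spec.deep_ratio,
                    transition_depth=group_spec.transition_depth,
                    baseline_offset=group_spec.baseline_offset,
                    baseline_slope=group_spec.baseline_slope,
                    noise_sd=group_spec.noise_sd,
                )
                curves.append(
                    simulate_force_curve(
                        truth,
                        protocol,
                        cell_id=cell_id,
                        group=group_spec.label,
                        grid_x=gx,
                        grid_y=gy,
                        rng=sub,
                    )
                )
                rows.append(
                    {
                        "group": group_spec.label,
                        "cell_id": cell_id,
                        "grid_x": gx,
                        "grid_y": gy,
                        "cell_modulus_pa": e_cell,
                        "point_modulus_pa": e_point,
                        "contact_point_m": truth.contact_point,
                    }
                )
    reference = simulate_reference_curve(
        protocol, contact_point=0.5 * (protocol.z_start + protocol.z_end),
        group=group_spec.label,
    )
    return CurveSet(curves=curves, reference=reference), pd.DataFrame(rows)


@dataclass(frozen=True)
class MaskGroundTruth:
    """Exact pixel bookkeeping for a simulated mask pair."""

    n_cells: int
    cell_areas_px: tuple[int, ...]
    nucleus_areas_px: tuple[int, ...]
    pixel_size_um: float

    @property
    def total_cell_area_px(self) -> int:
        return int(sum(self.cell_areas_px))

    @property
    def total_nucleus_area_px(self) -> int:
        return int(sum(self.nucleus_areas_px))


def _disk(shape: tuple[int, int], cy: int, cx: int, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def simulate_mask_pair(
    n_cells: int,
    cell_radius_px: float = 20.0,
    nucleus_fraction: float = 0.5,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.5,
    seed: int = 0,
    max_tries: int = 2000,
):
    """Disk-shaped cells with concentric nuclei and exact ground truth.

    Returns ``(cell_mask, nucleus_mask, truth)`` with boolean masks.  Disks
    are placed by rejection sampling with a 2-pixel clearance; placement
    failure after ``max_tries`` raises rather than silently overlapping.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0 < nucleus_fraction < 1:
        raise ValueError("nucleus_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    r = float(cell_radius_px)
    margin = int(math.ceil(r)) + 1
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping disks of radius "
                f"{r} in {image_shape} after {max_tries} tries"
            )
        tries += 1
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r + 2) ** 2 for y, x in centers):
            centers.append((cy, cx))
    cell_mask = np.zeros(image_shape, dtype=bool)
    nucleus_mask = np.zeros(image_shape, dtype=bool)
    cell_areas, nuc_areas = [], []
    for cy, cx in centers:
        cdisk = _disk(image_shape, cy, cx, r)
        ndisk = _disk(image_shape, cy, cx, r * nucleus_fraction)
        cell_mask |= cdisk
        nucleus_mask |= ndisk
        cell_areas.append(int(cdisk.sum()))
        nuc_areas.append(int(ndisk.sum()))
    truth = MaskGroundTruth(
        n_cells=n_cells,
        cell_areas_px=tuple(cell_areas),
        nucleus_areas_px=tuple(nuc_areas),
        pixel_size_um=pixel_size_um,
    )
    return cell_mask, nucleus_mask, truth


def simulate_plate(
    condition_means: dict[str, float] | Sequence[tuple[str, float]],
    noise_sd: float = 0.0,
    replicates: int = 12,
    seed: int = 0,
    assay: str = "MTS",
) -> pd.DataFrame:
    """Long-format plate table (condition, well, od) with known means.

    Twelve replicates per condition by default, matching a 3-repetition
    ELISA design read four wells at a time.  Optical densities are clipped
    at zero (a plate reader reports non-negative absorbance).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    items = list(condition_means.items()) if isinstance(condition_means, dict) else list(condition_means)
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mean in items:
        if mean < 0:
            raise ValueError(f"condition mean must be >= 0, got {mean} for {cond!r}")
        ods = np.full(replicates, float(mean))
        if noise_sd > 0:
            ods = ods + rng.normal(0.0, noise_sd, size=replicates)
        ods = np.clip(ods, 0.0, None)
        for i, od in enumerate(ods):
            rows.append(
                {"condition": cond, "well": f"{cond}_{i:02d}", "od": float(od), "assay": assay}
            )
    return pd.DataFrame(rows)
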