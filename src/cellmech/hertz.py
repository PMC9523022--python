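"""Apparent Young's modulus from force-indentation curves.

For a conical tip on an incompressible half-space the contact law is
``F = (2 tan(alpha)/pi) * E/(1 - mu^2) * delta^2``.  With the contact point
fixed upstream, E is the origin-constrained least-squares slope of F against
``(2 tan(alpha)/pi) * delta^2 / (1 - mu^2)`` over a depth window
``[0, delta_max]``.  Two windows are analyzed by default — 400 nm, probing
mostly the actin cortex, and 1200 nm, mixing in deeper structures — and
estimates aggregate map points -> cell (mean of the 6x6 map) -> group
(statistics over per-cell means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibrate import IndentationCurve
from .stats import GroupStats, summarize

__all__ = [
    "DEFAULT_WINDOWS",
    "ModulusEstimate",
    "CellMechanics",
    "fit_modulus",
    "aggregate_cell",
    "aggregate_group",
]

DEFAULT_WINDOWS = (400e-9, 1200e-9)


@dataclass(frozen=True)
class ModulusEstimate:
    """Apparent modulus of one curve over one depth window.

    Non-physical fits (non-positive slope) are flagged, never clipped, and
    excluded from aggregation with a recorded reason.
    """

    modulus: float  # Pa (apparent)
    depth_window: float  # delta_max, m
    n_points: int
    fit_rms: float  # N
    half_angle: float
    poisson: float
    cell_id: str = ""
    grid_x: int = 0
    grid_y: int = 0
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class CellMechanics:
    """Per-cell aggregation of map-point estimates, one entry per window."""

    cell_id: str
    estimates: dict[float, list[ModulusEstimate]]
    mean: dict[float, float]
    median: dict[float, float]
    n_flagged: dict[float, int]


def _window_ml_modulus(
    ic: IndentationCurve,
    delta_max: float,
    e_lin: float,
    prefactor: float,
) -> float:
    """Window modulus by least squares in deflection-vs-travel coordinates.

    The measured pair (delta, F) derives from one noisy deflection sample d
    via F = k*d, delta = s - d, so ``s = delta + F/k`` and ``d = F/k``
    reconstruct the instrument coordinates exactly.  Fitting the
    compliance-coupled contact law d(s; C) there puts all the noise on the
    ordinate, and the depth window is cut on the *noise-free* travel axis
    at ``s_max = delta_max + C*delta_max**2/k`` (the travel where the model
    reaches delta_max), iterated once as C updates.  Windowing on the noisy
    delta itself, or dropping samples with delta < 0, censors the noise
    near the boundaries and skews soft-sample shallow-window estimates; in
    (delta, F) coordinates the linearized slope additionally squares a
    noisy abscissa anti-correlated with the ordinate.  Noise-free data give
    exactly the linearized result.
    """
    from scipy.optimize import minimize_scalar

    k = ic.spring_constant
    d = ic.force / k
    s = ic.delta + d

    def rss(log_c: float, s_w, d_w) -> float:
        c = math.exp(log_c)
        pred = 2.0 * c * s_w**2 / (
            2.0 * c * s_w + k + np.sqrt(k**2 + 4.0 * c * k * s_w)
        )
        r = pred - d_w
        return float(r @ r)

    c_hat = max(e_lin * prefactor, 1e-9)
    for _ in range(2):
        s_max = delta_max + c_hat * delta_max**2 / k
        sel = (s >= 0) & (s <= s_max)
        if int(sel.sum()) < 3:
            break
        res = minimize_scalar(
            rss,
            args=(s[sel], d[sel]),
            bounds=(math.log(c_hat) - 6.0, math.log(c_hat) + 6.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        c_hat = math.exp(res.x)
    return c_hat / prefactor


def fit_modulus(
    ic: IndentationCurve,
    delta_max: float,
    half_angle: float | None = None,
    poisson: float = 0.5,
    min_points: int = 10,
    method: str = "compliance",
) -> ModulusEstimate:
    """Origin-constrained Hertz-Sneddon fit over ``[0, delta_max]``.

    ``method="linear"`` is the closed-form slope E = sum(x*F)/sum(x^2) with
    x = (2 tan(alpha)/pi) * delta^2/(1 - mu^2).  The default
    ``"compliance"`` refines that slope by least squares in the raw
    deflection-vs-travel coordinates (see :func:`_window_ml_modulus`): it
    is identical on noise-free data but stays unbiased when the in-window
    signal approaches the deflection noise.  Both are deterministic.
    Non-positive linearized slopes are flagged, never refined or clipped.
    """
    if not delta_max > 0:
        raise ValueError("delta_max must be > 0")
    if method not in ("compliance", "linear"):
        raise ValueError(f"unknown method {method!r}")
    if half_angle is None:
        half_angle = ic.half_angle
    mask = ic.fit_mask & (ic.delta <= delta_max)
    n = int(mask.sum())
    if n < min_points:
        raise ValueError(
            f"too few samples in window [0, {delta_max:g} m]: {n} < {min_points}"
        )
    delta = ic.delta[mask]
    force = ic.force[mask]
    prefactor = (2.0 * math.tan(half_angle) / math.pi) / (1.0 - poisson**2)
    x = prefactor * delta**2
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("window contains only zero indentation")
    e_hat = float(x @ force) / sxx
    flagged = not e_hat > 0
    if not flagged and method == "compliance":
        e_hat = _window_ml_modulus(ic, delta_max, e_hat, prefactor)
    resid = force - e_hat * x
    rms = float(np.sqrt(np.mean(resid**2)))
    return ModulusEstimate(
        modulus=e_hat,
        depth_window=float(delta_max),
        n_points=n,
        fit_rms=rms,
        half_angle=half_angle,
        poisson=poisson,
        cell_id=ic.cell_id,
        grid_x=ic.grid_x,
        grid_y=ic.grid_y,
        flagged=flagged,
        flag_reason="non-positive modulus" if flagged else "",
    )


def aggregate_cell(estimates: list[ModulusEstimate]) -> CellMechanics:
    """Collapse one cell's map-point estimates to per-window mean/median.

    Flagged estimates are excluded and counted; a window with nothing left
    is an error (the cell carries no usable signal there).
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    cell_ids = {e.cell_id for e in estimates}
    if len(cell_ids) > 1:
        raise ValueError(f"estimates span multiple cells: {sorted(cell_ids)}")
    by_window: dict[float, list[ModulusEstimate]] = {}
    for e in estimates:
        by_window.setdefault(e.depth_window, []).append(e)
    mean, median, n_flagged = {}, {}, {}
    for w, ests in by_window.items():
        good = [e.modulus for e in ests if not e.flagged]
        n_flagged[w] = sum(e.flagged for e in ests)
        if not good:
            raise ValueError(
                f"all {len(ests)} estimates flagged in window {w:g} m "
                f"for cell {estimates[0].cell_id!r}"
            )
        mean[w] = float(np.mean(good))
        median[w] = float(np.median(good))
    return CellMechanics(
        cell_id=estimates[0].cell_id,
        estimates=by_window,
        mean=mean,
        median=median,
        n_flagged=n_flagged,
    )


def aggregate_group(
    cells: list[CellMechanics], window: float, label: str = ""
) -> GroupStats:
    """Group statistics (mean/median/SD/quartiles, Pa) over per-cell means."""
    if not cells:
        raise ValueError("empty group")
    values = [c.mean[window] for c in cells]
    return summarize(values, label=label)
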