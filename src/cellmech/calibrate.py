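"""Raw-curve calibration: sensitivity, baseline, contact point, indentation.

The measurement chain is the standard AFM one.  A reference curve on the
rigid dish bottom gives the deflection sensitivity (contact-region slope);
a straight line fitted to the pre-contact region removes the optical
baseline; the contact point ``z0`` is located by an exhaustive two-piece
least-squares scan (flat zero before ``z0``, power-law ``a*(z - z0)^p``
after, ``p = 2`` for a cone); finally the calibration subtraction

    delta = (z - z0) - d,     F = k * d

turns deflection-vs-position into force-vs-indentation.  Processing the
rigid reference through the same subtraction yields zero indentation — the
identity the reference-curve procedure relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import ForceCurve

__all__ = [
    "CalibrationResult",
    "IndentationCurve",
    "DegenerateCurveError",
    "fit_sensitivity",
    "correct_baseline",
    "detect_contact_point",
    "to_force_indentation",
]


class DegenerateCurveError(ValueError):
    """Curve is all-baseline or all-contact; no contact point exists."""


@dataclass(frozen=True)
class CalibrationResult:
    """Sensitivity calibration from a rigid-substrate reference curve."""

    sensitivity: float  # m/V (1.0 for meter-unit curves)
    fit_window: tuple[int, int]
    residual_rms: float  # in the curve's own deflection unit
    reference_contact_point: float  # m

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be > 0")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


@dataclass
class IndentationCurve:
    """Force vs. indentation for the past-contact part of one curve.

    ``delta`` may contain small negatives from contact-point error; the
    fitted region (``fit_mask``) keeps ``delta >= 0`` only.
    """

    delta: np.ndarray  # m
    force: np.ndarray  # N
    contact_point: float  # m
    baseline: tuple[float, float] | None
    spring_constant: float
    half_angle: float
    sensitivity: float | None = None
    cell_id: str = ""
    group: str = ""
    grid_x: int = 0
    grid_y: int = 0
    fit_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, float)
        self.force = np.asarray(self.force, float)
        if len(self.delta) != len(self.force):
            raise ValueError("delta and force must have equal length")
        if self.fit_mask is None:
            self.fit_mask = self.delta >= 0


def _segment_line_rss(z: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix/suffix residual sums of squares of per-segment line fits.

    Returns ``(pre[i], post[i])`` where ``pre[i]`` is the RSS of a free
    straight line fitted to samples ``[0, i)`` and ``post[i]`` to
    ``[i, n)``, all in O(n) via cumulative sums.
    """

    def _rss_from_sums(n, sz, szz, sd, szd, sdd):
        with np.errstate(invalid="ignore", divide="ignore"):
            vz = szz - sz**2 / n
            czd = szd - sz * sd / n
            vd = sdd - sd**2 / n
            rss = vd - np.where(vz > 0, czd**2 / np.where(vz > 0, vz, 1.0), 0.0)
        return np.clip(np.nan_to_num(rss, nan=0.0), 0.0, None)

    ones = np.ones_like(d)
    arrays = [ones, z, z * z, d, z * d, d * d]
    pre_sums = [np.concatenate([[0.0], np.cumsum(a)]) for a in arrays]
    n_, sz, szz, sd, szd, sdd = pre_sums
    pre = _rss_from_sums(np.maximum(n_, 1), sz, szz, sd, szd, sdd)
    tot = [p[-1] for p in pre_sums]
    n2, sz2, szz2, sd2, szd2, sdd2 = [t - p for t, p in zip(tot, pre_sums)]
    post = _rss_from_sums(np.maximum(n2, 1), sz2, szz2, sd2, szd2, sdd2)
    return pre, post


def _coarse_contact_index(z: np.ndarray, d: np.ndarray) -> int:
    """Rough first-contact sample via a two-segment line breakpoint scan.

    Scans every breakpoint and scores "free line before, free line after"
    by total RSS — robust to baseline tilt and to contact anywhere in the
    ramp, with no noise-threshold tuning.  A curve that two segments fit no
    better than one line (all baseline, or all contact) is degenerate.
    """
    n = len(z)
    if n < 20:
        raise DegenerateCurveError("degenerate curve: too few samples")
    pre, post = _segment_line_rss(z, d)
    lo, hi = 5, n - 5
    total = pre[lo:hi] + post[lo:hi]
    bi = lo + int(np.argmin(total))
    rss_two = float(total.min())
    rss_one = float(post[0])  # single line over everything
    scale = float(np.sum(d * d)) or 1.0
    if rss_one - rss_two <= 0.01 * rss_one + 1e-20 * scale:
        raise DegenerateCurveError(
            "degenerate curve: no distinct baseline and contact segments"
        )
    # The optimal two-line breakpoint sits deep inside a convex contact
    # region (the chord absorbs the gentle onset), but its *pre* segment is
    # guaranteed to be mostly baseline, so the first half of it gives a
    # clean line; from there, locate the first sustained rise above the
    # noise band and tighten the line fit once or twice.
    ci = bi
    fit_stop = max(int(0.5 * bi), 10)
    for _ in range(3):
        coef = np.polyfit(z[:fit_stop], d[:fit_stop], 1)
        r = d - np.polyval(coef, z)
        med = np.median(r[:fit_stop])
        sigma = 1.4826 * float(np.median(np.abs(r[:fit_stop] - med)))
        span = float(np.max(np.abs(r))) or 1.0
        thr = max(5.0 * sigma, 1e-4 * span, 1e-15)
        below = np.nonzero(r - med <= thr)[0]
        if len(below) == 0 or below[-1] + 1 >= n:
            raise DegenerateCurveError(
                "degenerate curve: no distinct baseline and contact segments"
            )
        ci = int(below[-1]) + 1
        new_stop = max(int(0.9 * ci), 10)
        if new_stop == fit_stop:
            break
        fit_stop = new_stop
    return ci


def correct_baseline(
    curve: ForceCurve,
    min_pre_fraction: float = 0.3,
    contact_point: float | None = None,
) -> ForceCurve:
    """Subtract a straight line fitted to the pre-contact region.

    Without a ``contact_point`` the pre-contact region comes from a coarse
    threshold pass; it must cover at least ``min_pre_fraction`` of the
    samples.  The threshold pass cannot see a very gradual contact onset
    (soft samples), which leaks early-contact rise into the baseline fit
    and tilts it — so once a contact point has been detected properly, call
    again with ``contact_point`` to refit strictly before it (a few samples
    of standoff).  The fitted (offset, slope) is recorded on the returned
    curve; always applied to the *raw* deflection, so the call is
    idempotent in effect.
    """
    z, d = curve.z, curve.deflection
    if curve.baseline is not None:
        b0, b1 = curve.baseline  # undo previous correction, refit from raw
        d = d + b0 + b1 * z
    ci = _coarse_contact_index(z, d)
    if contact_point is not None:
        spacing = abs(z[-1] - z[0]) / max(len(z) - 1, 1)
        stop = int(np.searchsorted(z, contact_point - 3 * spacing))
    else:
        stop = int(0.9 * ci)  # stand off from the coarse kink
    if min(ci, stop) < min_pre_fraction * len(z) or stop < 10:
        raise ValueError(
            f"pre-contact region too short: {min(ci, stop)}/{len(z)} samples "
            f"(< {min_pre_fraction:.0%})"
        )
    slope, offset = np.polyfit(z[:stop], d[:stop], 1)
    corrected = d - (offset + slope * z)
    out = curve.with_deflection(corrected)
    out.baseline = (float(offset), float(slope))
    return out


def prepare_curve(
    curve: ForceCurve,
    min_pre_fraction: float = 0.3,
    refine_max_indentation: float | None = None,
) -> tuple[ForceCurve, float]:
    """Baseline-correct and locate contact, with one feedback pass.

    Coarse baseline -> contact detection -> baseline refit strictly before
    the detected contact -> final detection.  Returns the corrected curve
    and the contact point.  The feedback pass matters for soft samples,
    whose gradual onset otherwise contaminates the baseline fit.
    """
    first = correct_baseline(curve, min_pre_fraction=min_pre_fraction)
    z0 = detect_contact_point(
        first, refine_max_indentation=refine_max_indentation
    )
    second = correct_baseline(
        curve, min_pre_fraction=min_pre_fraction, contact_point=z0
    )
    z0 = detect_contact_point(
        second, refine_max_indentation=refine_max_indentation
    )
    return second, z0


def detect_contact_point(
    curve: ForceCurve,
    exponent: int = 2,
    min_pre: int = 5,
    min_post: int = 10,
    refine: bool = True,
    refine_max_indentation: float | None = None,
) -> float:
    """Locate the tip-sample contact point on a baseline-corrected curve.

    Stage one scans every candidate sample ``i`` and scores the two-piece
    model "zero before z[i], a*(z - z[i])**p after" by total squared
    residual (amplitude ``a >= 0`` solved in closed form per candidate),
    with parabolic interpolation of the residual profile around the winner.

    For cone contact (``exponent=2``) stage two refines (z0, stiffness) by
    nonlinear least squares of the full compliance-coupled force balance
    ``k*d = C*((z - z0) - d)**2``, whose deflection solution is known in
    closed form.  The raw scan misattributes the cantilever's own
    compliance to the contact position (a systematic ~0.1 um bias on soft
    cells); the NLS model is exact for a homogeneous sample and the noise
    lives only in the deflection ordinate, so the refined z0 is unbiased.
    ``refine_max_indentation`` restricts a second pass to samples shallower
    than the given depth (useful when stiffness varies with depth, where
    the homogeneous model only holds near the surface).  Deterministic
    throughout.

    ``exponent=1`` (rigid/linear contact, used for reference curves) keeps
    the pure scan, which is exact there.
    """
    z = np.asarray(curve.z, float)
    d = np.asarray(curve.deflection, float)
    _ = _coarse_contact_index(z, d)  # raises DegenerateCurveError on flat input
    n = len(z)
    lo, hi = min_pre, n - min_post
    if hi <= lo:
        raise DegenerateCurveError("degenerate curve: too few samples to bracket contact")

    # residuals computed from direct differences (no expanded power sums):
    # O(n^2) memory-bounded matrix, exact for any candidate position
    zc = z[lo:hi]
    diff = z[None, :] - zc[:, None]  # (n_cand, n)
    post = diff > 0
    g = np.where(post, diff, 0.0) ** exponent
    s_dg = g @ d
    s_gg = np.einsum("ij,ij->i", g, g)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(s_gg > 0, s_dg / s_gg, 0.0)
    a = np.clip(a, 0.0, None)
    d2 = d**2
    total_d2 = float(d2.sum())
    # RSS = sum over pre of d^2 + sum over post of (d - a g)^2
    rss = total_d2 - 2.0 * a * s_dg + a**2 * s_gg
    best = int(np.argmin(rss))
    z0 = float(zc[best])

    # parabolic refinement, skipped when the fit is already essentially exact
    if 0 < best < len(zc) - 1:
        r_m, r_0, r_p = rss[best - 1], rss[best], rss[best + 1]
        denom = r_m - 2.0 * r_0 + r_p
        scale = max(total_d2, 1e-300)
        if denom > 0 and r_0 > 1e-24 * scale:
            shift = 0.5 * (r_m - r_p) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            h = 0.5 * (zc[best + 1] - zc[best - 1])
            z0 = float(zc[best] + shift * h)
    if refine and exponent == 2:
        z0 = _refine_contact_nls(z, d, z0, curve.spring_constant)
        # optional shallow-restricted passes for depth-dependent stiffness,
        # iterated because the restricted problem has local minima
        if refine_max_indentation is not None:
            for _ in range(4):
                s = z - z0
                delta = np.clip(s, 0.0, None) - np.clip(d, 0.0, None)
                sel = (s <= 0) | (delta <= refine_max_indentation)
                if int((sel & (s > 0)).sum()) < min_post:
                    break
                z0_new = _refine_contact_nls(
                    z[sel], d[sel], z0, curve.spring_constant
                )
                if abs(z0_new - z0) < 1e-12:
                    z0 = z0_new
                    break
                z0 = z0_new
    return z0


def _cone_deflection(s: np.ndarray, z0: float, c: float, k: float) -> np.ndarray:
    """Closed-form deflection of the compliance-coupled cone law past z0."""
    sp = np.clip(s - z0, 0.0, None)
    return 2.0 * c * sp**2 / (2.0 * c * sp + k + np.sqrt(k**2 + 4.0 * c * k * sp))


def _refine_contact_nls(
    z: np.ndarray, d: np.ndarray, z0: float, k: float
) -> float:
    """Joint (z0, stiffness) NLS of the homogeneous cone force balance.

    Noise lives only in the deflection ordinate, so this is the proper
    least-squares formulation; ``least_squares`` never worsens the cost at
    the starting point, so the scan estimate is the fallback by
    construction.
    """
    from scipy.optimize import least_squares

    post = z > z0
    if int(post.sum()) < 5:
        return z0
    dmax = float(np.max(d[post]))
    smax = float(np.max(z[post] - z0))
    if dmax <= 0 or smax <= 0:
        return z0
    # initial stiffness from the deepest point, d ~ (c/k) * (s - d)^2
    c0 = max(k * dmax / max(smax - dmax, 1e-12) ** 2, 1e-6)

    def resid(p):
        return _cone_deflection(z, p[0], p[1], k) - d

    res = least_squares(
        resid,
        x0=[z0, c0],
        bounds=([z[0], 1e-12], [z[-1], np.inf]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    z0_new, c_new = res.x
    if not np.isfinite(z0_new) or c_new <= 0:
        return z0
    return float(z0_new)


def fit_sensitivity(
    reference: ForceCurve,
    min_contact_fraction: float = 0.2,
) -> CalibrationResult:
    """Deflection sensitivity from the rigid-substrate reference curve.

    The contact region (located with the linear-contact detector) is fitted
    with a straight line; for volt-unit curves the sensitivity is the
    inverse slope (m/V), for meter-unit curves the slope must be ~1 and the
    sensitivity is 1.0 by definition.
    """
    ref = correct_baseline(reference, min_pre_fraction=0.05)
    z0 = detect_contact_point(ref, exponent=1)
    z, d = ref.z, ref.deflection
    mask = z > z0
    n_contact = int(mask.sum())
    if n_contact < min_contact_fraction * len(z):
        raise ValueError(
            f"contact region covers {n_contact}/{len(z)} samples, "
            f"less than the required {min_contact_fraction:.0%}"
        )
    slope, icpt = np.polyfit(z[mask], d[mask], 1)
    if slope <= 0:
        raise ValueError(f"non-positive contact slope {slope:.3g}")
    resid = d[mask] - (icpt + slope * z[mask])
    rms = float(np.sqrt(np.mean(resid**2)))
    if reference.unit == "V":
        sensitivity = 1.0 / slope  # slope is V per m of travel
    else:
        if not math.isclose(slope, 1.0, rel_tol=0.05):
            raise ValueError(
                f"meter-unit reference slope {slope:.4f} differs from 1; "
                "check units or substrate stiffness"
            )
        sensitivity = 1.0
    i0 = int(np.argmax(mask))
    return CalibrationResult(
        sensitivity=float(sensitivity),
        fit_window=(i0, len(z)),
        residual_rms=rms,
        reference_contact_point=float(z0),
    )


def to_force_indentation(
    curve: ForceCurve,
    cal: CalibrationResult | None = None,
    contact_point: float | None = None,
) -> IndentationCurve:
    """Calibration subtraction: deflection-vs-position -> force-vs-indentation.

    ``d`` is converted to meters (volt curves need a sensitivity, from
    ``cal`` or the curve metadata), force is ``k*d``, and the indentation is
    the piezo travel past contact minus the deflection.  If no contact point
    is supplied it is detected on the (baseline-corrected) curve.
    """
    if curve.spring_constant is None or not curve.spring_constant > 0:
        raise ValueError("missing or invalid spring constant")
    if curve.baseline is None:
        curve = correct_baseline(curve)
    if contact_point is None:
        contact_point = detect_contact_point(curve)
    d = curve.deflection
    sensitivity = None
    if curve.unit == "V":
        sensitivity = cal.sensitivity if cal is not None else curve.sensitivity
        if sensitivity is None:
            raise ValueError(
                "volt-unit curve requires a sensitivity (CalibrationResult "
                "or curve metadata)"
            )
        d = d * sensitivity
    past = curve.z >= contact_point
    s = curve.z[past] - contact_point
    d_past = d[past]
    delta = s - d_past
    force = curve.spring_constant * d_past
    return IndentationCurve(
        delta=delta,
        force=force,
        contact_point=float(contact_point),
        baseline=curve.baseline,
        spring_constant=curve.spring_constant,
        half_angle=curve.half_angle,
        sensitivity=sensitivity,
        cell_id=curve.cell_id,
        group=curve.group,
        grid_x=curve.grid_x,
        grid_y=curve.grid_y,
    )
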