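"""Plate-assay arithmetic: LDH viability and MTS relative absorbance.

LDH release reports membrane damage.  With ``expLDH`` the experimental
release and ``maxLDH`` the maximum (lysis-buffer) release, both OD490:

    viability  = 1 - expLDH / maxLDH
    max. error = (d(expLDH) + (expLDH / maxLDH) * d(maxLDH)) / maxLDH

the error being first-order propagation with absolute-valued sensitivities.
MTS absorbance is normalized to the control-condition mean, so the control
group sits at 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ViabilityResult",
    "ldh_viability",
    "mts_relative",
    "max_ldh_from_conditions",
    "validate_plate",
]

PLATE_COLUMNS = ("condition", "well", "od")


@dataclass(frozen=True)
class ViabilityResult:
    """LDH viability (fraction) with propagated maximum error."""

    viability: float
    max_error: float
    exp_ldh: float
    max_ldh: float
    d_exp_ldh: float
    d_max_ldh: float
    warning: str = ""

    @property
    def viability_percent(self) -> float:
        return 100.0 * self.viability

    @property
    def max_error_percent(self) -> float:
        return 100.0 * self.max_error


def ldh_viability(
    exp_ldh: float,
    max_ldh: float,
    d_exp_ldh: float = 0.0,
    d_max_ldh: float = 0.0,
) -> ViabilityResult:
    """Viability and its propagated maximum error from LDH optical densities.

    ``exp_ldh > max_ldh`` yields a negative viability, returned as-is with a
    warning flag rather than clipped — such plates need inspection, not
    silent repair.
    """
    if not max_ldh > 0:
        raise ValueError("max_ldh must be > 0")
    if d_exp_ldh < 0 or d_max_ldh < 0:
        raise ValueError("uncertainties must be >= 0")
    if exp_ldh < 0:
        raise ValueError("exp_ldh must be >= 0")
    viability = 1.0 - exp_ldh / max_ldh
    max_error = (d_exp_ldh + (exp_ldh / max_ldh) * d_max_ldh) / max_ldh
    warning = ""
    if viability < 0:
        warning = "expLDH exceeds maxLDH: negative viability"
    return ViabilityResult(
        viability=viability,
        max_error=max_error,
        exp_ldh=exp_ldh,
        max_ldh=max_ldh,
        d_exp_ldh=d_exp_ldh,
        d_max_ldh=d_max_ldh,
        warning=warning,
    )


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format plate table (condition, well, od; OD >= 0)."""
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if len(plate) == 0:
        raise ValueError("empty plate table")
    if (plate["od"] < 0).any():
        bad = plate.loc[plate["od"] < 0, "well"].tolist()
        raise ValueError(f"negative OD in wells: {bad}")
    return plate


def mts_relative(plate: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-well relative absorbance, normalized to the control-condition mean.

    Returns the plate with an added ``relative`` column; the mean relative
    absorbance of the control condition is exactly 1.  Scale-invariant:
    multiplying every OD by a constant changes nothing.
    """
    plate = validate_plate(plate)
    control = plate.loc[plate["condition"] == control_condition, "od"]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} not in plate")
    control_mean = float(control.mean())
    if control_mean == 0:
        raise ValueError("control-condition mean OD is zero; cannot normalize")
    out = plate.copy()
    out["relative"] = out["od"] / control_mean
    return out


def max_ldh_from_conditions(
    plate: pd.DataFrame, conditions: Sequence[str]
) -> float:
    """Assemble maxLDH as the sum of per-condition mean ODs.

    The maximum release is tabulated from named lysis-buffer conditions
    (cells plus supernatant) rather than recomputed from raw well layouts.
    """
    plate = validate_plate(plate)
    total = 0.0
    for cond in conditions:
        sel = plate.loc[plate["condition"] == cond, "od"]
        if sel.empty:
            raise ValueError(f"condition {cond!r} not found in plate")
        total += float(sel.mean())
    return total
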