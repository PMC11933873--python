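"""SOD activity from the NBT photochemical-reduction assay.

One unit of SOD activity is the amount of enzyme inhibiting NBT photoreduction
by 50%.  From the absorbance at 560 nm of the illuminated control tube (A_s0)
and the sample tube (A_s), with V_t the total extract volume, V_s the volume
assayed and W the fresh sample weight, activity is

    SOD [U/mg] = ((A_s0 - A_s) * V_t) / (A_s0 * W * V_s * 0.5 * 1000)

As typeset in the source literature the grouping of this formula is ambiguous;
the form above is the standard 50%-inhibition NBT expression consistent with
the unit definition, and is what this module computes.  ``W`` defaults to
grams (300 mg of leaf is weighed as 0.3); pass ``weight_unit="mg"`` to supply
milligrams — the conversion is explicit, never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class AssayRecord:
    """One NBT assay measurement.

    a_s0: absorbance of the illuminated control tube (> 0)
    a_s:  absorbance of the sample tube (>= 0)
    v_t:  total extract volume, mL
    v_s:  extract volume assayed, mL
    w:    fresh sample weight, in ``weight_unit`` ("g" default, or "mg")
    """

    a_s0: float
    a_s: float
    v_t: float
    v_s: float
    w: float
    weight_unit: str = "g"

    def __post_init__(self) -> None:
        if self.a_s0 <= 0:
            raise ZeroDivisionError("control absorbance a_s0 must be > 0")
        if self.a_s < 0:
            raise ValueError("sample absorbance a_s must be >= 0")
        if min(self.v_t, self.v_s, self.w) <= 0:
            raise ValueError("volumes and weight must be > 0")
        if self.weight_unit not in ("g", "mg"):
            raise ValueError("weight_unit must be 'g' or 'mg'")


def sod_activity(rec: AssayRecord) -> float:
    """SOD activity in U/mg fresh weight.

    Negative activities (a_s > a_s0, i.e. the sample tube darker than the
    control) are returned as computed but a warning is emitted, since they
    usually indicate a swapped tube or a degraded control.
    """
    w_g = rec.w if rec.weight_unit == "g" else rec.w / 1000.0
    value = ((rec.a_s0 - rec.a_s) * rec.v_t) / (
        rec.a_s0 * w_g * rec.v_s * 0.5 * 1000.0
    )
    if value < 0:
        warnings.warn(
            f"negative SOD activity ({value:.4g} U/mg): a_s ({rec.a_s}) exceeds "
            f"a_s0 ({rec.a_s0})",
            stacklevel=2,
        )
    return value


def label_table(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Read a CSV of assay records, append a ``sod_u_per_mg`` column, write it.

    Expected columns: a_s0, a_s, v_t, v_s, w and optionally weight_unit.
    """
    df = pd.read_csv(path_in)
    required = {"a_s0", "a_s", "v_t", "v_s", "w"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path_in}: missing columns {sorted(missing)}")
    activities = []
    for row in df.itertuples(index=False):
        rec = AssayRecord(
            a_s0=row.a_s0,
            a_s=row.a_s,
            v_t=row.v_t,
            v_s=row.v_s,
            w=row.w,
            weight_unit=getattr(row, "weight_unit", "g"),
        )
        activities.append(sod_activity(rec))
    df["sod_u_per_mg"] = activities
    df.to_csv(path_out, index=False)
    return df
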