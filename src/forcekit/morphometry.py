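"""Cilium morphometry, scratch-assay closure and ddCt relative expression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CiliumMeasurement:
    """A traced primary cilium: ordered planar points (um) and focus flag."""

    cell_id: int
    polyline: np.ndarray  # (m, 2) um
    in_focus: bool = True

    @property
    def length_um(self) -> float:
        return cilium_length(self.polyline)


def cilium_length(polyline: np.ndarray) -> float:
    """Arc length (um) of a traced cilium polyline.

    Sum of segment lengths; duplicate consecutive points (zero-length
    segments) are allowed.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must contain at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def ciliation_fraction(n_ciliated: int, n_total: int) -> float:
    """Proportion of cells bearing a cilium."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_ciliated <= n_total:
        raise ValueError("need 0 <= n_ciliated <= n_total")
    return n_ciliated / n_total


def focus_filter(
    measurements: list[CiliumMeasurement],
    flags: list[bool] | None = None,
) -> list[CiliumMeasurement]:
    """Retain only cilia that are completely in focus.

    Focus flags default to each measurement's own ``in_focus`` attribute;
    an explicit parallel ``flags`` list overrides them.
    """
    if flags is None:
        return [m for m in measurements if m.in_focus]
    if len(flags) != len(measurements):
        raise ValueError("flags length must match measurements")
    return [m for m, keep in zip(measurements, flags) if keep]


def scratch_coverage(width_t0_um: float, width_t24_um: float) -> float:
    """Percent of the scratch gap covered between t=0 and the endpoint.

    100 x (w0 - w_end) / w0.  An end width outside [0, w0] is clamped with
    a warning (measurement jitter can push it slightly outside).
    """
    if width_t0_um <= 0:
        raise ValueError("initial width must be > 0")
    if width_t24_um < 0 or width_t24_um > width_t0_um:
        warnings.warn(
            f"end width {width_t24_um} outside [0, {width_t0_um}]; clamping",
            stacklevel=2,
        )
        width_t24_um = min(max(width_t24_um, 0.0), width_t0_um)
    return 100.0 * (width_t0_um - width_t24_um) / width_t0_um


def ddct_fold_change(
    table: pd.DataFrame,
    calibrator: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> pd.DataFrame:
    """Relative expression by the ddCt method with an sd-based interval.

    Per condition, dCt = Ct(target) - Ct(reference) paired by replicate;
    ddCt = dCt(condition) - dCt(calibrator); fold = 2^(-ddCt) (calibrator
    fold is exactly 1).  The interval is
    [2^-(ddCt + sd), 2^-(ddCt - sd)] with sd the replicate standard
    deviation (n-1 denominator) of the condition's dCt.

    Returns a DataFrame indexed by condition with columns
    ``delta_ct, sd, ddct, fold, fold_lo, fold_hi``.
    """
    required = {"condition", "gene", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")

    per_cond: dict[str, tuple[float, float]] = {}
    for cond, sub in table.groupby("condition", sort=False):
        tgt = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        if ref.empty:
            raise ValueError(f"condition {cond!r}: missing reference gene rows")
        if tgt.empty:
            raise ValueError(f"condition {cond!r}: missing target gene rows")
        if len(tgt) < 2 or len(ref) < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 replicates")
        dct = (tgt - ref).dropna()
        per_cond[cond] = (float(dct.mean()), float(dct.std(ddof=1)))

    if calibrator not in per_cond:
        raise ValueError(f"calibrator {calibrator!r} not in table")
    cal_dct = per_cond[calibrator][0]

    rows = {}
    for cond, (dct, sd) in per_cond.items():
        ddct = dct - cal_dct
        rows[cond] = {
            "delta_ct": dct,
            "sd": sd,
            "ddct": ddct,
            "fold": 2.0 ** (-ddct),
            "fold_lo": 2.0 ** (-(ddct + sd)),
            "fold_hi": 2.0 ** (-(ddct - sd)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cilia_table(measurements: list[CiliumMeasurement]) -> pd.DataFrame:
    """Tidy per-cilium table (cell_id, length_um, in_focus)."""
    return pd.DataFrame(
        [
            {"cell_id": m.cell_id, "length_um": m.length_um, "in_focus": m.in_focus}
            for m in measurements
        ]
    )
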