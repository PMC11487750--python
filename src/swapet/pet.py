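"""Amyloid-PET (PiB) SUVR aggregation, annualization and centiloid scaling.

Regional SUVRs from the six amyloid-susceptible cortical ROIs are averaged
(optionally with weights) into a global SUVR.  Longitudinal accumulation is
annualized on the log scale:

    ΔPiB(log)/year = (ln S2 − ln S1) / interval_years

The tracer-specific centiloid conversion is the affine map

    CL = 100 · ((−0.1620 + 0.9467 · SUVR) − 1.009) / 1.067

and baseline amyloid positivity (PiB+) is SUVR ≥ 1.48.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROIS",
    "PIB_POSITIVITY_CUTOFF",
    "PibScan",
    "global_suvr",
    "annualized_log_change",
    "suvr_to_centiloid",
    "centiloid_to_suvr",
    "classify_pib",
    "annualize_cohort",
]

#: Amyloid-susceptible regions of interest.
ROIS = (
    "orbitofrontal",
    "prefrontal",
    "anterior_cingulate",
    "posterior_cingulate_precuneus",
    "parietal",
    "temporal",
)

#: Baseline SUVR cutoff for global PiB positivity (inclusive).
PIB_POSITIVITY_CUTOFF = 1.48

# centiloid affine map coefficients
_CL_SLOPE = 0.9467
_CL_INTERCEPT = -0.1620
_CL_OFFSET = 1.009
_CL_SCALE = 1.067


@dataclass
class PibScan:
    """Regional SUVRs of one PiB-PET scan with optional ROI weights."""

    suvr: dict[str, float]
    scan_date: object = None
    weights: dict[str, float] | None = None

    def __post_init__(self):
        unknown = set(self.suvr) - set(ROIS)
        if unknown:
            raise ValueError(f"unknown ROIs {sorted(unknown)}; expected subset of {ROIS}")
        for k, v in self.suvr.items():
            if v <= 0:
                raise ValueError(f"SUVR must be positive; {k} = {v}")


def global_suvr(scan: PibScan) -> float:
    """Weighted mean SUVR over the six ROIs (unweighted when no weights given)."""
    missing = [r for r in ROIS if r not in scan.suvr]
    if missing:
        raise ValueError(f"missing ROI SUVRs: {missing}")
    vals = np.array([scan.suvr[r] for r in ROIS])
    if scan.weights is None:
        return float(vals.mean())
    w = np.array([scan.weights.get(r, 0.0) for r in ROIS], dtype=float)
    if w.sum() <= 0:
        raise ValueError("ROI weights must sum to a positive value")
    return float(np.sum(w * vals) / w.sum())


def annualized_log_change(s1: float, s2: float, interval_years: float) -> float:
    """Annualized log-scale change (ln s2 − ln s1)/interval, natural log."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SUVRs must be positive")
    if interval_years <= 0:
        raise ValueError("scan interval must be positive")
    return (math.log(s2) - math.log(s1)) / interval_years


def suvr_to_centiloid(s):
    """Centiloid value of a PiB SUVR via the tracer-specific affine map."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("SUVR must be positive")
    cl = 100.0 * ((_CL_INTERCEPT + _CL_SLOPE * s) - _CL_OFFSET) / _CL_SCALE
    return float(cl) if cl.ndim == 0 else cl


def centiloid_to_suvr(cl):
    """Inverse of :func:`suvr_to_centiloid` (the map is strictly increasing)."""
    cl = np.asarray(cl, dtype=float)
    s = ((cl * _CL_SCALE / 100.0) + _CL_OFFSET - _CL_INTERCEPT) / _CL_SLOPE
    return float(s) if s.ndim == 0 else s


def classify_pib(s_baseline: float, cutoff: float = PIB_POSITIVITY_CUTOFF) -> bool:
    """True (PiB+) iff the baseline global SUVR is at or above the cutoff."""
    if s_baseline <= 0:
        raise ValueError("SUVR must be positive")
    return bool(s_baseline >= cutoff)


def annualize_cohort(df: pd.DataFrame, rois: tuple[str, ...] = ROIS) -> pd.DataFrame:
    """Append global/regional annualized changes, CL values and PiB status.

    Expects one row per participant with columns ``{roi}_suvr1``,
    ``{roi}_suvr2`` for each ROI, ``interval_years`` and optionally
    ``{roi}_weight``.  Adds:

    - ``global_suvr1``, ``global_suvr2`` — weighted ROI means per timepoint
    - ``global_cl1``, ``global_cl2`` — centiloid-converted global SUVRs
    - ``dpib_log_yr`` and ``{roi}_dpib_log_yr`` — annualized log changes
    - ``dpib_cl_yr`` — (CL2 − CL1)/interval, the difference of converted
      values (not a conversion of the log change)
    - ``pib_positive`` — baseline PiB status (0/1)
    """
    out = df.copy()
    has_w = all(f"{r}_weight" in df.columns for r in rois)
    g1, g2 = [], []
    for _, row in df.iterrows():
        w = {r: row[f"{r}_weight"] for r in rois} if has_w else None
        g1.append(global_suvr(PibScan({r: row[f"{r}_suvr1"] for r in rois}, weights=w)))
        g2.append(global_suvr(PibScan({r: row[f"{r}_suvr2"] for r in rois}, weights=w)))
    out["global_suvr1"] = g1
    out["global_suvr2"] = g2
    out["global_cl1"] = suvr_to_centiloid(out["global_suvr1"].to_numpy())
    out["global_cl2"] = suvr_to_centiloid(out["global_suvr2"].to_numpy())
    iv = out["interval_years"].to_numpy()
    out["dpib_log_yr"] = (np.log(out["global_suvr2"]) - np.log(out["global_suvr1"])) / iv
    out["dpib_cl_yr"] = (out["global_cl2"] - out["global_cl1"]) / iv
    for r in rois:
        out[f"{r}_dpib_log_yr"] = (np.log(out[f"{r}_suvr2"]) - np.log(out[f"{r}_suvr1"])) / iv
    out["pib_positive"] = (out["global_suvr1"] >= PIB_POSITIVITY_CUTOFF).astype(int)
    return out
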