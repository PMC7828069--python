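"""CIELAB-derived color metrics and replicate quality control.

Meat color is read with a spectrophotometer in CIELAB space: L* is
lightness (black 0 → white 100), a* runs green (−) → red (+), and b*
runs blue (−) → yellow (+). From a* and b* two polar descriptors follow:
chroma C* = sqrt(a*² + b*²) and the hue angle H* = atan2(b*, a*) in
degrees. Each sample is read at several random points on the muscle
(three by default) and the replicate scatter is summarized as a
coefficient of variation (CV%), with readings above 5% CV flagged but
retained — replicate disagreement is treated as intrinsic variability of
the surface, not as a rejection criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "ColorReplicates",
    "chroma",
    "hue_deg",
    "aggregate_replicates",
    "read_color_csv",
    "aggregate_color_table",
]

PARAMETERS = ("L*", "a*", "b*", "C*", "H*")

#: Replicates with CV% above this are flagged (never rejected).
CV_FLAG_THRESHOLD = 5.0


def chroma(a: float, b: float) -> float:
    """Chroma C* = sqrt(a*² + b*²)."""
    return float(np.hypot(a, b))


def hue_deg(a: float, b: float) -> float:
    """Hue angle H* in degrees, wrapped to [0, 360).

    Uses the four-quadrant arctangent so non-positive a* is handled; for
    fresh pork (a* > 0, b* > 0) this coincides with tan⁻¹(b*/a*).
    """
    if a == 0 and b == 0:
        raise ValueError("hue is undefined at a* = b* = 0")
    return float(np.degrees(np.arctan2(b, a)) % 360.0)


@dataclass(frozen=True)
class ColorReplicates:
    """Replicate summary for one sample: means, CV% and QC flags."""

    readings: np.ndarray  # (k, 3) L*, a*, b*
    means: dict[str, float]
    cv_pct: dict[str, float]
    flagged: tuple[str, ...]

    def to_dict(self) -> dict:
        out = dict(self.means)
        out.update({f"CV%_{p}": self.cv_pct[p] for p in PARAMETERS})
        out["flags"] = ";".join(self.flagged)
        return out


def aggregate_replicates(
    readings, cv_flag_threshold: float = CV_FLAG_THRESHOLD
) -> ColorReplicates:
    """Summarize replicate L*, a*, b* readings of one sample.

    C* and H* are computed per reading and then aggregated alongside the
    instrument parameters. Per parameter the arithmetic mean and
    CV% = 100 × sample SD / |mean| are reported; parameters whose CV%
    exceeds ``cv_flag_threshold`` are flagged as a warning.
    """
    arr = np.asarray(readings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (k, 3) L*, a*, b* readings, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("at least 2 replicate readings are required")

    values = {
        "L*": arr[:, 0],
        "a*": arr[:, 1],
        "b*": arr[:, 2],
        "C*": np.array([chroma(a, b) for a, b in arr[:, 1:]]),
        "H*": np.array([hue_deg(a, b) for a, b in arr[:, 1:]]),
    }
    means = {p: float(v.mean()) for p, v in values.items()}
    cv = {}
    for p, v in values.items():
        sd = float(v.std(ddof=1))
        cv[p] = 100.0 * sd / abs(means[p]) if means[p] != 0 else np.inf if sd else 0.0
    flagged = tuple(p for p in PARAMETERS if cv[p] > cv_flag_threshold)
    return ColorReplicates(readings=arr, means=means, cv_pct=cv, flagged=flagged)


def read_color_csv(path) -> pd.DataFrame:
    """Read a long-format replicate CSV: sample_id, replicate, L, a, b."""
    df = pd.read_csv(path)
    required = {"sample_id", "replicate", "L", "a", "b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"color CSV missing columns: {sorted(missing)}")
    return df


def aggregate_color_table(replicates: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long replicate table to one row of color metrics per sample."""
    rows = []
    for sample_id, grp in replicates.groupby("sample_id", sort=True):
        agg = aggregate_replicates(grp[["L", "a", "b"]].to_numpy())
        row = {"sample_id": sample_id}
        row.update(agg.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
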