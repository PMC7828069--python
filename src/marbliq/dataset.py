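"""Feature-table assembly, scaling and semi-quantitative IMF grouping.

The modelling table has 13 predictors per measurement — carcass weight
(CW, kg), five CIELAB color variables (L*, a*, b*, C*, H*) and seven
image-analysis variables (Width, Height, REA, BFT, NOParticles,
Marb_area, Marb_area%) — and the chemically determined intramuscular fat
percentage (IMF%) as the response.

For semi-quantitative (juiciness) analysis, IMF% is discretized into
three groups: G1 = [0.6, 1.1]% (central value 0.85), G2 = [1.25, 1.5]%
(central value 1.38), G3 = (1.5, ∞)%. The gaps below 0.6 and between 1.1
and 1.25 are handled explicitly: strict mode leaves such values
unassigned, lenient mode snaps them to the nearest interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_COLUMNS",
    "GROUP_BOUNDS",
    "FeatureMatrix",
    "assign_group",
    "assign_groups",
    "group_central_value",
    "scale_center",
]

PREDICTOR_COLUMNS = (
    "CW", "L*", "a*", "b*", "C*", "H*",
    "Width", "Height", "REA", "BFT",
    "NOParticles", "Marb_area", "Marb_area%",
)

TARGET_COLUMN = "IMF%"

#: Closed lower/upper bounds of the finite groups; G3 is open below at 1.5.
GROUP_BOUNDS: dict[str, tuple[float, float]] = {
    "G1": (0.6, 1.1),
    "G2": (1.25, 1.5),
    "G3": (1.5, math.inf),
}


def assign_group(imf_pct: float, mode: str = "strict") -> str | None:
    """Map an IMF percentage to its semi-quantitative group label.

    Boundary ties are inclusive except G3's lower bound: 1.5 belongs to
    G2, anything strictly above to G3. Values in the gaps (< 0.6 or in
    (1.1, 1.25)) return ``None`` in strict mode and the nearest interval
    in lenient mode (equidistant values go to the lower group).
    """
    if not imf_pct > 0:
        raise ValueError(f"IMF% must be positive, got {imf_pct}")
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if GROUP_BOUNDS["G1"][0] <= imf_pct <= GROUP_BOUNDS["G1"][1]:
        return "G1"
    if GROUP_BOUNDS["G2"][0] <= imf_pct <= GROUP_BOUNDS["G2"][1]:
        return "G2"
    if imf_pct > GROUP_BOUNDS["G3"][0]:
        return "G3"
    if mode == "strict":
        return None
    # lenient: snap to the nearest interval edge
    if imf_pct < GROUP_BOUNDS["G1"][0]:
        return "G1"
    return "G1" if imf_pct - GROUP_BOUNDS["G1"][1] <= GROUP_BOUNDS["G2"][0] - imf_pct else "G2"


def assign_groups(
    table: pd.DataFrame, mode: str = "strict", column: str = TARGET_COLUMN
) -> pd.Series:
    """Vectorized :func:`assign_group` over a table column."""
    return table[column].map(lambda v: assign_group(float(v), mode=mode))


def group_central_value(label: str) -> float:
    """Midpoint of a finite group interval, rounded half-up to 2 decimals.

    G3 is unbounded above; its published central value is data-derived,
    not an interval midpoint, so asking for it is an error.
    """
    if label not in GROUP_BOUNDS:
        raise ValueError(f"unknown group label {label!r}")
    lo, hi = GROUP_BOUNDS[label]
    if not math.isfinite(hi):
        raise ValueError(f"group {label} is unbounded; its central value is not a midpoint")
    mid = (lo + hi) / 2.0
    return math.floor(mid * 100 + 0.5) / 100.0


@dataclass(frozen=True)
class FeatureMatrix:
    """A scaled/centred design matrix with its training-fold parameters.

    ``values`` holds z-scores computed with the stored training-column
    means and sample SDs, so held-out rows can be transformed without
    leakage and transformed values can be mapped back exactly.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    column_names: tuple[str, ...]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.column_names)].to_numpy(dtype=float)
        return (X - self.column_means) / self.column_sds

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.column_sds + self.column_means


def scale_center(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
    columns=PREDICTOR_COLUMNS,
) -> FeatureMatrix:
    """Center and scale predictors to zero mean, unit sample SD.

    Means and SDs are estimated on ``train`` only; ``apply_to`` (default:
    the training table itself) is transformed with those training
    parameters so no information leaks from held-out rows.
    """
    columns = tuple(columns)
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to estimate scale")
    X_train = train.loc[:, list(columns)].to_numpy(dtype=float)
    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [columns[i] for i in zero]
        raise ValueError(f"constant predictor column(s) with zero SD: {names}")
    target = train if apply_to is None else apply_to
    values = (target.loc[:, list(columns)].to_numpy(dtype=float) - means) / sds
    return FeatureMatrix(
        values=values, column_means=means, column_sds=sds, column_names=columns
    )
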