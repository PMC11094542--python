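"""Eco-enzymatic stoichiometry: activity ratios, vector analysis, limitation calls.

Seven extracellular enzymes summarize microbial investment into carbon
(AG, BG, XS, CB), nitrogen (NAG, LAP) and phosphorus (AP) acquisition.  Two
complementary classifiers translate them into nutrient-limitation calls:

* a quadrant scatter of (LAP+NAG)/AP against BG/(LAP+NAG), splitting samples
  into C&N, C&P, N and P limitation at the 1:1 reference lines;
* a vector summary of the point (X, Y) with
  X = (BG+CB)/(BG+CB+AP) and Y = (BG+CB)/(BG+CB+NAG+LAP): the vector length
  scales with relative C limitation, and the polar angle (measured from the
  positive x-axis, the Excel ``ATAN2(X, Y)`` convention, i.e. arctan(Y/X))
  reads as N limitation below 45 degrees and P limitation above.

Log-ratio statistics ln(BG)/ln(LAP+NAG), ln(BG)/ln(AP) and
ln(LAP+NAG)/ln(AP) quantify relative C:N, C:P and N:P enzyme allocation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import EnzymeActivities

__all__ = [
    "zscore", "stoich_ratios", "vector_metrics",
    "classify_quadrant", "classify_vector",
    "enzyme_summary", "EnzymeVector", "StoichRatios",
]


@dataclass(frozen=True)
class StoichRatios:
    cn: float   # ln(BG) / ln(LAP+NAG)
    cp: float   # ln(BG) / ln(AP)
    np: float   # ln(LAP+NAG) / ln(AP)


@dataclass(frozen=True)
class EnzymeVector:
    x: float
    y: float
    length: float
    angle_deg: float


def zscore(values, ddof: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD by default)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("zscore needs a 1-D vector of length >= 2")
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant vector: standard deviation is zero")
    return (v - v.mean()) / sd


def _ln_checked(value: float, label: str, sample: str) -> float:
    if value <= 0:
        raise ValueError(f"{label} must be > 0 for sample {sample!r} (got {value})")
    ln = np.log(value)
    return ln


def stoich_ratios(enzymes: EnzymeActivities | pd.DataFrame) -> pd.DataFrame:
    """Per-sample log-activity ratios (columns cn, cp, np).

    Requires BG, LAP+NAG and AP strictly positive; an activity of exactly 1
    makes a denominator ln() zero and is rejected as undefined.
    """
    df = enzymes.data if isinstance(enzymes, EnzymeActivities) else enzymes
    out = {}
    for sample, row in df.iterrows():
        ln_bg = _ln_checked(row["BG"], "BG", sample)
        ln_n = _ln_checked(row["LAP"] + row["NAG"], "LAP+NAG", sample)
        ln_ap = _ln_checked(row["AP"], "AP", sample)
        if ln_n == 0 or ln_ap == 0:
            raise ValueError(
                f"undefined ratio for sample {sample!r}: activity exactly 1 "
                "gives a zero ln() denominator")
        out[sample] = {"cn": ln_bg / ln_n, "cp": ln_bg / ln_ap, "np": ln_n / ln_ap}
    return pd.DataFrame.from_dict(out, orient="index").loc[df.index]


def _vector_row(row: pd.Series, sample: str) -> EnzymeVector:
    c = row["BG"] + row["CB"]
    denom_x = c + row["AP"]
    denom_y = c + row["NAG"] + row["LAP"]
    if denom_x <= 0 or denom_y <= 0:
        raise ValueError(f"zero enzyme denominators for sample {sample!r}")
    x = c / denom_x
    y = c / denom_y
    length = float(np.hypot(x, y))
    angle = float(np.degrees(np.arctan2(y, x)))  # angle of point (x, y)
    return EnzymeVector(float(x), float(y), length, angle)


def vector_metrics(enzymes: EnzymeActivities | pd.DataFrame) -> pd.DataFrame:
    """Per-sample vector coordinates, length and angle (degrees)."""
    df = enzymes.data if isinstance(enzymes, EnzymeActivities) else enzymes
    out = {s: vars(_vector_row(row, s)) for s, row in df.iterrows()}
    return pd.DataFrame.from_dict(out, orient="index").loc[df.index].rename(
        columns={"x": "x", "y": "y", "length": "length", "angle_deg": "angle_deg"})


def classify_quadrant(x_axis: float, y_axis: float) -> str:
    """Quadrant limitation call from ((LAP+NAG)/AP, BG/(LAP+NAG)).

    Boundary values (exactly 1.0) fall in the non-C-limited class.
    """
    if not (np.isfinite(x_axis) and np.isfinite(y_axis)):
        raise ValueError("quadrant inputs must be finite")
    if x_axis <= 0 or y_axis <= 0:
        raise ValueError("quadrant inputs must be > 0")
    c_limited = y_axis > 1.0
    p_limited = x_axis > 1.0
    if c_limited:
        return "C_and_P" if p_limited else "C_and_N"
    return "P" if p_limited else "N"


def quadrant_coordinates(enzymes: EnzymeActivities | pd.DataFrame) -> pd.DataFrame:
    df = enzymes.data if isinstance(enzymes, EnzymeActivities) else enzymes
    n_sum = df["LAP"] + df["NAG"]
    if (n_sum <= 0).any() or (df["AP"] <= 0).any() or (df["BG"] <= 0).any():
        raise ValueError("quadrant axes need BG, LAP+NAG and AP > 0")
    return pd.DataFrame({"x_axis": n_sum / df["AP"], "y_axis": df["BG"] / n_sum})


def classify_vector(vector: EnzymeVector | float, tol: float = 0.0) -> str:
    """N/P/balanced call from the vector angle with a +/- tol band at 45 deg."""
    angle = vector.angle_deg if isinstance(vector, EnzymeVector) else float(vector)
    if angle < 45.0 - tol:
        return "N_limited"
    if angle > 45.0 + tol:
        return "P_limited"
    return "balanced"


def enzyme_summary(enzymes: EnzymeActivities, tol: float = 0.0) -> pd.DataFrame:
    """Ratios, vector metrics and both limitation calls in one table."""
    ratios = stoich_ratios(enzymes)
    vectors = vector_metrics(enzymes)
    quad = quadrant_coordinates(enzymes)
    calls = pd.DataFrame({
        "quadrant": [classify_quadrant(x, y) for x, y in
                     zip(quad["x_axis"], quad["y_axis"])],
        "vector_call": [classify_vector(a, tol) for a in vectors["angle_deg"]],
    }, index=ratios.index)
    return pd.concat([ratios, vectors, quad, calls], axis=1)
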