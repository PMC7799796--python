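"""TOPSIS ranking of districts by spatial accessibility.

The Technique for Order of Preference by Similarity to Ideal Solution is
run separately on each coverage group (residential/clinic x individual/
public transport).  Each group is a two-criterion decision matrix — the
within-30-min and within-60-min coverage percentages — with the 30-min
criterion weighted more heavily (0.60/0.40 for residential groups,
0.70/0.30 for clinic groups).  All criteria are benefit criteria.

Steps: vector (Euclidean) column normalisation r_ij = x_ij / ||x_j||;
weighting v_ij = w_j r_ij; ideal alternative H_j = max_i v_ij and base
alternative D_j = min_i v_ij; Euclidean distances d+ and d- of each row
to H and D; relative closeness c_i = d- / (d- + d+) in [0, 1] (1 = ideal,
0 = base).  The four group scores average into the mean-total score MTc_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import GROUPS

__all__ = [
    "WeightScheme",
    "TopsisResult",
    "normalize",
    "apply_weights",
    "ideal_base",
    "distances",
    "closeness",
    "topsis",
    "run_group_topsis",
    "group_scores",
    "mean_total",
    "summarize_scores",
    "TopsisError",
    "DegenerateMatrixWarning",
]


class TopsisError(ValueError):
    pass


class DegenerateMatrixWarning(UserWarning):
    """All-zero criterion column or indistinguishable alternatives."""


def _group_weights() -> dict[str, tuple[float, float]]:
    return {
        "X4": (0.60, 0.40),
        "X5": (0.60, 0.40),
        "X6": (0.70, 0.30),
        "X7": (0.70, 0.30),
    }


@dataclass(frozen=True)
class WeightScheme:
    """Criterion weights (within-30, within-60) per coverage group."""

    group_weights: dict[str, tuple[float, float]] = field(
        default_factory=_group_weights
    )

    def weights_for(self, group: str) -> np.ndarray:
        w = np.asarray(self.group_weights[group], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise TopsisError(f"weights for {group} must be >= 0, not all zero")
        return w


def normalize(matrix: np.ndarray) -> np.ndarray:
    """Vector-normalised matrix: each column divided by its Euclidean norm.

    An all-zero column is returned as zeros with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise TopsisError("decision matrix must be 2-D with >= 2 alternatives")
    norms = np.sqrt((x**2).sum(axis=0))
    zero = norms == 0
    if zero.any():
        warnings.warn(
            "all-zero criterion column(s); normalised to zeros",
            DegenerateMatrixWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    return np.where(zero, 0.0, x / safe)


def apply_weights(r: np.ndarray, weights: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != r.shape[1]:
        raise TopsisError("one weight per criterion is required")
    if (w == 0).any():
        warnings.warn(
            "zero weight: criterion does not discriminate",
            DegenerateMatrixWarning,
            stacklevel=2,
        )
    return r * w


def ideal_base(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (ideal H, base D) of the weighted normalised matrix."""
    v = np.asarray(v, dtype=float)
    return v.max(axis=0), v.min(axis=0)


def distances(
    v: np.ndarray, h: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every alternative to the ideal and the base."""
    v = np.asarray(v, dtype=float)
    d_plus = np.sqrt(((v - h) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - d) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness(d_plus: np.ndarray, d_minus: np.ndarray) -> np.ndarray:
    """Relative closeness c = d- / (d- + d+); 0.5 where both distances are 0."""
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    if (d_plus < 0).any() or (d_minus < 0).any():
        raise TopsisError("distances must be nonnegative")
    both_zero = (d_plus == 0) & (d_minus == 0)
    if both_zero.any():
        warnings.warn(
            "indistinguishable alternatives: closeness set to 0.5",
            DegenerateMatrixWarning,
            stacklevel=2,
        )
    denom = np.where(both_zero, 1.0, d_plus + d_minus)
    return np.where(both_zero, 0.5, d_minus / denom)


@dataclass
class TopsisResult:
    """All intermediate matrices and the final ranking of one TOPSIS run."""

    alternatives: list[str]
    criteria: list[str]
    matrix: np.ndarray
    r: np.ndarray
    v: np.ndarray
    ideal: np.ndarray
    base: np.ndarray
    d_plus: np.ndarray
    d_minus: np.ndarray
    c: pd.Series  # closeness per alternative
    rank: pd.Series  # 1 = best; ties broken by alternative id

    def ranking(self) -> list[str]:
        return list(self.rank.sort_values().index)


def topsis(
    matrix: pd.DataFrame, weights: np.ndarray | list[float]
) -> TopsisResult:
    """Run the full five-step chain on an alternatives x criteria frame."""
    if matrix.isna().any().any():
        raise TopsisError("decision matrix contains missing values")
    if len(matrix) < 2:
        raise TopsisError("need at least 2 alternatives")
    x = matrix.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    r = normalize(x)
    v = apply_weights(r, w)
    h, d = ideal_base(v)
    d_plus, d_minus = distances(v, h, d)
    c = pd.Series(closeness(d_plus, d_minus), index=matrix.index, name="c")
    order = sorted(c.index, key=lambda a: (-c[a], str(a)))
    rank = pd.Series(
        {a: i + 1 for i, a in enumerate(order)}, name="rank"
    ).reindex(c.index)
    return TopsisResult(
        alternatives=list(matrix.index),
        criteria=list(matrix.columns),
        matrix=x,
        r=r,
        v=v,
        ideal=h,
        base=d,
        d_plus=d_plus,
        d_minus=d_minus,
        c=c,
        rank=rank,
    )


def run_group_topsis(
    indicator_table: pd.DataFrame,
    group: str,
    scheme: WeightScheme | None = None,
    exclude_zero_recipients: bool = True,
) -> TopsisResult:
    """TOPSIS over one coverage group's (a, b) criteria across districts.

    Districts with zero recipients carry no meaningful coverage and are
    dropped from the ranking (with a notice) unless disabled.
    """
    if group not in GROUPS:
        raise TopsisError(f"unknown group {group!r}; expected one of {list(GROUPS)}")
    scheme = scheme or WeightScheme()
    cols = [f"{group}a", f"{group}b"]
    table = indicator_table
    if exclude_zero_recipients and "X1" in table.columns:
        dropped = table.index[table["X1"] == 0]
        if len(dropped):
            warnings.warn(
                f"excluding zero-recipient districts from {group}: "
                f"{sorted(map(str, dropped))}",
                DegenerateMatrixWarning,
                stacklevel=2,
            )
            table = table[table["X1"] > 0]
    if len(table) < 2:
        raise TopsisError(f"group {group}: fewer than 2 districts with valid coverage")
    return topsis(table[cols], scheme.weights_for(group))


def group_scores(
    indicator_table: pd.DataFrame, scheme: WeightScheme | None = None
) -> pd.DataFrame:
    """Closeness per district for all four groups: columns X4ci..X7ci."""
    out = pd.DataFrame(index=indicator_table.index)
    for group in GROUPS:
        res = run_group_topsis(indicator_table, group, scheme)
        out[f"{group}ci"] = res.c
    out.index.name = "district_id"
    return out


def mean_total(scores: pd.DataFrame) -> pd.Series:
    """MTc_i: arithmetic mean of the four group closeness scores."""
    cols = [f"{g}ci" for g in GROUPS]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise TopsisError(f"missing group scores: {missing}")
    incomplete = scores.index[scores[cols].isna().any(axis=1)]
    if len(incomplete):
        raise TopsisError(
            f"districts missing a group score: {sorted(map(str, incomplete))}"
        )
    mt = scores[cols].mean(axis=1)
    mt.name = "MTci"
    return mt


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per score column.

    sd is the sample standard deviation (N-1); skewness is sample (Fisher)
    skewness and kurtosis is sample excess kurtosis, both as pandas
    computes them.
    """
    rows = {}
    for col in scores.columns:
        s = scores[col].dropna()
        rows[col] = {
            "mean": s.mean(),
            "median": s.median(),
            "sd": s.std(ddof=1),
            "min": s.min(),
            "max": s.max(),
            "skewness": s.skew(),
            "kurtosis": s.kurt(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
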