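"""Pairwise Pearson correlation with bootstrap percentile intervals.

The association phase correlates the demand and capacity indicators
(X1-X3) with the TOPSIS accessibility scores of the four coverage groups
(entered as X4-X7).  Each pair gets Pearson's r, two-sided significance
flags at the 0.05 and 0.01 levels (t-test with N-2 degrees of freedom),
a 95% percentile-bootstrap confidence interval over jointly resampled
district rows, and a verbal strength label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapConfig",
    "pearson",
    "significance",
    "bootstrap_ci",
    "correlation_matrix",
    "interpret",
    "STRENGTH_SCALE",
    "AssociationError",
]


class AssociationError(ValueError):
    pass


# |r| interval -> verbal label.  The middle two labels follow the
# published six-interval interpretation scale; the outer four extend it
# in the same spirit (documented extension).
STRENGTH_SCALE = (
    (0.00, 0.10, "negligible"),
    (0.10, 0.30, "low"),
    (0.30, 0.50, "moderate"),
    (0.50, 0.70, "substantial"),
    (0.70, 0.90, "very high"),
    (0.90, 1.0 + 1e-12, "near-perfect"),
)


@dataclass(frozen=True)
class BootstrapConfig:
    """Percentile-bootstrap settings.

    degenerate_policy governs zero-variance resamples: "redraw" replaces
    them (default), "drop" discards them before taking percentiles.
    """

    n_resamples: int = 2000
    confidence: float = 95.0
    seed: int = 0
    degenerate_policy: str = "redraw"

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise AssociationError("n_resamples must be >= 1")
        if not 0.0 < self.confidence < 100.0:
            raise AssociationError("confidence must be in (0, 100)")
        if self.degenerate_policy not in ("redraw", "drop"):
            raise AssociationError(
                f"unknown degenerate_policy {self.degenerate_policy!r}"
            )


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise AssociationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AssociationError("correlation undefined for zero-variance input")
    return x, y


def pearson(x, y) -> float:
    """Pearson's r: covariance (N-1 denominator) over the product of
    sample standard deviations; clipped to [-1, 1] against rounding."""
    x, y = _check_pair(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def significance(r: float, n: int, alpha: float) -> bool:
    """Two-sided t-test flag: t = r sqrt((N-2)/(1-r^2)) with N-2 df."""
    if n < 3:
        raise AssociationError("need N >= 3")
    if abs(r) >= 1.0:
        warnings.warn(
            "|r| = 1: flagged significant by convention", UserWarning, stacklevel=2
        )
        return True
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return bool(p < alpha)


def _rowwise_pearson(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """r per row of two equally shaped (B, n) resample arrays; NaN where
    either row has zero variance."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def bootstrap_ci(
    x, y, cfg: BootstrapConfig | None = None
) -> tuple[float, float]:
    """Percentile-bootstrap CI for Pearson's r.

    District rows (x_i, y_i) are resampled jointly with replacement,
    r is recomputed per resample, and the empirical percentile bounds of
    the configured confidence level are returned.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or BootstrapConfig()
    x, y = _check_pair(x, y)
    n = len(x)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.n_resamples, n))
    r = _rowwise_pearson(x[idx], y[idx])

    bad = np.flatnonzero(np.isnan(r))
    if bad.size and cfg.degenerate_policy == "redraw":
        for i in bad:
            for _ in range(1000):
                j = rng.integers(0, n, size=n)
                ri = _rowwise_pearson(x[j][None, :], y[j][None, :])[0]
                if not np.isnan(ri):
                    r[i] = ri
                    break
            else:  # pragma: no cover - pathological constant data
                raise AssociationError("could not redraw a non-degenerate resample")
        warnings.warn(
            f"redrew {bad.size} degenerate bootstrap resample(s)",
            UserWarning,
            stacklevel=2,
        )
    elif bad.size:
        r = r[~np.isnan(r)]
        warnings.warn(
            f"dropped {bad.size} degenerate bootstrap resample(s)",
            UserWarning,
            stacklevel=2,
        )
        if r.size == 0:
            raise AssociationError("all bootstrap resamples degenerate")

    half = (100.0 - cfg.confidence) / 2.0
    lower = float(np.percentile(r, half))
    upper = float(np.percentile(r, 100.0 - half))
    return lower, upper


def interpret(r: float) -> str:
    """Verbal strength label by |r| (sign-symmetric)."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise AssociationError("r must lie in [-1, 1]")
    for lo, hi, label in STRENGTH_SCALE:
        if lo <= a < hi:
            return label
    return STRENGTH_SCALE[-1][2]


def correlation_matrix(
    table: pd.DataFrame, cfg: BootstrapConfig | None = None
) -> pd.DataFrame:
    """All pairwise correlations over the table's columns.

    One row per unordered pair plus the diagonal, with columns var_a,
    var_b, n, r, sig05, sig01, ci_lower, ci_upper, label.  Bootstrap seeds
    are derived per pair from ``cfg.seed`` so results do not depend on
    pair order.
    """
    cfg = cfg or BootstrapConfig()
    if len(table) < 3:
        raise AssociationError("need at least 3 districts")
    # canonical row order makes the bootstrap resamples (and hence the CIs)
    # independent of the caller's row arrangement
    table = table.sort_index()
    cols = list(table.columns)
    rows = []
    for k, (a, b) in enumerate([(c, c) for c in cols] + list(combinations(cols, 2))):
        n = len(table)
        if a == b:
            r, ci = 1.0, (1.0, 1.0)
            sig05 = sig01 = True
        else:
            x = table[a].to_numpy(dtype=float)
            y = table[b].to_numpy(dtype=float)
            r = pearson(x, y)
            if abs(r) >= 1.0:
                sig05 = sig01 = True
                ci = (r, r)
            else:
                sig05 = significance(r, n, 0.05)
                sig01 = significance(r, n, 0.01)
                pair_cfg = BootstrapConfig(
                    n_resamples=cfg.n_resamples,
                    confidence=cfg.confidence,
                    seed=(cfg.seed * 1_000_003 + k) % (2**31),
                    degenerate_policy=cfg.degenerate_policy,
                )
                ci = bootstrap_ci(x, y, pair_cfg)
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "n": n,
                "r": r,
                "sig05": sig05,
                "sig01": sig01,
                "ci_lower": ci[0],
                "ci_upper": ci[1],
                "label": interpret(r),
            }
        )
    return pd.DataFrame(rows)
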