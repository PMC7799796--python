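"""Three-tier accessibility scale and its regional aggregation.

Each district x service class x transport mode combination is graded:

* I  (good, no gap): at least one provider is seated in the district and
  coverage within 30 minutes reaches 80-100%;
* III (poor, significant gap): no provider is seated in the district and
  at least 60% of demand sits beyond the 60-minute budget (coverage
  within 60 minutes at or below 40%);
* II (lowered, a gap): every other combination.  The published scale
  leaves holes between its verbal ranges (e.g. 70-80% within 30 min);
  making II the residual class yields a total, mutually exclusive rule.

The regional aggregation mirrors the study's summary tables: per-region
counts of districts in each class plus a "Total in %" row over all
districts, rounded half-up to a configurable number of decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

__all__ = [
    "GAP_CLASSES",
    "ScaleRule",
    "classify",
    "classify_dataset",
    "aggregate_scale_table",
    "round_half_up",
    "ClassificationError",
]

GAP_CLASSES = ("I", "II", "III")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleRule:
    """Thresholds of the accessibility scale (percent coverage).

    basis selects the coverage quantity: recipient-weighted shares
    (the formal indicator definition) or a municipality-count share as
    an area proxy for sensitivity runs.
    """

    good_min_cov30: float = 80.0
    lowered_min_cov30: float = 50.0
    poor_max_cov60: float = 40.0
    basis: str = "recipients"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lowered_min_cov30 < self.good_min_cov30 <= 100.0:
            raise ClassificationError(
                "require 0 <= lowered_min_cov30 < good_min_cov30 <= 100"
            )
        if self.basis not in ("recipients", "area"):
            raise ClassificationError(f"unknown basis {self.basis!r}")


def classify(
    provider_present: bool,
    cov30: float,
    cov60: float,
    rule: ScaleRule | None = None,
) -> str:
    """Grade one district/service/mode combination (returns "I"/"II"/"III")."""
    rule = rule or ScaleRule()
    if cov30 > cov60 + 1e-9:
        raise ClassificationError(
            f"cov30 ({cov30}) exceeds cov60 ({cov60}); bands are cumulative"
        )
    if provider_present and cov30 >= rule.good_min_cov30:
        return "I"
    if not provider_present and cov60 <= rule.poor_max_cov60:
        return "III"
    return "II"


def classify_dataset(
    dataset,
    coverage_table: pd.DataFrame,
    rule: ScaleRule | None = None,
    bands: tuple[int, int] = (30, 60),
) -> pd.DataFrame:
    """Long-form gap classes: district_id, service_class, mode, gap_class."""
    from .indicators import GROUPS

    rule = rule or ScaleRule()
    present: dict[tuple[str, str], bool] = {}
    mun_district = {m.id: m.district_id for m in dataset.municipalities}
    for f in dataset.facilities:
        present[(mun_district[f.municipality_id], f.service_class)] = True
    rows = []
    for district_id, row in coverage_table.iterrows():
        for group, (cls, mode) in GROUPS.items():
            rows.append(
                {
                    "district_id": district_id,
                    "service_class": cls,
                    "mode": mode,
                    "gap_class": classify(
                        present.get((district_id, cls), False),
                        float(row[f"{group}a"]),
                        float(row[f"{group}b"]),
                        rule,
                    ),
                }
            )
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (5 rounds away from zero), as in the tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_scale_table(
    classes: Mapping[str, str],
    district_region: Mapping[str, str],
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-region class counts plus the overall "Total in %" row.

    classes maps district id -> gap class for one service x mode slice;
    district_region maps district id -> region id.  The returned frame has
    one row per region (class counts) and a final ``Total in %`` row with
    the three shares of all districts, rounded half-up to ``decimals``
    (exported as integers when ``decimals`` is 0).
    """
    missing = sorted(set(district_region) - set(classes))
    if missing:
        raise ClassificationError(f"districts without a class: {missing}")
    unknown = sorted(set(classes) - set(district_region))
    if unknown:
        raise ClassificationError(f"classified districts without a region: {unknown}")
    bad = {d: c for d, c in classes.items() if c not in GAP_CLASSES}
    if bad:
        raise ClassificationError(f"invalid gap classes: {bad}")

    regions = sorted(set(district_region.values()))
    counts = {r: {c: 0 for c in GAP_CLASSES} for r in regions}
    for d, c in classes.items():
        counts[district_region[d]][c] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")[list(GAP_CLASSES)]
    table.index.name = "region"

    total = len(classes)
    shares = {
        c: round_half_up(100.0 * table[c].sum() / total, decimals)
        for c in GAP_CLASSES
    }
    if decimals == 0:
        shares = {c: int(v) for c, v in shares.items()}
    table.loc["Total in %"] = pd.Series(shares)
    return table
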