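"""District-level indicators.

X1 counts allowance-for-care recipients aged 65+, X2 sums residential
bed capacity and X3 clinic daily-spot capacity by district.  X4-X7 are
recipient-weighted coverage percentages: the share of a district's
recipients living in municipalities from which the nearest facility of a
service class is reachable within a time band, split by transport mode.
Each is decomposed into an ``a`` part (first band, 30 min) and a ``b``
part (second band, 60 min); bands are cumulative by default, so the
``b`` value can never fall below the ``a`` value.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .travel import InputError

__all__ = [
    "GROUPS",
    "COVERAGE_COLUMNS",
    "DegenerateDistrictWarning",
    "aggregate_district_base",
    "coverage",
    "compute_coverage",
    "indicator_table",
]

# coverage group -> (service class, transport mode)
GROUPS = {
    "X4": ("residential", "IT"),
    "X5": ("residential", "PT"),
    "X6": ("clinic", "IT"),
    "X7": ("clinic", "PT"),
}

COVERAGE_COLUMNS = [f"{g}{part}" for g in GROUPS for part in ("a", "b")]


class DegenerateDistrictWarning(UserWarning):
    """A district has no recipients; its coverage is defined as 0."""


def aggregate_district_base(dataset) -> pd.DataFrame:
    """X1-X3 per district as exact integer sums.

    Returns a frame indexed by district_id with columns X1, X2, X3.
    """
    rows = {}
    for d in dataset.districts:
        rows[d.id] = {"X1": 0, "X2": 0, "X3": 0}
    for m in dataset.municipalities:
        rows[m.district_id]["X1"] += int(m.recipients_65plus)
    mun_district = {m.id: m.district_id for m in dataset.municipalities}
    for f in dataset.facilities:
        key = "X2" if f.service_class == "residential" else "X3"
        rows[mun_district[f.municipality_id]][key] += int(f.capacity)
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "district_id"
    return out


def _band_column(reach: pd.DataFrame, band: float) -> str:
    col = f"within{int(band)}"
    if col not in reach.columns:
        raise InputError(f"reachability frame lacks band column {col!r}")
    return col


def coverage(
    district_id: str,
    service_class: str,
    mode: str,
    band: float,
    reach: pd.DataFrame,
    dataset,
) -> float:
    """Recipient-weighted coverage (%) of one district/service/mode/band.

    100 * (recipients in municipalities whose band flag is true) / (all
    recipients of the district); 0 with a warning when the district has no
    recipients.
    """
    muns = dataset.municipalities_in(district_id)
    if not muns:
        raise InputError(f"unknown district {district_id!r}")
    sub = reach[
        (reach["district_id"] == district_id)
        & (reach["service_class"] == service_class)
        & (reach["mode"] == mode)
    ]
    if sub.empty:
        raise InputError(
            f"no reachability rows for {district_id}/{service_class}/{mode}"
        )
    flags = dict(zip(sub["municipality"], sub[_band_column(reach, band)]))
    total = sum(m.recipients_65plus for m in muns)
    if total == 0:
        warnings.warn(
            f"district {district_id} has zero recipients; coverage set to 0",
            DegenerateDistrictWarning,
            stacklevel=2,
        )
        return 0.0
    inside = sum(m.recipients_65plus for m in muns if flags.get(m.id, False))
    return 100.0 * inside / total


def compute_coverage(
    dataset,
    reach: pd.DataFrame,
    bands: tuple[float, float] = (30.0, 60.0),
    cumulative: bool = True,
) -> pd.DataFrame:
    """X4a..X7b per district (floats in [0, 100]).

    With ``cumulative=False`` the second band is interpreted as the ring
    between the two budgets (sensitivity variant) instead of the nested
    "within 60" budget.
    """
    rec = pd.DataFrame(
        {
            "municipality": [m.id for m in dataset.municipalities],
            "district_id": [m.district_id for m in dataset.municipalities],
            "recipients": [m.recipients_65plus for m in dataset.municipalities],
        }
    )
    totals = rec.groupby("district_id")["recipients"].sum()
    zero = totals[totals == 0]
    for district_id in zero.index:
        warnings.warn(
            f"district {district_id} has zero recipients; coverage set to 0",
            DegenerateDistrictWarning,
            stacklevel=2,
        )

    col_a = _band_column(reach, bands[0])
    col_b = _band_column(reach, bands[1])
    merged = reach.merge(rec[["municipality", "recipients"]], on="municipality")
    out = pd.DataFrame(index=totals.index)
    out.index.name = "district_id"
    for group, (cls, mode) in GROUPS.items():
        sub = merged[(merged["service_class"] == cls) & (merged["mode"] == mode)]
        in_a = sub[col_a]
        in_b = sub[col_b] if cumulative else (sub[col_b] & ~sub[col_a])
        w_a = (sub["recipients"] * in_a).groupby(sub["district_id"]).sum()
        w_b = (sub["recipients"] * in_b).groupby(sub["district_id"]).sum()
        safe = totals.astype(float).replace(0.0, float("nan"))
        out[f"{group}a"] = (100.0 * w_a / safe).fillna(0.0)
        out[f"{group}b"] = (100.0 * w_b / safe).fillna(0.0)
    return out.sort_index()


def indicator_table(dataset, reach: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """X1-X3 joined with X4a..X7b, one row per district."""
    base = aggregate_district_base(dataset)
    cov = compute_coverage(dataset, reach, **kwargs)
    return base.join(cov)
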