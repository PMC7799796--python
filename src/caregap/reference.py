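"""Published regional accessibility-scale counts (Czech districts, 2018).

These per-region counts of districts in each accessibility class — for
residential care (homes for the elderly plus special-regime homes), day
services centres and day care centres, by individual (IT) and public
(PT) transport — serve as worked-example inputs: feeding them through
:func:`caregap.classification.aggregate_scale_table` must reproduce the
published "Total in %" rows.

Region keys are the 13 Czech self-governing regions (Prague excluded);
each value is the (class I, class II, class III) district count.  The
day-services IT block is known to be internally inconsistent in its
published form (its cells sum to 75 districts, not 76) and is therefore
not included here.
"""

from __future__ import annotations

from .classification import aggregate_scale_table

__all__ = [
    "REGION_DISTRICTS",
    "RESIDENTIAL_IT",
    "RESIDENTIAL_PT",
    "DAY_SERVICES_PT",
    "DAY_CARE_IT",
    "DAY_CARE_PT",
    "scale_table_from_counts",
]

# region -> number of districts
REGION_DISTRICTS = {
    "CBR": 12, "SBR": 7, "PLR": 7, "CR": 3, "UR": 7, "LR": 4, "HKR": 5,
    "PR": 4, "VR": 5, "SMR": 7, "OR": 5, "MSR": 6, "ZR": 4,
}

RESIDENTIAL_IT = {
    "CBR": (12, 0, 0), "SBR": (7, 0, 0), "PLR": (5, 0, 2), "CR": (2, 1, 0),
    "UR": (7, 0, 0), "LR": (4, 0, 0), "HKR": (5, 0, 0), "PR": (4, 0, 0),
    "VR": (5, 0, 0), "SMR": (7, 0, 0), "OR": (5, 0, 0), "MSR": (6, 0, 0),
    "ZR": (4, 0, 0),
}

RESIDENTIAL_PT = {
    "CBR": (12, 0, 0), "SBR": (5, 2, 0), "PLR": (3, 2, 2), "CR": (1, 2, 0),
    "UR": (7, 0, 0), "LR": (4, 0, 0), "HKR": (5, 0, 0), "PR": (4, 0, 0),
    "VR": (5, 0, 0), "SMR": (7, 0, 0), "OR": (5, 0, 0), "MSR": (6, 0, 0),
    "ZR": (4, 0, 0),
}

DAY_SERVICES_PT = {
    "CBR": (1, 9, 2), "SBR": (0, 0, 7), "PLR": (0, 1, 6), "CR": (0, 0, 3),
    "UR": (1, 4, 2), "LR": (1, 2, 1), "HKR": (0, 4, 1), "PR": (0, 2, 2),
    "VR": (0, 2, 3), "SMR": (1, 6, 0), "OR": (0, 3, 2), "MSR": (2, 3, 1),
    "ZR": (0, 3, 1),
}

DAY_CARE_IT = {
    "CBR": (9, 3, 0), "SBR": (3, 4, 0), "PLR": (3, 4, 0), "CR": (0, 3, 0),
    "UR": (3, 4, 0), "LR": (2, 2, 0), "HKR": (3, 2, 0), "PR": (2, 2, 0),
    "VR": (4, 1, 0), "SMR": (3, 4, 0), "OR": (1, 4, 0), "MSR": (4, 2, 0),
    "ZR": (4, 0, 0),
}

DAY_CARE_PT = {
    "CBR": (4, 6, 2), "SBR": (1, 4, 2), "PLR": (1, 4, 2), "CR": (0, 1, 2),
    "UR": (3, 3, 1), "LR": (1, 3, 0), "HKR": (1, 4, 0), "PR": (1, 3, 0),
    "VR": (2, 2, 1), "SMR": (1, 5, 1), "OR": (2, 3, 0), "MSR": (4, 2, 0),
    "ZR": (1, 3, 0),
}


def scale_table_from_counts(counts: dict, decimals: int):
    """Expand per-region (I, II, III) counts into per-district classes and
    aggregate them, exercising the real aggregation path."""
    classes = {}
    regions = {}
    for region, (n1, n2, n3) in counts.items():
        i = 0
        for cls, n in zip(("I", "II", "III"), (n1, n2, n3)):
            for _ in range(n):
                i += 1
                d = f"{region}-{i:02d}"
                classes[d] = cls
                regions[d] = region
    return aggregate_scale_table(classes, regions, decimals=decimals)
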