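"""Base nutritional conditions and condition groupings.

The experimental design crosses two nutritional factors, iron (Fe) and
molybdenum (Mo), each either sufficient (+) or starved (−), giving four base
conditions. Analyses pool the base conditions pairwise into four *groupings*,
one per factor level: e.g. the Fe-starvation grouping pools every sample grown
without Fe, regardless of Mo status. Each sample therefore belongs to exactly
two groupings (one per factor), which is why grouping-level co-expression
networks share half of their samples with two other groupings.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

#: The four base conditions (Mo status first, Fe status second).
BASE_CONDITIONS: tuple[str, ...] = ("+Mo+Fe", "+Mo-Fe", "-Mo+Fe", "-Mo-Fe")

#: Grouping name -> the two base conditions pooled into it.
GROUPINGS: dict[str, frozenset[str]] = {
    "Fe_sufficiency": frozenset({"+Mo+Fe", "-Mo+Fe"}),
    "Fe_starvation": frozenset({"+Mo-Fe", "-Mo-Fe"}),
    "Mo_sufficiency": frozenset({"+Mo+Fe", "+Mo-Fe"}),
    "Mo_starvation": frozenset({"-Mo+Fe", "-Mo-Fe"}),
}

#: Reporting order matching the +Fe / +Mo / −Fe / −Mo column layout.
GROUPING_ORDER: tuple[str, ...] = (
    "Fe_sufficiency",
    "Mo_sufficiency",
    "Fe_starvation",
    "Mo_starvation",
)

#: Factor -> level label -> base conditions at that level.
FACTOR_LEVELS: dict[str, dict[str, frozenset[str]]] = {
    "Fe": {
        "+Fe": GROUPINGS["Fe_sufficiency"],
        "-Fe": GROUPINGS["Fe_starvation"],
    },
    "Mo": {
        "+Mo": GROUPINGS["Mo_sufficiency"],
        "-Mo": GROUPINGS["Mo_starvation"],
    },
}

#: Complementary grouping on the same factor (disjoint sample sets).
COMPLEMENT: dict[str, str] = {
    "Fe_sufficiency": "Fe_starvation",
    "Fe_starvation": "Fe_sufficiency",
    "Mo_sufficiency": "Mo_starvation",
    "Mo_starvation": "Mo_sufficiency",
}


def validate_metadata(meta: pd.Series) -> None:
    """Check that a sample -> base-condition mapping uses known conditions.

    Raises ``ValueError`` on unknown condition labels or duplicated sample ids.
    """
    unknown = set(meta.unique()) - set(BASE_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown base conditions: {sorted(unknown)}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")


def samples_for_conditions(meta: pd.Series, conditions: Iterable[str]) -> list[str]:
    """Samples whose base condition is in ``conditions`` (metadata order)."""
    wanted = set(conditions)
    return [s for s, c in meta.items() if c in wanted]


def samples_for_grouping(meta: pd.Series, grouping: str) -> list[str]:
    """Samples pooled into a named condition grouping."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {sorted(GROUPINGS)}")
    return samples_for_conditions(meta, GROUPINGS[grouping])


def grouping_sizes(meta: pd.Series) -> dict[str, int]:
    """Number of samples per grouping (each sample counts in two groupings)."""
    return {g: len(samples_for_grouping(meta, g)) for g in GROUPING_ORDER}


def check_grouping_design(reps: Mapping[str, int]) -> None:
    """Validate a replicate allocation over the four base conditions.

    Raises ``ValueError`` if any base condition is missing or a count is not a
    positive integer.
    """
    missing = set(BASE_CONDITIONS) - set(reps)
    if missing:
        raise ValueError(f"reps_per_condition missing base conditions: {sorted(missing)}")
    for cond, n in reps.items():
        if cond not in BASE_CONDITIONS:
            raise ValueError(f"unknown base condition {cond!r}")
        if int(n) != n or n <= 0:
            raise ValueError(f"replicate count for {cond!r} must be a positive integer")
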