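"""miRNA family mapping and cross-study comparative labelling.

Mature miRNAs are grouped into seed families (e.g. mmu-miR-154-5p ->
mir-154); family-level sets are what can be compared across studies
that detect different mature species. The cross-study decision table
labels a family's behaviour here against an external ageing/calorie-
restriction (CR) study: a family whose dwarf-mouse age response is
absent while CR abolishes the external age response behaves "CR-like";
one whose dwarf response diverges from both the external age and CR
responses is "CR-independent".
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

__all__ = [
    "map_families",
    "family_summary",
    "family_venn",
    "cross_study_label",
]

_DIRECTIONS = ("up", "down", "none")
_PATTERNS = ("A", "B", "C", "D")

# dwarf-mouse age direction implied by each pattern label
_PATTERN_DWARF_DIR = {"A": "none", "B": "none", "C": "up", "D": "up"}


def map_families(mirnas: Sequence[str], family_map: Mapping[str, str]) -> list[str]:
    """Map mature miRNA tokens to family tokens; error on unmapped."""
    unmapped = [m for m in mirnas if m not in family_map]
    if unmapped:
        raise KeyError(f"miRNAs missing from the family map: {unmapped}")
    return [family_map[m] for m in mirnas]


def family_summary(
    mirnas: Sequence[str], family_map: Mapping[str, str]
) -> tuple[int, dict[str, int]]:
    """Distinct-family count and per-family member counts.

    The member counts sum to the number of input miRNAs.
    """
    fams = map_families(mirnas, family_map)
    members = dict(Counter(fams))
    return len(members), members


def family_venn(
    families_a: Iterable[str], families_b: Iterable[str]
) -> tuple[int, int, int]:
    """(only in A, shared, only in B) counts of two family sets."""
    a, b = set(families_a), set(families_b)
    return len(a - b), len(a & b), len(b - a)


def cross_study_label(
    pattern_here: str,
    external_age_direction: str,
    external_cr_direction: str,
) -> str:
    """Label a shared family's behaviour relative to an external CR study.

    Parameters
    ----------
    pattern_here : GbA pattern of the family in this study (A-D), or
        "" / "absent" when the family was not detected externally-shared
        analysis should not reach here.
    external_age_direction : direction of the family's change with age
        in the external study ("up", "down", "none"), or "absent" when
        the family was not detected there.
    external_cr_direction : the family's direction with age under CR in
        the external study.

    Returns one of "CR-like", "CR-independent", "unshared",
    "unclassified".
    """
    if external_age_direction == "absent" or external_cr_direction == "absent":
        return "unshared"
    if pattern_here not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern_here!r}")
    for d in (external_age_direction, external_cr_direction):
        if d not in _DIRECTIONS:
            raise ValueError(f"unknown direction {d!r}")
    dwarf_dir = _PATTERN_DWARF_DIR[pattern_here]
    # dwarf age response absent and CR abolishes the external age change
    if (
        dwarf_dir == "none"
        and external_age_direction != "none"
        and external_cr_direction == "none"
    ):
        return "CR-like"
    # dwarf response diverges from both external age and CR behaviour
    if (
        dwarf_dir != "none"
        and dwarf_dir != external_age_direction
        and dwarf_dir != external_cr_direction
    ):
        return "CR-independent"
    return "unclassified"
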