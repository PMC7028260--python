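"""Assign a single HbA1c dose to each exposure category.

Dose-response meta-analysis needs one exposure value per category.  Closed
intervals get their midpoint; an open-ended interval is extended by half
the width of its adjacent closed interval (the standard convention when a
study reports e.g. ">9%"), or by a fixed half-width when no closed
neighbour exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

from .errors import DoseAssignmentError
from .study_table import ExposureCategory, StudyRecord, StudyTable

log = logging.getLogger(__name__)

ADJACENT_WIDTH = "adjacent_width"
FIXED_WIDTH = "fixed_width"


@dataclass(frozen=True)
class DoseRule:
    """Policy for dosing open-ended intervals.

    ``adjacent_width`` (default) borrows half the width of the nearest
    closed interval; ``fixed_width`` uses a constant half-width ``w/2``.
    Point categories always take their printed value.
    """

    open_interval_policy: str = ADJACENT_WIDTH
    fixed_width: Optional[float] = None

    def __post_init__(self):
        if self.open_interval_policy not in (ADJACENT_WIDTH, FIXED_WIDTH):
            raise ValueError(f"unknown open-interval policy {self.open_interval_policy!r}")
        if self.open_interval_policy == FIXED_WIDTH:
            if self.fixed_width is None or self.fixed_width <= 0:
                raise ValueError("fixed_width policy requires a positive width")


def _closed_widths(categories) -> list[Optional[float]]:
    return [
        c.upper - c.lower if (c.lower is not None and c.upper is not None) else None
        for c in categories
    ]


def _adjacent_width(widths, idx, direction) -> Optional[float]:
    """Nearest closed-interval width scanning from idx in direction +-1."""
    j = idx + direction
    while 0 <= j < len(widths):
        if widths[j] is not None:
            return widths[j]
        j += direction
    # fall back to scanning the other way so a lone closed interval anywhere helps
    j = idx - direction
    while 0 <= j < len(widths):
        if widths[j] is not None:
            return widths[j]
        j -= direction
    return None


def assign_doses(record: StudyRecord, rule: DoseRule = DoseRule()) -> StudyRecord:
    """Return a copy of ``record`` with ``assigned_dose`` set on each category.

    Closed ``[a, b]`` -> ``(a+b)/2``; open-above ``>a`` -> ``a + w/2``;
    open-below ``<b`` -> ``b - w/2``, where ``w`` is the adjacent closed
    interval's width (or the rule's fixed width).  A reference category with
    no numeric information at all (a bare "control" group) is left
    unassigned; any other category without bounds raises.

    Raises
    ------
    DoseAssignmentError
        If an open interval has no width source, a non-reference category
        carries no numeric information, or assigned doses fail to be
        strictly increasing in category order.
    """
    if not record.categories:
        raise DoseAssignmentError(f"{record.study_id}: no categories to dose")

    cats = record.categories
    widths = _closed_widths(cats)
    new_cats: list[ExposureCategory] = []
    for i, c in enumerate(cats):
        dose: Optional[float]
        if c.point_value is not None:
            dose = c.point_value
        elif c.lower is not None and c.upper is not None:
            dose = (c.lower + c.upper) / 2.0
        elif c.lower is not None or c.upper is not None:
            if rule.open_interval_policy == FIXED_WIDTH:
                w = rule.fixed_width
            else:
                # open-above (>a): borrow from the next-lower closed interval;
                # open-below (<b): from the next-higher one
                w = _adjacent_width(widths, i, -1 if c.lower is not None else +1)
            if w is None:
                raise DoseAssignmentError(
                    f"{record.study_id}: open interval in category {i} but no closed "
                    "interval supplies a width; use a fixed_width rule"
                )
            dose = c.lower + w / 2.0 if c.lower is not None else c.upper - w / 2.0
        elif c.is_reference:
            dose = None  # bound-less control group: no dose is definable
        else:
            raise DoseAssignmentError(
                f"{record.study_id}: category {i} has no bounds, point value or reference role"
            )
        if dose is not None:
            log.debug("%s category %d -> dose %.4g", record.study_id, i, dose)
        new_cats.append(replace(c, assigned_dose=dose))

    assigned = [c.assigned_dose for c in new_cats if c.assigned_dose is not None]
    if any(b <= a for a, b in zip(assigned, assigned[1:])):
        raise DoseAssignmentError(
            f"{record.study_id}: assigned doses {assigned} are not strictly increasing"
        )
    return replace(record, categories=new_cats)


def assign_doses_table(table: StudyTable, rule: DoseRule = DoseRule()) -> StudyTable:
    """Apply :func:`assign_doses` to every record that has categories."""
    out = [assign_doses(r, rule) if r.categories else r for r in table.records]
    return StudyTable(out, table.provenance)
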