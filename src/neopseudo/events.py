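"""Parsimony assignment of pseudogenization events to tree branches.

Functionality calls for the four copies of an ortholog group are mapped
onto the fixed species topology ``(Dobs, (Dpse, (neoX, neoY)))``.  A
pseudogenization event is a functional -> pseudogene transition on a
branch; under parsimony, sister lineages that lost function for the
*same* cause share one event on their common ancestral branch, while
losses with different causes are independent events on the terminal
branches.

Branches:

* ``Anc``  — from the *D. miranda*/*D. pseudoobscura* split to the
  neo-X/neo-Y split (the neo-sex proto-chromosome);
* ``X``, ``Y`` — the neo-X / neo-Y terminal branches;
* ``Pse`` — the *D. pseudoobscura* terminal branch;
* ``Stem`` — the branch subtending the *D. miranda* + *D. pseudoobscura*
  ancestor; events here are reported but excluded from the four focal
  branches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .classify import CODING, DELETION, REGULATORY, FunctionalityCall, Status

BOTH = "both"

#: event causes; "both" = simultaneous regulatory + coding loss
CAUSES = (REGULATORY, CODING, BOTH, DELETION)


class Branch(str, enum.Enum):
    ANC = "Anc"
    X = "X"
    Y = "Y"
    PSE = "Pse"
    STEM = "Stem"


class Category(str, enum.Enum):
    """Ortholog-group functionality category on the neo-sex chromosomes.

    F = functional, P = pseudogenized (any pseudogene status or absent);
    e.g. XP_YF = non-functional on the neo-X, functional on the neo-Y.
    """

    XF_YF = "XF_YF"
    XF_YP = "XF_YP"
    XP_YF = "XP_YF"
    XP_YP = "XP_YP"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class EventAssignment:
    group_id: str
    events: frozenset  # of (Branch, cause)
    category: Category
    #: False when an unclassified neo-X/neo-Y call makes the group
    #: ineligible for X/Y/Anc event counting
    xy_eligible: bool = True


def _cause_set(call: FunctionalityCall):
    """Pseudogenization causes of a call; None marks unclassified."""
    if call.status is Status.UNCLASSIFIED:
        return None
    return call.causes  # empty frozenset for functional


def _cause_label(causes: frozenset) -> str:
    if causes == frozenset({REGULATORY}):
        return REGULATORY
    if causes == frozenset({CODING}):
        return CODING
    if causes == frozenset({REGULATORY, CODING}):
        return BOTH
    if causes == frozenset({DELETION}):
        return DELETION
    raise ValueError(f"uninterpretable cause set {set(causes)}")


def categorize_group(calls: dict[str, FunctionalityCall]) -> Category:
    """Category from the neo-X and neo-Y calls (functional -> F, any
    pseudogene status or absent -> P, unclassified -> UNASSIGNED)."""
    cx = calls.get("neoX")
    cy = calls.get("neoY")
    if cx is None or cy is None:
        return Category.UNASSIGNED
    if cx.is_pseudogene is None or cy.is_pseudogene is None:
        return Category.UNASSIGNED
    x = "P" if cx.is_pseudogene else "F"
    y = "P" if cy.is_pseudogene else "F"
    return Category[f"X{x}_Y{y}"]


def assign_events(group_id: str, calls: dict[str, FunctionalityCall]) -> EventAssignment:
    """Infer the minimum set of (branch, cause) pseudogenization events.

    Rules (Dobs is functional by the analysis-set precondition):

    a. a *D. pseudoobscura* pseudogene contributes an event on ``Pse``;
    b. neo-X and neo-Y both pseudogenized with intersecting cause sets
       share one event on ``Anc``; with disjoint cause sets they carry
       two independent events on ``X`` and ``Y``;
    c. exactly one pseudogenized neo-sex copy puts one event on that
       terminal branch;
    d. all three ingroup tips pseudogenized with one common cause
       collapse to a single event on ``Stem``;
    e. an unclassified neo-X or neo-Y call suppresses X/Y/Anc events for
       the group (a ``Pse`` event may still be counted).
    """
    cp = _cause_set(calls["Dpse"]) if "Dpse" in calls else frozenset()
    cx = _cause_set(calls["neoX"]) if "neoX" in calls else None
    cy = _cause_set(calls["neoY"]) if "neoY" in calls else None
    category = categorize_group(calls)

    xy_eligible = cx is not None and cy is not None
    events = set()

    if xy_eligible and cx and cy:
        shared_xy = cx & cy
        shared_all = shared_xy & cp if cp else frozenset()
        if shared_all:
            # one loss before the Dpse/Dmir split explains all three tips
            events.add((Branch.STEM, _cause_label(shared_all)))
            return EventAssignment(group_id, frozenset(events), category, True)
        if shared_xy:
            events.add((Branch.ANC, _cause_label(shared_xy)))
        else:
            events.add((Branch.X, _cause_label(cx)))
            events.add((Branch.Y, _cause_label(cy)))
    elif xy_eligible:
        if cx:
            events.add((Branch.X, _cause_label(cx)))
        if cy:
            events.add((Branch.Y, _cause_label(cy)))

    if cp:  # None never occurs: an unclassified Dpse has empty causes
        events.add((Branch.PSE, _cause_label(cp)))
    return EventAssignment(group_id, frozenset(events), category, xy_eligible)


def count_events(assignments, category_filter=()):
    """Tally events per branch with a cause breakdown.

    ``category_filter`` lists categories whose groups are dropped before
    counting (e.g. ``{Category.XP_YF}`` for the feminization recount).

    Returns ``{branch: {"n_events": int, "regulatory": int, "coding": int,
    "both": int, "deletion": int}}`` plus key ``"n_groups_at_risk"`` with
    the number of groups counted.
    """
    drop = {Category(c) for c in category_filter}
    counts = {b: {"n_events": 0, REGULATORY: 0, CODING: 0, BOTH: 0, DELETION: 0}
              for b in Branch}
    n_groups = 0
    for a in assignments:
        if a.category in drop:
            continue
        n_groups += 1
        for branch, cause in a.events:
            counts[branch]["n_events"] += 1
            counts[branch][cause] += 1
    counts["n_groups_at_risk"] = n_groups
    return counts
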