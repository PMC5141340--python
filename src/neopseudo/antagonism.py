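"""Sexual antagonism vs. neo-X functionality contingency analysis.

Sexual-antagonism labels (female-benefit/male-detriment Fb_Md,
male-benefit/female-detriment Mb_Fd, no_conflict, unclassified) are
transferred by homology from an external catalogue and joined to the
neo-X functionality calls.  The emitted table is 2 (functional/pseudo)
x 4 (label); the test is a Pearson chi-square, without continuity
correction, on the 2x2 sub-table restricted to the two antagonistic
label classes.  No-conflict and unclassified genes appear in the table
but not in the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .rates import Chi2Result, pearson_chi2_2x2

LABELS = ("Fb_Md", "Mb_Fd", "no_conflict", "unclassified")


@dataclass
class AntagonismResult:
    table: pd.DataFrame  # rows functional/pseudo, columns LABELS + Total
    ratio_functional: float | None  # Fb_Md : Mb_Fd among functional genes
    ratio_pseudo: float | None
    chi2: Chi2Result


def antagonism_contingency(is_pseudo: dict, labels: dict) -> AntagonismResult:
    """Build the functionality x antagonism table and test the 2x2 core.

    ``is_pseudo`` maps neo-X gene/group id -> bool (None-valued
    unclassified calls must be excluded by the caller); ``labels`` maps
    id -> label, with missing ids treated as unclassified.
    """
    if not labels:
        raise ValueError("empty antagonism label set")
    counts = {row: {lab: 0 for lab in LABELS} for row in ("functional", "pseudo")}
    for gid, pseudo in is_pseudo.items():
        lab = labels.get(gid, "unclassified")
        counts["pseudo" if pseudo else "functional"][lab] += 1
    table = pd.DataFrame(counts).T[list(LABELS)]
    table["Total"] = table.sum(axis=1)

    def _ratio(row):
        fb, mb = counts[row]["Fb_Md"], counts[row]["Mb_Fd"]
        return fb / mb if mb else None

    sub = [[counts["functional"]["Fb_Md"], counts["functional"]["Mb_Fd"]],
           [counts["pseudo"]["Fb_Md"], counts["pseudo"]["Mb_Fd"]]]
    chi2 = pearson_chi2_2x2(sub)  # raises on an empty/zero-marginal 2x2
    return AntagonismResult(table, _ratio("functional"), _ratio("pseudo"), chi2)
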