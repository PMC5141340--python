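"""Time calibration of branch event counts and chi-square comparisons.

The *D. miranda* / *D. pseudoobscura* divergence (default 2 Mya) and the
neo-sex-chromosome emergence (default 1 Mya, alternative 1.5 Mya) define
the time windows.  Assuming a constant pseudogenization rate on the
*D. pseudoobscura* lineage, its event count is prorated linearly into
the window comparable to the neo-sex branches; the resulting fractional
counts (e.g. 114.5) are compared with neo-sex branch counts by a 1-d.f.
equal-expectation goodness-of-fit chi-square.  Contingency analyses use
the Pearson chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TimeCalibration:
    """Divergence and neo-sex emergence times in Mya."""

    divergence_mya: float = 2.0
    emergence_mya: float = 1.0

    def __post_init__(self):
        if not (0 < self.emergence_mya <= self.divergence_mya):
            raise ValueError(
                f"need 0 < emergence ({self.emergence_mya}) <= divergence "
                f"({self.divergence_mya})"
            )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0 or df < 1:
        raise ValueError("need x >= 0 and df >= 1")
    return float(stats.chi2.sf(x, df))


def split_lineage_events(pse_events: float, cal: TimeCalibration):
    """Prorate Pse-lineage events into (pre-window, post-window) counts.

    The post-window — the time span during which the neo-sex chromosomes
    existed — receives ``pse_events * emergence / divergence`` events
    under a constant-rate assumption; fractional counts are kept.
    Returns ``(pre_window, post_window)``.
    """
    if pse_events < 0:
        raise ValueError("event count must be >= 0")
    post = pse_events * cal.emergence_mya / cal.divergence_mya
    return pse_events - post, post


def gof_two_counts(a: float, b: float) -> Chi2Result:
    """1-d.f. goodness-of-fit of two (possibly fractional) counts against
    equal expectation (a+b)/2 each; no continuity correction."""
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0:
        raise ValueError("cannot test two zero counts")
    stat, p = stats.chisquare([a, b])
    return Chi2Result(float(stat), 1, float(p))


def pearson_chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, expected counts from the
    row/column marginals, d.f. = 1, no Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


def branch_proportion(n_events: float, n_groups: int) -> float:
    """Percentage of the at-risk groups pseudogenized on a branch."""
    if n_groups <= 0:
        raise ValueError("n_groups must be > 0")
    return 100.0 * n_events / n_groups
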