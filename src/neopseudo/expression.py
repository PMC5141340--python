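"""Sex-biased expression analyses.

Two analyses on the *D. pseudoobscura* expression data, with genes
grouped by the functionality category of their neo-sex orthologs:

* female-to-male (F/M) expression ratios per tissue and category, with
  pairwise bootstrap median tests — male-biased ancestral expression of
  the XP_YF category is the feminization signal;
* the maximum-expression-tissue analysis: genes are assigned to the
  tissue where their (normalized) expression is at least two-fold that
  of every other tissue, and the pseudogene:functional ratio of their
  neo-X copies is computed per tissue with bootstrap confidence
  intervals.

cFPKM defaults to the raw FPKM; a per-tissue normalizer (e.g.
upper-quartile scaling) can be plugged in.  The two-fold argmax rule is
scale-invariant within a tissue, so the analysis logic is unaffected by
the normalizer choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import Category
from .io import ExpressionMatrix
from .molevol import bootstrap_median_test

logger = logging.getLogger("neopseudo")

#: sentinel tissue label pairing ovary (female) with testis (male)
GONAD = "gonad"


@dataclass
class TissueProfile:
    """Per-gene expression: FPKM by (tissue, sex) and cFPKM by tissue."""

    gene_id: str
    fpkm: dict = field(default_factory=dict)  # (tissue, sex) -> fpkm
    cfpkm: dict = field(default_factory=dict)  # tissue -> normalized value

    @classmethod
    def from_matrix(cls, gene_id: str, expr: ExpressionMatrix, normalizer=None):
        """Build a profile; cFPKM per tissue is the mean over measured
        sexes, optionally transformed by ``normalizer(tissue, value)``."""
        fpkm = {(t, s): v for (t, s, v) in expr.gene_samples(gene_id)}
        per_tissue: dict[str, list[float]] = {}
        for (t, _s), v in fpkm.items():
            per_tissue.setdefault(t, []).append(v)
        cfpkm = {t: float(np.mean(vs)) for t, vs in per_tissue.items()}
        if normalizer is not None:
            cfpkm = {t: normalizer(t, v) for t, v in cfpkm.items()}
        return cls(gene_id, fpkm, cfpkm)


def upper_quartile_normalizer(expr: ExpressionMatrix):
    """Per-tissue upper-quartile scaling factory.

    Returns a ``normalizer(tissue, value)`` dividing by the tissue's
    75th-percentile FPKM across genes (tissues with a zero quartile are
    left unscaled).
    """
    per_tissue: dict[str, list[float]] = {}
    for (g, t, s), v in expr.items():
        per_tissue.setdefault(t, []).append(v)
    uq = {t: float(np.percentile(vs, 75)) for t, vs in per_tissue.items()}

    def normalizer(tissue, value):
        q = uq.get(tissue, 0.0)
        return value / q if q > 0 else value

    return normalizer


def fm_ratio(profile: TissueProfile, tissue: str, pseudocount: float = 0.0,
             floor: float = 1.0):
    """Female/male expression ratio in one tissue, or None (excluded).

    The ``gonad`` tissue pairs ovary (female) with testis (male).  Genes
    with ``max(F, M) < floor`` are excluded (None); with pseudocount 0 a
    zero male value also excludes the gene (undefined ratio).
    """
    if tissue == GONAD:
        f_key, m_key = ("ovary", "F"), ("testis", "M")
    else:
        f_key, m_key = (tissue, "F"), (tissue, "M")
    if f_key not in profile.fpkm or m_key not in profile.fpkm:
        raise ValueError(f"{profile.gene_id}: tissue {tissue!r} lacks both sexes")
    f = profile.fpkm[f_key]
    m = profile.fpkm[m_key]
    if max(f, m) < floor:
        return None
    if m + pseudocount == 0:
        return None
    return (f + pseudocount) / (m + pseudocount)


def compare_fm_by_category(profiles: dict, categories: dict, tissue: str,
                           pseudocount: float = 0.0, floor: float = 1.0,
                           reps: int = 1000, seed: int = 0):
    """Per-category F/M ratio distributions and pairwise bootstrap tests.

    ``profiles`` maps gene_id -> TissueProfile (the expressed analysis
    set); ``categories`` maps gene_id -> Category.  UNASSIGNED genes and
    excluded ratios are dropped.  Categories with < 2 usable genes are
    skipped from the pairwise comparisons with a warning.

    Returns ``{"ratios": {cat: array}, "summary": {cat: {n, median, q25,
    q75}}, "pairwise_p": {(catA, catB): p}}``.
    """
    ratios: dict[Category, list[float]] = {}
    for gid, prof in profiles.items():
        cat = categories.get(gid)
        if cat is None or cat is Category.UNASSIGNED:
            continue
        try:
            r = fm_ratio(prof, tissue, pseudocount, floor)
        except ValueError:
            continue
        if r is not None:
            ratios.setdefault(cat, []).append(r)
    summary = {}
    for cat, vals in ratios.items():
        arr = np.asarray(vals)
        summary[cat] = {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "q25": float(np.percentile(arr, 25)),
            "q75": float(np.percentile(arr, 75)),
        }
    pairwise = {}
    cats = sorted(ratios, key=lambda c: c.value)
    for i, ca in enumerate(cats):
        for cb in cats[i + 1 :]:
            if len(ratios[ca]) < 2 or len(ratios[cb]) < 2:
                logger.warning("category with < 2 members; skipping %s vs %s", ca, cb)
                continue
            # sorted inputs make the result independent of gene input order
            pairwise[(ca, cb)] = bootstrap_median_test(
                sorted(ratios[ca]), sorted(ratios[cb]), reps=reps, seed=seed
            )
    return {"ratios": {c: np.asarray(v) for c, v in ratios.items()},
            "summary": summary, "pairwise_p": pairwise}


def max_expression_tissue(cfpkm: dict, fold: float = 2.0):
    """The tissue of clear maximum expression, or None.

    Returns the argmax tissue only when its value is >= ``fold`` times
    the value in every other tissue (and positive); otherwise None.
    """
    if len(cfpkm) < 2:
        raise ValueError("need >= 2 tissues")
    best = max(cfpkm, key=lambda t: (cfpkm[t], t))
    v = cfpkm[best]
    if v <= 0:
        return None
    if all(v >= fold * val for t, val in cfpkm.items() if t != best):
        return best
    return None


def pseudo_functional_ratio_by_tissue(is_pseudo: dict, max_tissue: dict,
                                      reps: int = 1000, seed: int = 0):
    """Pseudogene:functional ratio of neo-X copies per max-expression
    tissue, with 95% percentile bootstrap confidence intervals.

    ``is_pseudo`` maps gene_id -> bool (neo-X pseudogene status);
    ``max_tissue`` maps gene_id -> tissue or None (None genes excluded).
    A tissue with zero functional genes reports an infinite ratio with
    the CI suppressed.

    Returns ``{tissue: {"ratio", "ci_low", "ci_high", "n_pseudo",
    "n_functional"}}``.
    """
    rng = np.random.default_rng(seed)
    genes_by_tissue: dict[str, list[str]] = {}
    for gid, tissue in max_tissue.items():
        if tissue is None or gid not in is_pseudo:
            continue
        genes_by_tissue.setdefault(tissue, []).append(gid)
    out = {}
    for tissue in sorted(genes_by_tissue):
        gids = genes_by_tissue[tissue]
        flags = np.asarray([bool(is_pseudo[g]) for g in gids])
        n_p = int(flags.sum())
        n_f = int(flags.size - n_p)
        if n_f == 0:
            out[tissue] = {"ratio": float("inf"), "ci_low": None, "ci_high": None,
                           "n_pseudo": n_p, "n_functional": 0}
            continue
        ratio = n_p / n_f
        idx = rng.integers(0, flags.size, size=(reps, flags.size))
        boots = flags[idx]
        bp = boots.sum(axis=1)
        bf = flags.size - bp
        with np.errstate(divide="ignore"):
            boot_ratios = np.where(bf > 0, bp / np.maximum(bf, 1), np.inf)
        # nearest-rank percentiles: no interpolation between inf replicates
        lo, hi = np.percentile(boot_ratios, [2.5, 97.5], method="nearest")
        out[tissue] = {"ratio": float(ratio), "ci_low": float(lo),
                       "ci_high": float(hi), "n_pseudo": n_p, "n_functional": n_f}
    return out
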