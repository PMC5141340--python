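"""End-to-end orchestration: load a bundle, classify, assign events,
run the rate/dN-dS/expression/antagonism analyses, and summarize.

This is the layer the CLI wraps; every step is also usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import antagonism as antag
from . import rates
from .classify import ClassifierConfig, classify_group
from .events import Branch, Category, assign_events, count_events
from .expression import (TissueProfile, compare_fm_by_category,
                         max_expression_tissue,
                         pseudo_functional_ratio_by_tissue)
from .io import (read_antagonism_labels, read_expression_table,
                 read_gene_models, read_ortholog_map)
from .molevol import CodonAlignment, bootstrap_median_test, branch_dnds
from .simulate import read_alignments

logger = logging.getLogger("neopseudo")


@dataclass
class PipelineConfig:
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    calibration: rates.TimeCalibration = field(default_factory=rates.TimeCalibration)
    bootstrap_reps: int = 1000
    seed: int = 0
    fm_tissues: tuple = ("gonad", "abdomen", "abdomen_no_gonad")
    max_tissue_fold: float = 2.0


@dataclass
class Bundle:
    models: dict
    groups: list
    n_excluded_no_dobs: int
    expression: object
    labels: dict
    alignments: dict


def load_bundle(directory) -> Bundle:
    """Read a study bundle (as written by the simulator) from disk."""
    import os

    models = read_gene_models(os.path.join(directory, "annotation.gff3"),
                              os.path.join(directory, "genome.fasta"))
    groups, n_excl = read_ortholog_map(os.path.join(directory, "orthologs.tsv"), models)
    expr = read_expression_table(os.path.join(directory, "expression.tsv"))
    labels_path = os.path.join(directory, "antagonism.tsv")
    labels = read_antagonism_labels(labels_path) if os.path.exists(labels_path) else {}
    aln_path = os.path.join(directory, "alignments.fasta")
    alignments = read_alignments(aln_path) if os.path.exists(aln_path) else {}
    return Bundle(models, groups, n_excl, expr, labels, alignments)


def classify_bundle(bundle: Bundle, cfg: ClassifierConfig):
    """Functionality calls for every slot of every group."""
    return {g.group_id: classify_group(g, bundle.expression, cfg)
            for g in bundle.groups}


def assign_bundle_events(calls_by_group: dict):
    return [assign_events(gid, calls) for gid, calls in calls_by_group.items()]


def rate_comparisons(assignments, cal: rates.TimeCalibration,
                     category_filter=()):
    """Branch event counts, calibrated proportions and chi-square tests.

    The Pse count is prorated into the window comparable to the neo-sex
    branches; X vs Y, X vs prorated-Pse and X vs Anc are compared by the
    1-d.f. equal-expectation goodness of fit.
    """
    counts = count_events(assignments, category_filter)
    n_groups = counts["n_groups_at_risk"]
    n = {b: counts[b]["n_events"] for b in Branch}
    _pre, pse_post = rates.split_lineage_events(n[Branch.PSE], cal)
    out = {
        "n_groups_at_risk": n_groups,
        "counts": {b.value: counts[b] for b in Branch},
        "pse_post_window": pse_post,
        "proportions_pct": {
            b.value: round(rates.branch_proportion(n[b], n_groups), 1)
            for b in (Branch.ANC, Branch.X, Branch.Y, Branch.PSE)
        },
        "pse_post_window_pct": round(rates.branch_proportion(pse_post, n_groups), 1),
        "tests": {},
    }
    for name, (a, b) in {
        "X_vs_Y": (n[Branch.X], n[Branch.Y]),
        "X_vs_Pse_window": (n[Branch.X], pse_post),
        "X_vs_Anc": (n[Branch.X], n[Branch.ANC]),
    }.items():
        if a + b > 0:
            r = rates.gof_two_counts(a, b)
            out["tests"][name] = {"counts": [a, b], "chi2": r.statistic,
                                  "df": r.df, "p": r.p_value}
    return out


def dnds_analysis(bundle: Bundle, assignments, reps: int = 1000, seed: int = 0):
    """Per-branch NG86 estimates per group plus category comparisons.

    For each of branches Anc, X, Y the omega distributions of neo-X (or
    neo-Y) functional vs pseudogenized categories are compared with the
    bootstrap median test.
    """
    cat_by_group = {a.group_id: a.category for a in assignments}
    per_group = {}
    for group_id, seqs in bundle.alignments.items():
        if cat_by_group.get(group_id) is None:
            continue
        aln = CodonAlignment(group_id, seqs)
        est = branch_dnds(aln)
        if est:
            per_group[group_id] = est
    omegas = {b: {c: [] for c in Category} for b in
              (Branch.ANC, Branch.X, Branch.Y)}
    n_undefined = 0
    for gid, est in per_group.items():
        cat = cat_by_group[gid]
        for b in omegas:
            if b in est:
                if est[b].omega is None:
                    n_undefined += 1
                else:
                    omegas[b][cat].append(est[b].omega)
    comparisons = {}
    pools = {
        "X_pseudo_vs_functional": ((Category.XP_YF, Category.XP_YP),
                                   (Category.XF_YF, Category.XF_YP)),
        "Y_pseudo_vs_functional": ((Category.XF_YP, Category.XP_YP),
                                   (Category.XF_YF, Category.XP_YF)),
    }
    for b in omegas:
        for name, (cats_a, cats_b) in pools.items():
            va = [v for c in cats_a for v in omegas[b][c]]
            vb = [v for c in cats_b for v in omegas[b][c]]
            if len(va) >= 2 and len(vb) >= 2:
                p = bootstrap_median_test(va, vb, reps=reps, seed=seed)
                comparisons[f"{b.value}:{name}"] = {
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "n_a": len(va), "n_b": len(vb), "p": p,
                }
    return {"per_group": per_group, "omega_by_branch_category": omegas,
            "n_undefined_omega": n_undefined, "comparisons": comparisons}


def expression_analysis(bundle: Bundle, assignments, cfg: PipelineConfig):
    """F/M ratio comparisons and the max-expression-tissue analysis.

    Both analyses use the *D. pseudoobscura* copy's expression, restricted
    to expressed genes, joined to the group's neo-sex category.
    """
    cat_by_group = {a.group_id: a.category for a in assignments}
    profiles, categories = {}, {}
    dpse_gene_for_group = {}
    for g in bundle.groups:
        dpse = g.member("Dpse")
        if dpse is None or dpse.gene_id not in bundle.expression:
            continue
        if bundle.expression.max_fpkm(dpse.gene_id) < cfg.classifier.fpkm_threshold:
            continue  # analysis set: expressed orthologues
        prof = TissueProfile.from_matrix(dpse.gene_id, bundle.expression)
        profiles[dpse.gene_id] = prof
        categories[dpse.gene_id] = cat_by_group.get(g.group_id, Category.UNASSIGNED)
        dpse_gene_for_group[g.group_id] = dpse.gene_id
    fm = {}
    for tissue in cfg.fm_tissues:
        fm[tissue] = compare_fm_by_category(
            profiles, categories, tissue,
            floor=cfg.classifier.fpkm_threshold,
            reps=cfg.bootstrap_reps, seed=cfg.seed)

    is_pseudo, max_tissue = {}, {}
    for gid, prof in profiles.items():
        cat = categories[gid]
        if cat in (Category.XP_YF, Category.XP_YP):
            is_pseudo[gid] = True
        elif cat in (Category.XF_YF, Category.XF_YP):
            is_pseudo[gid] = False
        else:
            continue
        cfpkm = {t: v for t, v in prof.cfpkm.items() if t != "abdomen_no_gonad"}
        max_tissue[gid] = max_expression_tissue(cfpkm, fold=cfg.max_tissue_fold)
    ratios = pseudo_functional_ratio_by_tissue(
        is_pseudo, max_tissue, reps=cfg.bootstrap_reps, seed=cfg.seed)
    return {"n_expressed": len(profiles), "fm_by_tissue": fm,
            "pseudo_functional_ratio_by_tissue": ratios}


def antagonism_analysis(bundle: Bundle, calls_by_group: dict):
    """Table-1-style contingency analysis keyed by group id."""
    is_pseudo = {}
    for gid, calls in calls_by_group.items():
        flag = calls["neoX"].is_pseudogene
        if flag is not None:
            is_pseudo[gid] = flag
    return antag.antagonism_contingency(is_pseudo, bundle.labels)


def run_all(directory, cfg: PipelineConfig | None = None):
    """Run the whole pipeline on a bundle directory; returns a dict of
    results per stage."""
    cfg = cfg or PipelineConfig()
    bundle = load_bundle(directory)
    calls = classify_bundle(bundle, cfg.classifier)
    assignments = assign_bundle_events(calls)
    results = {
        "bundle": bundle,
        "calls": calls,
        "assignments": assignments,
        "rates": rate_comparisons(assignments, cfg.calibration),
        "rates_no_xpyf": rate_comparisons(assignments, cfg.calibration,
                                          category_filter={Category.XP_YF}),
        "dnds": dnds_analysis(bundle, assignments,
                              reps=cfg.bootstrap_reps, seed=cfg.seed),
        "expression": expression_analysis(bundle, assignments, cfg),
    }
    if bundle.labels:
        try:
            results["antagonism"] = antagonism_analysis(bundle, calls)
        except ValueError as exc:  # e.g. zero marginal in a tiny bundle
            logger.warning("antagonism analysis skipped: %s", exc)
    return results
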