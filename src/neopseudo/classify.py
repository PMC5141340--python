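"""Functionality classification of gene copies within ortholog groups.

Each gene copy is called functional, disrupted, silenced,
silenced-and-disrupted, unclassified, or absent from three predicates:

* E — expressed: FPKM >= threshold (default 1) in at least one sample;
* C — complete ORF: both an initiation and a stop codon present;
* L — relative CDS length: focal CDS length over the mean CDS length of
  the other members of its ortholog group (default threshold 0.8).

Silenced, disrupted and silenced-and-disrupted genes (and deleted ones)
are pseudogenes; the pseudogenization cause is regulatory for silencing,
coding for disruption/truncation, deletion for an absent copy.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .io import ExpressionMatrix, GeneModel, OrthologGroup

logger = logging.getLogger("neopseudo")


class Status(str, enum.Enum):
    FUNCTIONAL = "functional"
    DISRUPTED = "disrupted"
    SILENCED = "silenced"
    SILENCED_AND_DISRUPTED = "silenced_and_disrupted"
    UNCLASSIFIED = "unclassified"
    ABSENT = "absent"


REGULATORY = "regulatory"
CODING = "coding"
DELETION = "deletion"

_CAUSES_FOR_STATUS = {
    Status.FUNCTIONAL: frozenset(),
    Status.DISRUPTED: frozenset({CODING}),
    Status.SILENCED: frozenset({REGULATORY}),
    Status.SILENCED_AND_DISRUPTED: frozenset({REGULATORY, CODING}),
    Status.UNCLASSIFIED: frozenset(),
    Status.ABSENT: frozenset({DELETION}),
}

_PSEUDO_STATUSES = {
    Status.DISRUPTED,
    Status.SILENCED,
    Status.SILENCED_AND_DISRUPTED,
    Status.ABSENT,
}


@dataclass(frozen=True)
class FunctionalityCall:
    """Status plus derived cause set for one gene copy.

    ``is_pseudogene`` is True for silenced/disrupted/silenced-and-
    disrupted/absent, False for functional, and ``None`` for unclassified
    (such calls are excluded from counts).
    """

    status: Status
    rule: str | None = None
    length_ratio: float | None = None
    expressed: bool | None = None

    @property
    def causes(self) -> frozenset:
        return _CAUSES_FOR_STATUS[self.status]

    @property
    def is_pseudogene(self):
        if self.status is Status.UNCLASSIFIED:
            return None
        return self.status in _PSEUDO_STATUSES


@dataclass
class ClassifierConfig:
    """Tunable thresholds of the classifier.

    fpkm_threshold
        Minimum FPKM in at least one sample for a gene to count as
        expressed (default 1.0).
    cds_fraction_threshold
        Minimum CDS length relative to the group reference below which a
        gene is disrupted/truncated (default 0.8).
    rescue_genome_predictions
        Reanalysis mode: genome-predicted genes (no transcript support)
        are rescued by direct FPKM evidence over all samples, so a
        genome-predicted gene expressed at >= threshold is never called
        silenced.  Off by default.
    neox_female_only
        Evaluate neo-X expression from female samples only (neo-X
        transcripts are reconstructed from female reads to keep them
        separate from neo-Y reads).  On by default.
    reference_complete_only
        Compute the reference CDS length from non-focal members with
        complete ORFs when any exist (on, default), or always from all
        present non-focal members (off).
    """

    fpkm_threshold: float = 1.0
    cds_fraction_threshold: float = 0.8
    rescue_genome_predictions: bool = False
    neox_female_only: bool = True
    reference_complete_only: bool = True

    def __post_init__(self):
        if self.fpkm_threshold <= 0:
            raise ValueError("fpkm_threshold must be > 0")
        if not (0 < self.cds_fraction_threshold <= 1):
            raise ValueError("cds_fraction_threshold must be in (0, 1]")


def is_expressed(gene: GeneModel, expr: ExpressionMatrix, cfg: ClassifierConfig) -> bool:
    """True iff the gene reaches the FPKM threshold in >= 1 sample.

    Genome-predicted genes have no transcript support and count as not
    expressed unless rescue mode is on, in which case all samples (both
    sexes) are consulted.  Otherwise, neo-X genes are restricted to
    female samples when ``cfg.neox_female_only`` is set.  A gene absent
    from the matrix is not expressed.
    """
    if gene.annotation_source == "genome_prediction":
        if not cfg.rescue_genome_predictions:
            return False
        sexes = None
    elif gene.lineage_slot == "neoX" and cfg.neox_female_only:
        sexes = ("F",)
    else:
        sexes = None
    return expr.max_fpkm(gene.gene_id, sexes=sexes) >= cfg.fpkm_threshold


def reference_cds_length(group: OrthologGroup, focal_slot: str,
                         complete_only: bool = True) -> float:
    """Mean CDS length of the group's non-focal members.

    Members with complete ORFs (both start and stop codon) are preferred;
    if none exists — or ``complete_only`` is off — the mean is over all
    present non-focal members.  Raises ``ValueError`` when the focal gene
    is the only member (the group is unclassifiable).
    """
    others = [g for slot, g in group.members.items()
              if slot != focal_slot and g is not None]
    if not others:
        raise ValueError(f"group {group.group_id}: no non-focal member for reference length")
    if complete_only:
        complete = [g for g in others if g.is_complete_orf]
        if complete:
            others = complete
    return sum(g.cds_length for g in others) / len(others)


def classify_gene(gene: GeneModel | None, group: OrthologGroup,
                  expr: ExpressionMatrix, cfg: ClassifierConfig) -> FunctionalityCall:
    """Apply the six classification rules to one gene copy.

    Rules (E = expressed, C = complete ORF, L = relative CDS length,
    threshold t = ``cfg.cds_fraction_threshold``):

    1. E,  C, L >= t  -> functional
    2. E,  C, L <  t  -> disrupted
    3. !E,    L >= t  -> silenced
    4. !E,    L <  t  -> silenced_and_disrupted
    5. E, !C, clean flanks     -> disrupted
    6. E, !C, ambiguous flanks -> unclassified

    An absent copy is status absent (cause: deletion).  A zero reference
    length makes L undefined -> unclassified.
    """
    if gene is None:
        return FunctionalityCall(Status.ABSENT, rule="absent")
    ref = reference_cds_length(group, gene.lineage_slot,
                               complete_only=cfg.reference_complete_only)
    if ref <= 0:
        return FunctionalityCall(Status.UNCLASSIFIED, rule="zero_reference")
    L = gene.cds_length / ref
    E = is_expressed(gene, expr, cfg)
    C = gene.is_complete_orf
    t = cfg.cds_fraction_threshold
    if E:
        if C:
            if L >= t:
                return FunctionalityCall(Status.FUNCTIONAL, "rule1", L, E)
            return FunctionalityCall(Status.DISRUPTED, "rule2", L, E)
        if not gene.flank_has_ambiguity:
            return FunctionalityCall(Status.DISRUPTED, "rule5", L, E)
        return FunctionalityCall(Status.UNCLASSIFIED, "rule6", L, E)
    if L >= t:
        return FunctionalityCall(Status.SILENCED, "rule3", L, E)
    return FunctionalityCall(Status.SILENCED_AND_DISRUPTED, "rule4", L, E)


def classify_group(group: OrthologGroup, expr: ExpressionMatrix,
                   cfg: ClassifierConfig) -> dict[str, FunctionalityCall]:
    """Classify every slot of an ortholog group."""
    from .io import SLOTS

    return {slot: classify_gene(group.members.get(slot), group, expr, cfg)
            for slot in SLOTS}
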