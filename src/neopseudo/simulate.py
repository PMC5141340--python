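"""Synthetic study generator.

Produces a complete input bundle — per-gene genome contigs + GFF3
annotation, ortholog-group table, codon alignments, FPKM expression
matrix and sexual-antagonism labels — together with the planted ground
truth, so that every pipeline stage is testable end to end without any
sequencing data.

The generator emulates the structure the analysis assumes: every
ortholog group is functional in the outgroup; pseudogenization events
are planted on the Anc/X/Y/Pse branches with stated causes (silenced,
disrupted, both, or deleted); codon sequences evolve along the species
tree under a per-group omega; the expression matrix carries a male-bias
shift for designated genes (mostly the XP_YF category, the feminization
signal).  Default event probabilities and label frequencies follow the
published study conditions for the 1,282-orthologue Muller-C set.

Planted silenced copies never exceed FPKM 0.9 (safely below the
threshold of 1); planted disrupted copies are truncated to 20-30% of
their original CDS.  Because the classifier's reference length averages
over complete-ORF group members — which includes truncated copies that
retain start and stop codons — the reference can be dragged well below
the full length; 20-30% keeps the truncated/reference ratio strictly
below the 0.8 rule for every reference composition the generator can
produce, which makes planted-event recovery exact in the absence of
sister-branch same-cause homoplasy — and the generator never plants
such homoplasy (independent X and Y events are redrawn until their
cause sets are disjoint, and a Pse cause never overlaps a planted Anc
cause).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CODING, DELETION, REGULATORY
from .events import BOTH, Branch, Category
from .io import SLOTS, GeneModel, write_gene_models
from .molevol import GENETIC_CODE, NUCLEOTIDES

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

_CAUSE_SETS = {
    REGULATORY: frozenset({REGULATORY}),
    CODING: frozenset({CODING}),
    BOTH: frozenset({REGULATORY, CODING}),
    DELETION: frozenset({DELETION}),
}

#: tissues in the expression matrix; ovary is female-only, testis and
#: accessory gland male-only, the rest measured in both sexes
SEX_LIMITED = {"ovary": "F", "testis": "M", "accessory_gland": "M"}
DEFAULT_TISSUES = ("ovary", "testis", "accessory_gland", "head", "thorax",
                   "abdomen", "abdomen_no_gonad", "larva", "pupa")


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults reproduce the study conditions.

    Event probabilities are per-branch marginal probabilities over all
    groups (an Anc event pre-empts X and Y events, so the terminal
    probabilities are rescaled internally to hit the stated marginals).
    ``branch_lengths`` are substitution-proposal intensities per site.
    """

    seed: int
    n_groups: int = 1282
    branch_event_prob: dict = field(default_factory=lambda: {
        "Anc": 0.066, "X": 0.189, "Y": 0.584, "Pse": 0.179})
    cause_mix: dict = field(default_factory=lambda: {
        REGULATORY: 0.45, CODING: 0.35, BOTH: 0.10, DELETION: 0.10})
    omega_by_category: dict = field(default_factory=lambda: {
        Category.XF_YF: 0.10, Category.XF_YP: 0.15,
        Category.XP_YF: 0.35, Category.XP_YP: 0.30})
    branch_lengths: dict = field(default_factory=lambda: {
        "Obs": 0.03, "Stem": 0.01, "Pse": 0.02,
        "Anc": 0.01, "X": 0.01, "Y": 0.01})
    n_codons: int = 200
    tissues: tuple = DEFAULT_TISSUES
    #: lognormal location/scale of the per-group base expression (FPKM)
    expr_log_mean: float = 2.7
    expr_log_sd: float = 1.0
    #: per-sample lognormal noise scale
    sample_log_sd: float = 0.5
    #: male-bias shift: F values multiplied by 1/shift, testis M boosted
    male_bias_shift: float = 6.0
    male_biased_frac_xpyf: float = 0.8
    male_biased_frac_other: float = 0.05
    #: antagonism label frequencies conditional on neo-X functionality
    label_freqs_functional: dict = field(default_factory=lambda: {
        "Fb_Md": 0.031, "Mb_Fd": 0.054, "no_conflict": 0.911, "unclassified": 0.004})
    label_freqs_pseudo: dict = field(default_factory=lambda: {
        "Fb_Md": 0.048, "Mb_Fd": 0.039, "no_conflict": 0.862, "unclassified": 0.051})
    flank_size: int = 150
    minus_strand_prob: float = 0.3

    def validate(self):
        for name, probs in (("branch_event_prob", self.branch_event_prob),
                            ("cause_mix", self.cause_mix)):
            for k, p in probs.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"{name}[{k}] = {p} outside [0, 1]")
        if abs(sum(self.cause_mix.values()) - 1) > 1e-9:
            raise ValueError("cause_mix must sum to 1")
        if self.branch_event_prob.get("Anc", 0) >= 1:
            raise ValueError("Anc event probability must be < 1")
        if self.n_groups < 1 or self.n_codons < 12:
            raise ValueError("need n_groups >= 1 and n_codons >= 12")
        for b in ("Obs", "Stem", "Pse", "Anc", "X", "Y"):
            if self.branch_lengths.get(b, 0) < 0:
                raise ValueError(f"negative branch length for {b}")


@dataclass
class SimulatedBundle:
    """Paths of a written input bundle plus the planted ground truth."""

    directory: str
    truth: pd.DataFrame
    params: SimulationParams

    def path(self, name: str) -> str:
        return os.path.join(self.directory, name)


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------


def _random_cds(n_codons: int, rng) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _evolve_branch(seq: str, length: float, omega: float, rng) -> str:
    """Evolve one branch: Poisson(length * sites) candidate changes, each
    accepted with weight 1 (synonymous) or omega (nonsynonymous); changes
    creating stop codons are rejected.  The initiation and stop codons
    are held fixed so planted functionality is controlled elsewhere."""
    chars = list(seq)
    n = len(chars)
    if n < 9 or length <= 0:
        return seq
    n_attempts = rng.poisson(length * n)
    for _ in range(n_attempts):
        pos = int(rng.integers(3, n - 3))
        old = chars[pos]
        alts = [c for c in NUCLEOTIDES if c != old]
        new = alts[int(rng.integers(0, 3))]
        c0 = pos - pos % 3
        codon_old = "".join(chars[c0 : c0 + 3])
        codon_new = codon_old[: pos - c0] + new + codon_old[pos - c0 + 1 :]
        if GENETIC_CODE[codon_new] == "*":
            continue
        if GENETIC_CODE[codon_new] != GENETIC_CODE[codon_old] and rng.random() >= omega:
            continue
        chars[pos] = new
    return "".join(chars)


def simulate_codon_evolution(ancestor: str, branch_lengths: dict, omega: float,
                             rng_or_seed) -> dict:
    """Evolve an ancestral CDS along ``(Dobs, (Dpse, (neoX, neoY)))``.

    Returns tip and internal sequences: keys root, Dobs, A (Dmir/Dpse
    ancestor), B (neo-X/neo-Y ancestor), Dpse, neoX, neoY.
    """
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    bl = branch_lengths
    out = {"root": ancestor}
    out["Dobs"] = _evolve_branch(ancestor, bl.get("Obs", 0.0), omega, rng)
    out["A"] = _evolve_branch(ancestor, bl.get("Stem", 0.0), omega, rng)
    out["Dpse"] = _evolve_branch(out["A"], bl.get("Pse", 0.0), omega, rng)
    out["B"] = _evolve_branch(out["A"], bl.get("Anc", 0.0), omega, rng)
    out["neoX"] = _evolve_branch(out["B"], bl.get("X", 0.0), omega, rng)
    out["neoY"] = _evolve_branch(out["B"], bl.get("Y", 0.0), omega, rng)
    return out


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------


def _draw_cause(rng, mix: dict, forbidden: frozenset = frozenset()) -> str:
    """Draw a cause whose cause set is disjoint from ``forbidden``."""
    names = [c for c in mix if not (_CAUSE_SETS[c] & forbidden)]
    if not names:
        raise ValueError("no admissible cause left to draw")
    probs = np.array([mix[c] for c in names], dtype=float)
    probs /= probs.sum()
    return str(rng.choice(names, p=probs))


def _plant_events(rng, params: SimulationParams) -> dict:
    """Plant per-branch events for one group.

    Returns ``{branch_name: cause}`` using only Anc/X/Y/Pse, with no
    sister-branch cause overlap and no Anc/Pse cause overlap (so parsimony
    recovers exactly the planted events).
    """
    p = params.branch_event_prob
    events: dict[str, str] = {}
    if rng.random() < p.get("Anc", 0.0):
        events["Anc"] = _draw_cause(rng, params.cause_mix)
    else:
        denom = 1.0 - p.get("Anc", 0.0)
        cx = cy = None
        if rng.random() < p.get("X", 0.0) / denom:
            cx = _draw_cause(rng, params.cause_mix)
            events["X"] = cx
        if rng.random() < p.get("Y", 0.0) / denom:
            forbidden = _CAUSE_SETS[cx] if cx else frozenset()
            cy = _draw_cause(rng, params.cause_mix, forbidden)
            events["Y"] = cy
    if rng.random() < p.get("Pse", 0.0):
        forbidden = _CAUSE_SETS[events["Anc"]] if "Anc" in events else frozenset()
        events["Pse"] = _draw_cause(rng, params.cause_mix, forbidden)
    return events


def _slot_causes(events: dict) -> dict:
    """Planted cause per lineage slot (None = remains functional)."""
    causes = {"Dobs": None, "Dpse": events.get("Pse"),
              "neoX": events.get("X"), "neoY": events.get("Y")}
    if "Anc" in events:
        causes["neoX"] = causes["neoY"] = events["Anc"]
    return causes


def _planted_category(causes: dict) -> Category:
    x = "P" if causes["neoX"] else "F"
    y = "P" if causes["neoY"] else "F"
    return Category[f"X{x}_Y{y}"]


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def simulate_study(params: SimulationParams, outdir) -> SimulatedBundle:
    """Generate and write a complete input bundle with ground truth.

    Files written to ``outdir``: genome.fasta, annotation.gff3,
    orthologs.tsv, expression.tsv, antagonism.tsv, alignments.fasta and
    truth.tsv.  The same seed yields byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    os.makedirs(outdir, exist_ok=True)

    models: dict[str, GeneModel] = {}
    contigs: dict[str, str] = {}
    ortho_rows = []
    expr_rows = []
    label_rows = []
    aln_records = []
    truth_rows = []

    species_for_slot = {"Dobs": "Dobs", "Dpse": "Dpse", "neoX": "Dmir", "neoY": "Dmir"}

    for gi in range(params.n_groups):
        group_id = f"og{gi:05d}"
        events = _plant_events(rng, params)
        causes = _slot_causes(events)
        category = _planted_category(causes)
        omega = params.omega_by_category.get(category, 0.1)

        ancestor = _random_cds(params.n_codons, rng)
        seqs = simulate_codon_evolution(ancestor, params.branch_lengths, omega, rng)
        for slot in SLOTS:
            aln_records.append((f"{group_id}__{slot}", seqs[slot]))

        # shared truncation fraction for an ancestral coding loss
        anc_keep = float(rng.uniform(0.20, 0.30))
        male_biased = bool(
            rng.random() < (params.male_biased_frac_xpyf
                            if category is Category.XP_YF
                            else params.male_biased_frac_other)
        )

        gene_ids = {}
        for slot in SLOTS:
            cause = causes[slot]
            if cause == DELETION:
                gene_ids[slot] = "NA"
                continue
            gid = f"{group_id}_{slot}"
            gene_ids[slot] = gid
            cds = seqs[slot]
            truncated = cause in (CODING, BOTH)
            if truncated:
                keep = anc_keep if "Anc" in events and slot in ("neoX", "neoY") \
                    else float(rng.uniform(0.20, 0.30))
                m = max(1, int(round(keep * params.n_codons)) - 1)
                cds = cds[: 3 * m] + "TAA"
            silenced = cause in (REGULATORY, BOTH)

            # one contig per gene copy: flank + CDS + flank
            flank_up = "".join(rng.choice(list(NUCLEOTIDES), size=params.flank_size))
            flank_dn = "".join(rng.choice(list(NUCLEOTIDES), size=params.flank_size))
            strand = "-" if rng.random() < params.minus_strand_prob else "+"
            seqid = f"ctg_{gid}"
            if strand == "+":
                contig = flank_up + cds + flank_dn
            else:
                from Bio.Seq import Seq
                contig = flank_up + str(Seq(cds).reverse_complement()) + flank_dn
            contigs[seqid] = contig
            start = params.flank_size
            end = start + len(cds)
            models[gid] = GeneModel(
                gene_id=gid, species=species_for_slot[slot], lineage_slot=slot,
                element="C", cds_length=len(cds),
                has_start_codon=True, has_stop_codon=True,
                flank_has_ambiguity=False, annotation_source="transcriptome",
                seqid=seqid, strand=strand, cds_parts=((start, end),),
                cds_seq=cds,
            )

            # expression profile
            base = float(rng.lognormal(params.expr_log_mean, params.expr_log_sd))
            profile = {}
            for tissue in params.tissues:
                for sex in ("F", "M"):
                    if tissue in SEX_LIMITED and SEX_LIMITED[tissue] != sex:
                        continue
                    if slot == "neoY" and sex == "F":
                        continue  # neo-Y copies exist only in males
                    v = base * float(rng.lognormal(0.0, params.sample_log_sd))
                    if male_biased:
                        if sex == "F":
                            v /= params.male_bias_shift
                        elif tissue == "testis":
                            v *= params.male_bias_shift
                    profile[(tissue, sex)] = v
            # rescale so classification is unambiguous
            if slot == "neoX":
                relevant = max(v for (t, s), v in profile.items() if s == "F")
            elif slot == "neoY":
                relevant = max(profile.values())
            else:
                relevant = max(profile.values())
            if silenced:
                scale = (0.9 * float(rng.uniform(0.2, 1.0))) / max(profile.values())
            elif relevant < 1.5:
                scale = (1.5 + float(rng.exponential(10.0))) / relevant
            else:
                scale = 1.0
            for (tissue, sex), v in profile.items():
                expr_rows.append((gid, tissue, sex, _fmt(v * scale)))

        ortho_rows.append((group_id, gene_ids["Dobs"], gene_ids["Dpse"],
                           gene_ids["neoX"], gene_ids["neoY"]))

        freqs = (params.label_freqs_pseudo
                 if category in (Category.XP_YF, Category.XP_YP)
                 else params.label_freqs_functional)
        names = sorted(freqs)
        probs = np.array([freqs[n] for n in names], dtype=float)
        probs /= probs.sum()
        label_rows.append((group_id, str(rng.choice(names, p=probs))))

        truth_rows.append({
            "group_id": group_id,
            "category": category.value,
            "events": ";".join(f"{b}:{c}" for b, c in sorted(events.items())),
            "omega": omega,
            "male_biased": male_biased,
        })

    # ---- write files ------------------------------------------------------
    write_gene_models(models, contigs,
                      os.path.join(outdir, "annotation.gff3"),
                      os.path.join(outdir, "genome.fasta"))
    pd.DataFrame(ortho_rows, columns=["group_id", "dobs_id", "dpse_id",
                                      "neox_id", "neoy_id"]) \
        .to_csv(os.path.join(outdir, "orthologs.tsv"), sep="\t", index=False)
    pd.DataFrame(expr_rows, columns=["gene_id", "tissue", "sex", "fpkm"]) \
        .to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
    pd.DataFrame(label_rows, columns=["gene_id", "label"]) \
        .to_csv(os.path.join(outdir, "antagonism.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "alignments.fasta"), "w") as fh:
        for name, seq in aln_records:
            fh.write(f">{name}\n{seq}\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return SimulatedBundle(str(outdir), truth, params)


def read_alignments(fasta_path):
    """Load the bundle's per-group codon alignments.

    Returns ``{group_id: {slot: seq}}`` from records named
    ``<group>__<slot>``.
    """
    from Bio import SeqIO

    groups: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        group_id, slot = rec.id.rsplit("__", 1)
        groups.setdefault(group_id, {})[slot] = str(rec.seq)
    return groups


def truth_events(truth: pd.DataFrame) -> dict:
    """Planted events per group as ``{group_id: {(Branch, cause), ...}}``."""
    out = {}
    for row in truth.itertuples(index=False):
        ev = set()
        if row.events:
            for item in row.events.split(";"):
                b, c = item.split(":")
                ev.add((Branch(b), c))
        out[row.group_id] = ev
    return out
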