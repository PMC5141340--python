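"""Record types and readers/writers for the pipeline's on-disk formats.

The pipeline consumes per-species gene models (GFF3 + genome FASTA), an
ortholog-group table (TSV linking the *D. obscura*, *D. pseudoobscura*,
neo-X and neo-Y copies of each ancestral gene), and an expression matrix
(TSV of FPKM by gene x tissue x sex).

Coordinates are 1-based inclusive on disk (GFF3) and 0-based half-open
internally; conversion happens only at this I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("neopseudo")

#: the four lineage slots of an ortholog group, in tree order
SLOTS = ("Dobs", "Dpse", "neoX", "neoY")

#: valid species tokens; neo-X/neo-Y copies belong to D. miranda
SPECIES = ("Dobs", "Dpse", "Dmir")

SEXES = ("F", "M")

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: unambiguous nucleotides; anything else in a 100-nt flank sets the
#: flank-ambiguity flag (the field's example is "N", but any IUPAC
#: ambiguity code or gap counts)
_UNAMBIGUOUS = frozenset("ACGT")

FLANK_SIZE = 100


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene copy (a single representative CDS per gene).

    ``cds_parts`` are 0-based half-open intervals on ``seqid`` in genomic
    order; ``strand`` is '+' or '-'.  Codon logic (start/stop presence)
    always operates on the sense strand: minus-strand CDS are
    reverse-complemented before inspection.
    """

    gene_id: str
    species: str
    lineage_slot: str
    element: str
    cds_length: int
    has_start_codon: bool
    has_stop_codon: bool
    flank_has_ambiguity: bool
    annotation_source: str = "transcriptome"
    seqid: str = ""
    strand: str = "+"
    cds_parts: tuple = ()
    frame_ok: bool = True
    cds_seq: str = ""

    def __post_init__(self):
        if self.cds_length < 0:
            raise ValueError(f"{self.gene_id}: negative CDS length")
        if self.lineage_slot in ("neoX", "neoY") and self.species != "Dmir":
            raise ValueError(
                f"{self.gene_id}: slot {self.lineage_slot} implies species Dmir, "
                f"got {self.species}"
            )

    @property
    def is_complete_orf(self) -> bool:
        return self.has_start_codon and self.has_stop_codon


class ExpressionMatrix:
    """FPKM values keyed by (gene_id, tissue, sex).

    The tissue vocabulary is open (ovary, testis, head, abdomen,
    abdomen_no_gonad, ...).  Keys are unique; FPKM is non-negative.
    """

    def __init__(self, entries: dict | None = None):
        self._entries: dict[tuple[str, str, str], float] = {}
        self._by_gene: dict[str, list[tuple[str, str, float]]] = {}
        if entries:
            for (g, t, s), v in entries.items():
                self.add(g, t, s, v)

    def add(self, gene_id: str, tissue: str, sex: str, fpkm: float) -> None:
        if sex not in SEXES:
            raise ValueError(f"unknown sex token {sex!r} for gene {gene_id}")
        if fpkm < 0:
            raise ValueError(f"negative FPKM for ({gene_id}, {tissue}, {sex})")
        key = (gene_id, tissue, sex)
        if key in self._entries:
            raise ValueError(f"duplicate expression entry for {key}")
        self._entries[key] = float(fpkm)
        self._by_gene.setdefault(gene_id, []).append((tissue, sex, float(fpkm)))

    def get(self, gene_id: str, tissue: str, sex: str, default: float = 0.0) -> float:
        return self._entries.get((gene_id, tissue, sex), default)

    def max_fpkm(self, gene_id: str, sexes=None) -> float:
        """Maximum FPKM over the gene's samples, optionally sex-restricted.

        Returns 0.0 for genes absent from the matrix.
        """
        vals = [
            v
            for (t, s, v) in self._by_gene.get(gene_id, ())
            if sexes is None or s in sexes
        ]
        return max(vals, default=0.0)

    def gene_samples(self, gene_id: str) -> list[tuple[str, str, float]]:
        return list(self._by_gene.get(gene_id, ()))

    def tissues(self, gene_id: str) -> list[str]:
        return sorted({t for (t, _s, _v) in self._by_gene.get(gene_id, ())})

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    def items(self):
        return self._entries.items()


@dataclass
class OrthologGroup:
    """Slots for the four lineage copies of one ancestral gene.

    A member is a :class:`GeneModel` or ``None`` (explicitly absent, i.e.
    deleted in that lineage).  The analysis set requires a functional
    *D. obscura* member; groups without one are excluded on ingest.
    """

    group_id: str
    members: dict = field(default_factory=dict)
    element: str = "C"

    def member(self, slot: str):
        return self.members.get(slot)

    def present_slots(self) -> list[str]:
        return [s for s in SLOTS if self.members.get(s) is not None]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _flank_ambiguous(seq: str) -> bool:
    return any(c not in _UNAMBIGUOUS for c in seq.upper())


def read_gene_models(gff3_path, fasta_path) -> dict[str, GeneModel]:
    """Parse gene models from a GFF3 file plus the genome FASTA.

    One :class:`GeneModel` per mRNA.  Start/stop presence is determined
    from the spliced CDS sequence on the sense strand against the standard
    genetic code; the flank-ambiguity flag is set when any non-ACGT base
    occurs within 100 nt up- or downstream of the CDS span.

    mRNA features missing CDS children are skipped with a warning.
    Coordinates outside the parent sequence raise ``ValueError``.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    n_skipped = 0
    for mrna in db.features_of_type("mRNA"):
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            logger.warning("mRNA %s has no CDS feature; skipped", mrna.id)
            n_skipped += 1
            continue
        seqid = mrna.seqid
        if seqid not in contigs:
            raise ValueError(f"mRNA {mrna.id}: sequence {seqid!r} not in FASTA")
        contig = contigs[seqid]
        parts = tuple(sorted((f.start - 1, f.end) for f in cds_feats))
        for start, end in parts:
            if start < 0 or end > len(contig) or start >= end:
                raise ValueError(
                    f"mRNA {mrna.id}: CDS interval [{start}, {end}) outside "
                    f"sequence {seqid} (length {len(contig)})"
                )
        cds = "".join(contig[s:e] for s, e in parts)
        strand = mrna.strand if mrna.strand in "+-" else "+"
        if strand == "-":
            cds = _revcomp(cds)
        span_lo, span_hi = parts[0][0], parts[-1][1]
        up = contig[max(0, span_lo - FLANK_SIZE) : span_lo]
        down = contig[span_hi : span_hi + FLANK_SIZE]
        flank_amb = _flank_ambiguous(up) or _flank_ambiguous(down)

        attrs = mrna.attributes
        def _attr(key, default):
            vals = attrs.get(key, [])
            return vals[0] if vals else default

        slot = _attr("slot", "Dobs")
        species = _attr("species", "Dmir" if slot in ("neoX", "neoY") else slot)
        has_start = len(cds) >= 3 and cds[:3] == START_CODON
        has_stop = len(cds) >= 3 and cds[-3:] in STOP_CODONS
        frame_ok = True
        if cds and has_start and has_stop and len(cds) % 3 != 0:
            logger.warning("gene %s: complete ORF with length %d not a multiple of 3",
                           mrna.id, len(cds))
            frame_ok = False
        gm = GeneModel(
            gene_id=mrna.id,
            species=species,
            lineage_slot=slot,
            element=_attr("element", "C"),
            cds_length=len(cds),
            has_start_codon=has_start,
            has_stop_codon=has_stop,
            flank_has_ambiguity=flank_amb,
            annotation_source=_attr("source_type", "transcriptome"),
            seqid=seqid,
            strand=strand,
            cds_parts=parts,
            frame_ok=frame_ok,
            cds_seq=cds,
        )
        if gm.gene_id in models:
            raise ValueError(f"duplicate gene id {gm.gene_id}")
        models[gm.gene_id] = gm
    logger.info("read %d gene models (%d mRNAs skipped)", len(models), n_skipped)
    return models


def write_gene_models(models, contigs: dict[str, str], gff3_path, fasta_path) -> None:
    """Write gene models back to GFF3 (+ genome FASTA).

    Inverse of :func:`read_gene_models`: re-reading the written files
    yields identical GeneModel fields.
    """
    with open(fasta_path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in sorted(models.values() if isinstance(models, dict) else models,
                         key=lambda g: (g.seqid, g.gene_id)):
            lo = gm.cds_parts[0][0] + 1
            hi = gm.cds_parts[-1][1]
            gene_id = f"{gm.gene_id}.gene"
            fh.write(
                f"{gm.seqid}\tneopseudo\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
                f"ID={gene_id}\n"
            )
            fh.write(
                f"{gm.seqid}\tneopseudo\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
                f"ID={gm.gene_id};Parent={gene_id};species={gm.species};"
                f"slot={gm.lineage_slot};element={gm.element};"
                f"source_type={gm.annotation_source}\n"
            )
            for i, (s, e) in enumerate(gm.cds_parts):
                fh.write(
                    f"{gm.seqid}\tneopseudo\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t0\t"
                    f"ID={gm.gene_id}.cds{i};Parent={gm.gene_id}\n"
                )


def read_expression_table(tsv_path) -> ExpressionMatrix:
    """Read a TSV with header ``gene_id  tissue  sex  fpkm``.

    Duplicate (gene, tissue, sex) keys, negative FPKM, or unknown sex
    tokens raise ``ValueError``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str, "tissue": str, "sex": str})
    required = ["gene_id", "tissue", "sex", "fpkm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    mat = ExpressionMatrix()
    for row in df.itertuples(index=False):
        mat.add(row.gene_id, row.tissue, row.sex, row.fpkm)
    logger.info("read %d expression entries for %d genes", len(mat), len(mat.genes))
    return mat


def read_ortholog_map(tsv_path, gene_models: dict[str, GeneModel]):
    """Read the ortholog-group table and resolve member gene ids.

    Columns: ``group_id dobs_id dpse_id neox_id neoy_id``; the literal
    token ``NA`` marks an absent (deleted) member.  Groups without a
    *D. obscura* member are excluded from the analysis set and counted.

    Returns ``(groups, n_excluded_no_dobs)``.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["group_id", "dobs_id", "dpse_id", "neox_id", "neoy_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns: {missing}")
    col_for_slot = {"Dobs": "dobs_id", "Dpse": "dpse_id", "neoX": "neox_id", "neoY": "neoy_id"}
    groups: list[OrthologGroup] = []
    n_excluded = 0
    for row in df.itertuples(index=False):
        members = {}
        for slot, col in col_for_slot.items():
            gid = getattr(row, col)
            if gid == "NA" or gid == "":
                members[slot] = None
            else:
                if gid not in gene_models:
                    raise ValueError(
                        f"group {row.group_id}: gene id {gid!r} not found among gene models"
                    )
                members[slot] = gene_models[gid]
        if members["Dobs"] is None:
            n_excluded += 1
            continue
        element = members["Dobs"].element
        groups.append(OrthologGroup(group_id=row.group_id, members=members, element=element))
    logger.info("read %d ortholog groups (%d excluded: no Dobs member)", len(groups), n_excluded)
    return groups, n_excluded


def read_antagonism_labels(tsv_path) -> dict[str, str]:
    """Read a sexual-antagonism label table (columns ``gene_id  label``)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "label" not in df.columns:
        raise ValueError("label table must have columns gene_id, label")
    valid = {"Fb_Md", "Mb_Fd", "no_conflict", "unclassified"}
    labels = {}
    for row in df.itertuples(index=False):
        if row.label not in valid:
            raise ValueError(f"unknown antagonism label {row.label!r} for {row.gene_id}")
        if row.gene_id in labels:
            raise ValueError(f"duplicate label for gene {row.gene_id}")
        labels[row.gene_id] = row.label
    return labels
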