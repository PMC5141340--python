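"""Branch-specific dN/dS on the 4-taxon tree via NG86 counting.

Synonymous and nonsynonymous sites/differences are counted with the
Nei–Gojobori (1986) method: per codon, each position contributes the
fraction of its three single-nucleotide mutants that are synonymous
under the standard genetic code (mutations to stop codons count as
nonsynonymous); differences between codon pairs are averaged over all
minimal substitution pathways, excluding pathways through stop codons.
Proportions are corrected with the Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``; omega = dN/dS is undefined when dS = 0 or a
proportion is saturated (p >= 3/4).

Per-branch estimates on the topology ``(Dobs, (Dpse, (neoX, neoY)))``
use nucleotide-level Fitch parsimony to reconstruct the two internal
nodes (A = Dmir/Dpse ancestor, B = neo-X/neo-Y ancestor), then compare
A vs B (branch Anc), B vs neo-X (branch X) and B vs neo-Y (branch Y).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .events import Branch

logger = logging.getLogger("neopseudo")

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
#: codon -> amino acid, with '*' for the three stop codons
GENETIC_CODE = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

NUCLEOTIDES = "ACGT"


def _is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(c in NUCLEOTIDES for c in codon)


@dataclass(frozen=True)
class DnDsEstimate:
    """NG86 site/difference counts and corrected distances for one
    sequence pair (or branch).  ``omega`` is None when undefined."""

    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    dn: float | None
    ds: float | None
    omega: float | None
    n_codons: int = 0


@dataclass
class CodonAlignment:
    """Aligned CDS for the four lineage slots of one ortholog group.

    All sequences equal length, divisible by 3; the gap character ``-``
    is allowed in whole-codon units.  Missing members may be omitted.
    """

    group_id: str
    seqs: dict  # slot -> str

    def __post_init__(self):
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.group_id}: unequal sequence lengths {lengths}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError(f"{self.group_id}: alignment length not a multiple of 3")
        self.seqs = {k: v.upper() for k, v in self.seqs.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0


@lru_cache(maxsize=None)
def codon_site_counts(codon: str):
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    mutants that preserve the amino acid; mutants that create stop codons
    are nonsynonymous.  n + s = 3 always.
    """
    codon = codon.upper()
    if not _is_valid_codon(codon) or GENETIC_CODE[codon] == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = sum(
            1
            for nt in NUCLEOTIDES
            if nt != codon[pos]
            and GENETIC_CODE[codon[:pos] + nt + codon[pos + 1 :]] == aa
        )
        s += syn / 3.0
    return 3.0 - s, s


def codon_pair_diffs(c1: str, c2: str):
    """(nonsynonymous, synonymous) differences between two sense codons,
    averaged over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used with a warning.  n + s equals the number
    of differing positions.
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if not _is_valid_codon(c) or GENETIC_CODE[c] == "*":
            raise ValueError(f"cannot compare codon {c!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        """(n, s, hits_stop) along one substitution ordering."""
        cur = c1
        n = s = 0.0
        stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        return n, s, stop

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    usable = [(n, s) for n, s, stop in paths if not stop]
    if not usable:
        logger.warning("all substitution pathways %s -> %s pass through stops; "
                       "including them", c1, c2)
        usable = [(n, s) for n, s, _ in paths]
    n = sum(p[0] for p in usable) / len(usable)
    s = sum(p[1] for p in usable) / len(usable)
    return n, s


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None  # saturated
    return -0.75 * math.log(1 - 4.0 * p / 3.0) + 0.0


def ng86(seq_a: str, seq_b: str) -> DnDsEstimate:
    """NG86 estimate for one aligned CDS pair.

    Codons containing gaps, ambiguities or stops (in either sequence)
    are excluded.  Site counts are averaged between the two sequences.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("sequences must be aligned with length a multiple of 3")
    N = S = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_is_valid_codon(ca) and _is_valid_codon(cb)):
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        na, sa = codon_site_counts(ca)
        nb, sb = codon_site_counts(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = codon_pair_diffs(ca, cb)
        Nd += nd
        Sd += sd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons in alignment")
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    omega = None
    if dn is not None and ds is not None and ds > 0:
        omega = dn / ds
    return DnDsEstimate(N, S, Nd, Sd, dn, ds, omega, n_codons)


# ---------------------------------------------------------------------------
# ancestral reconstruction and per-branch estimates
# ---------------------------------------------------------------------------


def fitch_ancestral(aln: CodonAlignment):
    """Fitch-parsimony nucleotide sequences at the two internal nodes.

    Bottom-up state sets on ``((neoX, neoY)B, Dpse)A`` with Dobs as the
    outgroup; top-down final states prefer the parent's state, with the
    A node preferring the outgroup state, and remaining ties broken
    alphabetically.  Columns with a gap or ambiguity in any member
    propagate a gap to both ancestors.

    Returns ``(seq_A, seq_B)``.
    """
    required = ("Dobs", "Dpse", "neoX", "neoY")
    missing = [s for s in required if s not in aln.seqs]
    if missing:
        raise ValueError(f"{aln.group_id}: cannot reconstruct without {missing}")
    obs, pse, nx, ny = (aln.seqs[s] for s in required)
    a_chars, b_chars = [], []
    for o, p, x, y in zip(obs, pse, nx, ny):
        if any(c not in NUCLEOTIDES for c in (o, p, x, y)):
            a_chars.append("-")
            b_chars.append("-")
            continue
        b_set = {x} & {y} or {x} | {y}
        a_set = b_set & {p} or b_set | {p}
        a = o if o in a_set else min(a_set)
        b = a if a in b_set else min(b_set)
        a_chars.append(a)
        b_chars.append(b)
    return "".join(a_chars), "".join(b_chars)


def fitch_change_count(aln: CodonAlignment) -> int:
    """Minimum number of nucleotide changes implied by the alignment
    (bottom-up Fitch union count, rooted at the outgroup edge)."""
    obs, pse, nx, ny = (aln.seqs[s] for s in ("Dobs", "Dpse", "neoX", "neoY"))
    changes = 0
    for o, p, x, y in zip(obs, pse, nx, ny):
        if any(c not in NUCLEOTIDES for c in (o, p, x, y)):
            continue
        b_set = {x} & {y}
        if not b_set:
            b_set = {x} | {y}
            changes += 1
        a_set = b_set & {p}
        if not a_set:
            a_set = b_set | {p}
            changes += 1
        if o not in a_set:
            changes += 1
    return changes


def branch_dnds(aln: CodonAlignment) -> dict:
    """NG86 estimates for branches Anc, X and Y of one group.

    Anc compares the two reconstructed ancestors; X and Y compare the
    neo-X/neo-Y tips against their reconstructed common ancestor.  A
    missing tip makes reconstruction impossible: affected branches are
    skipped (empty mapping).
    """
    try:
        seq_a, seq_b = fitch_ancestral(aln)
    except ValueError:
        return {}
    return {
        Branch.ANC: ng86(seq_a, seq_b),
        Branch.X: ng86(seq_b, aln.seqs["neoX"]),
        Branch.Y: ng86(seq_b, aln.seqs["neoY"]),
    }


def bootstrap_median_test(values_a, values_b, reps: int = 1000, seed: int = 0) -> float:
    """Two-sided bootstrap test for a difference in medians.

    Resamples each group with replacement ``reps`` times and takes
    ``p = 2 * min(P(diff <= 0), P(diff >= 0))`` over the bootstrap
    distribution of median(A*) - median(B*), clamped to [1/reps, 1].
    None values (undefined omegas) are excluded.
    """
    a = np.asarray([v for v in values_a if v is not None], dtype=float)
    b = np.asarray([v for v in values_b if v is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if reps < 100:
        warnings.warn(f"only {reps} bootstrap replicates; p-value resolution is poor")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(reps, a.size))
    idx_b = rng.integers(0, b.size, size=(reps, b.size))
    diffs = np.median(a[idx_a], axis=1) - np.median(b[idx_b], axis=1)
    p = 2.0 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return float(min(1.0, max(1.0 / reps, p)))
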