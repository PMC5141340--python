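"""NG86 counting against brute-force enumeration oracles, Fitch
reconstruction, per-branch estimates, and the bootstrap median test."""

import itertools
import math

import numpy as np
import pytest

from neopseudo.molevol import (GENETIC_CODE, NUCLEOTIDES, CodonAlignment,
                               bootstrap_median_test, branch_dnds,
                               codon_pair_diffs, codon_site_counts,
                               fitch_ancestral, fitch_change_count, ng86)
from neopseudo.events import Branch
from neopseudo.simulate import simulate_codon_evolution, _random_cds

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_site_counts(codon):
    """Enumerate all 9 single-site mutants against the genetic code."""
    s = 0.0
    for pos, frac in itertools.product(range(3), [1.0]):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


def oracle_pair_diffs(c1, c2):
    """Average syn/nonsyn steps over all orderings of the differing
    positions, skipping orderings that visit a stop codon."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, n, s, hit_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                hit_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        results.append((n, s, hit_stop))
    ok = [(n, s) for n, s, stop in results if not stop] or \
         [(n, s) for n, s, _ in results]
    return (sum(n for n, _ in ok) / len(ok), sum(s for _, s in ok) / len(ok))


class TestSiteCounts:
    def test_phe_codon(self):
        # TTT: only the third-position TTT->TTC change is synonymous
        n, s = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(3 - 1 / 3)

    def test_leu_codon(self):
        # TTA: TTA->TTG and TTA->CTA are synonymous
        n, s = codon_site_counts("TTA")
        assert s == pytest.approx(2 / 3)

    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert codon_site_counts(codon) == pytest.approx(
                oracle_site_counts(codon))

    def test_site_conservation(self):
        for codon in SENSE_CODONS:
            n, s = codon_site_counts(codon)
            assert n + s == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")


class TestPairDiffs:
    def test_phe_to_leu_single_change(self):
        assert codon_pair_diffs("TTT", "TTA") == (1.0, 0.0)

    def test_identical_codons(self):
        assert codon_pair_diffs("AAA", "AAA") == (0.0, 0.0)

    def test_random_pairs_match_pathway_enumeration(self):
        rng = np.random.default_rng(11)
        pairs = rng.choice(len(SENSE_CODONS), size=(100, 2))
        for i, j in pairs:
            c1, c2 = SENSE_CODONS[i], SENSE_CODONS[j]
            got = codon_pair_diffs(c1, c2)
            want = oracle_pair_diffs(c1, c2)
            assert got == pytest.approx(want), (c1, c2)

    def test_difference_conservation(self):
        rng = np.random.default_rng(12)
        for i, j in rng.choice(len(SENSE_CODONS), size=(50, 2)):
            c1, c2 = SENSE_CODONS[i], SENSE_CODONS[j]
            k = sum(a != b for a, b in zip(c1, c2))
            nd, sd = codon_pair_diffs(c1, c2)
            assert nd + sd == pytest.approx(k)


class TestNg86:
    def test_identical_sequences(self):
        est = ng86("ATGAAA", "ATGAAA")
        assert est.dn == 0 and est.ds == 0 and est.omega is None

    def test_single_codon_hand_computation(self):
        est = ng86("TTT", "TTA")
        assert est.n_sites == pytest.approx(2.5)
        assert est.s_sites == pytest.approx(0.5)
        assert est.dn == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert est.ds == 0 and est.omega is None

    def test_symmetry(self):
        a = _random_cds(40, np.random.default_rng(3))
        b = simulate_codon_evolution(a, {"X": 0.1}, 0.5, 4)["neoX"]
        assert ng86(a, b) == ng86(b, a)

    def test_site_sum_is_three_per_codon(self):
        a, b = "ATGAAACCC", "ATGAAGCCA"
        est = ng86(a, b)
        assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)

    def test_gap_codons_excluded(self):
        est = ng86("ATG---AAA", "ATGCCCAAA")
        assert est.n_codons == 2

    def test_neutral_simulation_recovers_omega_one(self):
        rng = np.random.default_rng(99)
        anc = _random_cds(2000, rng)
        tips = simulate_codon_evolution(anc, {"X": 0.08}, 1.0, rng)
        est = ng86(anc, tips["neoX"])
        assert est.omega == pytest.approx(1.0, abs=0.25)


class TestFitch:
    def _aln(self, obs, pse, x, y):
        return CodonAlignment("g", {"Dobs": obs, "Dpse": pse,
                                    "neoX": x, "neoY": y})

    def test_change_on_ancestral_branch(self):
        # neo-X/neo-Y share A while Dpse and the outgroup carry G
        a, b = fitch_ancestral(self._aln("GGG", "GGG", "AGG", "AGG"))
        assert a == "GGG" and b == "AGG"

    def test_invariant_column(self):
        a, b = fitch_ancestral(self._aln("ACG", "ACG", "ACG", "ACG"))
        assert a == b == "ACG"

    def test_change_on_terminal_branch(self):
        a, b = fitch_ancestral(self._aln("AAA", "AAA", "AAA", "GAA"))
        assert a == "AAA" and b == "AAA"

    def test_gap_column_propagates(self):
        a, b = fitch_ancestral(self._aln("---", "---", "---", "---"))
        assert a == b == "---"

    def test_total_changes_equal_bottom_up_minimum(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            anc = _random_cds(20, rng)
            tips = simulate_codon_evolution(
                anc, {"Obs": 0.1, "Stem": 0.05, "Pse": 0.1,
                      "Anc": 0.05, "X": 0.1, "Y": 0.1}, 0.6, rng)
            aln = self._aln(tips["Dobs"], tips["Dpse"], tips["neoX"],
                            tips["neoY"])
            a, b = fitch_ancestral(aln)
            implied = sum(
                sum(c1 != c2 for c1, c2 in zip(s1, s2))
                for s1, s2 in [(a, b), (b, aln.seqs["neoX"]),
                               (b, aln.seqs["neoY"]), (a, aln.seqs["Dpse"]),
                               (a, aln.seqs["Dobs"])])
            assert implied == fitch_change_count(aln)

    def test_agrees_with_exhaustive_minimum_change(self):
        """Per-column change count equals brute-force minimum over all
        internal labellings of the 4-taxon tree."""
        for o, p, x, y in itertools.product("AG", repeat=4):
            aln = self._aln(o * 3, p * 3, x * 3, y * 3)
            best = min(
                (a != b) + (b != x) + (b != y) + (a != p) + (a != o)
                for a, b in itertools.product(NUCLEOTIDES, repeat=2))
            assert fitch_change_count(aln) == 3 * best


class TestBranchDnds:
    def test_divergent_neox_loads_x_branch(self):
        aln = CodonAlignment("g", {
            "Dobs": "ATGAAACCC", "Dpse": "ATGAAACCC",
            "neoX": "ATGACACCA", "neoY": "ATGAAACCC"})
        est = branch_dnds(aln)
        assert est[Branch.ANC].dn == 0 and est[Branch.ANC].ds == 0
        assert est[Branch.Y].dn == 0 and est[Branch.Y].ds == 0
        assert est[Branch.X].n_diffs + est[Branch.X].s_diffs == 2

    def test_identical_alignment_all_zero(self):
        aln = CodonAlignment("g", {s: "ATGAAATTT" for s in
                                   ("Dobs", "Dpse", "neoX", "neoY")})
        for est in branch_dnds(aln).values():
            assert est.dn == 0 and est.ds == 0

    def test_missing_tip_skips_branches(self):
        aln = CodonAlignment("g", {"Dobs": "ATG", "Dpse": "ATG", "neoX": "ATG"})
        assert branch_dnds(aln) == {}

    def test_planted_omega_recovered_within_tolerance(self):
        """Median branch omega within +-0.1 of the planted value."""
        rng = np.random.default_rng(7)
        lengths = {"Obs": 0.05, "Stem": 0.02, "Pse": 0.05,
                   "Anc": 0.05, "X": 0.05, "Y": 0.05}
        omegas = {b: [] for b in (Branch.ANC, Branch.X, Branch.Y)}
        for _ in range(200):
            anc = _random_cds(300, rng)
            tips = simulate_codon_evolution(anc, lengths, 0.2, rng)
            aln = CodonAlignment("g", {k: tips[k] for k in
                                       ("Dobs", "Dpse", "neoX", "neoY")})
            for b, est in branch_dnds(aln).items():
                if est.omega is not None:
                    omegas[b].append(est.omega)
        for b, vals in omegas.items():
            assert np.median(vals) == pytest.approx(0.2, abs=0.1), b


class TestBootstrapMedianTest:
    def test_identical_samples_not_significant(self):
        vals = list(np.random.default_rng(1).normal(size=60))
        assert bootstrap_median_test(vals, vals, reps=500, seed=2) > 0.5

    def test_extreme_separation_hits_floor(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        assert bootstrap_median_test(a, b, reps=1000, seed=4) == 1 / 1000

    def test_none_values_excluded(self):
        a = [1.0, None, 2.0, 3.0]
        b = [1.5, 2.5, None]
        assert 0 < bootstrap_median_test(a, b, reps=200, seed=5) <= 1

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            bootstrap_median_test([], [1.0], seed=1)

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_median_test([1.0, 2.0], [1.0, 2.0], reps=50, seed=1)


def test_alignment_validation():
    with pytest.raises(ValueError, match="unequal"):
        CodonAlignment("g", {"Dobs": "ATGAAA", "Dpse": "ATG"})
    with pytest.raises(ValueError, match="multiple of 3"):
        CodonAlignment("g", {"Dobs": "ATGA", "Dpse": "ATGA"})
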