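# Methods

This note documents the models and procedures implemented in
`neopseudo`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Analysis set and tree

The unit of analysis is the ortholog group: the four copies of one
ancestral gene in *D. obscura* (outgroup), *D. pseudoobscura*, and the
*D. miranda* neo-X and neo-Y, on the fixed topology
`(Dobs, (Dpse, (neoX, neoY)))`. The analysis set contains only groups
whose outgroup copy is functional, so every gene can be assumed
functional in the common ancestor; groups without an outgroup member
are excluded on ingest and counted. Ortholog calling itself is out of
scope — the group table is an input.

Coordinates are GFF3 1-based inclusive on disk and 0-based half-open
internally, converted only at the I/O boundary. All codon logic runs on
the sense strand; minus-strand CDS are reverse-complemented on read.
"Ambiguous" means any character outside A/C/G/T (case-insensitive) — a
superset of the canonical N.

## Functionality classification

Three predicates per gene copy:

* **E (expressed)** — FPKM ≥ `fpkm_threshold` (default 1.0) in at
  least one (tissue, sex) sample. Neo-X expression is evaluated from
  female samples only by default (`neox_female_only`), because neo-X
  transcripts can only be cleanly separated from neo-Y reads in
  females. Genes absent from the matrix are not expressed.
* **C (complete ORF)** — initiation codon ATG and a stop codon present
  at the ends of the spliced CDS.
* **L (relative length)** — CDS length over the mean CDS length of the
  *other* group members. Members with complete ORFs are preferred for
  the reference (configurable: `reference_complete_only`); a truncated
  member would otherwise drag the reference down and mask disruptions.
  A zero reference makes L undefined → unclassified.

The six rules (threshold `cds_fraction_threshold`, default 0.8, the
boundary inclusive):
E∧C∧L≥0.8 → functional; E∧C∧L<0.8 → disrupted; ¬E∧L≥0.8 → silenced;
¬E∧L<0.8 → silenced-and-disrupted; E∧¬C with clean 100-nt flanks →
disrupted; E∧¬C with ambiguous flanks → unclassified (the missing
codon may be an assembly artifact). Non-expressed copies are length-
ruled regardless of codon completeness — a deliberate literal reading
of the rule set. An absent copy is status absent, cause deletion.

**Rescue mode** (`rescue_genome_predictions`) models the reanalysis in
which genes annotated purely from the genome sequence (no transcript
support) are rescued by direct FPKM evidence. In the default mode such
genes count as not expressed; with rescue on, their expression is read
from the matrix over *all* samples (both sexes — the point of the
reanalysis is catching male-limited neo-X genes), and the full C/L
rules then apply. By construction rescue can only move calls out of
{silenced, silenced-and-disrupted}, never into them.

## Parsimony event assignment

A pseudogenization event is a functional → pseudogene transition on a
branch of the tree (branches *Anc*, *X*, *Y*, *Pse*; plus *Stem*, the
branch subtending the ingroup ancestor). Causes: regulatory
(silencing), coding (disruption/truncation), both, deletion.

The assignment minimizes the number of independent losses under the
constraint that causes are never lost along a branch (no reversal):

* neo-X and neo-Y both pseudogenized with intersecting cause sets →
  one shared event on *Anc*; disjoint cause sets → two independent
  terminal events. A silenced-and-disrupted copy carries both causes,
  so it shares an *Anc* event with a silenced (or disrupted) sister.
* all three ingroup tips pseudogenized with one common cause → a
  single *Stem* event. Stem events are reported separately and excluded
  from the four focal branches, since folding them into *Pse* or *Anc*
  would bias rates.
* deletion is its own cause: it can be shared between the two neo-sex
  copies (one ancestral deletion) but never "shares" with silencing or
  disruption, which are mechanistically independent mutations.
* a group with an unclassified neo-X or neo-Y contributes no X/Y/Anc
  events (it still may contribute a *Pse* event).

The test suite checks this procedure against an exhaustive
minimum-change labelling of the 4-taxon tree over all 64 three-tip
state combinations, with ties broken toward deeper (shared) events.

Event counts use all groups in the analysis set as the at-risk
denominator for every branch (config-exposed category filters support
recounts, e.g. dropping X_P-Y_F groups for the feminization recount).

## Time calibration and χ² tests

Defaults: divergence 2.0 Mya, neo-sex emergence 1.0 Mya (alternative
1.5). Assuming a constant rate on the *Pse* lineage, its event count is
prorated linearly: the window comparable to the neo-sex branches gets
`count × emergence / divergence` events; fractional counts are kept —
no rounding, since the proration itself produces halves.

Two-count comparisons use the 1-d.f. equal-expectation goodness of fit
χ² = (a−ē)²/ē + (b−ē)²/ē with ē=(a+b)/2 — this is the form that
reproduces the published statistics from the published counts; a 2×2
test of proportions does not. Contingency analyses use the Pearson χ²
with expected counts from the marginals and *no* continuity correction
(a Yates-corrected core gives a visibly different statistic).
Upper-tail p-values come from the χ² survival function.

## Branch dN/dS (NG86)

Nei–Gojobori (1986) counting: per codon, each position contributes the
fraction of its three single-nucleotide mutants that are synonymous
under the standard genetic code (mutants creating stops count as
nonsynonymous); differences between codon pairs are averaged over all
minimal substitution pathways (1, 2, or 6 orderings), excluding
pathways through stop codons (if all pass through stops they are
included with a warning). Site counts are averaged between the two
sequences; codons containing gaps, ambiguities or stops are excluded.
Proportions are corrected with Jukes–Cantor, d = −(3/4)·ln(1−4p/3);
ω = dN/dS is undefined when dS = 0 or a proportion saturates (p ≥ 3/4).
Undefined ω are excluded from medians and reported as counts — box
plots cannot hold infinities and any imputation would be arbitrary.
This deliberately simple estimator (equal pathway weights, no
transition/transversion bias, no rate variation) is fully specifiable
and reproducible; the scientific claims tested with it are ordinal
(category A above category B), which is robust to estimator choice.

Per-branch estimates need the two internal nodes. They are
reconstructed by nucleotide-level Fitch parsimony: bottom-up state
sets, then top-down final states preferring the parent state, with the
ingroup-root choice preferring the outgroup state and remaining ties
broken alphabetically (deterministic). Columns with a gap or ambiguity
in any member propagate a gap to both ancestors and drop out of the
counts. Branch *Anc* compares the two reconstructed nodes; *X* and *Y*
compare each neo-sex tip with its reconstructed ancestor.

The bootstrap median test resamples each group with replacement
(default 1,000 replicates) and takes
p = 2·min(P(Δmedian ≤ 0), P(Δmedian ≥ 0)), clamped to [1/reps, 1]. The
seed is an explicit, logged parameter everywhere randomness occurs.

## Expression analyses

F/M ratios are computed per tissue as F/M (pseudocount configurable,
default 0), with the "gonad" label pairing ovary (F) with testis (M);
genes with max(F, M) below the expression floor (default 1 FPKM) are
excluded rather than padded — a pseudocount would fabricate ratios for
silent genes. The analysis set is the expressed *D. pseudoobscura*
orthologs, grouped by their neo-sex category. Gonadless abdomen is a
first-class tissue label. Before bootstrapping, per-category ratio
lists are sorted so results are invariant to gene input order at a
fixed seed.

cFPKM defaults to raw FPKM (per tissue, mean over measured sexes); a
per-tissue normalizer (upper-quartile scaling provided) can be plugged
in. The max-expression-tissue rule — argmax tissue if its value is at
least two-fold every other tissue's, else unassigned — is
scale-invariant within tissues, so the default does not change the
analysis logic. Per-tissue pseudogene:functional ratios get 95%
percentile bootstrap CIs (nearest-rank, so infinite replicates from
zero-functional resamples do not interpolate); a tissue with zero
functional genes reports an infinite ratio with the CI suppressed.

## Sexual antagonism

Labels (Fb/Md, Mb/Fd, no-conflict, unclassified) are an external input
transferred by homology; deriving them is out of scope. The emitted
table is 2 (functional/pseudo) × 4 (label); the χ² is computed on the
2×2 antagonistic core only — no-conflict and unclassified genes appear
in the table but not in the test.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes: outgroup-
functional groups; per-branch events with marginal probabilities
(defaults Anc 0.066, X 0.189, Y 0.584, Pse 0.179, matching the study's
per-branch proportions over the 1,282-group analysis set; an Anc event
pre-empts terminal events, so terminal draws are rescaled to hit the
stated marginals); a cause mix over regulatory/coding/both/deletion
(default 0.45/0.35/0.10/0.10); codon evolution along the tree with a
per-group ω set by category (defaults 0.10/0.15/0.35/0.30 for
X_F‑Y_F / X_F‑Y_P / X_P‑Y_F / X_P‑Y_P — pseudogenizing categories
under weaker constraint); lognormal expression with a male-bias shift
planted in 80% of X_P‑Y_F groups (feminization signal, shift 6-fold,
with a testis boost); antagonism label frequencies conditional on
neo-X functionality, matching the published marginal rates; 1,282
groups of 200 codons by default.

Planted causes are realized so the classifier must recover them:
silenced copies are rescaled so no sample exceeds 0.9 FPKM (safely
below the threshold — no knife-edge flakiness); disrupted copies are
truncated (start and stop retained) to 20–30% of the original CDS.
The truncation range is the one genuinely delicate choice: truncated
copies keep complete ORFs and therefore enter *other* members'
reference averages, which can drag a reference as low as
(1 + 2×0.2)/3 of the full length; 20–30% keeps the truncated/reference
ratio strictly below 0.8 for every composition the generator can
produce (bound (0.9n+1.5)/(1.4n−1) < 0.8, requiring ≥ 12 codons,
enforced in validation). Deleted copies are absent from annotation,
ortholog table and expression. Independent sister events are redrawn
until their cause sets are disjoint, and a *Pse* cause never overlaps
a planted *Anc* cause — so parsimony recovery of planted events is
exact by construction, which is precisely the no-homoplasy condition
under which exactness is a meaningful test.

The codon evolver proposes Poisson(branch length × sites) single-
nucleotide changes, accepting synonymous proposals always, nonsynonymous
with probability ω, and rejecting stop-creating ones; initiation and
stop codons are held fixed so functionality is controlled only by the
planted events. Branch lengths are proposal intensities per site
(defaults 0.01–0.03, giving weakly diverged sequences on a ~2-My
timescale).

What the generator does **not** emulate: indels and alignment error
(sequences stay aligned by construction), transposable elements,
demography/linked selection, isoform structure, mapping noise in FPKM,
inter-chromosomal translocation, and real parallel same-cause losses
on sister branches. Passing recovery tests therefore shows the
pipeline's inferential machinery is correct under its own assumptions,
not that those assumptions hold for any real dataset — on real data,
homoplasy would fold some independent terminal losses into shared
ancestral events.

## Problem sizes and numerical choices

Unit and property tests run on bundles of 150 groups × 40 codons and on
simulated alignments of 120–200 genes × 150–300 codons; the acceptance
script uses 300 groups × 40 codons for its end-to-end stage and 300–
1,000 bootstrap replicates — sizes chosen to make sampling error small
relative to the effects tested while keeping the whole suite fast.
Statistics are rounded to one decimal (ratios to two) only in
human-readable output; JSON carries full precision. Degenerate inputs
(zero reference length, empty alignments, zero marginals, two zero
counts, tissues with one measurement) raise or return explicit
sentinels rather than NaN.

## Known limitations

* The dN/dS estimator and the cFPKM normalization are deliberate
  simplifications of the original analysis chain; absolute ω values
  and absolute tissue rankings should not be over-interpreted.
* Fitch reconstruction underestimates changes on long branches and its
  deterministic tie-break can bias individual columns (not the branch
  ordering the analyses rely on).
* The equal-expectation χ² treats prorated fractional counts as
  observations; this mirrors the published analysis but is not a
  calibrated test for small counts.
* Sexual-antagonism labels assume conservation of antagonism across
  species; the pipeline records label provenance but cannot test this.
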