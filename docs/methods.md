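# Methods

`paracis` implements the computational core of a cis-regulatory analysis of a
recently expanded paralogous gene family (modeled on the murine Ly49 /
killer-cell lectin-like receptor cluster): a set of near-identical loci whose
promoters and enhancers must be compared base-by-base even though short-read
signal cannot be assigned uniquely to any one of them. This note records the
models, the parameters that matter, and the choices made where the design was
genuinely open.

## Consensus projection

Paralogous regions are related through a multiple sequence alignment. The
consensus is majority-rule with threshold 0.5: per column, character
frequencies are computed over all rows *including gaps*; the modal character
is emitted when its frequency is ≥ 0.5, `N` otherwise; columns whose
consensus character is the gap are removed. Counting gaps in the denominator
decides whether heavily gapped columns are dropped, which is the behavior
the pipeline needs — a column present in a minority of paralogs should not
appear on the consensus axis. Ties between two nucleotides give `N`
(conservative); a tie between a nucleotide and the gap resolves to the
nucleotide, so a column is only dropped when the gap is strictly modal or
tied-modal with no unique nucleotide alternative.

Coordinate maps send each ungapped paralog base to the consensus index of
its alignment column (or UNMAPPED when the column was dropped). Maps are
strictly increasing on their mapped domain; projection is per-base
assignment, so signal mass over mapped positions is conserved exactly and no
averaging rule is ever needed — with constructively built alignments, two
paralog bases can never hit the same consensus column.

Projected tracks are scaled to a common sum (`target_sum`, default 1e4 —
only the *equality* across tracks is meaningful, the constant is arbitrary)
and a uniform noise floor is added. The floor has a physical meaning: with
`noise_floor(read_pairs, read_length, genome_length) = 2nL/G`, the default
1.5 per bp is the mean genomic coverage of a 30 M-pair, 2×75 bp library on a
3 Gbp genome. Without it, a track with a handful of reads would normalize to
spuriously dominant peaks.

## Multimapper rescue

Reads from near-identical paralogs multimap; discarding them silences
exactly the loci under study. The rescue rule works on the normalized
alignment score nAS = AS / read_length, where AS ≤ 0 is the end-to-end
(glocal) alignment score and 0 is a perfect match. With inbred samples
aligned to their own reference, any deviation from 0 reflects library or
sequencing error, which motivates the hard cutoff at −0.1:

1. placements with nAS < −0.1 are dropped (the inequality is evaluated in
   exact rational arithmetic — `AS·q ≥ p·L` for cutoff p/q — so a read at
   exactly −0.1 is retained without float round-off risk);
2. a unique best survivor takes the read; ties take it jointly;
3. a target-set placement strictly below the read's best score anywhere is
   never assigned ("removed: better elsewhere");
4. reads found by the primary unique-mapper pipeline are merged back in by
   union per region, deduplicated by read id.

Duplicate placements at one region (secondary/supplementary records)
collapse to the best-scoring one before the rules apply. Scoring follows the
bowtie2-like end-to-end scheme (match 0, mismatch −6, first gap base −8, gap
extension −3); the production scorer is Biopython's `PairwiseAligner` in
glocal mode, and the test oracle is an independently written Gotoh dynamic
program (`dp_alignment_score`, vectorized over the reference axis with a
running-maximum recurrence for the affine gap-in-read state). The two agree
exactly on randomized instances with substitutions and indels, and rescue
decisions agree with the oracle on 100% of synthetic multireads.

Paired reads are treated as fragments: both mates must pass the cutoff at
concordant placements. Discordant mate placements are out of scope — the
generators only emit single-end reads, and the fragment-level contract is
the package's explicit choice.

## ATAC insertion signal

Each Tn5 insertion event extends ±75 bp into a 150 bp pseudo read
(half-open intervals, clipped at chromosome bounds). Pileups are scaled by
`scale / total_events` (default scale 1e7) so libraries of different depth
are comparable. The +4/−5 Tn5 duplication offset is available
(`tn5_correct`) for raw fragment ends and skipped for pre-corrected input.

MAP (major ATAC-seq peak) quantification counts pseudo reads with ≥ 1 bp
overlap per MAP per sample; overlapping MAP definitions are rejected because
attribution would be ambiguous. Cross-sample normalization scales every
column so its total equals the reference sample's raw total, where the
reference is the sample whose total is the median (lower median for an even
sample count — deterministic, and the reference stays "one of the
samples"). Counting is per insertion event (two per fragment for paired
data), which is documented rather than configurable.

## CAGE TSS processing

The stringent architecture filter removes records with |template length| >
10 kb (cross-gene chimeras), soft clipping > 3 bp, or any mismatch; each
rule is per-record, so filter composition is order-independent, and removal
counts are reported per rule. UMI proximity deduplication keeps the first
record per UMI within a sliding window of 100 000 records (position-sorted
input required); every occurrence refreshes the window, collapsing chains.

Power-law normalization maps per-bp TSS counts onto a reference law with
exponent α = 1.2 and total T = 1e6. The fit is ordinary least squares on
log(reverse cumulative count) vs log(count) restricted to counts in
[5, 1000]; the reference intercept is solved (Brent) from the law's implied
total tag count. Counts drawn from the reference law normalize to
themselves within ~1%; degenerate fits (fewer than two distinct counts in
range, or a non-decreasing fit) fall back to plain scaling with a warning.

Tag clustering (distclu): positions with normalized signal ≥ 2 in at least
`min_samples` samples seed clusters; same-strand seeds within 50 bp are
single-linkage merged; singleton clusters survive only above signal 4
(strict >, measured as the maximum per-sample value at the position). The
two-step caller runs a loose pass (any sample) and a strict pass (all
samples) and accepts loose clusters overlapping ≥ 1 bp of a same-strand
strict cluster, with boundaries from the loose pass; an allowlist exempts
condition-specific promoters that can only have signal in a sample subset.
The cap filter retains clusters with strictly more than 70% of reads
carrying the cap signature (≥ 1 reference-unencoded G at the 5′ end — the
single-G rule is the package's reading; a run-of-Gs variant would be
stricter and is not implemented).

CAGE–ATAC correlation: ATAC values are scaled to a fixed total of 100 000
over the peaks used, both axes are log2-transformed (pseudocount
configurable, default 0 on positive normalized values), and Pearson's r with
its two-tailed t-test p-value is reported.

## Co-expression odds ratios

Cells are binarized ('+' = at least one read). For a gene pair (x, y) the
2×2 table is a = x−y−, b = x−y+, c = x+y−, d = x+y+, and the odds ratio of
y's expression in x+ vs x− cells is (d/c)/(b/a) = ad/bc — numerically
symmetric in x and y even though the heatmap is displayed directionally.
Zero-cell tables are flagged (infinite when only bc = 0, undefined when both
products vanish) rather than continuity-corrected; Fisher's p is unaffected
by the flagging.

`fisher_exact` implements the two-sided probability-mass definition
directly: all tables with the observed margins are enumerated, hypergeometric
probabilities computed via log-gamma, and those no more probable than the
observed table (relative tolerance 1e−7) are summed. It matches an exact
integer-arithmetic enumeration for every table with n ≤ 40 (complete sweep)
and scipy's implementation on random tables. FDR control is
Benjamini–Hochberg (statsmodels). Replicates combine as the arithmetic mean
of odds ratios with the *least significant* (largest) FDR; with more than
two samples the rule generalizes to max FDR and mean OR. Entries with any
non-finite per-sample OR are flagged and their mean withheld.

The generator solves the Plackett quadratic for p11 given marginals and a
target odds ratio, taking the root inside the Fréchet bounds. A solution
that pushes any cell probability below 1e−4 is rejected as infeasible: such
a joint distribution would plant fewer than one expected cell per thousand
in the rarest category, below what the simulated cell counts can represent.

## Hi-C contacts

Vanilla-coverage (VC) normalization divides each contact by the product of
its anchors' coverage factors, v_i = rowsum_i / mean(positive rowsums); the
mean-scaling keeps the normalized matrix on the raw matrix's magnitude
(the external pipeline being mirrored does not print its constant, so the
choice is the package's own). Zero-coverage bins are masked as NaN.
Uniform-coverage matrices are a fixed point; planted coverage biases are
removed within sampling error.

Hotspot strength is the mean normalized frequency over the inner rectangle
vs the frame between inner and outer rectangles (the neighborhood).
Rectangle coordinates are user inputs, as in the source analysis where they
were drawn by hand.

Matched backgrounds: for each foreground interaction, candidates within
±5 kb of its genomic distance (inclusive) — excluding the foreground set —
are ranked by Euclidean distance in the 2-D space of (centromeric anchor
coverage, telomeric anchor coverage), and the k = 10 nearest are selected,
with deterministic tie-breaking (coverage distance, then distance
difference, then anchor indices). When several samples contribute, each
coverage profile is scaled to sum 100 000 and the mean profile drives the
matching. Enrichment is a Welch two-sample t-test (the unequal-variance
form, the default of the statistical environment being mirrored), two-
tailed, with BH adjustment across the declared family of tests. Against
distance-matched backgrounds the null is calibrated: with hotspot
multiplier 1, rejection at 0.05 stays within binomial error of nominal over
200 simulation replicates.

The contact generator draws Poisson counts with mean
`intensity · c_i · c_j · max(|i−j|, 1)^(−α) · h_ij` (the distance factor is
clamped at 1 on the diagonal, where a pure power law is undefined),
symmetrized from the upper triangle.

## Conserved elements, motifs, homology

Column identity is the modal *nucleotide* frequency per column with gaps in
the denominator and never modal — nine A's and a gap in ten rows score 0.9.
Conserved elements are maximal runs of ≥ 10 consecutive columns with
identity ≥ 0.9 (both bounds inclusive). On a fully carried planted element
flanked by heavily diverged sequence the caller recovers the planted column
interval exactly.

PWM scanning uses log2-odds scores against the background after a 0.01
pseudocount per count cell. P-values are exact: scores are discretized to a
1e−3 grid and the null distribution of a background k-mer's total score is
built by convolving per-position score distributions; p = P(score ≥
observed) with observed scores discretized on the same grid, so boundary
handling is consistent. The DP distribution matches complete 4^k
enumeration for k ≤ 8 to 1e−9 relative accuracy. Hits are reported at
p < 0.01 (strict), both strands by default.

Sliding-window identity mirrors VISTA: 100 bp windows, gaps count as
mismatches, each column takes the identity of the window centered on it
(edge columns inherit the nearest full window), and maximal runs longer
than 100 bp with identity strictly above 70% are highlighted.

Homology search is ungapped seed-and-extend: exact 6-mer seeds, ±1 x-drop
extension (budget 25), chaining of collinear hits within 30 bp on the same
diagonal, then a maximal extension that grows the segment while both the
added stretch and the whole segment stay at or above the identity threshold
— so a high-identity core is never diluted by random flank. Cores that fall
just short of the length threshold are rescued by an exact longest-segment
scan (longest diagonal interval with mean identity ≥ threshold, linear
time); cores shorter than half the length threshold are not rescued, which
prevents chance-matching flanks from inflating short perfect matches into
spurious qualifying regions. Inverted homology searches the reverse
complement of the second sequence with coordinates reported on its original
strand. At the (100 bp, 60%) thresholds the search recovers planted
120 bp/65%-identity segments in ~90% of random realizations with no false
positives on unrelated kilobase sequences; the tool being emulated is an
unspecified dot-plot algorithm, so planted-truth recall — not tool-for-tool
identity — is the correctness surface. The (35 bp, 60%) parameterization
used for cross-family comparisons is reachable through `min_len`.

## Synthetic data: what it emulates, and what it does not

The generators provide every input with known truth: a paralog family
derived from one ancestor (substitutions uniform over three alternatives,
geometric indel lengths, one RNG stream per generator spawned from the
master seed by fixed keys); planted conserved elements spliced into the
ancestor so all rows share aligned columns (carriers verbatim, non-carriers
decayed by per-base substitutions — indels never split a planted element);
Tn5 insertions as an inhomogeneous Poisson process with element-restricted
multipliers (enrichment in carriers only by default, where the element is
intact); multireads as error-bearing substrings scored exhaustively against
every paralog; binary cell matrices with exact planted joint distributions;
and Poisson contact matrices with distance decay, coverage biases and
rectangular hotspots.

The true alignment is constructed from the mutation log, never estimated,
so consensus and projection tests are independent of any aligner. Passing
tests therefore demonstrate correctness of the *computational procedures*,
not robustness to alignment error, sequencing-quality artifacts, GC bias,
chromatin-state confounders, or the fragment-length structure of real
paired-end libraries, none of which the generators model.

Default study conditions used by the test suite and the acceptance script:
8–16 paralogs of 0.5–2 kb, substitution rates 0.02–0.05 (0.5 for
conserved-element flanks), 2 000 reads of 50 bp at 4% error for the
oracle-equivalence sweep, 5 000 cells with marginals 0.3 and planted odds
ratios in {0.5, 1, 2, 6} over 50 seeds, and 80-bin contact matrices at
intensity 3 000 with a 4×4-bin hotspot over 20 seeds. These sizes make the
statistical tolerances (3 SE parameter recovery, ±15% hotspot ratio,
binomial bounds on null rejection rates) tight enough to be meaningful
while keeping the full suite under a minute of compute apart from the
rescue sweep.

## Known limitations

- Rescue handles single-end reads end-to-end; local/soft-clipped alignment
  modes are not modeled.
- `distclu` singleton signal uses the maximum per-sample value; a
  total-across-samples variant would keep marginally more singletons.
- The homology search is ungapped; diverged homologs whose alignment
  requires indels are found only if collinear segments chain within 30 bp.
- VC is the only matrix-balancing method implemented (no iterative
  corrections), matching the analysis being reproduced.
- The CLI covers the file-facing workflows (synthesis, pileup, rescue, MAP
  quantification, co-expression, Hi-C normalization/hotspots, conservation
  scans); purely in-memory steps (CAGE filtering/clustering, background
  selection, enrichment tests) are library calls.
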