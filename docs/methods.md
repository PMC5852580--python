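# Methods

This note documents the models, conventions, and numerical choices
behind each stage of the pipeline, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Duplicate calling and classification

Duplicate pairs are called from pairwise local protein alignments
(Smith–Waterman, BLOSUM62, gap open −11 / extend −1, i.e. BLASTP-like
costs through Biopython's `PairwiseAligner`). Percent identity is
computed over all aligned columns of the local region, counting internal
gap columns as mismatches; coverage of each partner is the locally
aligned span divided by its full length. A pair is a duplicate when
identity **and both** coverages are strictly greater than the threshold
(default 80%). Coverage is enforced symmetrically because duplicate
pairs are reciprocal: requiring only one partner's coverage would admit
fragment-vs-full-length pairs.

Classification uses only genomic coordinates (1-based inclusive, as
printed in genome-database tables):

- *distance* between two genes is the nearest-edge gap between their
  spans (0 if they overlap), not start-to-start; this is the stricter
  reading of "distance between genes" and both conventions agree on all
  bundled published pairs;
- *tandem* iff same chromosome and distance ≤ 100 kb, with the boundary
  inclusive ("within 100 kb"); everything else, including every
  cross-chromosome pair, is *segmental*;
- *gene clusters* are found by a greedy left-to-right sweep per
  chromosome: a run is anchored at its leftmost unassigned gene and
  absorbs consecutive genes whose start lies within 200 kb of the
  anchor's start; runs of ≥3 genes are clusters, and no gene joins two
  clusters. The sweep is deterministic and reproduces the single
  published cluster on the bundled data.
- scaffold pseudo-chromosomes (label "00") are ordinary labels: two
  genes on the scaffold are "same chromosome" for the tandem test. The
  bundled published table contains a known printing conflict (two genes
  with identical scaffold coordinates); the reader loads it as printed
  rather than repairing it, and classification follows the chromosome
  column.

## Nei–Gojobori K_a/K_s

Site counting: each codon position contributes one site. The synonymous
fraction at a position is the fraction of its single-nucleotide changes
that preserve the amino acid, computed over the non-stop alternatives
only (changes creating stop codons are excluded and the fraction is
renormalized over the remainder). Hence S + N = 3 per codon exactly.

Difference counting: for a codon pair differing at k ∈ {1,2,3}
positions, the synonymous/nonsynonymous step tallies are averaged over
all k! orderings of introducing the changes, skipping orderings whose
intermediate codons are stops. If every ordering were blocked the k
steps would be counted nonsynonymous with a warning — exhaustive
enumeration shows no sense-codon pair in the standard code triggers
this, so the branch is purely defensive.

Codon alignments are built by back-translating a global protein
alignment (same scoring as above); columns with a gap in either sequence
are excluded pairwise (complete deletion at codon level). Site totals
are averaged between the two sequences before forming p_S = S_d/S and
p_N = N_d/N (the NG86 convention), then corrected with Jukes–Cantor
d = −(3/4)·ln(1 − (4/3)p). p ≥ 3/4 is saturation: the result is flagged
with NaN rates rather than extrapolated. K_a/K_s is undefined when
K_s = 0; otherwise the selection mode is >1 positive, <1 purifying, =1
(tolerance 1e-9) neutral. Divergence time is T = K_s/(2r)/10⁶ Mya with
r = 1.5×10⁻⁸ synonymous substitutions/site/year, the dicot synonymous
clock; T is linear in K_s and inverse in r.

Plain NG86 + JC is implemented deliberately — no transition/transversion
weighting, no site-class models, no confidence intervals. Biopython's
independent NG86 implementation is used in the test suite as a loose
cross-check (it renormalizes stop-adjacent sites differently, so
agreement is ~10%, not exact); the exact oracle is in-suite exhaustive
enumeration over all 61 sense codons and all 61×61 codon pairs.

## Phylogeny

Distances are protein p-distances under complete deletion: columns
containing a gap in any sequence are removed globally, then distance =
mismatches / retained columns. Tree building is Saitou–Nei
neighbor-joining with two pinned conventions so results are
bit-reproducible: ties in the Q criterion break toward the lowest index
pair, and negative pendant lengths (an NJ artifact) are clamped to zero
with the deficit transferred to the sibling branch. The final three
lineages join at an unrooted trifurcation. On additive matrices NJ
reproduces the generating tree's path lengths exactly (tested at 4 and
5 taxa).

Bootstrap supports resample alignment columns with replacement, rebuild
the tree per replicate, and report the percentage of replicates
containing each internal bipartition of the full-data tree; the
generator is `numpy.random.default_rng(seed)`, so supports are
reproducible. Alignments of identical sequences give a degenerate
distance matrix; the arbitrary resolution is returned flagged
`resolved=False`.

Class assignment mirrors how family surveys label members from reference
proteins: for each unlabeled leaf, every tree edge defines a surrounding
leaf set containing it; sets are scanned smallest-first and the first
size at which labeled references appear decides — unanimous labels give
the class, disagreement (a mixed clade, or equidistant conflicting
clades) gives "unclassified".

## Protein properties

Molecular weight is the sum of Expasy average residue masses plus one
water (18.01524 Da), in kDa. The isoelectric point solves net
charge(pH) = 0 by bisection on [0, 14] to 10⁻³ pH (the charge is
strictly decreasing, positive at pH 0 and negative at pH 14, so the
bracket is always valid), using Henderson–Hasselbalch terms for K, R, H,
D, E, C, Y and both termini with the Bjellqvist pKa set of the Expasy
tool, including its residue-specific terminal values (e.g. N-terminal
Ala 7.59, C-terminal Asp 4.55). Because terminal pKa depends on which
residue carries the terminus, pI is invariant under permutations of
internal residues only. The suite checks the charge model exactly
against Biopython's `IsoelectricPoint` (same pKa table; note its own
bisection clamps to [4.05, 12], so extreme pI values below 4.05 are
reported more faithfully here).

## Expression

2^−ΔΔCt follows the Livak convention: replicate Cq values are averaged
within each (gene, line, temperature, time) cell first; ΔCt = target −
reference, ΔΔCt subtracts the calibrator cell (the 0 h time point of the
same gene/line/temperature series, configurable), fold = 2^−ΔΔCt. The
calibrator cell therefore has fold 1 by construction, and fold is
invariant to adding a constant to all four Cq inputs. Replicate-level
folds (per-replicate ΔCt against the calibrator mean) are retained for
ANOVA. A single configurable reference gene is supported; combining
multiple reference genes is out of scope.

One-way ANOVA uses `scipy.stats.f_oneway`; pairwise comparison is Tukey
HSD (statsmodels) at α = 0.05, summarized as a compact letter display by
a greedy insertion in descending-mean order (groups sharing a letter are
never significantly different). Degenerate inputs: zero within-group
variance with equal means flags F as undefined; zero variance with
unequal means reports F = ∞ with all unequal-mean pairs distinct.

Heatmap matrices are log2 folds (no row-centering) over gene ×
line/temperature/time columns; missing cells are imputed as 0 log2-fold
and flagged. Optional row ordering is average-linkage hierarchical
clustering on correlation distance, with NaN distances from constant
rows treated as 0 (constant rows are mutually identical); leaf order is
scipy's deterministic ordering.

## Synthetic data

The family generator emulates the *inputs* of a family survey, not full
genome evolution. An ancestral CDS is drawn uniformly over sense codons
(ATG start, no internal stops) and each planted pair's second copy is
derived by applying round(p·sites) synonymous and nonsynonymous point
substitutions, where p inverts the JC correction at the target K_s
(resp. K_a = ω·K_s) and sites are the NG86 totals of the ancestor.
Substitutions are placed uniformly over the currently eligible
single-base changes, rejecting stops; multiple hits at one site are
allowed, which is why recovered K_s shrinks slightly below target at
high divergence (the saturation trend is itself asserted in the suite).
Defaults are ω = 0.3, K_s = 0.2, 300 codons — moderate purifying
selection at comfortably sub-saturation divergence. Tandem pairs are
placed on one chromosome at a configurable nearest-edge offset (default
5 kb < 100 kb); segmental pairs go on two different chromosomes;
unrelated background genes are spaced 500 kb apart so they never form
spurious tandem calls or clusters. Not emulated: indels, intron
structure, codon-usage bias, rate heterogeneity — so passing recovery
tests demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-genome complications.

The Cq generator plants per-cell log2 fold-changes: target Cq =
baseline − log2fold + N(0, sd) per replicate, reference Cq = constant +
N(0, sd); defaults are triplicate wells, sd 0.2 cycles, baseline 24,
reference 20 — typical qPCR magnitudes. With sd 0.2 on both target and
reference, the ΔΔCt estimate has standard deviation √(4·0.2²/3) ≈ 0.23
log2 units, so a ±25% fold band captures ≈88% of genes analytically;
the suite's recovery assertions are set accordingly.

Both generators are deterministic under their seed and write exactly the
dialects the readers accept (byte-identical reruns are tested).

## Problem sizes

The default test and reproduction runs use: 50 replicate families of
300 codons for ω recovery; 5 families × 3 planted pairs for end-to-end
label recovery; 200 bootstrap replicates over 8 sequences × 120 columns
for clade support; 100 simulated genes for the noisy fold envelope.
These sizes give stable medians/rates (checked across seeds) while the
whole suite runs in well under a minute.

## Known limitations

- The published family's sequences are not deposited, so per-gene
  K_s/K_a, pI/MW, and the published tree cannot be recomputed from
  scratch; the bundled printed tables (coordinates; pair-level K_s/K_a)
  are treated as inputs, and sequence-level behavior is validated on
  synthetic data and against in-suite oracles instead.
- MSA construction is an input (any external aligner); only pairwise
  alignment is built in.
- No amplification-efficiency correction or melt-curve QC in the qPCR
  path; no E-value statistics in duplicate calling (the rule depends
  only on identity/coverage).
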