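# Methods

This note records the models, numerical choices and simplifications behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Conventions

All genomic coordinates at the API surface are 1-based inclusive (the GFF3
convention); BED output converts to 0-based half-open at the boundary. CDS
sequences are always returned 5′→3′ of the coding strand, so codon-level
analyses never see antisense sequence. Reported percentages are rounded
half-up to one decimal, matching the "x of y (z%)" style of family surveys;
every filter stage logs its input count, surviving count and threshold so
such summaries are reconstructible from the log. All stochastic procedures
take an explicit seed and draw from one `numpy` generator per call; no
global RNG state is touched.

## Family identification

The membership criterion is one copy of the conserved ~100-residue domain.
The profile-HMM search of a full-scale survey is replaced by a gapless
position-specific log-odds profile (log₂ of smoothed column frequency over
background, Jeffreys +0.5 pseudocount per residue, columns with > 50% gaps
dropped, X scoring 0 everywhere). The domain this family is built around is
compact and well conserved, so insert/delete states add little
discrimination; the simplification is deliberate and means marginal,
heavily indel-ed domain copies would be missed.

E-values are calibrated empirically rather than taken from Karlin–Altschul
theory: the best window score of each of N = 10 000 shuffled decoys is
fitted with a Gumbel distribution (the asymptotic law of maxima), and
e(s) = N·P(score ≥ s). The Gumbel tail extrapolates stably to the 10⁻¹⁰
gate, and the calibration is itself tested (the observed decoy tail must
match the predicted e-value within binomial error). Overlapping hits are
resolved best-score-first, leftmost on ties. Candidates route to exactly
one of {accepted, rejected_no_domain, rejected_multi_domain}; the rule for
multi-domain detection (≥ 2 non-overlapping hits each passing the gate) is
this package's own, since published surveys rarely state one.

Molecular weight sums average residue masses plus one water (X contributes
the 20-residue mean); the isoelectric point is found by bisection on the
net charge under the Bjellqvist pKa set (via biopython) to |charge| < 10⁻⁶.

## Alignment and phylogeny

Pairwise global and local alignments use BLOSUM62 with affine gaps (open
10, extend 0.5 — the classic progressive-aligner defaults) through
`Bio.Align.PairwiseAligner`. The multiple alignment is guide-tree
progressive: a 3-mer distance matrix, an NJ guide tree, and profile–profile
merges by affine-gap dynamic programming on column-frequency vectors
(sum-of-pairs scores fᵃ·S·fᵇ; gap states open only from the match state,
which keeps each DP row vectorizable at a negligible cost in optimality).
No iterative refinement is performed. An internal invariant checks that
degapping any output row reproduces its input sequence exactly.

Distances are Poisson-corrected p-distances d = −ln(1 − p) over columns
ungapped in both rows; saturated pairs (p ≥ 0.95) are capped at d = 3.0
with a warning rather than diverging. Neighbor joining is the standard
Saitou–Nei Q-criterion agglomeration; Q-ties break to the lexicographically
smallest active pair, and negative branch lengths are clamped to zero with
the deficit moved to the sister edge, so additive inputs are reproduced
exactly (tested to 10⁻⁹ against random additive metrics, and cross-checked
against scikit-bio's independent NJ). Bootstrap resamples alignment columns
with replacement, rebuilds the tree per replicate (a vectorized
distance-from-column-counts path keeps 1000 replicates cheap), scores
internal edges by unrooted-bipartition frequency, and collapses edges below
50%.

Subfamily assignment transfers labels from reference leaves: a query takes
the label of the smallest supported clade (either side of any retained
split) containing it together with references of exactly one label, else
"orphan". A consequence of unrooted-split logic worth knowing: with only
two reference labels an orphan is impossible (the complement of a
single-label side is always single-labeled), so orphans only arise with ≥ 3
labeled groups — consistent with how orphans appear in real surveys, which
use many reference subfamilies.

## Motif discovery

Motifs are found by ZOOPS (zero-or-one occurrence per sequence) EM: per
candidate width, 10 seeded restarts of EM on window posteriors, Jeffreys
+0.5/residue Dirichlet smoothing in the M-step (EM is asserted monotone in
the penalized likelihood each iteration), best restart kept by likelihood.
Widths are scanned over the coarse grid {8, 12, 16, 21, 29, 41, 58, 81,
100} clipped to the configured range, and the winning width maximizes
bias-corrected information content. After each motif, its occurrences
(best window per sequence when more likely under the motif than background)
are masked and the background re-estimated from unmasked residues.

Discovery stops at the motif cap (8) or when the best candidate carries
less than 0.5 bits/column. The IC that this rule sees is corrected for two
inflation sources: the Miller–Madow small-sample entropy bias
(K−1)/(2N ln 2) at N effective occurrences, and an order-statistic term
log₂(m)/width for EM having chosen the best-looking of m windows per
sequence. Uncorrected, EM converged on pure-background sequences reports
≈ 0.7 bits/column and the stop rule cannot discriminate; with both
corrections, background runs report ≈ 0 while genuinely shared motifs stay
well above 0.5. Motif occurrences across a database are mapped by the same
log-odds/Gumbel-calibration machinery as the domain scan.

## Duplication detection

Tandem events follow the positional rule: per chromosome, family genes
sorted by start are linked when consecutive starts are ≤ 200 kb apart, and
maximal runs of ≥ 2 form clusters — exactly the connected components of the
proximity graph (tested against a networkx oracle).

Collinear (segmental) blocks chain all-vs-all similarity anchors. A
retained hit needs (i) a decoy-calibrated e-value below the 10⁻²⁰ gate,
(ii) an e-value within the configured factor (10²⁰) of the best non-self
hit of either endpoint — computed in log-space to dodge underflow — and
(iii) alignment coverage ≥ 50% of the longer protein. The "minimum of 6
unduplicated genes … allowed" wording of such protocols is grammatically
ambiguous; it is implemented as the conventional gap parameter: at most 6
intervening genes (by rank difference) between consecutive anchors on each
chromosome. Same-chromosome pairs within tandem range (rank difference ≤
gap + 1) are excluded from anchors, the standard pre-filter that keeps
tandem arrays from masquerading as local collinearity. Chains must advance
strictly in rank on both chromosomes (both orientations tried), are
extracted best-first with each anchor used once, and need ≥ 2 anchors.
Chaining agrees with an exhaustive enumeration oracle on small anchor sets.

## Ka/Ks and dating

The estimator is classical Nei–Gojobori (1986) with unweighted pathways:
synonymous site fractions per codon position count only non-stop single-
nucleotide changes in the denominator; observed per-codon differences are
averaged over all minimal substitution pathways with stop-passing pathways
discarded; pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
K = −¾ ln(1 − 4p/3). Columns containing gaps, ambiguity codes or stops are
skipped with a warning. p ≥ ¾ leaves the estimate undefined (NaN) and the
pair is flagged and excluded from dating. Codon alignments are built by
back-translating the pairwise protein alignment; translation of each CDS is
validated against its protein row. Selection classes follow Ka/Ks (> 1
positive, = 1 within 10⁻⁹ neutral, < 1 purifying; Ks = 0 undefined), and
dates are T = Ks/(2r), r = 2.6 × 10⁻⁹ substitutions/site/year, divided by
10⁶ exactly once at the reporting boundary.

## Expression

"Expressed" is strict FPKM > 1 (the protocol wording; cells exactly at the
boundary are logged so the inclusive convention is recoverable).
Stress calls use ratio = (t + 0.01)/(c + 0.01) with strict > 2 (up) and
< 0.5 (down) bounds; the 0.01 pseudocount handles zero-FPKM controls and is
configurable. Patterns come from average-linkage hierarchical clustering on
1 − Pearson r of log₂(FPKM + 1) rows, cut at cophenetic distance 0.5 (i.e.
merge similarity ≥ 0.5 correlation — the named clustering tool's threshold
is interpreted as a correlation cut, which its convention supports but does
not state); zero-variance rows get singleton clusters with a warning.
2^(−ΔΔCt) pairs target and reference Ct by replicate, with replicate SD
propagated and a two-sided t-test against the calibrator ΔCt supplied for
completeness.

## Synthetic data

The generator emulates exactly the features the pipeline measures: a
multi-chromosome genome whose family members each embed one diverged copy
of a fixed synthetic ~100-residue consensus (per-site substitution
probability 0.10 per lineage by default); tandem clusters placed with
start-to-start spacing below the 200-kb window; collinear segments whose
anchor pairs are codon sequences evolved from a common ancestor at known Ks
(default range 0.1–0.4) and ω (default 0.25, purifying — the regime such
families mostly show); decoys drawn from the family residue composition and
rejection-sampled against the domain profile so they contain no domain;
gene models with 0/1/multiple introns in roughly the half/quarter/quarter
proportions such families show; FPKM matrices whose up/down/unchanged genes
sit outside the calling margins by construction (margin 1.5 by default, and
generation refuses margins the noise level would blur); and Ct tables built
by inverting the 2^(−ΔΔCt) formula.

The codon process is Goldman–Yang-like but simplified to equal codon
frequencies and no transition/transversion bias — deliberately matched to
the Nei–Gojobori estimator's assumptions so parameter recovery is a clean
test of the estimator rather than of model mismatch. Each branch runs a
per-codon Gillespie simulation for time calibrated so expected synonymous
substitutions per NG synonymous site equal Ks/2 per branch (the
calibration accounts for stop-neighbor exclusions; without it Ks recovery
is biased a few percent low). Features of real data that are *not*
emulated: indels within coding sequence, intergenic sequence composition,
isoforms, transition bias and codon-usage bias, expression count noise
models. Passing tests therefore demonstrate correctness of the pipeline's
rules and estimators under their own assumptions, not robustness to every
property of real genomes.

Non-cluster family genes are always placed more than one window apart so
the planted tandem truth is exhaustive; collinear anchors sit > 200 kb
apart on their own chromosomes for the same reason, with the requested
number of decoys between them.

## Problem sizes

Default test and acceptance runs use genomes of 3 chromosomes, ~14 family
genes and ~30 decoys; ω/Ks recovery uses 3000-codon sequences over 10–20
replicates; NJ correctness uses 100–500 random additive trees of ≤ 12
leaves; identification uses 5–10 genomes against a profile calibrated on
10 000 decoys. These sizes make every distributional claim in the tests
measurable in seconds while keeping estimator standard errors (e.g. ~3% on
mean Ks at 3000 codons) well inside the asserted tolerances.

## Known limitations

The gapless profile scan will miss domain copies with large insertions;
e-values are calibrated per profile, so they are comparable within a run,
not across search tools; maximum-likelihood tree inference is out of scope
(NJ is the implemented method); NG86 underestimates ω above 1 by ~10% at
these divergences (visible in the recovery tests, inside their 15% band);
collinearity counts intervening genes by rank difference, treating
other-block anchors like any other gene; and the qPCR module normalizes to
a single reference gene only.
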