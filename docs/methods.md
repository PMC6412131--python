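# Methods

## The CSC model

For gene *i* with sense-codon length ℓ<sub>i</sub> and codon counts
C<sub>ij</sub>, the proportion of codon *j* is N<sub>ij</sub> =
C<sub>ij</sub>/ℓ<sub>i</sub>. The codon stabilization coefficient of codon
*j* is the Pearson correlation coefficient across genes between
N<sub>ij</sub> and the gene's mRNA half-life in minutes, and the gene
score is CSCg<sub>i</sub> = Σ<sub>j</sub> CSC<sub>j</sub>·N<sub>ij</sub>.
The statistic makes no causal claim: it quantifies the linear association
between a codon's usage and transcript stability, whatever drives it.

Assumptions and conventions:

* Only the 61 sense codons enter any score. The terminal stop codon is
  retained on sequences (`has_terminal_stop`) but excluded from
  C<sub>ij</sub> and ℓ<sub>i</sub>; the initiator ATG counts as an
  ordinary Met codon. `positional_csc_profile(include_start=False)` drops
  the invariant position 1 from head averages when wanted.
* Half-lives are used untransformed. The Pearson correlation is invariant
  to positive affine rescaling of half-lives (asserted to 1e-12 in the
  property suite), so units only matter for interpretability. A
  `log_transform` option correlates against log half-lives for users who
  prefer a multiplicative error model; it is off by default.
* One global shared gene set — genes present in both the CDS collection
  and the half-life table — is used for all 61 correlations, so CSC
  values are comparable across codons. At least 3 shared genes are
  required; a codon with zero proportion variance across that set has an
  undefined CSC, which is surfaced (NaN + `undefined` set) and never
  imputed; downstream operations that need it fail loudly naming the
  codon.

Codon classes follow the strict-inequality convention: optimal CSC > 0.1,
non-optimal CSC < −0.1, boundary values neutral. Both thresholds are
parameters of `classify_codons`.

## Input validation

CDS FASTA records are normalized (uppercase, U→T) and rejected — with
machine-readable reasons written to a rejection report — when their length
is not a multiple of 3, they contain a base outside {A,C,G,T}, they carry
an internal stop codon, or they are shorter than two codons. Rejection is
total: valid + rejected = input records. Exclusion lists (e.g. dubious
ORFs, mitochondrial genes) are supplied by the user as plain-text id
lists; the package never fetches annotation. Each FASTA record is treated
as an independent gene; no isoform reconciliation is attempted.

## The synonymous shuffle

The null genome exchanges each codon for a synonymous one while keeping
(a) every protein sequence and (b) the genome-wide copy number of every
codon, exactly. Implementation: all occurrences of each amino acid's
codons are pooled over the bias-source genes, each pool is permuted with a
seeded generator, and codons are dealt back in gene order. Exact pooled
permutation was chosen over independent proportional draws because only
the former guarantees count conservation deterministically; marginally,
each dealt codon is still drawn proportionally to its pool frequency.
Met, Trp and the stop codons have no degrees of freedom and pass through
unchanged; six-fold families (Leu, Ser, Arg) are pooled by amino-acid
identity, not by codon box. Restricted-bias designs (e.g. shuffling only
the genes with CSCg < 0 under their own bias) are expressed by passing
that subset as both `genes` and `bias_source`.

Two conservation facts shape the test suite. The *length-weighted* mean
CSCg (total CSC mass over total codons) is exactly invariant under a
self-sourced shuffle, because the genome-wide codon counts are. The
*unweighted* gene mean is not: for a fixed finite genome it differs from
its shuffled expectation by a small bias (each gene's own codon choices
vs the count-weighted pool mean), so the suite asserts exact invariance
of the weighted mean and brackets the unweighted mean by gene-sampling
error. Likewise, shuffling preserves each gene's amino-acid sequence, so
per-position amino-acid composition — and through it a residual
positional CSC signal — is shared by all shuffles of one genome; flatness
of shuffled positional profiles is therefore judged against gene-level,
not shuffle-level, standard errors.

## Stretch scanning

`window_sums` computes the summed CSC of every w-codon window (default
w = 10) by prefix sums; entry k covers codons k..k+w−1, codon 1 = ATG.
Windows summing ≤ −1.28 are non-optimal stretches, ≥ +1.28 optimal — the
defaults mirror the summed-score level associated with destabilization,
and both thresholds are flags. Overlapping or abutting qualifying windows
of one polarity merge into a single stretch anchored at the leftmost
qualifying start and carrying the run's most extreme window sum; merging
prevents one long non-optimal run from inflating counts, and
`merge=False` (`--no-merge`) reports every raw qualifying window for
sensitivity analysis, since published stretch counts may follow either
convention. Metagene-ready filtering removes, in order and with counts
reported: genes with more than one stretch of the polarity, stretches
starting at codon ≥ 200, and genes without a measured half-life. A
stretch's anchor nucleotide is 3·(start_codon − 1) + 1.

## Coverage normalization and metagenes

Per-nucleotide footprint counts on CDS coordinates are normalized by the
summed reads in a fixed window — not by the gene total, which would make
long genes systematically lower — so the in-window values of every gene
sum to 1. Genes whose window holds zero reads are excluded and counted,
never NaN-propagated. For start-anchored profiles the window is nt 1–500
after the ATG; for stretch-anchored profiles it is the anchored span
itself; both are parameters.

A metagene with span L (default 500) covers offsets −L..L−1: L
nucleotides before the anchor and L from the anchor on, with the anchor
at offset 0. This makes a uniform-coverage gene's profile exactly
1/(2L) everywhere, and matches the "N nucleotides before and after"
phrasing with an even window of 2L positions. Group comparison runs a
Welch (unequal-variance) t-test per offset — group sizes and variances
differ in practice, so the pooled-variance form was not used — and
adjusts the per-offset p-value family by the Holm–Šidák step-down rule:
with p-values sorted ascending, adjusted p<sub>(i)</sub> =
max<sub>k≤i</sub>[1 − (1 − p<sub>(k)</sub>)<sup>m−k+1</sup>], clipped at
1. Offsets where the statistic is undefined (both groups degenerate) get
p = 1 and a flag. Offsets are nucleotide-resolution; no codon binning is
applied before testing.

One consequence of window normalization worth knowing: when a pause lies
inside the normalization window, the paused group's baseline is genuinely
depressed (its extra mass is redistributed), e.g. by factor
5000/5600 ≈ 0.89 for a 30-nt, 5-fold pause on a 1000-nt window at base
rate 5. Comparisons against a control group therefore show a strong
positive signal at the pause and a small negative one elsewhere; only a
control-vs-control comparison is truly flat.

## Concordance, ECDFs, clustering

Cross-dataset concordance is the pairwise Spearman ρ (average ranks on
ties) over the 61 CSC values, with pairwise deletion and per-pair support
counts when tables contain undefined entries; the same machinery
correlates CSC against external per-codon metrics (tAI, tRNA abundance,
inverse ribosome residence time — the caller supplies the inversion).
ECDF comparisons use the two-sample Kolmogorov–Smirnov statistic with the
asymptotic p-value, switching to the exact distribution when both samples
have ≤ 25 points. Gene clustering on (optimal, neutral, non-optimal)
composition triples uses Euclidean distances with average linkage cut at
k = 3; the linkage criterion and k are declared defaults, not inferred
from any reference workflow, and both are configurable. Genes are sorted
by id before linkage so results are input-order independent.
Kruskal–Wallis and D'Agostino–Pearson tests are exposed as thin
pass-throughs over scipy; no post-hoc (Dunn) procedure is bundled.

## Synthetic data

The simulator defines the package's study conditions:

* `make_genome(n, (min, max), codon_usage, seed)` — bodies i.i.d. from the
  usage weights (uniform over the 61 sense codons by default), ATG start,
  TAA stop, sense-codon lengths uniform on the closed interval. Defaults
  (100–600 codons) bracket typical yeast ORF lengths.
* `make_half_lives` — the linear model above, intercept 20 min (a typical
  yeast-scale mean), truncated below at 0.1 min so the positive-half-life
  invariant survives high noise. `planted_halflife_experiment` draws
  per-codon effects β<sub>j</sub> ~ N(0, 10 min), builds a 2000-gene
  genome, and sets the noise SD to half the SD of the noiseless signal —
  the package's standard parameter-recovery setting, at which the Spearman
  correlation between recovered CSC and planted β exceeds 0.9.
* `make_coverage` — Poisson(base rate 5 reads/nt) per nucleotide, with an
  optional (anchor, width, fold) pause multiplying the rate; the standard
  pause setting is 200 genes of 400 codons, a 5× pause of 30 nt at
  nt 501.

What the generator does not emulate: real codon-usage bias and its
correlation structure across genes, length-dependent composition, 3-nt
footprint periodicity and A-site offsets, library-size variation between
genes, and measurement error models specific to decay protocols
(transcription shutoff vs metabolic labeling). Passing tests therefore
demonstrate correctness of the estimators and the pipeline's statistical
behavior under its matched generative family, not performance on any
particular organism's data.

## Numerical choices and edge cases

* CSC via vectorized centered dot products; agreement with a textbook
  pairwise Pearson implementation is asserted to 1e-12 on instances up to
  50 genes. CSCg computed from counts equals the proportion form to
  1e-12.
* Rolling window sums satisfy the prefix-sum identity to 1e-12 and are
  checked against a naive per-window scanner on 200-gene fixtures.
* Ties: Spearman uses average ranks; gene rankings break ties by
  lexicographic gene id (stable sorts throughout), so decile and α/β
  group assignment (ranks 1..50 and 51..100 on the ascending initial-CSC
  ranking) is deterministic.
* Degenerate inputs fail explicitly rather than silently: constant
  half-lives, < 3 shared genes, pool exhaustion (named amino acid),
  zero-read normalization windows (counted exclusions), constant inputs
  to rank correlations (reported NaN).
* Deciles with n not divisible by 10 put the remainder in the last
  groups.
* Acceptance and test problem sizes (2000-gene recovery, 500-gene × 20
  seed conservation, 200-gene pause metagene) are the package's standard
  study conditions; all complete in seconds on one CPU.

## Known limitations

CSC inherits the quality of the half-life table: datasets measured with
different protocols can yield poorly correlated CSCs, which is precisely
what the concordance tooling is for. The shuffle preserves only codon
counts and proteins — not dicodon frequencies, GC3, or RNA structure — so
it tests codon-choice arrangement, nothing else. Metagene inference
assumes coverage is comparable across genes after window normalization;
no A-site offsetting or periodicity modeling is applied. The CSCg of
genes using a codon with undefined CSC is undefined by design.
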