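# Methods

## Data model

A *repertoire* is one serum sample's IgG-bound peptide set: a map from
12-mer amino-acid sequences (20 canonical residues) to read counts.
Cleaning removes peptides of length ≠ 12, peptides containing
non-canonical letters (stop `*`, ambiguity `X`, …) and any peptide on a
user-supplied artefact list; the artefact list defaults to empty because
platform-specific artefact catalogues are not portable, and the cleaning
report makes whatever was removed auditable. Counts are then scaled so
each sample sums to 3 × 10⁶ reads (the conventional MVA depth).
Normalized counts are kept real-valued rather than re-rounded: downstream
abundance sums and ratios are real-valued, and rounding would break the
composition-conservation invariant (pairwise count ratios are preserved
to 1 × 10⁻⁹ relative). Normalization is idempotent at a fixed target. No
library-bias correction is applied.

## Epitope patterns and exhaustive discovery

An *epitope* is a motif with ≥ 4 fixed amino-acid positions inside a
window of at most 12 residues. The pattern grammar is a string over the
20 residue letters plus the single-position wildcard `.`, with fixed
residues at both ends (wildcards are interior only). This is the minimal
grammar consistent with 12-mer windows and with the fixed-residue
alignment rule used downstream; variable-length gaps are excluded.

Discovery enumerates patterns breadth-first: starting from single
residues, each pattern is extended on the right by a residue or a
wildcard, carrying a match list of (peptide, offset) occurrences over
the pooled query + reference peptides. The only pruning criterion is the
minimum support (default 10 distinct matching query peptides), which is
monotone non-increasing under extension, so the search is provably
exhaustive within the span/support bounds; the test suite verifies
equality with a full enumeration of the bounded pattern space on small
instances. Support below roughly 10 unique peptides cannot reach the
p < 10⁻⁸ selection threshold at realistic set sizes, so the default
bounds the search without affecting reported output.

A pattern's enrichment is scored two ways:

* **Fold enrichment** `fold = (k_q/n_q) / ((k_r + 1)/n_r)` with a +1
  pseudocount on the reference matches only; this keeps zero-reference
  folds finite and biases conservatively (never inflating the query
  side). Abundances default to normalized reads, because an epitope's
  abundance is defined as the number of IgG-bound peptide observations
  containing it; a distinct-peptide mode is available
  (`count_mode="unique_peptides"`).
* **Hypergeometric p-value** on *distinct peptides* regardless of the
  abundance mode — the urn model requires exchangeable discrete units,
  and normalized read counts are not integers. With `n` distinct query
  peptides among `N` pooled and `K` pooled matches, the score is
  P(X ≥ k), computed in log space (`lgamma` term sums combined by a
  scaled `fsum`), accurate to ~10⁻¹² relative down to p ≈ 10⁻³⁰⁰. The
  fixed 10⁻⁸ cutoff is used as-is; no multiple-testing correction is
  applied in discovery (an optional Benjamini–Hochberg column is emitted
  in marker tables, clearly labelled as an extension).

Default thresholds: fold ≥ 2 for discriminative mode (query versus the
same subject's paired pre-treatment sample) and fold ≥ 10 for vs-random
mode (query versus a generated random-peptide reference), both with
p < 10⁻⁸ and ≥ 4 fixed positions.

**Core reduction.** Raw output is redundant (a strong motif surfaces with
many sub/super-patterns). A pattern is dropped when its set of matching
distinct query peptides is a subset of a retained pattern's match set
with smaller-or-equal p-value; among mutually subsuming equal-p patterns
the one with more fixed positions, then the lexicographically smallest,
is kept. This subsumption rule is this package's definition of a *core
epitope*; other implementations of the idea exist and may differ.

Output ordering is fully deterministic: ascending p, then descending
fold, then pattern string.

## Antigen mapping

A pattern is placed on a protein sequence wherever **every fixed
residue matches exactly** (wildcards unconstrained); all placements are
reported, overlaps allowed, coordinates 1-based inclusive (the
protein-annotation convention). Matching a pattern to a linear database
epitope means the pattern occurs *inside* the epitope sequence; the
reverse containment (epitope inside a longer pattern) is not counted.
Antigens with identity to at least one epitope from each of two pattern
sets (e.g. disease-specific and treatment-specific) are recruited by set
intersection. An antigen's response score in a sample is the mean, over
distinct patterns aligning to it, of each pattern's repertoire abundance
(a pattern hitting several offsets counts once), reported raw and as
log₁₀(mean + 1) — the +1 keeps zero abundance defined on the log scale
and is recorded in output metadata. One sequence per accession; isoforms
are not expanded.

## Profile metrics

* **CSI** (cosine similarity index): each sample is represented by its
  2500 highest-abundance peptides (ties broken lexicographically); the
  vectors live on the union of the two top lists and a sample
  contributes its abundance only for peptides inside its *own* top list,
  zero elsewhere — both the magnitudes and the membership of the top
  list carry signal. The alternative (full-repertoire values on union
  axes) is available via `full_values=True`. CSI is symmetric, in
  [0, 1], scale-invariant, and exactly 1 for a sample against itself.
* **Z-score maps**: for one patient's top-epitope × paired-sample
  sub-matrix, one mean and one sample standard deviation (n − 1
  denominator) are computed over *all* entries, and z = (x − mean)/sd.
  A per-epitope standardization across just the two samples would be
  degenerate (n = 2 per row) and was rejected. For display the values
  are capped at the patient's 97.5th percentile (upper-sided; a
  symmetric cap is available behind a flag).
* **Abundance ratio** log₁₀((post + 1)/(pre + 1)); 0 means unchanged
  reactivity, and the function is antisymmetric in its arguments.
* **Competition relative abundance**: competed / uncompeted abundance of
  an epitope, ≈ the retained fraction after pre-blocking serum with
  lysate.

## Biomarker statistics

Group differences per epitope use the two-sided Wilcoxon rank-sum test
with midranks, tie-corrected variance and continuity correction 0.5
(the base-R `wilcox.test(correct=TRUE)` convention, provided by
`scipy.stats.mannwhitneyu`); all values identical gives p = 1. ROC
analysis uses the rule *positive when score ≥ threshold* with one
operating point per distinct score value plus +∞; the reported point
maximizes Youden's J = sensitivity + specificity − 1, ties broken toward
higher specificity, then lower threshold. AUC uses the rank-statistic
(Mann–Whitney) formulation with ties counted one half. Markers must
exceed sensitivity > 0.72 and specificity > 0.67 (strict floors, both
configurable) and are ranked by descending J, ties by ascending Wilcoxon
p then pattern string; the top 15 are kept by default.

Combined models are unpenalized logistic regressions fitted by IRLS on
log₁₀(x + 1)-transformed abundances (they span orders of magnitude; a
raw-scale option exists). Convergence is declared when the
log-likelihood changes by < 10⁻⁸ (cap 100 iterations). On complete
separation the MLE does not exist; the fit detects the saturated
solution, flags `converged=False`, and still reports scores, AUC and the
Youden operating point, which are invariant to the diverging coefficient
scale — no penalization is substituted, since the small case-control
designs this analysis targets plausibly produce near-separation. Small
marker subsets (≤ 3 by default, candidates capped at 20) are searched
exhaustively for the highest-AUC combination; ties prefer the smaller
subset, then lexicographic marker order. **All reported performance is
apparent performance** — there is no cross-validation, and the model
report says so.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
at desk scale. Defaults: 3 × 10⁵ reads over 5 × 10⁴ unique peptides per
sample (about a tenth of a deep MVA run, which averages ~3 × 10⁶ reads
and ~6 × 10⁵ unique peptides); background residues i.i.d. uniform over
the 20 canonical letters (configurable — the true composition of a
selected phage library is platform-specific); counts Zipf-distributed
with exponent 2.0 (`count_dispersion`), giving the heavy-tailed skew of
deep sequencing while keeping the mean finite so planted read fractions
are stable; group sizes default to a study-like design (6 paired MelVac
subjects, 5 PEM-Mel, plus controls) scaled to desk size.

Planted motifs rewrite existing background peptides in place (fixed
residues imposed at a random admissible offset) until the motif's
matching read fraction reaches `baseline_fraction` in the reference
condition or `baseline_fraction × fold` in the query condition, so the
unique-peptide count stays a clean knob. Peptides are skipped when
adding them would overshoot the target by more than 5 %, which keeps the
realized fraction within a few percent of the target. Paired groups get
a pre (reference) and post (query) sample per subject with mutual
pairing; competition samples are derived from the post sample by
binomial thinning of motif-matching reads at the configured retained
fraction (unbiased; a factor of 1 reproduces the parent exactly).
Antigens are random background protein sequences with each motif's fixed
residues written at recorded, non-overlapping 1-based offsets in a
random antigen subset; a truth table lists every placement.

All randomness flows from one seed through `numpy` seed sequences (the
pipeline derives a stage-specific substream per stage name), so outputs
are byte-identical across runs. Written tables carry raw integer counts
so that generated cohorts round-trip exactly through the loader.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: phage selection rounds, NNK codon
composition, amplification bias, sequencing error profiles, and shared
peptide backbones between a subject's pre and post samples (each sample
draws an independent background, so paired samples share planted motif
structure but essentially no individual peptides; real longitudinal
samples are far more self-similar). Recovery results on synthetic
cohorts demonstrate algorithmic correctness, not clinical performance.

## Problem sizes used in the test and acceptance suites

Tests run the discovery stack at 10⁴–3 × 10⁴ unique peptides and
2 × 10⁴–10⁵ reads per sample, the exhaustiveness comparison at ≤ 30
unique peptides with spans ≤ 6 (where full enumeration is feasible), the
hypergeometric check on every urn with N ≤ 60 against exact rational
arithmetic, and the pipeline end-to-end at 2 paired subjects plus
controls with 3 × 10³ unique peptides per sample. These sizes are the
package's chosen desk-scale study conditions; the algorithms themselves
have no size-dependent switches.

## Known limitations

* The core-epitope subsumption rule and the pattern grammar are this
  package's declared conventions; published exhaustive-search tools may
  group patterns differently.
* Marker selection reports apparent (resubstitution) performance only.
* The hypergeometric model treats a peptide present in both query and
  reference as two distinct urn elements (the sets are compared as
  labelled samples, not as a union).
* `reduce_to_core` is quadratic in the number of retained patterns and
  is intended for post-threshold result lists, not raw pattern spaces.
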