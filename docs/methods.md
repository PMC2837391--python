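# Methods

## The measurement model

MPSS produces, per library, a fixed number of 21-nt tag reads, each
beginning at the 3′-most DpnII site (GATC) of a transcript.  Each distinct
tag ("signature") proxies one transcript species and its read count is a
digital abundance measurement.  The pipeline treats a library as a
multinomial sample of fixed depth over tag species, which is also exactly
how the synthetic generator draws counts; per-library count sums therefore
equal the configured depth by construction.

## Signature QC and normalization

Tags containing any non-ACGT character are unreliable base calls and are
removed first; tags containing a homopolymer run strictly longer than 7 nt
(default `max_homopolymer_run`) are treated as synthesis/sequencing
artifacts and removed second.  The two filters commute and are idempotent.
TPM is computed on the post-sequence-QC table: TPM(i, ℓ) = x(i, ℓ) /
Σ<sub>j</sub> x(j, ℓ) × 10⁶, so before abundance filtering every library
column sums to 10⁶ exactly.  The abundance filter keeps signatures with
TPM ≥ 4 (default `min_tpm`) in at least one library and deliberately does
not recompute the totals: the denominator is defined by the deterministic
tag set, not by the retained subset.  "Unique"/"specific" in the library
summary use TPM > 0 on the retained set (expressed at all, not expressed
above 4 TPM); summary bins use ≥ thresholds.

## Differential expression

For each treatment library vs the control, each signature's TPM values are
rounded half-away-from-zero to integers and tested with a two-sided Fisher
exact test on [[x_t, S−x_t], [x_c, S−x_c]] with S = 10⁶.  The
implementation enumerates the hypergeometric support directly (log-space
point probabilities via `gammaln`, minimum-likelihood two-sided rule with a
1e-7 relative tie tolerance) and is checked in the tests against both an
exact-integer enumeration oracle and `scipy.stats.fisher_exact`.  Equal
counts return p = 1 exactly; p-values that underflow double precision are
floored at the smallest normal double so downstream BH input stays in
(0, 1].  BH adjustment (statsmodels step-up, verified against the textbook
definition) is applied within each library pair, and classification uses
adjusted p < 1E-10 (`strict_alpha`).  Signatures expressed in exactly one
library are reported as condition-exclusive instead of receiving a fold
change, which is undefined at zero.

Two caveats are intentional properties of the method rather than bugs:

* **Scale sensitivity.** The 2×2 table uses TPM-scale integers with totals
  fixed at 10⁶.  When the true sequencing depth is below 10⁶ the test is
  anticonservative (TPM noise exceeds what the table implies), and
  conservative above it.  The synthetic study conditions therefore use
  depth 10⁶ so TPM equals raw counts and the null is exact.
* **Compositional effects.** TPM is a proportion; planting strong
  expression changes (or hundreds of exclusive transcripts, as in the
  xenic condition) shifts every other signature's TPM through the
  denominator.  With a heavy-tailed abundance distribution this makes very
  abundant null signatures genuinely significant — in the data-generating
  sense the proportions really do differ.  Tests that assert exact
  called-set/planted-set equality use balanced, low-fraction designs where
  the compositional shift is orders of magnitude below the significance
  scale.

## Tag-to-unigene mapping

The published analysis used a heavily relaxed blastn search (word size 2,
e-value 10³) followed by rule-based validation; for fixed-length tags the
rules themselves define an exact computation, implemented here as an
exhaustive anchored scan: every GATC occurrence on either strand is a
candidate anchor, the 17-nt tail is compared by Hamming distance, and hits
with more than 3 mismatches (`max_mismatches`) are discarded.  Hits are
ranked by identity, ties broken by unigene id and then by the 3′-most
anchor position (MPSS tags derive from the 3′-most DpnII site).
Coordinates are 0-based on the reported strand.  The scan is verified
against a naive all-offsets oracle; a vectorized batch implementation is
hit-for-hit identical to the per-signature scan.  The compared region is
the full 21-nt signature; the length is configurable
(`MatchConfig.signature_length`) because published tag-length conventions
vary between 20 and 21 nt.

## Gene families

Family structure is inferred from the observation that recently duplicated
genes carry nearly identical 3′ tags.  On an annotated subset, all pairwise
Hamming distances are split into within-family and between-family
distributions; for every candidate threshold t the 2×2 table (≤ t vs > t ×
within vs between) is scored with a one-sided Fisher exact test for
enrichment of within-family pairs at ≤ t.  The chosen threshold is the
largest significant t among those minimizing total misclassification: in a
regime where within-family pairs reach 5 mismatches and between-family
pairs start at 6, this selects t = 5; with a wider gap it selects the top
of the gap.  Which test and selection rule produced the published
five-mismatch cutoff is not documented anywhere we know of, so the per-t
table is returned in full and the rule is explicit.  Genome-wide families
are single-linkage components of the ≤ t graph — the natural reading of "a
maximum number of pairwise mismatches" as a clustering rule; complete
linkage would not be transitive under tag chains.  Family ids are the
lexicographically smallest member, making the partition input-order
invariant.  All-pairs distances are computed by chunked numpy comparison;
at desk scale (≤ a few thousand tags) this is milliseconds and no indexing
is needed.

## Co-regulation

The family score is the mean pairwise Pearson correlation of member TPM
profiles over the four conditions, squared; for the two-member families
that dominate such screens this is the ordinary pairwise r².  Raw TPM (not
log) is the default profile scale, matching heatmap-style presentation; a
log2(TPM+1) flag exists.  Two "p-values" are reported: `p_convention` =
1 − r², which reproduces the published family tables row-for-row at their
printed precision but is not a calibrated test, and a permutation p
obtained by independently shuffling each member's condition labels
(B = 10,000 by default, seeded) and counting shuffles whose mean pairwise
correlation reaches the observed value, with the +1 correction keeping it
in (0, 1].  With only n = 4 conditions both numbers are screening scores,
not inference.  Members with constant profiles have undefined correlation
and are excluded with a warning.

## The synthetic generator

The generator defines the study conditions for all recovery tests.

* **Scale.** 2,000 genes and 10⁶ reads per library by default — desk-scale
  minutes while keeping TPM magnitudes in the same regime as the published
  worked examples (hundreds to thousands of TPM for abundant transcripts).
* **Abundance.** Baselines are log-normal (σ = 1.4 on the log scale),
  reproducing heavy-tailed abundance with tens of signatures above 1000
  TPM.  The true abundance law of the organism is unknown; log-normal is a
  modeling stand-in, not a claim.
* **Families.** Family sizes follow a geometric law (mean 2) over 250
  families, padded with singleton genes.  Member tags differ from their
  founder only within a family-private set of at most
  `within_family_max_mm` = 5 tail positions, so within-family pairwise
  distances are ≤ 5 by construction and reach 5 in practice.  Founders and
  background tags are admitted by greedy packing so that tags of different
  families are ≥ `between_family_min_mm` apart.  The default minimum
  separation is 6: one more than the within-family maximum, which already
  makes the planted partition exactly recoverable at threshold 5.
  Guaranteeing a separation of 8 for thousands of 17-nt tails is a
  sphere-packing regime that random tag sets do not occupy (the probability
  that two random tails sit closer than 8 is ≈ 3×10⁻³, so a 2,000-tag set
  has thousands of such pairs); configurations that need the ≥ 8 geometry
  (e.g. the wide-gap recovery tests) use it at a few hundred tags, where it
  exists comfortably.
* **Condition structure.** Per treatment, a configurable fraction of genes
  (default 5%) receives a planted signed log₂ fold change
  (0.5 + Exponential(1) magnitude by default).  Condition-exclusive genes
  (defaults 18/2/12/487 for F/N/P/X, the published counts) have expected
  TPM exactly 0 elsewhere and a floor of 25 TPM in their own condition so
  they are never lost to sampling or the abundance filter.  Because TPM is
  compositional, realized expected-TPM ratios differ from planted fold
  changes by the ratio of library totals (≈ 1–2% at the default DE
  fraction); the ground-truth table stores the exact post-normalization
  expectations.
* **Artifacts.** Three noise classes: tags with ambiguity codes, tags with
  homopolymer runs of 8–10 nt (both at 1% of gene count, 4–50 TPM, removed
  by sequence QC) and sub-threshold background tags (10% of gene count,
  2.5–3.9 TPM everywhere, mostly removed by the abundance filter).  Gene
  tags are constructed QC-clean, so no planted signal is lost to filtering.
* **Unigenes.** Each gene's unigene embeds its tag in a simulated 3′ UTR
  with no other GATC at or downstream of the tag, making the planted site
  the 3′-most DpnII site; upstream sequence is unconstrained and provides
  decoy anchors.
* **Determinism.** All randomness flows from one seed through named
  sub-streams (structure, tags, expression, noise, counts, sequences); a
  fixed configuration reproduces byte-identical output files.

What passing the recovery tests shows — and does not.  The generator
reproduces the statistical structure the analysis assumes: multinomial
counting noise at fixed depth, clean mismatch geometry, exact exclusivity.
Real MPSS libraries additionally contain overdispersion between biological
replicates (the study had none), sequencing errors inside tags, incomplete
digestion, and tags shared between paralogs — so sensitivity numbers on
synthetic data are upper bounds, and exact-partition family recovery will
not survive tags whose families overlap in sequence space (the published
data itself contains same-family tags with near-zero identity).

## Numerical conventions

Fold changes are reported internally as signed log₂ values at full
precision; printed-style display rounds to one decimal for large
magnitudes and two otherwise.  Fisher p-values use a 1e-7 relative tie
tolerance (the convention of mainstream exact-test implementations).
Ties in hit ranking and family ids are broken lexicographically.  Degenerate
inputs (empty tables, zero-total libraries, constant profiles, infeasible
family geometry) raise errors naming the offending record or constraint
rather than propagating NaNs.
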