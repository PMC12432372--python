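# Methods

This note records the statistical models implemented in `flgenomics`, the
conventions adopted where the underlying procedures leave freedom, and what
the synthetic cohorts do and do not establish about behaviour on real data.

## Substitution catalogs and signatures

Somatic SNVs are classified into 96 channels: six pyrimidine-centered
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) by the 5' and 3'
flanking bases. Purine-reference records are folded to the
reverse-complement channel; generated cohorts store ref/alt on the
reference strand (VCF semantics) and folding happens only at catalog
construction. Channel order is the lexicographic convention (substitution
blocks of 16; contexts sorted A, C, G, T) — files exchanged with other
tools must match it exactly, and readers reject rather than silently
re-sort.

**De-novo extraction.** The catalog X (samples × 96) is factorised by NMF
minimising the generalised Kullback–Leibler divergence with multiplicative
updates, the convention of the signature-extraction literature (a
Frobenius objective is available via `beta_loss`). Because the problem is
non-convex, each rank k is fitted from `n_restarts` (default 100) seeded
random initialisations; each restart's components are matched to the
best-error restart by cosine similarity (Hungarian assignment) and the
mean silhouette (cosine metric) of the pooled matched components measures
the rank's stability. The selected rank is the **largest k with stability
≥ 0.8** (fallback: the most stable k); `k=` overrides selection. This
stability rule is this package's own model-selection criterion; exposures
are emitted both as attributed counts and as per-sample proportions since
either convention is used downstream.

**Refitting.** Exposures against fixed profiles solve per-sample NNLS
min‖x − Se‖₂, e ≥ 0 (active-set solver). For mutually orthogonal profiles
this equals the clipped scalar projections, which the tests use as a
closed-form oracle; refitting is scale-equivariant and conserves counts up
to the reported residual.

**K1/K2 reference profiles.** The two kataegis signatures attributed to
AID and POLH are supplied as inputs. The bundled defaults are *synthetic*
fixtures: `K1-like` puts its mass on the 16 W[C>K]N channels (5' A/T, the
W of the AID WRCY hotspot motif; C>T weighted 2:1 over C>G) and `K2-like`
is T>N-dominated (T>C 0.6 / T>G 0.3 / T>A 0.1). Their disjoint supports
make NNLS mixture fractions exactly identifiable, which the dominance
statistics exploit. Any 96×2 TSV can be substituted via
`k_signatures_tsv`.

## Kataegis detection

Per sample:

1. **ADL** — one-tenth of the mean adjacent intermutation distance;
   distances are computed within chromosomes, never across boundaries, and
   pooled genome-wide (pooling, rather than per-chromosome averaging, is a
   documented choice). A distance exactly equal to the ADL counts as
   *above* (strict `<` defines clustered spacing) — conservative toward
   fewer calls.
2. **Window scan** — every run of `window_n = 10` consecutive
   same-chromosome mutations whose first-to-last span is ≤
   `max_span_bp = 10 000` (inclusive) contributes a 2×2 table: its 9
   internal adjacent distances split below/above the ADL versus the
   sample-wide split. Windows are all stride-1 runs, not disjoint blocks,
   and 9 (the internal distances), not 10, are counted per window. The
   background includes the window's own distances, mirroring a comparison
   against the *overall* sample distribution; `include_window_in_background
   = False` excludes them.
3. **Test** — one-tailed Fisher's exact p = the hypergeometric upper tail
   P(X ≥ a); candidates require p < 10⁻⁴.
4. **Merging** — candidates overlapping by a member mutation or ≥ 1 bp are
   chained transitively; the pooled run of member mutations is re-tested
   and kept merged only while the pooled p stays below threshold,
   otherwise the chain splits back greedily into maximal passing prefixes.
   Because windows may span up to 10 kb, a merged event can legitimately
   absorb an adjacent background mutation.

On uniform backgrounds (the simulator's null: positions uniform per
chromosome, hence approximately exponential spacings) the detector calls
essentially nothing — far below the nominal windows × 10⁻⁴ bound — and
planted runs of 10 mutations with adjacent gaps ≤ ADL/10 are recovered
essentially always. An independent brute-force caller (exact rational
hypergeometric sums, naive window enumeration and merging) reproduces the
event sets identically in the test suite.

**Dominance statistics.** Each event's member catalog is refit against
{K1, K2}; contribution = K1/(K1+K2) exposure (undefined and flagged when
both are zero). The per-sample mean is **unweighted by event size**;
samples split at the cohort median of these means (samples with ≥ 1 event
only): strictly above → K1-high, at or below → K1-low (so a single-sample
cohort is K1-low), no events → no-kataegis. Events are classed Ig:V /
Ig:S / Ig:J&C by BED overlap (largest overlap wins), otherwise
TSS-proximal when the event midpoint lies ≤ 2 000 bp (inclusive) from the
nearest annotated TSS, else TSS-distal.

## Lesion encoding and subtyping

Scores: nonsilent/indel 2, synonymous 1, none 0; SV 3; copy number at a
gain peak 2 if CN > 3.7, 1 if 2.4 ≤ CN ≤ 3.7; at a loss peak 2 if
CN ≤ 0.80, 1 if 0.80 < CN ≤ 1.6; anything else (including a loss at a gain
peak or vice versa) 0. The printed tier limits overlap at exactly 3.7 and
0.80 copies; this package resolves the boundaries as stated (3.7 →
low-grade gain, 0.80 → high-grade loss). Negative copy numbers are errors;
CN in (1.6, 2.4) is neutral, not an error. Encoding is a pure function of
the calls; duplicate (sample, marker) records collapse to the maximum
score.

**Consensus clustering.** For each K in 2…10, `n_runs` (default 100)
Frobenius NMF factorisations from seeded random initialisations each
assign every sample to its maximum-loading factor; consensus(i,j) is the
co-assignment fraction. The cophenetic coefficient — Pearson correlation
between the 1−consensus distances and the cophenetic distances of their
average-linkage dendrogram — selects K (ties → smaller K, for parsimony);
final labels cut that dendrogram at K. Degenerate cases: a 2-sample
matrix has a single distance, reproduced exactly by any dendrogram
(coefficient 1 by construction); identical distances everywhere leave the
correlation undefined (NaN, and that K is skipped in selection). Raw 0–3
scores are clustered unscaled; all-zero samples are retained (they carry
no loading signal and are placed by the hierarchical step, listed in
`zero_samples`).

**Markers.** Per (marker, cluster): 2×2 table of lesioned (score > 0, so
synonymous counts — the dichotomisation is configurable in spirit but > 0
is the default) versus intact, in-cluster versus rest; two-sided Fisher's
exact test, assignment at p ≤ 0.05 **and** in-cluster odds ratio > 1
(`alternative="greater"` gives the one-sided variant). The full table
including non-significant rows is always emitted. New samples are
assigned by nearest centroid in score space under cosine distance; an
all-zero row has no direction and is assigned to the smallest-norm
centroid with a low-confidence flag.

## Group comparisons

Continuous variables: two-sided Mann–Whitney rank-sum. Groups of ≤ 10
observations each use exact enumeration of all assignments (ties handled
by computing U on the actual values; two-sided p = probability of a
deviation |U − n₁n₂/2| at least as large). Larger groups use the
tie-corrected normal approximation **without** continuity correction: the
corrected variant is measurably conservative at moderate n (exact type-I
0.0479 vs 0.0496 at 30 per group), and the uncorrected approximation is
the better-calibrated choice. Categorical variables use chi-square or
(2×2) Fisher's exact test.

## The synthetic cohort generator

The generator emulates exactly the structure the analyses assume:
per-sample Poisson mutation counts around `background_rate` (the real
cohort reports only per-megabase means, so the rate is a parameter, not an
asserted distribution), uniform placement per chromosome (exponential
spacings — the detector's null), channel identities drawn from per-sample
signature mixtures with the generating signature recorded per record,
planted kataegis runs, and lesion matrices with cluster-enriched markers
(own-cluster lesion probability 0.9 vs 0.05 background by default,
~127 markers × ~120 samples in the recovery studies, mirroring the
dimensions of the real marker matrix). CNV details are sampled half from
each scoring tier so every encoding branch is exercised.

Two placement modes: without a genome, contexts are synthesised from the
sampled channel and stored on a random strand (exercising the folding
path); with a reference genome, positions are drawn from
context-matching sites. Planted clusters without a source signature use
gap-bounded geometry (adjacent gaps uniform in [1, max_span/(n−1)]), which
guarantees the spacing needed for recall studies; context-matched plants
guarantee only the overall span.

**What passing tests do not show:** the generator has no indels, no
purity/ploidy distortion, no mapping artifacts, no germline leakage (so no
analogue of a germline-associated signature), uniform rather than
replication-timing-dependent mutation rates, and independent markers
within clusters. Recovery results on it are necessary, not sufficient,
evidence about patient genomes.

## Problem sizes and numerical choices

The test suite runs the oracle-equivalence study on 50 samples × ≤ 2 000
mutations, calibration/recall on 200 × 2 000 and 500 planted samples,
signature recovery on 30 × 3 000 mutations, and the subtype-recovery sweep
on 50 master seeds of a 127 × 120 matrix with 30 consensus runs per rank —
sizes chosen so the full suite completes in a few minutes while keeping
every estimate's Monte-Carlo error far below the asserted margins.
p-values are compared against exact rational summation at 10⁻¹⁰–10⁻¹²
absolute; NNLS against closed forms at 10⁻⁶. The type-I calibration
designs (30 per group for rank-sum; 350 vs 353 binary at rate 0.5 for
Fisher) were selected by computing the discrete tests' exact rejection
rates: unbalanced Fisher groups break the hypergeometric pmf ties that
otherwise cap the achievable level near 0.046.

Known limitations: the exact K-selection rule used for the original
signature extraction is not public, so the stability rule above is this
package's documented stand-in; the true K1/K2 vectors are likewise
unpublished (synthetic fixtures stand in); merging very long candidate
chains re-tests pooled prefixes greedily rather than optimally; and NMF
restarts make extraction only approximately permutation-symmetric at
finite restart counts.
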