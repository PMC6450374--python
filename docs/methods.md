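# Methods

## Genetic model

All computations assume a biparental F2 intercross segregating a single
recessive causal allele, with every mutant-parent allele in coupling phase
(the F1 carries one intact mutant-parent homolog). Gametes recombine
between adjacent loci independently with the stated recombination
frequency (RF, α ∈ [0, 0.5]); no crossover interference is modelled, since
every statistic used is two-point. Phenotype is fully penetrant: a plant
is recessive iff it is homozygous mutant at the causal locus.

Conditioning the 16 equiprobable gamete pairings of a plant on its
phenotype class gives the per-plant marker genotype distributions used
throughout (recessive class: (1−α)², 2α(1−α), α²; dominant class:
α(2−α)/3, 2(1−α+α²)/3, (1−α²)/3 for 2/1/0 mutant-parent alleles). The
dominant-class expressions are a derivation this package makes explicit
and validates against a brute-force gamete-pairing enumeration in the test
suite; only the recessive case is commonly quoted.

## Pooled read-count likelihood (`pooled_rf`)

For a bulk of n plants, G (the mutant-parent allele count among 2n
chromosomes) is the n-fold trinomial sum of the per-plant distribution,
computed by convolution and cross-checked against the direct trinomial sum.
Reads are modelled in two stages: the library's mutant-read fraction
Γ ~ Beta(G·ξ, (2n−G)·ξ) captures unequal tissue contributions of the
pooled plants, and M ~ Binomial(c, Γ) the sequencing draw — together a
beta-binomial with overdispersion factor 1 + (c−1)/(2n·ξ+1).

Numerical and boundary choices:

* **Boundary G ∈ {0, 2n}.** Beta(0, ·) is undefined; we use the limiting
  point mass Γ = G/(2n), so P(M=m|G=2n) = 1{m=c} and P(M=m|G=0) = 1{m=0}.
  Generator and likelihood use the same convention, so simulated data are
  exactly distributed under the fitted model.
* **ξ (mixing accuracy, dimensionless, default 10).** No published value
  exists for tag-seq root pools; ξ = 10 gives Γ a standard deviation of
  ≈0.03 around 0.9 for a 5-plant pool with one heterozygote — visibly
  overdispersed relative to binomial sampling, which matches the motivation
  for the Beta stage (mixing noise matters for small n). It is exposed as a
  user parameter everywhere; sensitivity: larger ξ narrows CIs and makes
  the exclusion test stricter, ξ → ∞ recovers the plain binomial.
* **Maximisation.** Log-likelihood on a dense α grid (step 1e-4, vectorised
  over the grid with per-(n, class) cached G-distributions), then bounded
  scalar refinement around the best grid point. Deterministic; no random
  restarts. Estimates are capped at 0.5 — repulsion is not modelled because
  the cross design fixes coupling phase.
* **Confidence interval (default 80%).** Profile likelihood-ratio set
  {α : 2(ℓ(α̂) − ℓ(α)) ≤ χ²₁(0.80) = 1.642}, reported as the connected
  interval containing α̂, intersected with [0, 0.5]; interval ends are
  interpolated linearly between grid points. At the α = 0 boundary this
  reproduces the truncated "(0–x]"-style intervals expected for perfectly
  linked SNVs. Simulated calibration at α = 0.1 (4 recessive pools of 5,
  c = 100, ξ = 10) is close to nominal (the acceptance test bounds it in
  [0.70, 0.90]).
* **LOD** = (ℓ(α̂) − ℓ(0.5))/ln 10, clipped at 0.
* **Pools with c = 0** contribute a constant to the likelihood and are
  inert; an SNV whose every pool has c = 0 is returned flagged undefined
  rather than raising.

### Improbable-ratio exclusion test

Cross-library read contamination ("index hopping") produces wrong-parent
reads that can mimic or distort linkage. The exclusion statistic: for each
pool, the exact tail probability min(P(M ≤ m), P(M ≥ m)) under the
G-marginalised beta-binomial at a given α; an SNV is excluded iff **no**
α ∈ [0, 0.5] (scanned on a 101-point grid) makes every pool's tail clear
the threshold (default 1e-3). The smaller tail is used without doubling:
the test asks whether the observation is extreme in *some* direction, and
doubling would let genuinely impossible configurations (an all-wild-type
pool among all-mutant pools) slip past the threshold at α = 0.5 on a
factor-of-two technicality.

A known, deliberate property: a *single* pool showing ~7% wrong-parent
reads alongside clean pools is **not** excluded. One heterozygous plant
(G = 2n−1) puts the Beta mean at 0.9 with SD ≈ 0.03, so m/c ≈ 0.93 is
plausible at any α above ~0.005 — the contamination is statistically
indistinguishable from loose linkage and biases α̂ upward instead of
failing the test. This matches the observed behaviour of pooled mapping in
practice (hopped libraries inflate RF estimates of the closest markers);
only patterns irreconcilable at every α (e.g. wrong-parent reads where the
model forces fixation) are excluded.

## SNV filtering (`snv_filter`)

Three rules, applied in the fixed order qual → type/novelty → coverage so
rejection counts are reproducible; each record carries exactly one primary
reason. Coverage uses total site depth (both counted alleles) and must
clear the threshold in every library, parents and pools alike. Parental
origin is assignable when each parent library is near-homozygous (minor
allele fraction ≤ 0.1, configurable) for a different allele; failure is
the "novel variant" rejection, not an error. Pool counts keep only the two
parental alleles: m = mutant-parent-allele depth, c = m + wild-type-allele
depth. Coordinates are 1-based transcript positions (VCF convention); no
liftover or strand normalisation.

## Individual-plant linkage (`cosegregation`)

Six-cell tables use the multinomial cell probabilities (1−α²)/4,
(1−α+α²)/2, α(2−α)/4 | α²/4, α(1−α)/2, (1−α)²/4 (A = wild-type-parent
allele). ML by dense grid (1e-4) plus bounded refinement. χ² statistics
are plain goodness-of-fit without continuity correction — 3:1 for
phenotype (df 1) and the 3:6:3:1:2:1 joint expectation for the six cells.
LOD at the MLE versus α = 0.5 is reported as missing (NaN) when α̂ = 0.5,
where the ratio is identically 1.

Phase is taken from the allele-origin coding supplied by the caller, not
inferred from the data: an unlinked marker can produce a repulsion-looking
table by sampling noise, and such tables must legitimately return the
capped estimate 0.5 rather than an error.

Marker–marker RFs come from the 3×3 codominant joint table under the
independent-gamete model; ordering of ≤10 loci is exhaustive minimisation
of summed adjacent RFs with canonical orientation (first locus name sorts
before last) and lexicographic tie-breaks. Map distance is 100·RF cM with
no mapping function, appropriate for the short intervals this screen
produces.

## Simulator (`synthetic_data`)

The generator draws plants as pairs of Markov-chain gametes, composes
bulks without replacement within phenotype class, and draws reads from
exactly the boundary-respecting beta-binomial above — so estimator
round-trips are exact-model recovery exercises. Defaults mirror the
motivating experimental design: four recessive bulks of 5 plants, two
dominant bulks of 6, coverage ~100, ξ = 10. Index hopping replaces each
read with probability `hop_rate` by a read drawn from the
coverage-weighted mutant fraction of the other libraries.

What the simulator does **not** emulate: read-level errors (sequencing,
mapping, demultiplexing), variable coverage across SNVs within a library,
linked SNVs sharing a transcript, segregation distortion, and phenotyping
error. A green round-trip therefore establishes correctness of the
statistical machinery under its own assumptions, not robustness to those
real-data artefacts.

## Variant effect and CAPS screening (`marker_design`)

Restriction-site search expands IUPAC ambiguity codes to regex classes,
matches both strands via the reverse-complement motif, reports overlapping
hits, and counts palindromic sites once. Diagnosis uses fragment-length
multisets (cut positions approximated by motif starts) — stricter than a
site-count comparison and sensitive to indels shifting downstream sites;
true cleavage offsets are enzyme metadata deliberately out of scope, so
reported lengths are pattern proxies, not gel-calibrated sizes. Premature
termination is flagged when the mutant translation ends before the residue
aligned to the reference stop, or when a frameshift scrambles the tail and
loses the stop codon entirely; a deletion whose shifted frame re-encodes
the same protein is not flagged.

## Reporting (`reporting`)

RF ranking is ascending by point estimate, ties by LOD descending then id,
excluded SNVs listed separately. The candidate search interval widens the
anchor-gene span by `factor` × span on each side (interpretation of
"tripling the distance up and down the chromosome": 3× the span added per
side), half-open and clipped at 0. Differential-expression input is an
externally produced table (DESeq2-style padj and log2 fold change);
significance is strict padj < 0.05, missing padj is reported in its own
"not calculated" bucket.

## Known limitations

* Per-SNV estimates treat SNVs independently; no multi-locus smoothing.
* The exclusion test cannot detect single-library contamination below the
  level that contradicts every α (see above) — by design, documented.
* Exhaustive map ordering refuses >10 loci.
* The mixing coefficient ξ is not estimated from data; it is a modelling
  input.
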