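# Methods

This note documents the models, conventions and design choices behind
`esnvsig`, in the spirit of the methods documentation of packages such
as statsmodels or msprime: enough detail that a reader can predict what
the code computes without reading it.

## The analysis model

The pipeline assumes that the expressed single-nucleotide variants
(eSNVs) observed in a tumor's RNA-seq are, after artifact filtering, a
sample from a mixture of mutational processes, each process being a
fixed probability distribution over the 96 substitution-in-context
channels. For a cohort, the channel-count matrix V (96 × N) is modeled
as V ≈ W·H with W ≥ 0 the process signatures (columns sum to 1) and
H ≥ 0 the per-sample mutation counts attributed to each process.
POLE-exonuclease-deficient tumors are then recognizable by a large
contribution from the signature resembling COSMIC v2 signature 10
(TCT>TAT, TCG>TTG enriched), quantified as a tumor mutation burden:

    TMB_k(s) = H[k, s] / capture_bases(s) × 10⁶   [mut/Mb]

where the capture region of a sample is the set of positions with
sequencing depth ≥ 20×. Samples whose POLE-signature TMB exceeds the
upper Tukey fence of the cohort distribution are called hypermutated,
and the call is corroborated by expressed POLE hotspot mutations.

## Filtering conventions

All thresholds are read literally and implemented with the stated
strictness; each is a parameter with the default shown:

| rule | default | comparison |
| --- | --- | --- |
| variant quality score | 0.10 | strictly greater than |
| read depth | 10 | strictly greater than (depth 10 is removed) |
| population allele frequency | 0.02 | strictly less than; missing AF = novel |
| panel of normals | — | exact (chrom, pos, ref, alt) membership |
| capture depth | 20 | at least (≥ 20× counts) |
| minimum capture size | 5,000,000 | samples below are excluded |

Removed variants are attributed to the first failing rule in the order
quality → depth → population AF → panel, so per-rule counts partition
the input; the order is a reporting convention only and does not affect
which variants survive. The quality score is interpreted as a score
value in [0, 1] compared against 0.1 (a percentile interpretation would
require the score distribution, which a VCF does not carry); the
threshold is configurable for either reading. The panel of normals is a
site list; when raw normal variant sets are given, a site is recurrent
if seen in ≥ 2 distinct normals — the minimal definition. Multi-allelic
VCF rows are split into biallelic records before filtering.

## Channels

Channel order is the standard catalog order: substitution blocks C>A,
C>G, C>T, T>A, T>C, T>G; within a block the 5' flank varies slowest and
the 3' flank fastest, each in A, C, G, T order. Purine-reference
substitutions are reverse-complemented before classification; the
involution property (classifying from either strand gives the same
channel) is tested exhaustively over all 4³ × 3 cases. Variants whose
context cannot be resolved (an N base, or a missing flank at a contig
edge) are skipped and tallied per sample, never guessed, so column sums
plus skips always equal the filtered variant count. A variant whose REF
base contradicts the reference sequence is a hard error, not a skip.
Counts, not proportions, are factorized so the count scale survives
into H and hence into TMB.

## KL-NMF

The factorization minimizes the generalized Kullback–Leibler divergence
D(V‖WH) = Σ V log(V/WH) − V + WH by Lee–Seung multiplicative updates,
the algorithm family behind the R implementations commonly used for
signature extraction. Details:

* **Initialization**: entries uniform(0, 1) scaled by √(mean(V)/K);
  `n_restarts = 30` by default, best final objective wins, ties to the
  lowest restart index. Fully deterministic given `random_state`
  (restart streams are spawned from one seed sequence).
* **Stopping**: relative objective decrease per iteration < `tol`
  (default 1e-6) or `max_iter` (default 2000).
* **Numerical guards**: 1e-12 added inside divisions and logs; the
  objective uses the 0·log 0 := 0 convention and is tested to be
  non-increasing at every iteration of every restart.
* **Normalization**: after convergence W columns are scaled to sum 1
  with the scale absorbed into H, so Σ_k H[k, s] ≈ the sample's count
  (conserved within a few percent at stationarity).
* **Degenerate input**: all-zero samples are excluded from the fit and
  reported (`dropped_samples`), re-inserted as zero columns of H; an
  all-zero matrix or rank exceeding the non-empty sample count is an
  error.
* **Rank**: fixed at 4 by default to mirror the four-process structure
  of the motivating analysis; exposed as a parameter, with no automatic
  rank selection. A median per-sample reconstruction cosine below 0.8
  triggers a logged warning suggesting the rank is too small.

`KLNMF` follows the scikit-learn estimator contract (`fit`,
`fit_transform`, `transform` with frozen components, `components_`,
`get_params`/`set_params`), so it composes with sklearn tooling;
`nmf_factorize` wraps it in the domain's channels × samples orientation.

## Matching and calling

Cosine similarity on non-negative 96-vectors lies in [0, 1]; zero
vectors are an error rather than a silent 0. Catalog ordering for
heatmaps uses average-linkage (UPGMA) hierarchical clustering on
1 − cosine. Best-match reporting enforces no threshold; the decision
threshold lives in the calling layer, where the extracted signature
most similar to the catalog's POLE entry is accepted only at cosine
≥ 0.8 (configurable); otherwise the pipeline reports zero POLE calls.

Outlier calling uses linear-interpolation quantiles (the common
statistical-software default) and flags values strictly above
Q3 + 1.5·IQR. Only the upper fence triggers calls — hypermutation is
one-sided — and the fence actually used is stored per call so calls are
reproducible from the output alone. A fixed threshold override is
supported for users who prefer a published cutoff (e.g. 5 mut/Mb on
real data). The fence population is all retained samples in the run;
cohort labels are not treated specially.

Hotspot confirmation is an exact (chrom, pos, ref, alt) match between
filter-passing variants and a user-supplied hotspot table. No human
genomic coordinates are hardcoded: real-data users must supply
coordinates on their own assembly.

## Statistics

Mann–Whitney U is computed from rank sums with midranks for ties and
satisfies U_x + U_y = n_x·n_y. The two-sided p-value is exact —
min(1, 2·min(P(U ≤ u), P(U ≥ u))) over all rank assignments — when the
pooled size is ≤ 12 with no ties, and otherwise a normal approximation
with tie-corrected variance and a 0.5 continuity correction, clipped to
(0, 1]. The Fisher exact test enumerates the hypergeometric support and
sums probabilities ≤ the observed table's (with 1e-7 relative slack
against floating-point ties): the point-probability convention of
standard statistical environments. Both are validated in the test suite
against exhaustive enumeration oracles (all inputs with pooled n ≤ 10)
and against an independent implementation, and the Mann–Whitney type-I
error is calibration-tested at α = 0.05 over 1,000 null replicates.
Group summaries use the arithmetic mean and linear-interpolation
quantiles.

## The synthetic cohort generator

The generator emulates the data a real study of this kind consumes —
per-sample VCFs with quality/depth/population-AF annotations, per-base
coverage, a panel of normals built from synthetic normal tissue,
POLE hotspot spikes, and clinical annotations — with full ground truth.
Mutations are drawn hierarchically (per-signature counts from the
sample's mixture weights, then channel counts from each signature) and
placed uniformly at unused reference positions whose context matches
the drawn channel on either strand, so channel recomputation from the
written FASTA + VCF round-trips exactly. Planted filter failures each
violate exactly one rule; panel artifacts occur in ≥ 2 of the synthetic
normals; hotspots are assigned cyclically so some samples share a
hotspot, as in real POLE cohorts. Identical config and seed give
byte-identical output files.

Default study conditions (chosen once; all configurable):

* 195 samples, 6 hypermutated, on a 100 kb reference at GC 0.41 with a
  contiguous ~50 kb capture window per sample (≥ 20× inside, < 20×
  flanks). Dense per-base coverage files make multi-Mb captures
  impractical at desk scale, so the genome is scaled down; TMB
  arithmetic is scale-free, which means *absolute* mut/Mb values in
  synthetic runs are inflated by the small denominator and only
  contrasts are meaningful. The pipeline's synthetic `min_capture`
  default (10,000) is scaled accordingly; the filtering function itself
  defaults to the real-data 5,000,000.
* A four-signature synthetic catalog (`synthetic_signature_catalog`):
  a POLE-like column concentrated on T[C>A]T (0.45) and T[C>T]G (0.10)
  — the exonuclease-deficiency character, kept strongly C>A-dominant so
  it remains identifiable against the CpG-deamination aging-like column
  (C>T at NCG) — plus a broad-C>A tobacco-like column and a
  near-uniform flat column. These are synthetic stand-ins with the
  *character* of known processes, not published catalog values; real
  COSMIC v2 TSVs are accepted wherever a catalog is read.
* Hypermutated samples: 400–900 mutations at 75–90% POLE-like weight.
  Background samples: ~Poisson(200) mutations with a POLE-like
  contribution whose expected count is uniform on [0, 48]. The
  background POLE attribution is deliberately a compact, light-tailed
  distribution: NMF attribution noise on a few-hundred-mutation sample
  has a worst-case tail of roughly 15–20 counts across a 189-sample
  null, and the Tukey fence is only a sound separator when the null's
  genuine spread dominates that tail. With these conditions the
  outlier set, the planted set and the hotspot-positive set coincide
  robustly across seeds.
* Clinical annotations mirror a mixed ovarian-carcinoma cohort
  (histology mix ~60% serous / 22% endometrioid / rest other; ages
  ~N(61, 12)); hypermutated samples are endometrioid with early onset
  (~N(48, 2)), enabling the age and histotype comparisons downstream.

What passing synthetic tests do **not** show about real data: RNA-seq
artifact structure beyond the four modeled failure classes (e.g. RNA
editing beyond the panel mechanism, allele-specific expression,
strand bias), realistic genome composition and context frequencies,
multi-Mb capture regions, real COSMIC signature collinearity (flat
signatures 3/5/8 are far harder to separate than the synthetic
catalog), or calibration of the absolute 5 mut/Mb clinical cutoff.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use: the 195 × 6 default
cohort above for end-to-end concordance; 200 samples × 500 mutations
from 3 signatures for de novo recovery (each true signature recovered
at cosine ≥ 0.95 after optimal assignment; median per-sample
reconstruction cosine ≥ 0.90); rank-1 exact recovery to 1e-3 relative
error; and 1,000 null replicates at n = 25 + 25 for type-I calibration.

## Known limitations

* KL-NMF is non-convex; restarts mitigate but do not eliminate local
  optima, and signatures present at low levels or collinear with others
  may be split or merged (small cohorts with rank ≥ the number of real
  processes can dedicate a component to a single hypermutated sample).
* The Tukey fence is distribution-sensitive: on a strongly skewed null
  it will flag heavy-tail values that are not biologically hypermutated;
  the fixed-threshold override exists for exactly that situation.
* Exact Mann–Whitney is only attempted for tie-free pooled n ≤ 12;
  elsewhere the normal approximation is used, which is what mainstream
  software does but is approximate for small tied samples.
* The published per-signature cosine similarities and the 5.74 mut/Mb
  fence value depend on cohorts that are not publicly deposited and are
  not reproduced here; the package reproduces the *procedure* and its
  arithmetic, validated on synthetic ground truth.
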