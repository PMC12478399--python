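# Methods

`svscape` analyzes cohorts of curated somatic structural variants (SVs).
Each SV is a pair of stranded breakpoints plus a type (DEL, DUP, INV on one
chromosome; TRA across two). This note describes the models behind each
stage, the parameters that matter, and what the synthetic-data validation
does and does not demonstrate.

## Breakpoint hotspot detection

**Model.** Both breakpoints of every SV (including both ends of a
translocation, each on its own chromosome) enter a pooled cross-sample
breakpoint field. For each breakpoint we compute the distance to the
nearest breakpoint on the same chromosome *from a different sample*;
intra-sample neighbors are ignored so that one tumor's clustered
rearrangement cannot fake recurrence.

In a cohort containing recurrent loci this distance distribution is
bimodal on the log scale: a tight mode from breakpoints that recur at the
same coordinates across patients, and a diffuse mode whose location
reflects overall burden. We fit a two-component Gaussian mixture to
log10(d + 1) by EM (deterministic k-means++ initialization, tolerance
1e-8, up to 500 iterations) and take the joining cutoff as the largest
integer distance still assigned to the tight component (posterior 0.5
crossing, evaluated as a log-density comparison so degenerate point-mass
fits cannot underflow). When the components do not separate — either
weight under 0.01 or means within 0.25 log10 units — we fall back to the
package default of 98 bp, the value this procedure settles at on the
pediatric pan-cancer cohort the pipeline was designed around. At least 100
finite distances are required for the fit; smaller inputs should use the
fixed cutoff.

Breakpoints whose cross-sample nearest-neighbor distance is within the
cutoff are chained into segments by single linkage (consecutive sorted
positions join while the gap stays within the cutoff); singletons are
dropped. Each segment of `n` breakpoints and length `L = end − start + 1`
is scored against a Poisson null with rate

    λ = max(L, cutoff) / cutoff,

i.e. one expected breakpoint per cutoff distance, and p-value
`P(X ≥ n)` under Poisson(λ) via the survival function. Benjamini–Hochberg
correction is applied genome-wide in one family; hotspots are segments
with q < 0.05 carrying breakpoints from at least two samples.

**Why the length floor.** Segments are data-selected dense runs. A
two-breakpoint segment of length 3 bp would receive λ ≈ 0.03 and an
artificially small p-value purely because the pair was selected for being
close; analytically, BH over such segments rejects ~9% of tested segments
on homogeneous-background cohorts. Testing every segment against a window
no narrower than the cutoff removes this selection artifact: null cohorts
then produce essentially zero calls, while genuine hotspots — which carry
many breakpoints against the same λ — are unaffected. The floor is
configurable (`min_length_bp`).

**Tail convention.** The enrichment statistic is the upper-tail
probability, not the pmf at the observed count: a point mass is not a
p-value, and the tail preserves the monotonicities an enrichment test
needs (non-increasing in `n`, non-decreasing in length). `n` counts
breakpoints; the distinct-sample count is reported alongside and filtered
at ≥ 2.

## Hotspot annotation

Classification uses 75% majority rules, with ties at exactly 75% passing:

* **dominant type / category** — label carried by ≥ 75% of member SVs (an
  SV with both ends inside counts once), else OTH / "multiple";
* **immune** — ≥ 75% of member breakpoints within 1 Mb of an antigen
  receptor locus (IGH, IGK, IGL, TRA, TRB, TRD, TRG or an orphan-receptor
  region; shipped as an editable hg19 BED asset, since no canonical
  machine-readable list exists);
* **RSS** — ≥ 75% of member breakpoints within 20 bp of a retained
  recombination signal sequence site.

RSS sites are consumed from precomputed RIC-score tables: sites are kept
when their raw RIC score meets the spacer-type threshold (−38.81 for
12-spacer, −58.45 for 23-spacer sites), scores are re-expressed as
`adjusted = raw − threshold ≥ 0`, and overlapping retained sites merge to
the union interval keeping the best adjusted score. RIC computation itself
is out of scope. A scanner reports exact matches of the RAG heptamer
CACAGTG (and reverse complement) on supplied sequence; hotspot intervals
are padded 20 bp per side before scanning. "Member breakpoints" means the
breakpoints inside the hotspot only, not the partner ends of member SVs.

## 32-channel SV catalog

Channels are SV type × size bin × intra-sample clustered status: {del,
dup, inv} × {1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, > 10 Mb} × 2, plus
clustered/non-clustered translocations — 32 in total. Bins are
lower-inclusive/upper-exclusive (a 10,000 bp deletion is 10–100 kb);
intra-chromosomal SVs under 1 kb are filtered before classification.

Clustered status is decided per sample: per chromosome, sorted
inter-breakpoint gaps are segmented by a piecewise-constant fit (binary
segmentation on log10 gap with a BIC acceptance rule, 2·log N penalty per
changepoint), and a breakpoint is clustered when its segment's mean gap is
below one tenth of the sample's genome-wide mean gap; an SV is clustered
if either end is. The 1/10-of-mean criterion follows the
rearrangement-signature convention this channel scheme derives from; the
ratio and the segmentation penalty are configurable because upstream
implementations do not publish theirs. The criterion is scale-equivariant.
Samples need at least 20 post-filter SVs to enter the signature matrix;
low-burden samples mostly add multinomial noise.

## Signature extraction

KL-divergence NMF (the maximum-likelihood factorization for Poisson
counts) with multiplicative updates, tolerance 1e-9, up to 10,000
iterations, random non-negative initialization per replicate. For each
candidate rank k the matrix is Poisson-bootstrapped per replicate
(resampled counts `V' ~ Poisson(V)`, the standard perturbation for
count matrices); replicate signatures are pooled and clustered by
partition around medoids on cosine distance; the mean silhouette of that
clustering is the stability of k, the medoids are the reported profiles,
and reconstruction error is the mean KL divergence of replicate fits
against the observed matrix. For k = 1, stability is the mean cosine of
replicate profiles to the medoid.

The selected rank is the largest k with stability ≥ 0.80 whose mean
reconstruction error improves on k − 1 by more than 1% relative; k = 1
needs only the stability condition, and when nothing qualifies the method
returns k = 1 with a warning. Both thresholds are explicit, configurable
stand-ins for the undocumented composite criteria of upstream signature
tools. The default replicate count is 100 (configurable; recovery on
clean synthetic mixtures is already stable at ~20–30, which the test
suite uses).

Exposures are per-sample non-negative least squares against fixed
profiles. A per-sample reconstruction cosine guards downstream calls: a
sample is *positive* for a signature only when at least one SV is
assigned to it **and** the sample's reconstruction cosine is ≥ 0.80;
low-cosine samples count as negative for every signature but remain in
prevalence denominators, so poor fits cannot inflate prevalence.

Extracted profiles are compared to a reference catalog by cosine
similarity, considering both single references and the best non-negative
two-reference combination; a match requires cosine ≥ 0.80 and the best
cosine is always reported. The packaged catalog
(`reference_signatures.synthetic.tsv`) is a synthetic stand-in whose ten
profiles echo the qualitative character of the published rearrangement
signatures; it validates the matching machinery and must be replaced with
a licensed catalog for substantive claims about real cohorts.

## Chromothripsis screen

Two numeric criteria per sample and chromosome:

1. ≥ 6 interleaved intra-chromosomal SVs and ≥ 7 contiguous copy-number
   segments oscillating between two (integer-rounded) states;
2. ≥ 3 interleaved intra-chromosomal SVs, ≥ 4 inter-chromosomal SVs with
   an end on the chromosome, and the same oscillation run.

Interleaving means partial interval overlap — intersecting without either
containing the other; nested deletions are not interleaved. The oscillation
statistic is the longest contiguous run alternating between any two
states. The statistical refinements of dedicated callers (fragment-join
test, chromosomal enrichment, exponential breakpoint-spacing test) are
intentionally omitted: this is a sensitivity screen whose positives merit
review, not a high-confidence caller, and cohort-level chromothripsis
percentages should not be quoted from it. Missing copy-number data is
flagged and fails both criteria rather than guessing.

## Evolution grouping

For patients with several spatiotemporally distinct samples, the same
physical rearrangement may be reported with coordinates a few bp apart.
SVs are matched across samples when type and chromosomes agree and both
breakpoints lie within a tolerance (default 10 bp), transitively closed
with union–find; the lexicographically smallest record represents each
group. Junction-read re-counting against raw reads would be more
sensitive but requires BAMs, which are out of scope; externally computed
support counts are accepted as optional input. Groups follow from the
presence pattern: truncal (all samples), shared:<subset> (≥ 2 but not
all; subset keys canonicalized by sorted sample id), private:<sample>.
Per-group 32-channel proportion profiles flag groups under 20 SVs as
low-confidence instead of suppressing them.

## Burden and driver annotation

Per-cancer-type burden medians include zero-SV samples. TP53
stratification uses a two-sided Wilcoxon rank-sum test, restricted to
types with at least three TP53-altered samples. The age–burden
association is Pearson's R (the convention in comparable burden analyses
reporting "R"; Spearman is available as an option since the estimator is
not universally fixed). Genic annotation marks genes containing either
breakpoint and flags common fragile site genes from an editable BED.

Regulatory (cis-activation) annotation evaluates locus rules from a YAML
config — one pure predicate per rule over a single SV record, covering
MYC enhancers (NME, BENC — duplications), PVT1 and CEBPD (translocations),
TAL1/STIL deletions, DUX4–IGH translocations, TERT rearrangements with a
gene-body exclusion, GFI1/GFI1B, BCL11B (downstream duplication or
enhancer-partner translocation), SNCAIP (≤ 1 Mb), FLT3 (deletions < 1 Mb,
strict), MECOM flanks, and CRLF2. Two printed source intervals are
internally inconsistent (TERT upstream bounds reversed; a GFI1B bound
beyond the chromosome end); the config normalizes them and marks both
REVIEW. Rules are independent by construction: removing one never changes
another's verdict.

## Synthetic cohorts

The generator produces the structures the analysis assumes, each SV
carrying exactly one origin label:

* **background** — per-sample Poisson SV counts (rate expressed as
  breakpoints per Mb; uniform positions; 12% translocations; spans
  log-uniform 1 kb–10 Mb); optionally per-type median burdens spanning
  ~100-fold (OS 245 … LGG 2) to emulate realistic cohort heterogeneity;
* **planted hotspots** — an anchor/partner pair hit by a chosen number of
  samples with Normal jitter (default SD 10 bp, matching recombinase
  cleavage within ~20 bp of its motif) producing 10 kb–1 Mb deletions,
  optionally co-located with planted RSS intervals;
* **chromothripsis bursts** — 2n sorted points in a region joined i→i+n,
  a chain of guaranteed mutually interleaved fragments, with copy-number
  segments alternating between two states;
* **signature mixtures** — channel draws ∝ exposure·profile, materialized
  as SVs consistent with the channel (clustered channels share per-sample
  cluster centers so the clustering detector sees genuine density);
* **multi-sample patients** — truncal/shared/private sets with a chosen
  strict shared subset.

Randomness derives from one cohort seed with fixed per-component child
streams, so adding a component never perturbs another. The background is
homogeneous: no mappability, replication timing, or chromatin covariates.
Passing tests therefore demonstrate calibration and recovery under the
homogeneous null and clean planted signal — not robustness to the
covariate structure, caller artifacts, or purity effects of real tumors.

## Numerical choices and degenerate inputs

* Poisson tail via the survival function (stable for λ ≤ 50, n ≤ 200 to
  1e-10 against direct summation; extreme tails below 1e-300 underflow to
  0 on both routes).
* BH q-values via the standard step-up procedure (monotone, q ≥ p).
* Tie-breaks are lexicographic everywhere (deduplication representative,
  patient-sample consolidation, evolution representatives), making every
  output invariant to input row order.
* Coordinates are 1-based inclusive internally; BEDPE converts at the
  boundary. pos2 < pos1 on one chromosome is swapped silently and logged;
  unknown chromosomes, bad strands, and type/chromosome mismatches reject
  the row into an error report rather than aborting.
* Zero-count samples get zero exposures and NaN cosine (flagged);
  empty cohorts yield a 32 × 0 matrix.

## Validation problem sizes

The test suite and acceptance script validate on: 50 (tests) / 20
(script) null cohorts of 100 samples at 1 breakpoint/Mb on a 10 × 100 Mb
genome for FDR control; 20 planted RSS-anchored hotspots on a 5 × 50 Mb
genome for recovery; 10,000-point two-component mixtures over 10 seeds
for cutoff calibration; 200 samples × 500 SVs with 3 planted profiles at
30 NMF replicates, ranks 1–5, for signature recovery; 10 multi-sample
patients for evolution round-trip; 3–5 planted bursts for the
chromothripsis screen. These sizes were chosen as the smallest at which
the statistical assertions are comfortably stable.

## Known limitations

* The hotspot null is homogeneous; covariate-aware nulls are future work.
* The clustering criterion's agreement with any specific upstream tool's
  piecewise-constant fit is approximate by construction.
* The chromothripsis screen omits the statistical tests of dedicated
  callers and must not be used for cohort prevalence estimates.
* VCF BND parsing, BAM access, and breakpoint re-alignment are out of
  scope; inputs are expected as curated BEDPE/TSV calls.
* The packaged reference signature catalog is synthetic (see above).
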