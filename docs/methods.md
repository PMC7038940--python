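# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `circabs`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, keys, and site roles

All genomic intervals are 0-based half-open (BED convention).  A circRNA
is keyed by `(chrom, strand, start, end)` with `start < end` on the
genome axis.  Site roles are strand-aware: on "+" the acceptor (3′
back-splice site) is the interval start and the donor (5′ site) the end;
on "−" the roles swap.  genePred/refFlat input already uses 0-based
half-open exon coordinates; any 1-based table must be converted by the
caller.  A single internal convention avoids off-by-one drift between the
junction caller, the gene models, and the repeat annotation.

## Normalization and confidence

Junction reads are normalized to RPM = reads / mapped_reads × 10⁶ per
sample, then averaged across replicates per tissue (or per
tissue-individual pair, selectable).  A circRNA absent from one replicate
contributes 0 RPM to the mean: junction callers emit no row for an
undetected junction, and treating absence as missing rather than zero
would bias averages upward for noisy low-coverage circRNAs.  circRNAs
reaching 0.1 RPM (inclusive) in at least one tissue are high-confidence;
the threshold is a config value.  The comparison is applied to
tissue-level (replicate-averaged) values uniformly, including
single-replicate designs.

RNase-R fold enrichment is treated RPM / untreated RPM with no
pseudocount; circRNAs undetected in the untreated sample are excluded
(a ratio with a zero denominator estimates nothing), and circRNAs lost
after treatment get fold 0.  Statistical significance of enrichment is
out of scope; only the per-circRNA folds and their median are reported.

## Event calling and classification

Candidate events are groups of ≥ 2 circRNAs sharing `(chrom, strand,
acceptor)` (A5BS) or `(chrom, strand, donor)` (A3BS).  The grouping key
includes the strand: coordinate-identical sites on opposite strands never
merge.  Gene annotation is not needed for grouping — coordinates suffice —
so the caller works with any junction source.  A high-confidence event
has ≥ 2 high-confidence members; low-confidence members are retained as
auxiliary context but excluded from complexity, which counts
high-confidence members only.  Each circRNA has exactly one acceptor and
one donor, hence belongs to at most one event of each type; labels
(A5BS, A3BS, A5BS&A3BS, constitutive) therefore partition the
high-confidence set.  Event ids are deterministic:
`{type}:{chrom}:{strand}:{site}`.

Per-tissue ABS counts support two confidence scopes: the default
re-evaluates the 0.1 RPM rule within each tissue (a circRNA and its
event partners must reach the threshold *there*), while the global scope
reuses the dataset-wide flag and counts flagged circRNAs detected in the
tissue.  Per-tissue is the default because per-tissue count figures
answer "what is called ABS in this tissue alone".

## Saturation analysis

High-confidence circRNAs are pooled (sum of per-tissue RPMs), sorted
ascending, and chunked into equal bins.  The remainder that does not fill
a bin is dropped at the *low*-coverage end: the high-coverage tail is
what identifies the asymptote, and discarding it at large bin sizes
(up to bin_size − 1 circRNAs) measurably destabilizes the bin-size
robustness analysis, so all bin sizes share the same top endpoint.  The
bin coordinate is x = log10(mean pooled RPM) by default (config allows
linear x and median instead of mean); the log scale keeps the sigmoid
well-conditioned across three decades of abundance.

The model F(x) = α/(1 + e^−(x−m)·n) is fitted by bounded trust-region
least squares (α ∈ [0,1], n ≥ 0, tolerances 1e-10, ≤ 10,000 evaluations)
from a deterministic grid of starts: α₀ = max fraction, m₀ ∈ {25th, 50th,
75th percentile of x}, n₀ ∈ {0.5, 1, 2, 4}; the lowest residual wins.  A
single start proved unreliable — on flat or slowly rising series the
optimizer locks onto the α = 1 bound with a shallow slope.  Requires ≥ 4
bins.  Two degenerate situations are flagged rather than reported as
clean asymptotes:

* flat series (zero variance): α and m are not jointly identifiable;
  the fit returns α = mean fraction with n = 0;
* the fitted curve never reaches 90% of its own asymptote within the
  observed coverage range: α would be pure extrapolation, so the fitted
  value at the deepest observed coverage is reported instead.

Separate fits are available for the ABS, A5BS, A3BS, and A5BS&A3BS label
sets (A5BS/A3BS sets include the dual-label circRNAs, which are members
of both event types).

## PCU and tissue specificity

Within a scope (a cohort or one individual), the predominant circRNA is
the member that is the per-tissue most abundant one in the largest number
of scope tissues with nonzero event total.  Ties — within a tissue and on
win counts — break by larger pooled RPM across the scope, then by
lexicographic (chrom, acceptor, donor); deterministic outputs are
required for testing.  PCU(event, tissue) = 100 × RPM(predominant) /
Σ member RPMs, computed only where the event is eligible: ≥ 1 member at
the high-confidence threshold in that tissue and positive total (the
second clause is implied by the first at a 0.1 threshold but guards
custom thresholds of 0).  ΔPCU is the largest pairwise PCU difference
over eligible tissues (≥ 2 required); the tissue-specific call uses an
inclusive cutoff by default, with a strict-greater flag.  "Majority of
tissues" counts only tissues with nonzero event totals, and ΔPCU only
eligible tissues; both choices discard tissues whose PCU would be
undefined noise.

Correlation summaries compute Spearman ρ per sample pair over
pairwise-complete rows (≥ 3 shared rows, else the pair is skipped with a
warning), split pairs into same-tissue/different-individual versus
same-individual/different-tissue classes, and contrast the two with a
two-sided rank-sum test.  Tissue clustering uses average linkage on
1 − ρ with pairwise-complete correlations; columns are processed in
alphabetical order so ties resolve deterministically, and tissues with
fewer than 3 shared events against some other tissue are excluded with a
warning.  The dendrogram is exported as Newick with branch lengths.

## Flanking-intron features

A circRNA is assigned to the gene model whose exon boundaries match both
back-splice sites (same chrom and strand).  No match yields an
`unannotated` record, matches in two genes an `ambiguous` record; among
matching isoforms of one gene the model with the most exons wins (a
deterministic stand-in for a principled isoform choice).  Upstream and
downstream flanking introns are defined in gene orientation; first-/last-
exon circRNAs have the corresponding side undefined.  A5BS co-members
share the upstream intron, A3BS co-members the downstream one — a direct
consequence of the shared site, asserted on every simulated catalog.

Alu counting uses interval-tree overlap with ≥ 1 bp intersect semantics
(bedtools-intersect defaults); each element counts once per intron.
Control introns are drawn uniformly, one per circRNA and independently
across circRNAs, from the host gene's introns excluding that circRNA's
two flanking introns (internal introns are eligible).

Class comparisons (complexity high/low/constitutive/control, per side
and feature) use the two-sided Wilcoxon rank-sum test;
predominant-vs-other comparisons pair the predominant member's value with
the mean of the other members' values per event (config: best-other) and
use the two-sided signed-rank test.  Both tests are exact for n ≤ 25
without ties and use the normal approximation with continuity correction
above; p-values are raw, with no multiple-testing correction.  Groups
under 3 members are skipped; fewer than 2 usable pairs is an error.

### CSI-style pairing score

The package computes a CSI-*style* score — a documented surrogate, not a
reimplementation of any published CSI — for the strongest inverted-repeat
pairing between two flanking introns.  Candidate segments are the
Alu-overlapping subsequences of each intron, capped at 400 bp for
desk-scale runtime; candidate pairs must have their elements on opposite
annotation strands (inverted-Alu logic).  For a pair (u, d):
S = Smith–Waterman local score of u against the reverse complement of d
(match +1, mismatch −1, gaps −2, via Biopython's PairwiseAligner);
symmetry = min(|u|,|d|)/max(|u|,|d|); competition = Σ of the scores of
all alternative pairs sharing u or d; and

CSI(u, d) = S × symmetry / max(1, 1 + competition − S).

A pair that outscores its combined competition keeps its full
symmetry-weighted score; a single pair with no competitors reduces to
S × symmetry.  The reported CSI is the maximum over candidate pairs.  The
score is symmetric under exchanging the two introns.

## Synthetic-data generator

The generator emulates the statistical structure of multi-tissue
ribo-depleted RNA-seq circRNA catalogs at desk scale.  Reference
conditions (the defaults): 5,000 circRNA loci, planted ABS fraction 0.84,
truncated-geometric event complexity (p = 0.6, max 10), A5BS:A3BS ratio
65:52.2 among single-type events, 20% of ABS groups forming dual
(A5BS + A3BS, shared member) structures, 8 tissues of which 3 form a
coherent "brain-like" block, 2 replicates, 20M mapped reads per sample.

Each locus group is one synthetic gene whose back-splice sites sit on
exon boundaries.  Locus activity is log-normal (ln-median 0.25 RPM,
σ = 1.6) — most circRNAs sit near or below the 0.1 RPM threshold, as in
real catalogs, while leaving enough high-confidence circRNAs (~3,300 of
5,000) that bins of up to 500 still give ≥ 4 points for the sigmoid.
Member weights come from a Dirichlet with one inflated component
(concentration 6 vs 1.5), giving a clear but dispersed predominant share;
the draw's maximum is swapped into the planned predominant component so
the planted annotation effects, the weights, and the truth tables agree.
Constitutive loci draw a random component of the same construction, which
makes abundance independent of ABS status — the property that ties the
sigmoid asymptote to the planted fraction.  Detection censoring is not a
separate knob: Poisson read sampling at sample depth plus the 0.1 RPM
filter produce the rising observed ABS fraction with coverage.

Per-tissue structure: a group-level log-normal abundance factor
(σ = 0.7, brain boost ×1.5), per-tissue log-weight jitter (σ = 0.25)
shared across individuals — with brain-block tissues drawing 80% of their
jitter from a common component — and per-individual noise (σ = 0.1).
Tissue-specific events (30% of events, shift 40 PCU points in 2 designated
tissues) have the predominant share reduced and the remainder
redistributed proportionally.  True per-tissue PCU is recorded before
individual noise and Poisson sampling.

Planted feature effects multiply intron length and Alu density: shared
flanking introns of complex events (low ×1.6, high ×2.5 on the A5BS
upstream / A3BS downstream side) and the predominant member's
member-specific intron (A5BS downstream ×2.0 length and Alu; A3BS
upstream ×1.5 length only — the weaker mirrored effect).  When sequences
are emitted (small runs only; the genome is random), each ABS member gets
one planted inverted-Alu pair across its two flanking introns, the two
copies of a private motif mutated at 2% (predominant) or 20% (other
members); background Alu annotations carry no shared motif.

What the generator does **not** emulate: read-level artifacts (FASTQ,
mapping, PCR duplicates), linear splicing, sequence splice-site motifs,
real Alu family structure (background elements are annotation-only),
inter-gene interactions, and library-size variation beyond the sample
sheet.  Passing closed-loop tests therefore shows the pipeline's
statistics are self-consistent and recover planted structure under
Poisson detection noise — not that the biological effect sizes in real
tissues match the planted ones.

## Problem sizes and runtime

The test suite and acceptance script run the reference 5,000-locus
configuration, a 600-locus well-covered configuration (~200 reads per
event and tissue) for predominant recovery and ΔPCU calls, a
1,200-locus × 4-individual configuration for correlation structure,
3,000-locus configurations for the feature comparisons, and ≤ 120-locus
sequence-emitting runs for CSI.  Predominant recovery is assessed on the
well-covered configuration because at low coverage (~1 pooled RPM)
Poisson noise genuinely flips per-tissue ranks; that is a property of the
data, not the estimator.

## Known limitations

* The sigmoid asymptote is mildly biased upward (~0.02 at the reference
  conditions) because the minor members of well-expressed events are
  classified ABS down to the detection floor, lifting the low-coverage
  end of the curve; the bias is well inside the stochastic spread.
* The A3BS predominant-vs-other contrast is underpowered at a few hundred
  events with the planted 1.5× effect; the A5BS side carries the
  detectable signal, and only the planted direction is asserted for A3BS.
* PCU eligibility and ΔPCU consider only eligible tissues; events
  expressed everywhere below threshold yield no specificity call at all
  rather than a negative one.
* Host-gene expression enters only as an externally computed table; no
  quantification from reads is attempted.
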