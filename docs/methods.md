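# Methods

`trflp` implements community fingerprinting by terminal restriction
fragment length polymorphism (T-RFLP) of a functional marker gene, built
around the acetogen marker formyltetrahydrofolate synthetase (FTHFS) but
agnostic to the gene: any taxonomically annotated reference amplicon set,
any restriction enzyme and any degenerate primer pair can be supplied.

## The observable

A PCR amplicon carries a fluorophore on the 5' end of its forward primer.
After digestion with a restriction enzyme, only the fragment retaining the
label is detected on the capillary sequencer, so each template contributes
exactly one observable: the distance in bp from the amplicon's 5' end to
the first cut (or the full amplicon length if no site exists — an
*unrestricted* fragment, which is kept through binning but flagged so
reports can exclude it). The in silico (IS) side computes this quantity
for every reference sequence; the experimental (Ex) side measures it as a
sized fluorescence peak.

## In silico digestion under degeneracy

Reference sequences and primers may contain any of the 15 IUPAC codes.
Every comparison is performed on base sets. Two site semantics are
exposed:

- **guaranteed** (default): a window is a site iff, at every position,
  the sequence code's base set is a subset of the pattern's — i.e. every
  disambiguation of the window contains the site;
- **possible**: non-empty intersection at every position — i.e. at least
  one disambiguation contains the site.

Guaranteed is the default because the tagged primers contribute many N
positions and possible-semantics would invent cut sites inside them. The
equivalence of these definitions with intersection/union over exhaustive
disambiguation is property-tested. Patterns that are not their own
reverse complement are additionally scanned as rc(pattern) so
bottom-strand sites are found; both bundled enzymes (AluI `AGCT`^2,
Hpy188III `TCNNGA`^2, REBASE-standard definitions) are
reverse-complement-palindromic, which the tests assert.

Amplicons are built as `fwd + insert + rc(rev)` (634 bp for a 588 bp
insert with two 23 bp primers). A primer-anchored in silico PCR
(leftmost compatible forward window, leftmost downstream reverse window)
is provided for extracting inserts from full-length references;
alignment-based trimming is intentionally out of scope.

## oTRF binning

Raw integer fragment sizes are clustered into operational TRF units
(oTRFs) with a ±w bp window (default w = 2, size range 50–640 bp
inclusive at both ends):

1. sort unique sizes; chain successive sizes with gap ≤ w;
2. split any chain whose span exceeds 2w recursively at its largest
   internal gap (leftmost on ties);
3. label each cluster with the abundance-weighted mean of member sizes
   rounded to the nearest even integer (exact ties to the lower even
   value); colliding labels merge.

Nearest-even labelling is the default because observed oTRF labels in
this assay family are even under the size standard used; it is
configurable (`label_rounding="nearest-integer"`). Exact ties are
detected with rational arithmetic when weights are integral.

Guaranteed properties (tested): weight conservation, cluster span ≤ 2w,
even labels, and label ∈ [min member − 1, max member + 1]. Re-clustering
the produced labels reproduces them whenever labels are pairwise more
than w apart; the unqualified fixpoint property cannot hold for any
labelling rule, because two bins can legitimately receive even labels
2 bp apart and labels 2 bp apart re-chain under a ±2 bp window.

**Dataset-level bins.** For multi-sample tables the bins are derived from
the pooled (union) multiset of all samples and per-sample weights are
aggregated by the shared size→label map. This keeps one label meaning
one unit in every sample — a prerequisite for tracking a bin through a
time series and for ordination — and makes bin labels robust to per-sample
size-calling jitter. Independent per-sample clustering is available as
`mode="per-sample"`.

## Experimental peak processing

Ingestion starts at the instrument software's CSV export (columns `Size`,
`Height`, optionally `Dye/Sample Peak` and `Sample File Name`; all names
configurable). The labelled channel is selected by dye letter (FAM =
blue = `B`). Background noise is removed by an iterative proportion
threshold: peaks with height < `min_proportion` of the current
per-sample total are discarded and the total recomputed until stable
(iteration cap 100, logged). The threshold default is 0.5 %,
configurable, since published uses of this filter family do not fix a
single constant. The filter is idempotent and monotone in the threshold
(property-tested). Relative abundance is 100·height/total on sizes
rounded half-away-from-zero to integer bp, aggregating equal rounded
sizes.

## Ex ↔ IS matching and taxonomy rollup

For each Ex oTRF label: *exact hits* are IS fragments whose size equals
the label; *window hits* are members of IS oTRF bins within ±w bp. Exact
hits take precedence as the active set (a reference fragment of exactly
the observed size is the most direct explanation); the windowed set is
the fallback when no exact size exists, and both are always reported.
Taxon counts are distinct named phyla/genera over the active set, with NA
ranks excluded (optionally countable as a pseudo-taxon). The tool never
reduces a bin to a single taxon call: distinct taxa routinely share
fragment sizes, so candidate sets are the honest output. Two IS TRF
counts are emitted — fragments at the exact label (`n_is_trf`) and
distinct IS sizes within ±w (`n_is_trf_sizes`) — because either
convention is found in practice.

## Ordination

Euclidean distance and Bray–Curtis dissimilarity
(1 − 2Σmin(x,y)/Σ(x+y)) over sample columns; Bray–Curtis between two
all-zero samples is defined as 0 with a warning. PCoA is classical
scaling: Gower double-centering of −D∘D/2, eigendecomposition, axes
scaled by √λ for positive eigenvalues only (negative eigenvalue mass is
logged), variance proportions relative to the positive total, and a
deterministic sign convention (largest-magnitude loading positive). On a
Euclidean matrix this equals PCA of the centred data up to sign, which is
tested, along with a cross-check against an independent implementation.
NMDS and environmental-vector fitting are deliberately not reimplemented;
covariates (VFA, CH4, CO2, …) are carried through to the coordinate
output for external overlay.

## Synthetic data generator

The simulator emulates a two-reactor disturbance experiment at desk
scale and is the ground truth for every end-to-end test. Defaults:

- **Reference set**: 20 taxa, inserts 520–600 bp at GC 0.5, one planted
  enzyme site per taxon positioned so the tagged terminal fragment equals
  an assigned size; planted sizes are even integers ≥ 8 bp apart in
  60–516 bp, so each taxon owns one oTRF label equal to its planted size.
  Accidental earlier guaranteed sites (including primer-junction
  straddles) are removed by bounded mutate-and-rescan repair. Lineages
  come from a small synthetic taxonomy (4 phyla, unique genus per taxon).
- **Community series**: 12 timepoints × 2 reactors. Control proportions
  are Dirichlet(α = 5) with per-timepoint multiplicative drift
  (σ = 0.05); the disturbed reactor multiplies 3 designated taxa by a
  half-sine fold-change pulse (peak fold 8) inside the disturbance window
  (timepoints 3–8) and renormalises. Drift is shared between reactors,
  so a fold change of 1 makes the reactors identical by construction.
  Covariates mirror the pulse: VFA rises to ~20 g/L while CH4 falls and
  CO2 rises.
- **Electropherograms**: per taxon, size ~ Normal(planted, σ = 0.4 bp) —
  the single-base size-calling uncertainty that motivates the ±2 bp
  window; jittered sizes round to within ±1 bp of truth almost surely —
  and height ∝ abundance × lognormal(σ = 0.15) amplification noise,
  a realistic replicate-level PCR/injection variability. Poisson(3)
  noise peaks per sample are drawn with heights below half the noise
  threshold share, so the filter removes them all deterministically; an
  orange-channel size-standard ladder exercises channel selection.

What the simulator does **not** emulate: PCR chimeras, pseudo-TRFs
(mobility shifts), partial digestion, multi-template ragged amplicons,
or taxa sharing fragment sizes. Passing the end-to-end tests therefore
shows the pipeline machinery is correct under the stated noise model, not
that real communities resolve this cleanly — on real data many taxa share
an oTRF, which is exactly why the matcher reports candidate sets.

## Problem sizes and numerics

The bundled end-to-end check uses 20 taxa × 24 samples, where the full
pipeline recovers each timepoint's profile to Bray–Curtis ≤ 0.1, matches
every recovered oTRF to its generating taxon by exact IS fragment size,
and separates disturbance-window samples from the control reactor in
PCoA (positive silhouette). Property suites use 1,000 random concrete
sequences per enzyme (site-finder vs brute force), 200 random degenerate
sequences with ≤ 6 ambiguous positions (exhaustive disambiguation),
1,000 random multisets (binning invariants) and 1,000 random peak sets
(noise-filter invariants). Degenerate inputs behave as follows: empty
samples after range filtering yield zero columns with a warning;
removing every peak as noise is an error advising a lower threshold;
eigenvalues below 1e-12 of the spectral radius are treated as zero.

## Known limitations

- Pooled binning means adding a sample can, in principle, shift bin
  boundaries for all samples; freeze bins by binning once and mapping new
  data onto the saved label map if that matters.
- The moving-average scheme is order-free but not a fixpoint operator
  (see above); labels are stable only when separated by more than w.
- Methylation sensitivity, star activity and partial digestion are not
  modelled; multi-cut fragment catalogues are out of scope (only the
  labelled terminal fragment is observable in this assay).
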