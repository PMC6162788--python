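# Methods

This note documents the models, parameters and numerical choices behind
`lncfocal`, and what the synthetic-data validation does and does not show.

## Coordinate and annotation model

All coordinates are 0-based half-open (BED convention); GFF3 is converted
on read/write. "Non-redundant" exon cataloguing is exact-coordinate
deduplication — overlapping but distinct exons stay separate entries, and
duplicate *signal* over overlapping exons is resolved at probe selection
instead. This preserves per-transcript exon structure, which the
whole-transcript amplification rule needs.

Intergenicity is tested against full protein-coding transcript *spans*, not
just exons: an intronic lncRNA offers no flanking-exon contrast, so only
span-disjoint lncRNAs enter probe design and calling. Flanking neighbours
are assigned gene-to-gene on genomic coordinates, ignoring strand
("upstream" = genomic left); the nearest-neighbour distance is measured
from the lncRNA transcript span. Ties (identical span end/start) break by
nearer gene body, then lexicographic id, for determinism.

## Probe design emulation

Vendor probe scoring is replaced by deterministic coordinate tiling: probes
of fixed length (default 60 bp) at a fixed step (default half-length)
within the exon and within 100/300/500 bp extended windows, plus a
"relaxed" tier that re-tiles the widest window at a half-step phase offset
— a stand-in for less stringent selection parameters that admits candidates
the strict tiers skip. Selection takes two probes per exon minimising
distance to the exon (ties: lower tier, then leftmost start), never
re-selects coordinates already chosen for an overlapping exon, and fills
transcripts with fewer than five exons up to ≥ 10 probes by drawing
next-nearest candidates round-robin across the transcript's exons, which
spreads coverage. Flanking genes get the two candidates nearest the lncRNA
span, drawn from their two nearest exons (distance ties: leftmost).
Sequence thermodynamics, uniqueness screening and melting behaviour are out
of scope; probes are coordinate intervals only.

## Segmentation

Circular binary segmentation: for each probe stretch the two-sample
pooled-variance *t*-statistic is maximised over all circular arc boundary
pairs (i, j) with at least `min_width` probes per arm (linear arcs cover
every circular split because the wrap-around arc is the complement of a
linear one). The split is accepted when the permutation p-value — the
fraction of `n_perm` label shuffles whose maximal statistic reaches the
observed one — is below `alpha`, and the procedure recurses on the
resulting pieces.

Defaults: `alpha = 0.01`, `n_perm = 1000`, `min_width = 2`, mirroring
common practice for this algorithm; all configurable. Numerical choices:

- zero pooled variance with a non-zero mean difference scores +inf (the
  noise-free degenerate case), 0/0 scores 0; a constant stretch is never
  split;
- permutations run in blocks with early termination once the exceedance
  count can no longer fall below `alpha` — the decision and p-value are
  deterministic under a fixed seed;
- no post-hoc segment merging ("undo") is applied; splits are final. This
  is the simplest faithful variant and the main divergence risk versus
  reference implementations: on noisy signals it occasionally emits an
  extra spurious split (observed in ~2–5 % of randomized instances), which
  the boundary-agreement checks accept within their tolerance;
- no outlier smoothing is applied before segmentation;
- segment coordinates are stored as [first probe position, last probe
  position + 1); inter-probe gaps belong to no segment. Segment means are
  exact arithmetic means of member probes.

Profile-level QC is the Pearson correlation of per-bin mean log-ratios in
fixed non-overlapping genomic bins (default 1 Mb) over bins where both
profiles have probes; fewer than 3 shared bins is flagged undefined.

## Focal filter cascade

Rules, in order, for one sample's segments against one lncRNA gene:
(1) exon overlap (half-open, ≥ 1 bp); (2) the segment is discarded when
*fully contained* within a segmental duplication, but (3) known germline
variants count by *any overlap* of distinct intervals (≤ `max_variants`,
default 3) — the two tracks deliberately use different verbs; (4)
|mean log-ratio| ≥ `t_focal` (default 1.5, direction by sign);
(5) gains must cover the entire gene span; (6) no overlap with any
flanking protein-coding flank exon; (7) the lncRNA segment's absolute mean
must exceed the nearest flank segment's by ≥ `flank_delta` (default 0.5,
about one copy) on every evaluable side. A lncRNA whose flank exons are
covered by no segment on either side is suppressed and logged, never
silently dropped. A segment overlapping exons of several lncRNAs is
evaluated once per gene.

**Gain containment and segment support.** Stored segment coordinates run
probe-to-probe, so a segment can never literally reach before its first
probe midpoint — read literally, no amplification could ever contain a
whole transcript. Rule 5 therefore evaluates the segment's *support
interval*: each boundary extended to the midpoint between the segment's
outermost probe and the adjacent probe of the neighbouring segment
(unbounded at chromosome extremes). This is the standard reading of
array-CGH segment boundaries — the true breakpoint lies somewhere between
the last probe inside and the first probe outside — and it preserves the
intended semantics: an amplification covering all of a transcript's probes
(with the adjacent outside probes in neighbouring segments) passes, a
partial amplification whose internal boundary falls between the
transcript's own probes fails. All other rules use the stored coordinates.

The nearest flank segment per side is the one covering the flank exon
closest to the lncRNA, greatest overlap first (ties: nearer the lncRNA).
Stringency: a call is *stringent* iff every existing flank segment is
copy-number neutral, |mean log-ratio| < `t_neutral` (default 0.35),
strictly — a flank exactly at the threshold stays *standard*, the class
that keeps superimposed (stacked) events. High confidence is
|mean log-ratio| > `t_high` (default 2.5).

## qPCR model

Relative quantity versus each flank is the ΔΔCq contrast with
amplification efficiency fixed at perfect doubling (2), replicates
aggregated by arithmetic mean, and per-replicate log₂ rq (replicates
paired by index) kept for a two-sided one-sample *t*-test against 0 at
α = 0.05. The significance requirement on verdicts is configurable off,
since a purely directional reading of "expected relative difference" is
also defensible. A flank with mean Cq above the no-amplification ceiling
(default 35 cycles) is a dropout: that side yields no rq. Degenerate
replicate sets (single replicate or zero variance) get p = 0 when the mean
differs from 0, else 1.

Population-screen copy states are artifact-defined thresholds on rq
(geometric mean over evaluable flanks): homozygous deletion below 0.25 or
aberration Cq above the ceiling, heterozygous deletion in [0.25, 0.75),
neutral in [0.75, 1.5), gain at ≥ 1.5. These map exact copy numbers
0/1/2/≥3 to rq 0/0.5/1/≥1.5 with maximal margins.

## Text mining

Tokens are lower-cased whitespace words after punctuation stripping;
stopwords (a standard 174-word English list shipped with the package),
user-supplied excluded names, and digit-bearing tokens are removed. The
counting unit is token occurrences; a document-presence 2×2 variant is
available (`unit="document"`) since either reading of "word frequency" is
possible. Comparison scores are per-word deviations of within-group
relative frequency from the cross-group mean (they sum to zero across
groups). Enrichment is two-sided Fisher's exact, computed directly from
the hypergeometric mass: the sum of probabilities of all tables with the
observed margins that are no more probable than the observed table (with
the standard 1 + 1e-7 relative tie tolerance). No stemming is applied.

## Synthetic data and what it shows

The generator's defaults define the study conditions used throughout the
validation: 5 chromosomes × 10 Mb carrying 100 protein-coding and 50
intergenic lncRNA genes (protein-coding genes anchored at both chromosome
ends so every lncRNA has two neighbours), a 5-sample panel with 10 planted
focal CN-0 deletions and 10 focal CN-8 amplifications assigned round-robin
to samples on distinct lncRNAs, exclusion tracks placed in intergenic
space, and Gaussian probe noise in log₂ units (0 or 0.25 depending on the
check). Focal event intervals cover the lncRNA span plus a 500 bp margin
and always stop short of the nearest flank exons; stacked events nest the
CN-0 interval inside a CN-1 interval that also covers both neighbours.
Homozygous-deletion log-ratios are floored at CN 0.1 (log₂ 0.05 ≈ −4.32),
matching the finite high-magnitude ratios real arrays produce. qPCR Cq
values follow Cq = base − log₂(max(CN, floor)/2) + noise with base 25,
σ = 0.15–0.2, 3 replicates, and a floor small enough (0.001) that true
CN 0 lands above the 35-cycle ceiling. Corpora are drawn word-by-word from
Zipf-weighted group multinomials with planted words at a base rate of
0.002 and a group-specific multiplier (default "cancer" × 5).

Validation problem sizes were chosen as the smallest at which each
property is statistically meaningful: 20 seeds for noisy recovery, 200
randomized segmentation instances (≤ 100 probes, ≤ 2 breakpoints, jumps
≥ 1), 1000 randomized filter configurations, 200 qPCR events, 500 Fisher
tables (n ≤ 200, where exact rational enumeration is cheap) and 100 null
corpus seeds.

What passing these checks does **not** show about real data: the simulator
has no GC waves, no dye bias, no hybridisation physics, no segmental-
duplication cross-hybridisation artifacts, uniform probe response, and
clean breakpoints exactly at event boundaries. Real-array performance
therefore depends on upstream normalisation quality that is out of scope
here; the checks establish the correctness of the calling logic, not the
platform's wet-lab sensitivity. Reproduction of any particular cell-line
panel's counts would require the original array data and versioned
annotation/track databases, which this package does not ship.

## Known limitations

- CBS without the merge/undo step can over-segment noisy stretches; the
  filter cascade is robust to this (extra boundaries inside copy-neutral
  regions change no rule outcome) but segment counts are not comparable to
  reference implementations probe-for-probe.
- The probe-design emulation shares only the *selection logic* with vendor
  pipelines, not candidate quality; coverage fractions on real designs
  will differ.
- The flank-contrast rule needs at least one flank exon covered by a
  segment; lncRNAs at chromosome ends with a single neighbour are
  evaluated on that side alone.
- Fisher enrichment treats tokens as independent draws; abstracts are not
  independent bags of words, so token-mode p-values on real corpora are
  anti-conservative (the document-presence mode is the safer variant).
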