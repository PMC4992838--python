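# Methods

This note documents the models and procedures implemented in
`mapanchor`, the parameters that matter, the numerical choices made
where a convention had to be fixed, and what the synthetic-data tests
do and do not demonstrate about real data.

## Map binning

Linkage-map software reports marker positions to limited precision, and
markers with no recombination between them ("bins") share a position.
Lacking access to the co-segregation patterns themselves, `build_bins`
uses identical-rounded-cM as the bin criterion, with `cm_precision = 2`
decimals by default (typical map-software output precision).  Binning
partitions the marker set and is invariant to input row order; LG order
follows first appearance in the map file unless an explicit order is
configured.

## Anchoring model

A scaffold's position on its linkage group is the mean of its member
markers' bin cM, each marker counted once.  This weights bins by the
number of markers they contribute, which is the maximum-likelihood
location under i.i.d. marker noise and requires no tuning.  The minimum
marker count to anchor is 1 (configurable `min_markers`): a single
mapped SNP fixes position but not orientation, which is then flagged
ambiguous rather than discarded.

### Chimera criterion

Two triggers, checked on markers sorted by scaffold bp:

* **multi_lg** — adjacent markers on different linkage groups.  Always a
  mis-assembly signal; no threshold.
* **intra_lg_gap** — adjacent markers on one group whose bin positions
  differ by more than `max_intra_lg_gap_cm` (default 20 cM).  The
  threshold trades sensitivity to within-chromosome fusions against
  false splits in regions where the map is locally distorted; 20 cM is
  far above any plausible within-scaffold genetic span (a 1 Mb scaffold
  at ~4 cM/Mb spans ~4 cM) while still far below typical chromosome map
  lengths.

The split coordinate is the floor midpoint of the two flanking markers'
bp positions.  Absent any sequence signal (the true junction is
somewhere in the marker-free interval), the midpoint is the unbiased,
deterministic choice; each piece retains a contiguous marker run, so
every piece re-anchors.

### Orientation

The call is the sign of Kendall's τ between marker bp and cM.  Rank
correlation was chosen over strict monotonicity so that one noisy
marker cannot flip a well-supported call.  τ = 0 or fewer than two
distinct cM (or bp) values give '?', treated downstream as '+' with an
`ambiguous_orientation` flag — the original strand is retained, which
is the only defensible default.

### Ordering

Within a linkage group, anchors sort by position ascending; ties break
by descending scaffold length (placing the longest, best-supported
sequence first), then lexicographic id for determinism.

## Pseudomolecule construction

Adjacent components are joined with exactly `gap_length` N (default
10,000), a fixed sentinel for "unknown distance, map-joined" junctions.
AGP v2.1 rows (gap rows typed `map`/`no` linkage) are generated in
lockstep with the sequence; `reconstruct_from_agp` must reproduce the
FASTA byte-for-byte and is exercised on every pipeline test run.
Unanchored scaffolds form an unplaced pool and are reported, not
concatenated.  Internally all coordinates are 0-based half-open;
AGP and placement files are 1-based inclusive, converted only at the
I/O boundary.

Reported percentages (anchored fraction, coverage, completeness, GC%)
are rounded half-up to 1 decimal, matching report-table conventions.

## Assembly statistics

* **N50**: length at which the descending cumulative sum first reaches
  half the total.  Under this convention ties need no special handling.
* **GC%**: G+C over A+C+G+T only.  Draft pseudomolecules can be >10% N;
  including Ns (or ambiguity codes) in the denominator would make GC%
  depend on gap policy rather than composition.
* **k-mer genome size**: the depth histogram's error spike is cut at the
  first local minimum at depth ≥ `min_depth` (default 2); when the
  histogram rises from the start (no spike) the valley falls back to
  `min_depth − 1` so no genuine coverage mass is discarded.  The peak is
  the modal depth beyond the valley, and genome size is total k-mers
  beyond the valley divided by the peak depth, floored.  A
  monotonically decaying histogram has no coverage peak and is a hard
  error.  On simulated Poisson coverage at depth ≥ 15 the estimate is
  within 5% of truth (seeded test); real histograms with strong repeat
  shoulders or heterozygosity peaks will bias the simple estimator and
  are not modelled.

## Comparative computations

* **RBH**: best hit per query by bit score, ties resolved by lower
  e-value, higher identity, then lexicographic subject id (full
  determinism); pairs kept iff mutual.  E-value cutoff 1e-10 by default.
* **NG86 Ks/Ka**: per-codon synonymous-site fractions from the standard
  genetic code (mutations producing stop codons count as
  nonsynonymous); sites averaged over the two sequences, so
  S + N = 3 × codons identically.  Codons differing at k positions are
  resolved by averaging synonymous/nonsynonymous step counts over all
  k! single-step pathway orderings, including pathways through stop
  codons (keeping the estimator total-count-conserving).  Alignment
  columns with gaps or ambiguity are dropped; columns where either
  codon is a stop are excluded with a warning.  Proportions are
  corrected with Jukes–Cantor, d = −¾ ln(1 − 4p/3), and flagged
  undefined (not raised) when p ≥ 3/4.  NG86 is the canonical fully
  specified counting estimator; model-based estimators (GY94 etc.) are
  out of scope.
* **Divergence times**: a node's height is its *mean* path length to
  descendant tips, which ultrametricizes a non-clock tree in one pass;
  ages are heights scaled so the calibration node (MRCA of the two
  calibration taxa) has exactly the calibration age.  A final preorder
  pass clips each node's age to its parent's, guaranteeing
  parent-monotone ages on pathological trees.  Doubling all branch
  lengths leaves ages unchanged (rate/time confounding is resolved
  entirely by the calibration).  This operationalizes a uniform-rate
  distance-to-time conversion; it is not a relaxed-clock method.

## Synthetic data: what it emulates and what it does not

`generate_dataset` draws i.i.d. bases at the configured GC (default
0.33), cuts each chromosome at uniformly random breakpoints (mean piece
50 kb), inverts pieces with probability 0.10, fuses pieces from
different chromosomes with probability 0.05, and places markers
uniformly at 100/Mb with cM = 3.8 · Mb (a linear, monotone map).
Defaults mirror a clover-scale mapping project shrunk to desk size:
8 × 2 Mb chromosomes give ~320 scaffolds and ~1,600 markers, and the
per-scaffold genetic span (~0.2 cM) matches what 50 kb scaffolds see on
a real ~4 cM/Mb map.  Optional `cm_jitter_sd` adds i.i.d. Gaussian
noise to each marker's observed cM.

Not modelled: recombination interference and map-function curvature,
suppressed-recombination heterochromatin plateaus (the map is strictly
linear), repeat content, assembly gaps inside scaffolds,
genotyping-batch map errors (which are locally correlated, not i.i.d.),
and within-chromosome fusions (planted fusions are cross-chromosome
only; the intra-LG gap rule is exercised by constructed marker sets in
the unit tests).  Passing recovery tests therefore demonstrates
correctness of the anchoring logic under clean monotone maps, not
robustness to structured map error.

### Recovery metrics

* Orientation accuracy is computed over non-chimeric scaffolds with
  ≥ 2 distinct-cM markers — below that the orientation is unidentifiable
  by construction.
* Chimera sensitivity is computed over planted fusions in which *both*
  components carry at least one mapped marker.  A fusion with a
  marker-free side anchors to a single linkage group and is invisible
  to any map-based detector; including such cases would measure marker
  density, not detector quality.  Precision counts all detection calls.
* Ordering is scored per linkage group as the Spearman correlation
  between the pipeline's scaffold order and the true chromosome
  coordinate of the non-chimeric scaffolds assigned to that group.
  Reported ρ is rounded to 12 decimals to absorb floating-point noise
  from the rank-correlation routine (the smallest genuine deviation,
  one adjacent transposition, is orders of magnitude larger).

### Observed behaviour under marker jitter

With the default geometry, per-marker cM jitter of SD 0.5 exceeds the
~0.19 cM true genetic span of an average 50 kb scaffold, so
within-scaffold orientation becomes statistically unidentifiable: the
optimal sign estimator's success probability is ≈ Φ(0.25) ≈ 0.6, and
measured orientation accuracy is 0.63–0.68 across seeds.  This is a
property of the data geometry (scaffold size × cM/Mb vs noise), not of
the estimator, and holds at full genome scale too.  Chimera detection
is unaffected by cM jitter (linkage-group assignment does not move),
and per-LG ordering degrades only mildly (ρ ≈ 0.96–0.99) because each
scaffold position averages ~5 markers.

## Problem sizes used in tests

Unit and property tests run on 2-chromosome × 300–500 kb datasets
(seconds); the end-to-end recovery checks run the generator's full
default conditions (8 × 2 Mb, ~1,600 markers).  `scripts/acceptance.py`
uses the same defaults plus a 1 Mb Poisson coverage simulation for the
genome-size estimator.  These sizes were chosen so the complete suite
runs in well under a coffee break while every code path — fusion,
inversion, splitting, re-anchoring, AGP round trip — is exercised.

## Known limitations

* The intra-LG chimera threshold is a blunt instrument; a local
  likelihood test against the map would be more sensitive but needs a
  map error model.
* The genome-size estimator has no heterozygosity or repeat model.
* `calibrate_times` assumes a rooted input tree; it does not infer the
  root, and mean-height ultrametricization can shrink deep nodes on
  strongly non-clock trees.
* Half-up decimal rounding is applied at the reporting boundary only;
  internal values are full precision.
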