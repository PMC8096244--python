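# Methods

## The octad model

One meiosis of an S288C×SK1 hybrid diploid produces four spores; after one mitosis
each spore yields two daughter cells, and sequencing all eight exposes the two
strands of each spore's chromatid.  `meiorec` represents this as an 8×M matrix of
parental-origin calls (`P1`/`P2`/`NA`) over an ordered biallelic marker map, rows
paired `s1a,s1b … s4b` into spores.  Absent recombination, two spores carry the
parent-1 haplotype and two the parent-2 haplotype, so every marker segregates 4:4.

Because the modeled strains are mismatch-repair deficient (*msh2*Δ), heteroduplex
DNA persists through the post-meiotic division: a marker inside an hDNA tract shows
one parental allele on one daughter strand and the other allele on the second
(daughter-discordant, 5:3 over the octad).  A fully converted marker shows the
opposite-to-background allele on both daughters (6:2).

## Synthetic octads

`simulate_octad` plants a Poisson number of events (default λ = 3 per chromosome)
on a 200 kb chromosome with geometric inter-marker gaps of mean 160 bp, emulating
the hybrid's SNP density.  Event anatomy:

- **NCO** (SDSA outcome): one gamma-length hDNA tract centered on the event
  midpoint on one chromatid; one daughter strand is inverted over the tract.
- **CO** (DSBR outcome): a reciprocal exchange of all markers right of the midpoint
  between two chromatids of distinct parental origin, plus one gamma-length hDNA
  tract per involved chromatid abutting the midpoint on opposite sides (two-ended
  break-repair geometry).  Symmetric trans-hDNA is not modeled.

Tract lengths are gamma distributed with shape 2 (scale = mean/2), a right-skewed
family consistent with long-tailed conversion-tract distributions; only the mean is
treated as a biological parameter (1.3 kb reference-like, 3.0 kb for the
long-tract mutant regime).  Event midpoints are uniform on the chromosome
conditional on pairwise separation of at least `min_event_sep` (default 10 kb),
sampled by the order-statistics construction (sorted uniforms in the interval
shrunk by the total spacing, plus offsets) — exactly the rejection-sampling
distribution, but exact and failure-free whenever the draw is feasible; an
infeasible event count for the chromosome raises a stage error.  Midpoints are
also kept at least that margin from the chromosome ends so tracts and their
classification flanks stay inside the marker map.  Crossover partners are drawn among chromatids
whose *current* local background differs at the midpoint: an exchange between
locally identical chromatids (possible after an earlier crossover) would leave no
flanking-marker footprint and is unobservable by design of the assay, so the
generator does not plant it.  Genotyping error (per-call allele flip) and missing
calls (`NA`) are applied independently per strand-marker call after all events.

Every planted interval is recorded in a truth table, making the caller testable by
round trip without any external data.

What the generator does **not** emulate: read-level noise correlated along the
genome, marker-density variation between chromosomes (real SNP density is locally
heterogeneous), chromatid interference, aneuploidy, complex multi-invasion events,
and mitochondrial DNA.  Passing round-trip tests therefore demonstrates the
correctness of the calling logic under the stated event anatomy, not performance
on every pathology of real sequencing data.

## The caller

Per spore, each marker is classified **Mendelian**, **hDNA** (daughters
discordant), **full conversion** (both daughters opposite to the local background)
or **missing** (any daughter `NA`).  The haplotype background is anchored on
maximal runs of at least `flank_k` (default 5) consecutive concordant markers of
one origin; between anchors of different origin — a crossover span — the left
anchor wins, matching the left-flank rule used for event classification.

Tracts are maximal runs of non-Mendelian markers.  Missing markers are neutral
(they neither extend nor break a run); a tract may bridge at most
`merge_gap_markers` (default 0) interior Mendelian markers, so by default a single
restored marker splits a tract.  Isolated single-marker tracts whose informative
neighbours are Mendelian on both sides are flagged `low_confidence` — with
per-call error rate ε, the expected number of such false positives is
≈ 8·M·ε per octad, and the pipeline summary reports the high-confidence subset
alongside all tracts — but they are never silently dropped.

Tract boundaries use inter-marker midpoints (see README); at a chromosome end the
terminal converted marker position is used.  Tracts within `event_merge_bp`
(default 5 kb) are grouped into events by single-linkage along the chromosome.
For classification, each spore's left/right backgrounds are the majority origin of
the nearest `flank_k` concordant markers outside the event span: **CO** requires
two spores switching in complementary directions, **NCO** requires no switch,
three or more switching chromatids give **complex**, and anything else
(insufficient flank markers near a chromosome end, a lone switch) stays
**unclassified** rather than being forced into a class.

Two adjacent crossovers whose tracts approach within the merge radius coalesce
into one four-chromatid event and are reported as `complex`; this is the intended
behavior of proximity grouping, not a mis-call.

## Genotype calling from depths

From per-strand allele depths, a call is made when total depth ≥ `min_depth`
(default 5) and the major-allele fraction ≥ `min_purity` (default 0.9); everything
else is `NA`.  Purity is compared inclusively (9 of 10 reads passes at 0.9).

## Statistics

- **Mann–Whitney U**, two-sided: exact null distribution when both samples have
  ≤ 8 observations and the pooled sample is tie-free; otherwise the normal
  approximation with tie and continuity corrections.  Both branches can be forced.
- **Fisher's exact**, two-sided by the sum of hypergeometric outcome
  probabilities no larger than the observed one; degenerate margins give p = 1.
- **Benjamini–Hochberg** step-up adjustment, capped at 1.
- **Proteomics filter**: a protein is enriched iff fold change ≥ 2, BH-adjusted
  p < 0.05 and ≥ 3 distinct peptides.
- **Short tracts**: strict `< cutoff` (default 300 bp) proportions, compared
  between samples by Fisher's exact test on the 2×2 counts.

The scipy/statsmodels implementations stand behind these interfaces; the test
suite checks them against independent enumeration oracles (all labelings for
Mann–Whitney at n ≤ 6, full hypergeometric support for Fisher up to N = 40, hand
step-up for BH).

## ChIP signal

Tracks are fixed-step vectors with an explicit normalization state.  Mean
normalization divides by the genome-wide mean (per-million scaling would only
rescale and is omitted); control subtraction requires both tracks mean-normalized
on the same grid and **keeps signed residuals** — correlation must see the full
residual distribution — with flooring at zero an explicit flag for display and
profiles.  Smoothing is a centered moving average whose window shrinks at
chromosome ends (constant tracks are preserved exactly); windows of 2000 bp
(correlation) and 200 bp (browser-scale views) are the defaults used in the
analyses this package reproduces.  Meta-profiles average equal-weighted windows
around anchor midpoints, dropping (and counting) anchors whose window leaves the
chromosome.  Correlation matrices are Spearman (average ranks) over bins
overlapping a region union, after smoothing.

Feature enrichment is a permutation test: observed mean signal over features
versus `n_perm` uniform length-matched placements per chromosome, with
empirical p = (1 + #{null ≥ observed}) / (n_perm + 1).  The +1 correction makes
the smallest attainable p equal 1/(n_perm+1) and the null distribution discrete
uniform, which the tests verify by Kolmogorov–Smirnov against the discrete law.

qPCR fold enrichment divides the target locus percent-input by a negative-control
locus at the same time-point, then by the same ratio at t = 0 h.

## Numerical and design choices

- Coordinates: 1-based inclusive in genotype/event tables, 0-based half-open in
  BED/bedGraph.
- Single-chromosome simulation unit; multi-chromosome octads are concatenations
  with independent draws.
- A one-bin smoothing window returns the input unchanged rather than via
  cumulative sums, avoiding float round-off that would perturb rank ties.
- All generators take explicit integer seeds; fixed seed ⇒ bitwise-identical
  outputs, which the pipeline uses to make whole runs reproducible (octad k of a
  run uses seed `seed + k`).
- Problem sizes in the test suite and acceptance script (200 octads of a 200 kb
  chromosome per regime; 200 Mann–Whitney replicates at n = 100 per arm; 999
  permutations for the enrichment spot check and 200×99 for the null-uniformity
  check) were chosen so that sampling error is well below the tested tolerances
  while a full run completes in seconds.

## Known limitations

- The event-grouping gap rules and the exact tract-boundary convention of
  published octad analyses are not fully standardized; the defaults here
  (midpoint boundaries, 0-marker gap tolerance, 5 kb merge) are this package's
  documented choices, exposed in configuration and echoed in run metadata.
- Whether published tract sets include full-conversion-only (6:2) tracts is
  ambiguous; both categories are emitted with per-marker labels so either
  convention can be applied downstream.
- The caller assumes the 8 strands are correctly paired into spores; pairing
  errors are not detected.
- The permutation null places intervals uniformly and independently, ignoring
  chromosomal covariates (GC, replication timing); enrichment p-values on real
  data should be interpreted accordingly.
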