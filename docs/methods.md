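# Methods

This note records the models, conventions and design choices behind
`poolanchor`, in the order the pipeline applies them.

## Coordinates and geometry

All chromosome coordinates are 0-based half-open base pairs; megabases are
`bp / 1e6` exactly. Abutting intervals do not overlap. Well addresses are
(plate 1.., row letter, column 1..); the three pool axes partition the wells
so every BAC lies in exactly one plate, row and column pool. Bin names are
opaque labels whose order comes from the input file; arm assignment and bin
geometry (full size, distance to centromere) are optional inputs because
they derive from cytogenetic data, not from the map itself.

## Normalisation

Step 1 divides each intensity by the median of its own pool (60 medians),
equalising per-sample hybridisation levels; step 2 divides each value by
its probe-row median, making probes comparable. After both steps every
probe-row median is exactly 1. A zero pool median aborts with the pool
named — it indicates an empty or failed sample, not something to patch
silently.

## Positive-pool scoring

**Automated.** Per probe and axis, the threshold is mean + k·SD with
k = 2.8 (plate), 2.5 (row), 3.0 (column); SD is the sample SD (n−1), and a
pool must be *strictly* above the threshold. The step is repeated twice
more, each time excluding previously detected positives from the mean/SD
computation (they remain detected); the union of the three passes is
returned, and all thresholds are recorded for audit. Two structural facts
matter here: among n values the largest attainable z-score is (n−1)/√n, and
for two equal spikes it is smaller still (≈ 2.92 / 2.56 / 3.25 at
n = 20 / 16 / 24). The multipliers are therefore matched to the full
20 × 16 × 24 pool geometry — with materially fewer pools per axis no
outlier could ever exceed the threshold — so the simulator keeps that
geometry at every scale (see below).

**Boxplot.** Positives are values above Q3 + 1.5·IQR with quartiles by
linear interpolation. Being permissive, its calls are only kept downstream
when they resolve to two or three overlapping BACs.

**Semi-automated.** A probe with five positives in a 2/2/1 axis pattern is
resolved by enumerating the two complementary pairings of the doubled
coordinates; it is accepted only when exactly one pairing names two
occupied wells whose BACs overlap on the map. **Manual.** A probe with two
positives on two axes is resolved by scanning the third axis; it is
accepted only when exactly one candidate well holds an MTP BAC. Both rules
deliberately refuse ties: an ambiguous probe is a status, not an error.

## Deconvolution

A probe's positive coordinates imply a Cartesian product of candidate
wells. A *covering set* is a subset of occupied wells using every positive
pool. Resolution searches covering sets from the smallest feasible size
(1–3): at the first size with any mutually-overlapping covering set, the
set must be unique or the probe stays unresolved; smaller address sets are
preferred when both a unique well and a larger combination are consistent.
A full 2/2/2 pattern explained by exactly one pair of occupied wells on
*different contigs* resolves as two addresses of a duplicated (two-copy)
gene; any five-positive disjoint configuration stays unresolved. When
several scoring methods call the same probe, precedence is
automated > boxplot > semi-automated > manual and the first resolution
wins; every call is logged.

Loci merge a probe's addresses on mutually overlapping BACs; disjoint
groups become separate loci flagged `duplicated`. A locus inherits its
contig's deletion bin; conflicting bins within one locus violate the map
and raise.

## Repeat filtering

The filter aligns each 60-mer probe to a repeat library with an in-package
Smith-Waterman (match +1, mismatch −1, gap −2, linear gaps) and flags the
probe when the best-scoring local alignment reaches ≥ 80% identity
(matches / columns) over ≥ 45 columns. The aligner is written here rather
than wrapped from a library so the traceback tie-break — first maximal end
cell in row-major order; diagonal preferred over up over left — is fixed
and testable: identity and span of an optimal alignment are only
well-defined once those ties are pinned down. Alignment scores are
cross-checked against an independent aligner in the tests, and the flag
decision against a separately coded exhaustive DP oracle. Per-probe best
identities are surfaced so stricter cut-offs can be applied without
re-aligning.

## Comparative analyses

Synteny is residence on the orthologous chromosome (barley 3H, rice 1) and
ignores order. Probes attach to genetic-map markers through alignment hits
filtered at ≥ 85% identity over ≥ 100 nt, best hit first. Because locus
order *within* a deletion bin is unknown, synteny blocks are built from a
maximal order-consistent subset of binned syntenic loci: loci are sorted by
bin order and a longest non-decreasing subsequence of reference positions
is retained (both chromosome orientations are tried; ties are broken by
preferring loci nearest their own bin's median position, which keeps a
stray locus from displacing a bin's resident loci). Each bin's block is the
[min, max] reference interval of its retained loci; a locus is collinear
iff its position falls in its own bin's block, which makes the collinear
set invariant under any order-preserving transform of reference positions.

Chi-square uniformity tests construct expected counts from a global
proportion applied to per-bin totals (for densities: totals are contig
lengths), with df = bins − 1. Non-syntenic placement bias is tested against
expected counts proportional to per-chromosome gene totals. The t-test is
Welch's (variance equality is not assumable); all p-values are two-sided.

## Gene space

Density is loci per Mb of contigs assigned to the bin; normalized density
divides by the mean of the (unrounded) per-bin densities, so its mean is
exactly 1. Distance to the centromere is measured to bin midpoints. Gene
islands are connected components (≥ 2 members) of the relation "same BAC,
overlapping BACs, or BAC-interval footprints separated by less than the gap
threshold (150 kb default) within one contig"; inter-contig gaps always
break islands because the physical distance across them is unknown.
Extrapolation projects observed densities onto full bin sizes, then
rescales all bins so they sum to a target chromosome-wide gene count;
kb-per-gene follows directly. The tandem-duplication correction reports
`1 − observed/reference` per bin (floored at 0) between two normalized
density profiles; it is a coarse ratio diagnostic, and the reference
profile must share the bin definitions.

## The synthetic screen

The generator is the package's study-condition bed: its defaults are fixed
once and the tests treat them as the experiment.

* **Map.** Contigs cover 82% of the chromosome (gaps elsewhere); BACs tile
  each contig with ~30% pairwise overlap and jittered lengths, the last BAC
  clamped so contigs tile exactly. Eight deletion bins use deletion-line
  style breakpoints (arm fractions 1.00/0.78/0.57/0.33 on the short arm,
  0.22/0.50/0.63/1.00 on the long arm) around a centromere at 40% of the
  chromosome; contigs bin by midpoint, with a configurable fraction left
  unbinned.
* **Scale.** Desk-scale defaults are a 100 Mb chromosome, ~350 BACs of
  ~335 kb, 800 genes — but the full 20 × 16 × 24 pool geometry is kept, for
  the threshold-attainability reason above, and BACs are scattered across
  the wells (`well_assignment="scattered"`). Plate-by-plate filling
  (`"sequential"`, the real screen's layout) is only meaningful when the
  geometry is nearly full: ~350 sequentially filled wells would collapse
  into a single plate pool and destroy the plate axis.
* **Genes.** Positions follow a piecewise-linear density rising twofold
  from centromere to telomeres (rejection sampling). Island membership is
  distance-dependent; the configured island fraction is the fraction of
  *genes* in islands, so the per-anchor cluster probability is deflated by
  the mean cluster size (q = p / (k(1−p) + p)). Island members are laid
  down with intra-cluster gaps below the island gap. A small fraction of
  genes receives a second independent placement (two-copy genes).
* **Signals.** value = log-normal background + Σ over member BACs of
  base · (1 − decrease(identity)) · abundance(BAC). The attenuation curve
  is piecewise linear through its three known anchor points: 0 at 100%
  identity, a per-probe draw from [0.73, 0.99] at 90%, total loss at the
  80% detectability floor — the simplest curve consistent with the known
  range. Per-BAC abundance is log-normal with configurable CV (pooled BAC
  DNA cannot be assumed equimolar); the background's log-normal parameters
  are a modelling choice exposed in the config, as no background
  distribution is established. Repeat-derived probes receive moderate
  signal in a random ~30% of all pools.
* **References.** A synthetic barley map and rice ortholog table place a
  configurable fraction of genes non-syntenically; syntenic positions are a
  noisy monotone image of chromosome position (cM, or ordinal rank), so
  collinearity is high but imperfect.

What the generator does *not* emulate: real sequence content (probe
sequences are random 60-mers except the planted repeat windows), spatial
chip artefacts, dye effects, partial BAC amplification, or genetic-map
errors with realistic structure. Passing recovery tests therefore show the
*analysis* is correct and calibrated to the screen's statistical structure,
not that the wet-lab screen achieves these rates.

## Test and experiment sizes

Recovery experiments run at the desk scale above (≈ 2 s per end-to-end
pipeline): noiseless recovery on 800 genes; 500 random deconvolution
instances against brute-force enumeration; 200 probe/repeat pairs against
the alignment oracle; gradient recovery over 20 seeds. Island-fraction
recovery runs at the real screen's scale (1 Gb chromosome, 160 kb BACs,
800 genes, 150 kb gap) because island statistics are only meaningful when
gene spacing is large against BAC size; at desk scale nearly all loci share
BACs and the island rate saturates. Even at the realistic scale, loci
co-locate by chance at a non-negligible rate (the footprint of a
BAC-resolution locus is BAC length + gap threshold), so recovery is
measured as the excess of the observed island rate over a chance-matched
null — a run with no planted islands and the same number of independent
objects (isolated genes plus one per planted cluster) — via
f̂ = (p_obs − p_null)/(1 − p_null). This estimator recovers the planted
fraction to within a few points; the residual bias comes from island
fragmentation at contig boundaries.

## Known limitations

* The uniformity tests' df convention (bins − 1 with constructed expected
  values) is one of several defensible choices; small differences in
  published p-values for such tests can arise from category structure
  alone.
* The tandem-duplication correction is a ratio heuristic; no simple formula
  reproduces an independent study's missed-gene percentages exactly, and
  the op reports its own formula's value.
* Full (non-contig-covered) bin sizes are not derivable from the map and
  must be supplied for extrapolation; absent them the op is skipped with a
  notice.
* Duplicated genes are only resolvable from a clean 2/2/2 pattern; a
  two-copy gene sharing any pool coordinate between its copies is
  conservatively left unresolved.
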