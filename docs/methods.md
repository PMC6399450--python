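# Methods

This note records the models and procedures motulite implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Profiling model

A sample is a set of *inserts* (read pairs, or single reads) aligned to
the marker-gene database in SAM format.  The profiler never aligns
reads itself; it consumes alignments with NM (or MD) and, optionally,
AS tags.

**Filtering.**  An alignment's length is the sum of its CIGAR M/=/X
columns; its nucleotide identity is `(aligned_length − NM) /
aligned_length`.  Defaults keep alignments with identity ≥ 0.97 and
length ≥ *l* (75 bp minimum; the shipped presets range from `-l 30 -g 1`
for maximum recall to `-l 140 -g 6` for high precision, with `-l 100 -g
3` the default).  Soft-clipped bases never count.  When AS is absent
the per-alignment score falls back to `aligned_length − 2·NM`, which
ranks simulator alignments identically.

**Insert assignment.**  For each insert and each MGC, every mate
contributes its single best-scoring alignment to any member of that
MGC (mates hitting different members of one MGC are still one target);
the insert's MGC score is the sum over mates.  The argmax set over MGCs
is the insert's best-target set: one element → *unique*, several →
*multiple*.

**Redistribution.**  Unique inserts are counted directly.  Each
multiple insert is split across its tied MGCs proportionally to the
unique-count profile, or uniformly when every tied MGC has zero unique
counts.  The redistribution is single-pass (no EM iteration): the
unique profile is computed once and the multiples are distributed once.
Counts are conserved exactly — the sum over MGCs equals the number of
assigned inserts — and the same fractional weights are applied to the
aligned bases of multiple inserts when computing base coverage (the
symmetric treatment is our choice; only the insert-count case is
externally specified).

**Units.**  `base.coverage` divides the (weighted) aligned bases on an
MGC by its centroid's coding length.  `insert.raw_counts` rounds the
redistributed insert counts half-away-from-zero to integers (stable
across platforms, unlike banker's rounding).  `insert.scaled_counts`
rescales the mOTU-level coverage vector so that its total (including
the unbinned row) equals the number of aligned inserts; it inherits the
gene-length normalisation of coverages on the scale of counts and is
the unit for relative abundances.

**mOTU summarisation.**  A mOTU's value is the median of its *detected*
(nonzero) MGC values, provided at least *g* MGCs are detected, else 0.
Taking the median over detected values rather than all 6–10 slots makes
the *g* threshold meaningful (with the all-slot median, any mOTU with
fewer than half its MGCs detected would be 0 regardless of *g*); a
`detected_only=False` switch provides the all-slot alternative.  The
unbinned row `-1` is the median of the ten per-COG sums of unbinned MGC
values — summing within a COG first mimics how a single unobserved
genome would spread reads over its ten (unbinned) marker genes.

**Relative abundance.**  Fractions are computed over all mOTU rows
including `-1` (default) or with `-1` dropped and the rest renormalised
to 1.  The second convention is what common benchmark harnesses
enforce; it inflates named taxa whenever part of the community is only
quantifiable as unbinned markers, and the evaluation module measures
exactly that effect.

## Clustering

Global pairwise identities use Needleman–Wunsch with match +1, mismatch
−1, gap −2, end gaps penalised.  The production systems this models
delegate alignment to an external tool whose exact parameters are not
recoverable, so a fixed, documented scheme was chosen to make tests
exact.  Identity is matching columns over all alignment columns; the
lexicographically smaller sequence is always aligned first so that
identity(a, b) = identity(b, a) even when multiple optimal alignments
exist.  Genome-to-genome distance is the gene-length-weighted mean of
per-MG distances.

Average-linkage agglomeration merges the pair of clusters with the
smallest mean inter-cluster distance while that minimum is ≤ the cutoff
(0.035, i.e. 96.5% identity); ties are broken by the lexicographically
smallest pair of cluster representatives, making the partition
deterministic.  Open-reference clustering assigns metagenome-derived
genes to existing reference clusters greedily in order of decreasing
best identity (the interleaving of assignment and de-novo clustering is
unspecified upstream; assigning the most confident genes first lets
later genes see the augmented clusters), treats alignments under 20
aligned bases as identity 0, and clusters the remainder de novo at the
same cutoff.  The centroid (medoid) of a cluster is the member with
maximal mean identity to the others, ties to the smallest id.

## Co-abundance binning

Correlations are computed per biome on column-normalised (relative)
abundances, optionally log-transformed after adding a pseudocount of
half the smallest nonzero relative abundance in the biome (no
pseudocount rule is specified upstream; half the smallest observed
value keeps zeros below every real observation without distorting the
scale).  MGCs detected in fewer than the biome's prevalence minimum are
excluded pairwise.  Shipped biome presets: gut 5/Pearson/log, ocean
5/Pearson/raw, oral 50/Pearson/raw, vaginal 5/Pearson/log, skin
10/Spearman/log.

Because raw correlations are not comparable across biomes, each biome's
values are mapped to an FDR-calibrated association using reference MGC
pairs of known same/different-species status: the empirical FDR at
threshold t (false fraction among labelled pairs with correlation ≥ t)
is monotonised as in q-value estimation (reverse running minimum), and
the association of a correlation c is 1 − FDR(c).  Two correlations
with the same empirical FDR therefore receive the same association,
which is the defining property of the calibration; its exact functional
form upstream is unknown.  A pair's final association is the maximum
over biomes in which it survived filtering, and the binning cutoff of
0.8 is read on the calibrated scale, i.e. binning stops when the
empirical FDR exceeds 0.2.

Greedy binning starts from the reference seed groups, processes pairs
in decreasing association (ties by pair id) down to the cutoff, and
merges two groups only when the union keeps at most one MGC per COG —
seed groups are extended, never split.  Groups of ≥ 6 MGCs become
mOTUs.  Binning quality is checked by resampled k-fold cross-validation:
held-out reference MGCs are stripped of labels, associations are
re-calibrated on the remaining labelled pairs, and held-out pairs are
scored against the same-group ground truth by AUROC.

## Taxonomy

The weighted LCA retains protein hits within 90% of the top bitscore
and, walking from species upward, reports the deepest taxon whose
retained hits cover ≥ 75% of the retained bitscore sum.  MGCs inherit
the lineage of their best-scoring member (ties to the smallest member
id).  A meta-mOTU is annotated per rank by the plurality name among
MGCs annotated at that rank, requiring ≥ 3 of them; plurality ties
break lexicographically (no tie rule is specified upstream).  "At least
half in agreement" is read non-strictly (≥).  Ranks are forced
consistent top-down: a rank is blanked, truncating the lineage, when no
lineage supporting the chosen name extends the chosen parent — this
preserves the gap-freeness invariant of lineages.

## SNV profiling

Only unique-insert alignments against the centroid database feed the
pileups; padded positions are excluded and positions are reported in
coding coordinates.  Per sample and mOTU, horizontal coverage is the
percentage of pooled centroid positions covered ≥ 1×, vertical coverage
the mean reads per position.  The filter cascade (defaults fb = 80%,
fd = 5×, fm = 2 samples, fc = 5 reads, fp = 0.9) is applied in order:
sample kept iff horizontal ≥ fb and vertical ≥ fd; mOTU kept iff ≥ fm
samples remain; position kept iff depth ≥ fc in ≥ fp of the kept
samples.  A kept position becomes a SNV row only if some kept sample
shows the alternative allele at count ≥ 2 (the underlying pileup
caller's thresholds are not specified; 2 suppresses singleton
sequencing errors and is configurable).  At multi-allelic positions the
most frequent alternative across samples is reported and others are
dropped.  Cells where a sample's depth is below fc are missing and are
excluded pairwise from distances.

Manhattan distance is the summed absolute allele-frequency difference
over shared positions.  The major-allele distance counts positions
whose frequencies differ by more than 0.5 and divides by the number of
shared positions — normalising makes values comparable across sample
pairs with different missingness, at the cost of no longer being a raw
count.

## The simulator

The generator plants exactly the structure the methods assume: every
species carries one MG per COG (single-copy), members within an MGC are
≥ 99% identical, species are mutually far below the 96.5% boundary,
co-abundant MGC rows share a species trajectory, and strain mixtures
have exact known allele frequencies.  Reads are 150 nt pairs at
350 ± 30 nt insert size with uniform substitution errors only — no
indels (keeping NM/identity arithmetic exact), no quality scores, no
GC or coverage bias, no chimeras.  Genomes are small (~12 kb) and
marker-dense, so marker loci cover a far larger genome fraction than in
real organisms; this changes absolute coverage bookkeeping but not the
estimators under test.  Consequences for interpretation: passing tests
demonstrate the correctness of the algorithms under their own model
assumptions (and their exact arithmetic), not robustness to indel
errors, conserved cross-species regions causing ambiguous mappings, or
incomplete databases beyond the planted unbinned fraction.

Default study conditions, chosen as a ~2000× scale-down of a production
benchmark: 20 species (half without reference representation), 10
samples, 50,000 inserts per sample, log-normal (σ = 1) compositions;
binning uses 30 samples with σ = 0.1 log-noise; strain simulations use
10 samples of 2000 inserts with a 1% variant rate and mixture
proportions spanning 0–1.  All generators are pure functions of
(config, seed).

## Numerical and edge-case choices

* Coordinates are 0-based half-open internally; SAM input is converted
  on parse.  The manifest is a single TSV with a `#` header.
* Unbinned membership is encoded as mOTU id `-1`, matching the profile
  convention.
* A record lacking both NM and MD, or with an unparsable CIGAR, is a
  hard error naming the read — silent skipping would bias abundances.
* `scale_counts` with zero total coverage but nonzero inserts is an
  error (inconsistent inputs); all-zero profiles stay all-zero and are
  never renormalised.
* Constant abundance rows have undefined correlation; they are scored 0
  rather than NaN so downstream maxima stay defined.
* Empty hit lists and unannotated members yield empty lineages, never
  exceptions, since absence of annotation is a normal outcome.
* Bootstrap CIs (individuality AUROC) default to 1000 resamples with a
  recorded seed; production analyses would use more.

## Known limitations

* The average-linkage implementation is O(n³) and intended for the
  desk-scale databases the simulator produces, not for 10⁵-gene
  production clustering.
* The CAMI/Bioboxes writer emits the species-rank section only.
* Indels are unsupported throughout (parser, pileup, simulator).
* The MD-tag fallback counts substitutions only; NM is the primary
  source of edit distances.
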