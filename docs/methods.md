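# Methods

`markergeo` quantifies how well a genome collection represents the
microbial populations detectable in a set of metagenomes, using a
single-copy marker gene (canonically a short ribosomal protein) as the
unit of observation. This note records the models, the defaults and why
they hold, the numerical conventions, and what the synthetic communities
do and do not emulate.

## The population unit: marker-gene clusters

Every occurrence of the marker — in isolate genomes, MAGs, SAGs, and raw
metagenomic assemblies — is pooled and dereplicated at the nucleotide
level. A cluster of marker sequences is treated as one population; its
representative is the recruitment reference and the tree tip. Because
ribosomal proteins evolve under strong purifying selection, the
nucleotide identity separating distinct species is higher for them
(~99%) than the 95% genome-wide ANI convention; the default clustering
threshold of **97%** is deliberately conservative: it undercounts
populations rather than splitting one population into several references
that would then recruit each other's reads ambiguously.

### Hit filtering

Marker occurrences arrive as HMMER `--domtblout` domain hits. Two
filters remove spurious and artifactual hits:

* **model coverage** `(hmm_to − hmm_from + 1) / model_length ≥ 0.8` —
  a genuine marker hit spans most of the profile's match states;
* **complete ORF** — partial gene calls (typically contig-edge
  truncations) are excluded by default.

The marker family itself can be chosen automatically: among candidate
models, those whose metagenome hit count deviates from the median across
candidates by more than ±50% are discarded as under- or over-assembled
(an explicit, testable stand-in for what is usually a visual judgement;
the window is configurable), and the survivor annotated in single copy
in the largest fraction of genomes wins, with deterministic ties
(presence fraction, then name).

### Clustering semantics

Pairwise identity uses a global alignment with free terminal gaps
("glocal"; match +2, mismatch −3, gap −5/−2): identity = identical
aligned positions / alignment columns excluding terminal-gap columns
(`N` never matches), and target coverage = aligned positions / length of
the shorter sequence. This makes an extended open reading frame cluster
with its core: an exact fragment scores (1.0, 1.0). Clustering is
greedy-centroid: longest sequence first (ties by id), each sequence
joins the first representative it matches at identity ≥ 0.97 and target
coverage ≥ 0.8, else it seeds a new cluster. The default coverage floor
of 0.8 mirrors common dereplication practice and is configurable. A
second pass at **98%** (`recluster_representatives`) is available to
split clusters that lump near-identical genomes. The greedy rule is
deterministic end to end and is tested against a brute-force re-
evaluation of the same rule from an all-pairs identity table, and the
aligner configuration against an independent dynamic-programming oracle.

## Read recruitment and its statistics

References are short (~400 nt), so the built-in mapper is deliberately
simple: exact k-mer seeds (k = 15) on both strands, ungapped rescoring
of every candidate diagonal over the full read, primary = best score
with ties broken by reference id then leftmost position. A read is
mapped only if its best score is non-negative (≥ 60% matches at the
default scoring). Indels are not modelled — the paired synthetic reads
are substitution-only, and real alignments can be supplied as SAM with
`AS`/`XS` tags instead (pysam handles the format).

Per (reference, sample) the pipeline reports:

* **detection** — fraction of reference positions covered by ≥ 1 read.
  This is the statistic used for presence/absence and clustering because
  it saturates quickly and is insensitive to ambiguous read placement.
* **Q2Q3 coverage** — mean depth over the interquartile positions of the
  sorted depth vector: 1-based ranks `⌈n/4⌉+1 … ⌊3n/4⌋` (all positions
  when n < 4). The rank rule is stated exactly because percentile
  conventions differ between tools; it is robust to coverage spikes and
  feeds the Shannon/richness summaries.
* **non-specific fraction** — mapped reads whose best and second-best
  placement scores tie, divided by all mapped reads. Sister references
  above the clustering threshold inflate this number, which is the
  empirical argument for merging at 97%: in the packaged benchmark a
  98.5%-identity pair retained at a 0.99 threshold recruits ambiguously,
  and the same reads against the 97%-merged single representative do not.

## Phylogeny

Representative proteins are aligned progressively: guide tree from
3-mer-composition cosine distances (UPGMA), profile–profile merges
scored by mean BLOSUM62 sum-of-pairs with affine gaps (open −10,
extend −1), deterministic tie-breaks. Columns with > 50% gaps are
removed (a fixed-threshold approximation of adaptive gap trimming —
conservative for short, globally alignable ribosomal proteins), then
rows with > 50% gaps (strict inequality at the boundary). Distances are
gap-aware p-distances with the 20-state Poisson correction
`d = −(19/20)·ln(1 − 20p/19)`, capped at 10 when saturated. The tree is
classical neighbor joining (Saitou–Nei Q criterion) with lexicographic
tie-breaks and negative branch estimates clamped to zero; it is exact on
additive matrices (tested on random tree-derived matrices and against
scikit-bio's NJ). Approximate-ML inference and bootstrap support are out
of scope; topology is the tested contract. With ~130 alignment columns
the corrected distances saturate beyond roughly 1 substitution/site of
tip-to-tip divergence, so topology recovery is demonstrated at branch
lengths of 0.1 substitutions/site. In place of manual curation, tips
whose terminal branch exceeds 5× the median terminal branch are flagged
for human review, never removed.

## Integration and recovery rates

The detection matrix (samples × representatives) is assembled losslessly
from the profiles, with absent pairs at 0. Reference genomes — isolates,
SAGs, and MAGs not binned from the profiled samples — are dropped unless
detected at ≥ 0.9 in at least one sample; MAGs from the samples
themselves and assembly-only representatives are always kept. Samples
and sequences are clustered with Ward linkage on Euclidean distances
(labels are sorted first, so the result is invariant to input order);
the metric is configurable since it is a display convention, not a
claim.

A cluster's taxon is the per-rank strict-majority consensus of its
annotated members, truncated at the first rank without a majority.
Unassigned tree tips may inherit a lineage when the smallest enclosing
clade containing annotated tips holds at least two of them and all agree
on the identical lineage — deliberately conservative, single-pass (new
labels never seed further propagation), and every propagated label is
flagged for audit.

The **genome recovery rate** of a taxon for a set of recovery methods
is the fraction of that taxon's clusters containing at least one member
from any of those methods, with the denominator restricted to clusters
detected in at least one metagenome (detection > 0 by default; the floor
is configurable up to the 0.9 reference filter). Rates are exact
rationals internally and percentages (1 decimal) in reports. Two
ancillary genome-level filters: a genome counts as *detected* in a
metagenome when ≥ 50% of its positions are covered, and MAG/SAG inputs
are expected to meet the medium-quality draft bar (completion ≥ 50%,
redundancy ≤ 10%, both inclusive).

## Synthetic communities

The simulator provides ground truth for every stage. A Yule tree
(rescaled to a median tip-to-tip distance of 0.15 substitutions/site,
the regime where sister taxa straddle the 96–99% identity band) carries
a 393-nt stop-free coding marker evolved under Jukes–Cantor with codon
structure (third position 3× faster, rates normalised to mean 1). Taxa
are assigned to one of two habitats (10% cosmopolitan) with log-normal
relative abundances (σ = 1, plus a 0.005 floor so every resident is
detectable), and independently designated as having an isolate genome
(p = 0.4), a MAG (p = 0.6), and presence in the assembly (10% dropout,
modelling markers that fail to assemble). Default scale: 24 taxa, 2
habitats, 6 samples/habitat, 20,000 100-nt reads per sample at 0.5%
substitution error — chosen so a full end-to-end run completes in well
under a minute on one CPU while leaving tens of clusters and strong
habitat signal. Emitted fixtures include planted decoys (a 60%-coverage
hit and a partial ORF) that must be removed by the filters.

What the simulator does **not** emulate — and hence what passing tests
cannot certify about real data: indels and structural error in reads,
chimeric assembly artifacts, paired-end structure, genome-context
effects on assembly (dropout is assigned at random, not by community
complexity), uneven marker copy number, and taxonomy noise (labels are
exact by default). The expected cluster partition is computed by the
package's own clusterer at truth-build time, so the end-to-end closure
test certifies the pipeline plumbing; clustering correctness itself is
established against independent brute-force oracles.

All randomness in the simulator and workflow flows from a single integer
seed through `numpy.random.SeedSequence`; identical seeds produce
byte-identical fixtures and outputs.

## Workflow

`run_all` executes detect → cluster → recruit → tree → integrate →
recover, each stage writing plain-text outputs and recording its input
checksums, parameters and counts in `manifest.json`. A stage is skipped
when its outputs exist and its inputs' checksums are unchanged, so
replacing an intermediate re-runs exactly the downstream stages.
Exit codes: 0 success, 2 configuration error, 3 stage failure.
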