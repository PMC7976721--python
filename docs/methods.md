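# Methods

This note documents the models, defaults and design decisions behind
bseeker, and what the synthetic-data tests do and do not demonstrate.

## Copy-number model

Per-contig mean depth is converted as `copies = d·G/(2L)` with `d` the mean
depth over the CDS, `G` the effective genome size in bases and `L` the
library's total sequenced bases. The factor 2 reflects that a diploid
individual's two homologs both map onto the single haploid reference
coordinate; this is the unique normalization under which a single-copy gene
scores 1.0 and a gene with one extra B copy scores 1.5 in a 1B individual,
making the selection threshold log₂(3/2) self-consistent. `L` is taken as
raw library bases by default (mapped bases would be an alternative; the
choice only rescales all copy numbers of a library jointly and is
config-switchable in spirit by adjusting `total_bases`).

The effective genome size is
`(diploid_pg + b_count · b_fraction · diploid_pg/2) · 0.978 Gb/pg`.
Defaults: diploid size 3.74 pg, B fraction 5 % of the haploid complement —
giving 3.658 Gb (0B) and 3.749 Gb (1B). Sister taxa of a species complex
may reuse the same model. Mean depth is computed over the CDS by default
(`region="full"` is available) because the annotated CDS is the unit of
candidate selection; flow-cytometry, GC-bias and mappability corrections
are out of scope.

## Candidate selection

- Copy filter: contigs kept when mean 0B copies ∈ [0.5, 4], bounds
  inclusive. Below 0.5 suggests assembly/mapping artefacts, above 4
  repetitive DNA.
- gFC is per 1B individual against the 0B mean. The multi-replicate rule
  (all replicates ≥ threshold) exploits biological replication to control
  false positives; with only one 1B individual the threshold rises to 1.0.
- The threshold constant is stored as exact log₂(3/2) = 0.5849625…, not
  the printed rounding 0.585, and compared with ≥, so a noise-free contig
  at exactly 1.5× passes its own defining threshold.
- A contig whose 0B mean copy number is ≤ 0 cannot have a gFC; such
  records are flagged unselectable rather than raising, since they simply
  fail selection.

## Coverage-pattern segmentation

"Abrupt coverage changes" are operationalized as recursive binary
change-point splitting of the per-position log₂(pooled 1B / pooled 0B)
ratio (library-size normalized within each genotype group, 0B-zero
positions masked). A split is accepted when both sides span at least
`min_seg_len` positions (default 100 nt, about the scale of a qPCR
amplicon) and their mean log₂ ratios differ by at least log₂(`ratio_jump`)
(default 1.3, comfortably above Poisson noise at depth ≥ 30 yet below the
1.5× one-copy step). One segment ⇒ UC; several ⇒ IC. Segments are
labelled HC/LC relative to the contig-wide mean log₂ ratio, and adjacent
same-label segments are merged so labels alternate. Pooling depth across
libraries before the ratio stabilizes the per-position estimates.

## B-specific SNP cascade

Groups are merged by summing per-position counts across libraries (sums of
independent Poisson counts remain Poisson, so merging loses nothing at this
resolution). The Ref allele is the majority base in 0B gDNA; fixation
requires ≤ `max_0B_alt` (default 0) non-Ref reads there. The Alt allele is
the most-counted non-Ref allele in 1B gDNA (ties broken by the fixed order
A<C<G<T<ins<del). Filters: 0B fixation; 1B proportion (default keeps
Ref ≥ Alt — a single-copy B paralog predicts Ref:Alt ≈ 2:1, and sites
failing it typically reflect multi-copy B paralogs whose copies split
between Ref and Alt; the direction is a flag because either convention is
defensible); cross-species exclusion (≥ 2 Alt reads in any sister-species
0B library ⇒ ancestral polymorphism, not a B variant); depth ≥ 10 per gDNA
group. The PASS set is a conjunction of independent conditions, so it does
not depend on evaluation order; the verdict label uses a fixed priority.
Adjacent PASS indels of the same type share one event id. Synonymous /
non-synonymous classification is out of scope (requires codon frames).

## Expression

Per gene, Ref and Alt RNA reads are summed across passing SNP positions
before the Alt/Ref ratio is taken (ratio of sums, robust to per-SNP zero
counts). Normalization divides by transcript length — the curated
transcript including UTRs when that is the reference, else the CDS length.
A gene with Alt > 0 but Ref = 0 reports an infinite ratio rather than
being dropped; a gene with no passing SNPs yields no record because its B
paralog is indistinguishable from the A copies. Genes' shares of
B-derived transcription are alt-normalized values rescaled to sum to 1.

## qPCR arithmetic

Technical replicates are averaged per biological sample before any group
statistic (they estimate well-to-well noise, not biology). RQ = 2^−ΔCt;
NREQ = 2^−ΔΔCt calibrated to the 0B group's mean ΔCt, which forces the
calibrator group's geometric-mean NREQ to 1. The Gardner–Altman
comparison resamples each group with replacement (default 5000 resamples),
reports the 2.5/97.5 percentile interval of the mean difference, and
validates when the interval lies above zero; BCa was considered and
rejected in favour of the simpler percentile interval since the decision
rule is a sign test on the CI. With n = 3 per group the percentile
bootstrap is anti-conservative — the validation rate test therefore uses
n = 5, and single-1B designs use the strict rule (1B RQ above every 0B RQ).

## Comparative statistics

The binomial coincidence pmf is assembled from log-gamma terms, so
n in the hundreds needs no factorial arithmetic; the percent-rescaled
variant (k, n mapped to percentages of 100) is reported alongside for
comparability with spreadsheet-limited computations. The Mantel test is
one-tailed for positive association (the directional hypothesis that gene
content tracks phylogeny), with p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1)
and 10,000 permutations by default. p-distances use pairwise deletion of
gaps and ambiguity codes. Hierarchical clustering of gene content is not
needed: the Euclidean distance matrix between binary columns is the
statistic of record.

## Synthetic data

The generator reproduces the study design: a focal species with 3 0B +
3 1B gDNA libraries and 2 + 2 ovary RNA libraries, and a sister species
with a single 0B pair used by the cross-species SNP filter. Per-position
gDNA depth is Poisson with mean `copies_per_cell × L/G` (independent
across positions; a gamma-Poisson overdispersion knob exists for
robustness tests), which matches the copy-number estimator's assumptions
exactly — so these tests validate the pipeline's arithmetic and filter
logic, not its robustness to mapping bias, GC effects, paralog
cross-mapping or real overdispersion, none of which the generator
emulates. Defaults: 230 genes (200 single-copy, 14 UC + 6 IC B-linked,
5 repetitive at 6 copies/haploid, 5 low-copy at 0.3), 1000-nt contigs with
an 800-nt CDS, depth factor L/G = 20 (0B depth ≈ 40×), SNP rate 0.01/nt on
B paralogs with 10 % indels, RNA depth 200×, Ct noise 0.2 cycles.

`b_copies` defaults to 2 extra copies for UC B-linked genes and 4 for the
HC half of IC genes. A deliberate design point: a gene with exactly one
extra B copy has expected gFC exactly at the selection threshold, so with
symmetric sampling noise each replicate passes only about half the time —
the threshold is the theoretical *minimum*, and genuinely detectable
B-linked genes sit above it, as the validated genes in real B systems do
(multi-copy B paralogs are common). Recovery tests therefore plant a
detectable dose by default, while the unbiasedness of the gFC estimator at
one extra copy (mean log₂(1.5)) and the SNP caller's operating point at
Alt fraction 1/3 are tested with explicit `b_copies=1` configurations.
IC genes' B fragments are transcriptionally silent in the generator,
providing the "SNPs but no expression" phenotype; UC genes transcribe at a
configurable B:A ratio (default 1).

Ct tables encode the planted dose as ΔCt = −log₂(ratio) + N(0, σ²) per
well, with gDNA RQ seeing the HC-region dose (qPCR primers target HC
regions of IC genes) and RNA fold = 1 + B:A ratio.

## Problem sizes and numerical choices

The default fixture (230 genes × 1 kb, 10 focal libraries) simulates in
about two seconds and the full test suite runs in well under a minute, so
properties are tested at their stated sizes (≥ 200 neutral genes for the
gFC null, ≥ 100 planted SNPs, 500 null Mantel simulations, 1000 bootstrap
coverage simulations) rather than scaled down. Bootstrap and permutation
procedures take explicit seeds and are exactly reproducible; the pipeline
fans a single top-level seed out to stages by fixed offsets. Degenerate
inputs (all-masked ratio tracks, empty calibrator groups, constant
vectors, zero 0B means) raise informative errors or flagged undefined
values as documented per module.

## Known limitations

Simulation is at the depth/pileup level; read-level artefacts (mapping
ambiguity between diverged paralogs, indel realignment, base-quality
error) are upstream of the package's inputs and untested. The binomial
coincidence model assumes genes land on an extra chromosome independently
with equal probability per chromosome. The Mantel test with four species
has a minimum attainable one-tailed p of 1/24 ≈ 0.042. qPCR validation
with three samples per group relies on an anti-conservative bootstrap and
should be read as evidence ranking, not calibrated inference.
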