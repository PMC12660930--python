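# Methods

This note documents the models and procedures behind `snmctkit`, the
tunable parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was open.

## Data model

A nucleus is a pair: a per-cytosine methylation call table
(chrom, 0-based position, strand, context ∈ {CG, CHG, CHH}, methylated
reads `mc`, total reads `cov`, with `mc ≤ cov` and one record per site) and
an RNA count vector over a shared gene universe with organelle-gene flags.
Region sets are 0-based half-open intervals. Methylation files on disk
follow the common allc-style 1-based dialect by default; the reader's
`position_base` switch (0 or 1) makes the conversion explicit rather than
silent. Sequence context is carried in the file, not recomputed from a
reference genome, which removes any FASTA dependency; organelle sequences
are recognized by chromosome name (default `{ChrC, ChrM}`).

## Nucleus QC

*Basic filter.* Keep wells with ≥ 1000 RNA reads (total counts assigned to
genes — the available proxy once a count matrix is the input) over ≥ 200
detected genes, and ≥ 10% of 1-kb bins genome-wide with at least one WGBS
read. Bins tile each nuclear chromosome from 0; the last partial bin
counts. "At least" thresholds are inclusive; the organelle filter
("> 10% of RNA reads") is strict. A zero-read well fails the RNA filter
rather than raising.

*Coverage doublet censor.* In deduplicated haploid data no site can be
covered twice, so `multi_fraction` (share of covered sites with cov > 1) is
essentially zero for singletons and ≈ o/(2c − o) for a union of two nuclei
with capture rate c and overlap o = c². Because the statistic's sampling
floor rises with total coverage, nuclei are binned into quantile bins of
total covered sites (default 10 bins, value-based so tied totals share a
bin) and flagged when `multi_fraction` > median + k·1.4826·MAD within the
bin (default k = 5). In degenerate bins (MAD = 0, e.g. all singletons at
exactly 0) a nucleus is flagged only when strictly above both median + 1e−6
and every unflagged member, so identical values never censor each other.
The numeric rule is a declared stand-in — no published rule exists for this
statistic — and is validated against planted ground truth only. Cohorts
under 20 nuclei skip censoring with a warning.

*Conversion QC.* With an unmethylated chloroplast, apparent chloroplast
methylation Σmc/Σcov estimates 1 − conversion rate. Wells are censored from
methylome analyses when the fraction exceeds `max_chloro_mc` (default 0.03;
genuine failures are typically ≫ 3%) **and** chloroplast coverage is at
least `min_chloro_cov` (default 100) — below that the estimate is reported
but never flagged, since at 3% true failure the binomial SE at 100 reads is
±1.7% and a flag would be noise.

*Order.* Filters apply as: basic RNA/WGBS → coverage-doublet censor →
organelle → cluster assignment → VN/SN reassignment → conversion QC, the
last censoring methylome analyses only.

## Cluster assignment

Graph clustering and embedding are deliberately out of scope: pollen
nucleus types are few, well separated, and have validated markers, so
supervised marker scoring is the testable core. Expression is normalized to
counts-per-10k then log1p, with organelle genes excluded before scaling
(they reflect contamination, not cell state). Scores are per-cluster means
of gene-wise z-scored normalized expression; the argmax labels the nucleus,
ties broken by the developmental ordering (MN, MNtoVN, VN1, VN1to2, VN2,
VN3, VN4, VN5, GN, SN). Projection of a new experiment onto a reference
cohort freezes the reference's per-gene mean/SD (`ZParams`) and scores new
nuclei against them. Genes constant across nuclei contribute z = 0; markers
absent from the matrix are dropped with a warning, and a cluster losing all
markers is an error.

Mature VN and SN stick together physically during sorting, so wells
labelled VN4, VN5 or SN with
r = log2((mean SN-marker expr + ε)/(mean VN4/5-marker expr + ε)) inside
[−0.2, 0.2] (inclusive — "within") are relabelled `VN_and_SN`;
ε = 1e−9 guards empty marker means. Only those three labels can move.

## Methylome statistics

Per-nucleus region methylation is Σmc/Σcov over covered in-region sites of
one context; a nucleus with no qualifying site is missing (NaN), never 0.
`min_cov` defaults to 1 for single-nucleus statistics (haploid nuclei
rarely exceed 1×) and to 5 for bulk-style mC-density analyses, matching the
different sequencing regimes; `min_sites` (default 1) optionally requires a
minimum number of covered in-region sites per nucleus. Pseudobulk pooling
sums (mc, cov) per site over member nuclei split by genotype, so
pooled fractions are exactly coverage-weighted means of per-nucleus
fractions — an identity the test-suite asserts at 1e−12.

Metaplot profiles are strand-aware: reference-point mode bins [−flank,
flank) around the start (on −, end−1) anchor; scale-regions mode maps each
region body linearly onto n bins, reversing orientation on −. mC density
per 400-bp bin is the sum over qualifying cytosines of 100·mc/cov (units:
summed percent), tiled or centered on peak midpoints ([m − 200, m + 200)).
TSS windows are [anchor − 400, anchor + 400) clipped to chromosome bounds.
Chromosome-scale profiles are rolling weighted means (default 100-kb
window, 10-kb step; the smoothing method is otherwise unconstrained).

Cohen's d uses the pooled SD with n−1 denominators; s_p = 0 yields 0 for
equal means and a signed-infinity sentinel otherwise (star "****").
p-values are Welch two-sided t-tests — chosen over Student's since group
variances differ whenever coverage does; both conventions are the field's
robust defaults. Star boundaries are half-open, closed on the left
(n.e. < 0.2 ≤ \* < 0.5 ≤ \*\* < 0.9 ≤ \*\*\* < 1.5 ≤ \*\*\*\*), making the
map total where the legend convention (strict ">") leaves equality
unassigned. Grid cells with fewer than 2 non-missing nuclei per group are
marked insufficient rather than computed.

## Overlap and homology

Reciprocal overlap: interval A_i overlaps when its bases shared with the
(merged) union of the other set strictly exceed half its length, or when
some single interval B_j shares strictly more than half of *its* length
with A_i. ">50%" is read literally: exactly half does not qualify.
Overlapping or book-ended intervals within a set are merged first, with a
warning (whether to merge was an open choice; merging keeps the per-side
counts well-defined). The shuffle null preserves interval lengths and
per-chromosome counts (chromosomal composition matters — pericentromeric
region sets should stay pericentromeric in count), places starts uniformly
with rejection of intra-set overlap, and is deterministic under a seed. The
implementation is a sorted searchsorted sweep, tested for exact agreement
with an independent per-base brute-force oracle.

Homology: per locus, best (max) bitscore against gene vs TE/TE-gene
annotations; significance means bitscore > 100 (one unified cutoff — the
source rule names a cutoff only for TE hits and leaves "significant
homology" to genes undefined); only when both classes are significant does
the ≥ 3× ratio decide, else ambiguous; neither significant → neither.
Significance screens before the ratio.

## Expression statistics

TPM is the standard length-normalized rate scaled to 1e6. The DE test is an
explicitly simple stand-in — Welch t on log2(CPM + 1), BH correction,
significant iff padj < 0.05 and |log2FC| > 1, with the method name stamped
in the output metadata so its calls are never mistaken for a count-model
fit (count-model DE is out of scope by design).

The rescue classifier z-scores each mutant-upregulated transcript's TPM row
across samples, clusters rows with average-linkage Euclidean hierarchical
clustering, and labels each cluster by its centroid's rescue ratio
r = (log2(mutAB + 1) − log2(WT + 1)) / (log2(mutA + 1) − log2(WT + 1)):
r ≤ 0.25 rescued, ≤ 0.75 partially rescued, else not rescued. Clusters that
do not fall cleanly into that monotone pattern are "other": weak mutant
upregulation (|log2FC| < 0.5), overshoot (r < −0.25 or r > 1.5), or
misregulation in a control genotype (|log2FC(mutB/WT)| > 0.5). The default
cut is k = 8 clusters — deliberately more clusters than labels. Cutting the
dendrogram exactly at the class count proved brittle: at realistic
replicate noise, average linkage merges adjacent classes before separating
all four, and the merged centroid silently absorbs a class. Over-clustering
costs nothing (labels come from centroids and still partition the input)
and is robust; k, the linkage, and every threshold are configurable. All
numeric choices here (k, 0.25/0.75 ratio cuts, the "other" rules) are
package decisions: the three-way split plus an omitted residual class is
the structure being reproduced, not a published algorithm.

Activation timing: the earliest cluster along VN maturation where
log2((mut + 1)/(WT + 1)) exceeds 1 with mutant mean above `min_expr`
(default 0.5) classifies a transcript as immature-VN (VN1–VN3) or
mature-VN (VN4–VN5) activated, else none.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions
for every recovery test.

*Methylome.* Cytosine sites are placed uniformly per chromosome (default
3 sites/kb/context background, with denser placement inside modelled
regions — e.g. 20 CG sites/kb in CG-hypo DMRs, reflecting the CG-dense
nature of methyl-reader targets). Each region model sets per-context
baselines plus additive per-cluster and per-genotype deltas (clipped to
[0, 1]); defaults encode progressive CG demethylation at CG-hypo DMRs
(0 at MN falling to −0.58 by VN5, steepest across VN1–VN2 then
plateauing), progressive pericentromeric CHH gain (+0.34 by VN5), a
slight SN CG gain, and untouched control regions. Genotype deltas apply in
VN clusters and are cancelled at the flagged "rescued" region subset for
`rescued_genotypes`. A singleton nucleus captures each site independently
(Bernoulli, default 5% nuclear, 50% chloroplast — organelle copy number
makes chloroplast coverage deep in real data) and calls it methylated with
the site's true probability; conversion-failure nuclei add false methylated
calls at rate `1 − conversion` on all sites, chloroplast included.
Doublets are unions of two complete nuclei's reads (mature-VN + SN pairs
preferentially), which produces the > 1× coverage signal and the mixed
marker expression from one mechanism. A `gn_diploid` flag can make GN
post-S-phase two-copy; default off keeps the haploid invariant clean.

*Transcriptome.* Counts are negative binomial (default size 10) around a
baseline mean (2.0) scaled by a lognormal library factor (σ = 0.2), with
organelle genes taking a Beta-distributed read fraction (mean 3%, shape 5 —
tight enough that clean nuclei stay below the 10% censor threshold).
Marker programs are stage-graded, 8 markers per cluster: each cluster's
markers are at 8-fold in their home cluster and 2.5-fold in trajectory
neighbours; VN4/VN5 share a mature-VN core (expressed in both) plus
stage-specific markers; SN shares germline genes with GN. The grading is
what makes a real VN+SN doublet's SN/mature-VN marker log-ratio land near 0
(inside the ±0.2 reassignment window) while singletons stay well outside —
flat cluster-exclusive panels would bias the ratio and break both the
reassignment and the VN4-vs-VN5 distinction. Panel sizes and folds are free
parameters chosen once so the generator meets its own documented recovery
contracts.

*Determinism.* All randomness flows from one seed; per-nucleus substreams
are keyed by `SeedSequence([seed, crc32(nucleus_id), stream])`, so output
is byte-stable across runs, platforms and processes, and adding or removing
a nucleus never perturbs another's data.

*What it does not emulate.* No read-level or alignment artefacts, no
within-region spatial autocorrelation of methylation (downstream statistics
aggregate over regions, so it is not needed to test them), no batch or
plate effects, no doublets of more than two nuclei, no cell-cycle or
continuous pseudotime structure within a cluster, and no realistic sequence
content. Passing recovery tests therefore demonstrates the correctness and
calibration of the statistics under the generative assumptions, not
robustness to every artefact of real libraries.

*Fixture presets.* `tiny` (≤ 50 nuclei, 3 clusters, loads instantly),
`qc_stress` (planted counts of every QC failure category plus doublets),
`trajectory` (all 10 clusters × 100 nuclei, 3% VN+SN doublets),
`rescue` (3 genotypes × 6 clusters × 100 nuclei, half the CG-hypo DMRs
rescue-flagged). Problem sizes were chosen so the whole test-suite runs on
one CPU in about a minute while keeping per-group sample sizes at the
levels the recovery claims are stated for (100 nuclei/group for effect
grids, 300 + 15 for doublet censoring, 200 transcripts for rescue
classes).

## Pipeline

`snmctkit run` executes simulate/load → QC → censor → assign → reassign →
pool → region means → effect grid with a JSON run manifest (config hash,
seed, per-stage attrition, version, timestamps). Stage outputs are cached
keyed by a config/input checksum so an unchanged upstream stage is not
recomputed. All TSV outputs are byte-identical across reruns with the same
config; only manifest timestamps differ.

## Known limitations

- The doublet censor's quantile-bin MAD rule, the 0.03 conversion cutoff,
  and the rescue-classifier numeric rules are declared stand-ins validated
  on synthetic ground truth; real-data behaviour may need retuning of k,
  bin counts, or cutoffs.
- Marker-score assignment presumes a trustworthy marker panel; it cannot
  discover novel nucleus types, and panels are user input (the shipped
  panels are synthetic).
- With ~100 nuclei per group, a null Cohen's d fluctuates with SE ≈
  sqrt(2/n) ≈ 0.14, so individual unaffected grid cells occasionally cross
  the |d| = 0.2 "minimal effect" boundary; effect-size grids should be read
  with that sampling floor in mind.
- The DE stand-in has no count-model shrinkage and will be conservative at
  low counts.
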