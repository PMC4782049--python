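# Methods

`srexport` re-implements, as one tested pipeline, the computational analyses
used to establish that serine/arginine-rich (SR) splicing factors act as
adaptors for the mRNA export receptor NXF1: iCLIP cross-link site calling,
binding-landscape statistics, and fractionated (whole-cell vs cytoplasmic)
RNA-seq analysis of export, exon usage and alternative polyadenylation
(APA). All components are exercised end to end on a synthetic-data
generator with machine-readable planted truth. This note records the models,
the parameters that matter, the numerical choices, and what the simulations
do and do not establish.

## Coordinates and annotation

All internal coordinates are 0-based half-open; GTF I/O converts at the
boundary. Exon lists are kept in transcript 5'→3' order (reversed genomic
order on the minus strand). Per gene, one *representative transcript*
(longest CDS, ties broken by longest mature length then lexicographic id)
defines the region labels 5'UTR / CDS / 3'UTR / intron (noncoding genes:
`noncoding_exon` / intron); the labels tile the representative span exactly,
which is asserted in tests. Exon ordinals (first / internal / last / single)
are strand-aware per transcript. Splice sites follow the convention
5'ss = first intronic nucleotide, 3'ss = first exonic nucleotide of the
downstream exon, deduplicated across isoforms.

APA events are enumerated from isoform pairs that agree on all exons except
the last: **TandemUTR** when the two last exons share their 5' boundary and
differ in 3' extent (the distal region is the extension), **ALE**
(alternative last exon) when the last exons do not overlap. Other 3'
differences are ignored.

## Cross-link site calling

iCLIP truncation geometry: the cross-linked nucleotide is one base 5' of
the read start (plus strand: start − 1; minus strand: the half-open end
coordinate). Reads collapse to unique cDNAs by (chromosome, strand, 5' end,
random barcode), the barcode being the read-name suffix after the last ':'.

Significance is assessed per gene against a permutation null: each of
`n_perm` (default 100) permutations redistributes the gene's total cDNA
count uniformly over the gene's pre-mRNA span. For a count height h,
FDR(h) = E_perm[#positions with count ≥ h] / #observed positions with
count ≥ h, clipped to [0, 1] and made monotone non-increasing in h; a
position is significant when FDR(count) < 0.05. Genes with fewer than 10
events are skipped; intergenic events are reported but untested. The
uniform null omits mappability weighting — the synthetic genome is uniformly
mappable; users of real data should substitute a mappability-aware null.
Events are assigned to genes strand-specifically; same-strand overlaps go
to the gene with the longer span.

Significant positions within `max_gap` (default 15 nt) merge into binding
sites; the site center is the maximal-count position, ties breaking to the
5'-most position on the site's strand.

Properties verified on simulations: on a uniform (λ = 1) null the fraction
of tested positions called significant is far below the nominal 0.05
(aggregated over 20 seeds); planted 10×-enriched motif occurrences in genes
with ≥ 200 cDNAs are recovered (≥ 1 significant position within the 8-nt
footprint) with recall above 0.9. Recall is a per-occurrence quantity: a
single position with a Poisson(10) count fails the within-gene threshold
roughly 13% of the time at any depth, so position-level recall cannot reach
0.9 at 10× enrichment; occurrence-level recovery is the meaningful notion
and is what the ground-truth placement list records.

## Junction statistics

Profiles around splice sites accumulate event counts at signed offsets
(negative = exonic side of a 5'ss, intronic side of a 3'ss; i.e. offsets
increase in transcript direction), raw and per million unique cDNAs. At
annotated 5' splice sites, a read is *unspliced* when its contiguous
alignment covers ≥ `min_overhang` (default 3) nt on both sides of the
exon/intron boundary, and *spliced* when an alignment gap matches an
annotated intron exactly with ≥ 3 nt in both flanking exons; gapped reads
matching no annotated intron are tallied separately as novel junctions.
The pooled spliced proportion recovers the generator's spliced fraction
within ±0.03 at 10,000 junction reads. Last-exon metaprofiles scale each
last exon to 100 bins from the last 3'ss to the poly(A) end, with
fractional bin assignment so mass is conserved for short exons.

## Occupancy, cobinding and clustering

Region densities are significant events per nucleotide of each region
label, per million unique cDNAs; each event lands in exactly one label of
its gene's representative transcript. The exon-level binding matrix sums
significant counts per representative-transcript exon per library (raw and
per-million). An exon is *bound* at ≥ 1 significant position (stricter
thresholds are config knobs); a library's cobound-exon fraction is the
share of its bound exons also bound by another SR library (the receptor
and the nonspecific control are excluded from the SR set).

Library similarity uses Spearman rank correlation (default; rank-based and
scale-free, so raw vs log counts are irrelevant) or Székely–Rizzo distance
correlation (O(n²), computed on a seeded subsample of at most 5,000 exons),
followed by average-linkage clustering on 1 − correlation. Constant columns
are reported and excluded. The tree is exported as Newick with merge
heights as branch lengths.

NXF1-centric cobinding counts, for each SR library and NXF1 site, the
distinct significant SR positions within ±30 nt of the site center
(inclusive window, 61 positions; "more than three" = ≥ 4 positions
cobinds). Ratios are reported per stratum — sites whose center lies in a
first exon, a last exon, or all sites; a site whose window crosses an exon
boundary stays with its center. Exclusive counts attribute sites with
exactly one cobinding SR library; the pair matrix counts SR pairs cobinding
the same site, with sole-cobinder counts on the diagonal.

## k-mer enrichment

Observed windows are strand-oriented 41-nt sequences (`flank` 20) centered
on significant positions, restricted to a region stratum (all exonic
labels, 5'UTR, or 3'UTR); windows crossing the edge of their region
interval are discarded and counted, so observed and background windows live
in the same sequence space. The background places the same number of
windows uniformly at random in the same region intervals, `n_rand` (default
100) times. Enrichment per 8-mer is

    z = (obs − bg_mean) / sqrt(bg_sd² + bg_mean + 1)

The Poisson-scale regularizer in the denominator matters: without it a
k-mer observed once against a background mean of 1/n_rand receives an
arbitrarily large score from discreteness alone. With it, z behaves like a
standard normal under the null for well-sampled k-mers and is conservative
for sparse ones; on sequence-blind null simulations no k-mer exceeds the
Bonferroni-adjusted normal quantile over 4^8 k-mers. Known limitation:
when significant positions cluster tightly (as for burst-like binders),
neighbouring windows overlap and share sequence, which the
independent-placement background does not model; z-scores for such
libraries are anti-conservative and should be read at the site level.
Consensus strings are per-column majorities over the top-n k-mers (IUPAC
letters where no base reaches 50%); motifs print in DNA by default, RNA on
request.

## Fractionated differential analysis

Design: two fractions (whole-cell, cytoplasmic) × two conditions (control,
knockdown) × two biological replicates. Size factors are median-of-ratios,
computed within each fraction (the fractions are different RNA populations;
their absolute scales are not comparable).

Transcript-level testing is a Wald test on log counts: per feature, the
log-scale variance is estimated from the replicates (pooled over both
groups, df = 2) and shrunk toward the cross-feature trend
v(μ) = b0 + b1/μ — by the delta method, v ≈ 1/μ + α for a negative
binomial with dispersion α, so b0 estimates the dispersion — with weight
0.2 on the per-feature estimate. p-values are two-sided normal, q-values
Benjamini–Hochberg. Null calibration (fraction of p < 0.05 on no-effect
contrasts) sits at the nominal level over seeds.

Export targets: `is_target` iff q_cyto < α (default 0.05) AND
log2FC_cyto < 0 AND (log2FC_cyto − log2FC_whole) ≤ −δ (default 0.585, i.e.
1.5-fold net cytoplasmic decrease beyond the whole-cell change). Both
thresholds are config knobs. A power note: with 2 replicates and NB
dispersion 0.05, the log-fold-change standard error has a floor of
√((1/μ + 0.05)) ≈ 0.23 per group pair, so a 2-fold planted effect carries
|z| ≈ 3 and BH at 10% prevalence recovers roughly 40% of planted targets —
an information limit of the design, not of the estimator; the empirical
false discovery proportion of the caller stays near 0.01. Deeper replication
or smaller dispersion, not a different test, is what raises recall.

Exon usage: replicates pool per condition; each exon is tested on the 2×2
table [exon, rest-of-gene] × [kd, control] (chi-square, or Fisher's exact
when an expected cell < 5), BH at FDR 0.1; direction is the sign of the
usage change. The generator realizes exon counts as Poisson draws around a
shared per-gene Gamma multiplier, so usage ratios carry only counting
noise; with exon-level biological overdispersion in real data the pooled
2×2 is anti-conservative, and the FDR there should be read accordingly.

APA: Ψ is the long/distal-isoform fraction. TandemUTR: the proximal region
is shared by both isoforms, so Ψ = distal density / proximal density
(length-normalized counts, capped to [0, 1]); ALE: the regions are
isoform-exclusive and Ψ = d/(d + p). The TandemUTR ratio estimator is
intrinsically noisier than the ALE binomial (both its numerator and
denominator fluctuate); at 500 informative reads the mean absolute error
stays within 0.05. Calling uses a Beta-Binomial Bayes factor with uniform
priors on distal vs total distinguishing-region counts, pooled per
condition: BF = B(k_c+1, n_c−k_c+1)·B(k_k+1, n_k−k_k+1) / B(k_c+k_k+1,
n_c+n_k−k_c−k_k+1); called iff BF > 5 and |ΔΨ| ≥ 0.20; events with fewer
than 20 informative reads are flagged low-coverage and never called. The
closed form agrees with numeric quadrature of the binomial likelihood to
within 5% across random count configurations, and the null call rate is
≤ 0.05.

Integration reports, per SR library: export targets, targets with cognate
binding sites, with sites in last exons/3'UTRs, the same for NXF1 sites,
and targets undergoing called 3'UTR shortening whose distal region contains
an NXF1 site center (processing that removes receptor-binding sequence).

## The synthetic-data generator

The generator emulates the study design: eight iCLIP libraries (seven
SR-like binders with distinct planted 8-mers — two same-motif pairs and a
C-rich CAUC-core SRSF3-like binder — plus a nonspecific control), an
NXF1-like library, junction-spanning spliced/unspliced reads, PCR
duplicates with 9-nt random barcodes, and NB count tables with planted
export targets, exon-usage changes and Ψ shifts.

Mechanics and defaults (packaged scale: 200 genes, ~1 Mb, ≈200k cross-link
events per SR library; a full pipeline run takes about a minute):

* Genes have 2–10 exons on both strands (exons 80–300 nt, introns
  200–1200 nt, last exons 500–1500 nt of 3'UTR plus 100 coding nt); 20
  genes carry tandem-UTR and 10 ALE isoform pairs. Motif occurrences are
  written into the sequence at configured per-gene, per-region rates.
* Cross-links are Poisson per nucleotide: rate λ × background at motif
  positions (default λ 25 in the packaged run; criterion scenarios use the
  values they state), background elsewhere (default 0.2/nt). Each
  cross-link emits a read starting 1 nt 3' of the cross-linked base
  (length 20–40 nt); reads crossing a representative-transcript 5'ss splice
  with probability `spliced_fraction` (else continue into the intron). PCR
  copies are Geometric(1 − d), d = 0.15.
* The NXF1-like library has no motif: bursts of ~60 events with offsets
  Normal(0, 10 nt) around an anchor. In 3'UTRs the anchor is a partner
  (SRSF3-like) motif occurrence with probability `cobind_rate`, otherwise
  a uniform 3'UTR position at least 80 nt away from partner occurrences —
  the buffer makes the configured cobind_rate the true cobound fraction
  rather than a lower bound inflated by chance adjacency. Independent
  5'UTR sites are placed at `five_prime_rate` per gene.
* Counts: per transcript (representative isoform), NB via Gamma–Poisson
  with dispersion 0.05 and configured per-sample depth factors; export
  targets (planted among transcripts with base mean ≥ the configured mean,
  60% of them in genes carrying a partner 3'UTR motif) get the knockdown
  effect (−1 log2) in the cytoplasmic fraction only. Exon tables share the
  gene-level Gamma multiplier; APA distinguishing regions are generated
  from the per-condition Ψ truth.

What the generator does **not** model — and hence what green tests do not
establish about real data: sequencing error and mappability structure,
crosslinking sequence biases (e.g. U preference), isoform mixtures beyond
one representative + one APA partner, exon-level biological overdispersion,
batch effects, and correlated fractionation noise. The pipeline's
statistical guarantees (FDR control, calibration, recovery of planted
structure) are guarantees about the model, validated where the model
matches the assumptions each statistic makes.

## Determinism

Every stochastic step derives its generator from the run seed through
fixed, named streams (CRC-derived spawn keys), so simulation, calling and
background randomization are bit-reproducible across processes; the
pipeline's per-stage manifests record parameters and sha256 checksums, and
two runs with the same seed produce identical checksums.
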