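# srexport

Analysis toolkit for the question of how mRNA export machinery assembles on
transcripts: do serine/arginine-rich (SR) splicing factors act as adaptors
that recruit the export receptor NXF1 to mRNA? The package integrates two
data types around that question —

* **iCLIP** (individual-nucleotide-resolution UV cross-linking and
  immunoprecipitation) libraries for SRSF1–7-like binders and an NXF1-like
  receptor: unique-cDNA deduplication, cross-link site inference from read
  truncation, permutation-FDR significant positions, binding sites,
  splice-site metagene profiles, spliced/unspliced junction reads, region
  occupancy, exon cobinding, correlation clustering, ±30-nt cobinding
  windows around NXF1 site centers, and region-stratified 8-mer motif
  enrichment;
* **fractionated RNA-seq** (whole-cell and cytoplasmic, control vs
  knockdown, two replicates): median-of-ratios normalization, a
  trend-moderated log-scale Wald test, export-target calling (net
  cytoplasmic decrease beyond the whole-cell change), differential exon
  usage with first/internal/last classification, and alternative
  polyadenylation (tandem-3'UTR and alternative-last-exon Ψ with a
  Beta-Binomial Bayes factor) —

plus a synthetic-data generator that plants all of the above structure with
machine-readable ground truth, so every statistic is validated against
known answers. It is aimed at RNA biologists and methods developers who
want a transparent, fully testable re-implementation of this analysis
style, and at anyone who needs a planted-truth benchmark for CLIP-style
site callers or fractionation-based export analyses.

## The statistics at the core

* Cross-link calling: per gene, FDR(h) = E_perm[#positions ≥ h] / obs[#
  positions ≥ h] under uniform redistribution of the gene's cDNA count;
  positions with FDR < 0.05 merge into sites (gap ≤ 15 nt, center = modal
  position).
* Cobinding: an SR library cobinds an NXF1 site iff it has > 3 significant
  positions within ±30 nt of the site center; ratios per first-exon /
  last-exon / all strata.
* Motifs: z = (obs − bg_mean) / sqrt(bg_sd² + bg_mean + 1) per 8-mer
  against n_rand region-matched random placements.
* Export: is_target ⇔ q_cyto < 0.05 ∧ log2FC_cyto < 0 ∧ (log2FC_cyto −
  log2FC_whole) ≤ −0.585.
* APA: Ψ = long-isoform fraction from length-normalized
  distinguishing-region counts; BF = ∫ separate-Ψ likelihoods / shared-Ψ
  likelihood (Beta-Binomial, uniform priors); called at BF > 5 ∧ |ΔΨ| ≥ 0.2.

Details, assumptions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```bash
python examples/05_cobinding_windows.py
```

simulates 120 genes where half of the NXF1-like 3'UTR binding sites are
anchored on SRSF3-like motif occurrences (`cobind_rate = 0.5`), a second SR
library binds only coding sequence, then calls sites and measures cobinding:

```
NXF1 binding sites: 178
  stratum library  n_cobound  n_sites   ratio
last_exon   SRSF3         67      122 0.54918
last_exon   SRSF5          0      122 0.00000
  stratum library  n_exclusive
last_exon   SRSF3           67
last_exon   SRSF5            0
```

The SRSF3-like last-exon cobinding ratio recovers the planted 0.5 (here
0.549 from 122 sites, binomial sd ≈ 0.045), the CDS-only library sits at
zero, and every exclusively-cobound NXF1 site belongs to the partner — the
signature of sequence-specific receptor recruitment. In the same spirit,
`examples/06_motif_enrichment.py` shows the receptor library, which has no
sequence preference of its own, recovering the partner's motif in 3'UTRs
(top 8-mer `UCAUCAUC`, z ≈ 45) but only noise in 5'UTRs; and
`examples/08_full_pipeline.py` runs all stages end to end. The other
examples cover simulation, site calling, junction statistics, occupancy
clustering, and export/exon-usage/APA calling.

A command-line interface mirrors the pipeline stages
(`srexport all --seed 7 --outdir run/`, or stage by stage: `simulate`,
`callsites`, `junctions`, `occupancy`, `cobind`, `motifs`, `diffexport`,
`exonusage`, `apa`, `report`), writing per-stage manifests with parameters
and sha256 checksums; identical seeds give identical checksums.

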