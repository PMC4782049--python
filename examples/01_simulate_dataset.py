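"""Simulate a small benchmark dataset with planted ground truth.

Builds a 40-gene genome with tandem-UTR and alternative-last-exon isoform
pairs, an SRSF3-like iCLIP library with a planted C-rich motif, an
NXF1-like library whose 3'UTR sites co-occur with the partner's motif, and
fraction x condition count tables with planted export targets.
"""

from srexport.simulate import (
    SimulationConfig, simulate_fraction_counts, simulate_genome,
    simulate_iclip,
)

cfg = SimulationConfig(seed=7)
cfg.genome.n_genes = 40
cfg.genome.n_tandem = 6
cfg.genome.n_ale = 3
cfg.rnaseq.n_export_targets = 10

genome = simulate_genome(cfg)
n_bases = sum(len(s) for s in genome.sequences.values())
print(f"genome: {n_bases:,} nt, {len(genome.annotation.genes)} genes, "
      f"{len(genome.annotation.transcripts)} transcripts")

libs = simulate_iclip(cfg, genome, proteins=["SRSF3", "NXF1"])
for name, lib in libs.items():
    print(f"{name}: {len(lib.reads):,} reads, "
          f"{lib.n_unique:,} unique cDNAs, "
          f"spliced fraction {lib.truth['spliced_fraction']}")

counts = simulate_fraction_counts(cfg, genome)
print(f"count tables: {counts.transcripts.shape[0]} transcripts x "
      f"{counts.transcripts.shape[1]} samples; "
      f"{len(counts.truth['export_targets'])} planted export targets; "
      f"{sum(t['shifted'] for t in counts.truth['apa'])} shifted APA events")

# The truth objects list every planted motif occurrence, NXF1 site,
# export target and Psi shift, so downstream estimates can be scored.
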