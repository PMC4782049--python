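"""Region occupancy and hierarchical clustering of binding profiles.

Densities are significant events per nucleotide of 5'UTR / CDS / 3'UTR /
intron, per million unique cDNAs.  The exon-level binding matrix drives
correlation clustering: libraries planted with the same motif cluster as
sisters.
"""

from srexport.annotation import classify_exons
from srexport.occupancy import (
    cobound_exon_fraction, correlation_clustering, exon_binding_matrix,
    region_density,
)
from srexport.simulate import SimulationConfig, simulate_genome, simulate_iclip
from srexport.xlink import call_significant_positions, deduplicate, extract_crosslinks

cfg = SimulationConfig(seed=7)
cfg.genome.n_genes = 40
genome = simulate_genome(cfg)
names = ["SRSF2", "SRSF3", "SRSF5"]  # SRSF2 and SRSF5 share a motif
libs = simulate_iclip(cfg, genome, proteins=names)

sig, sizes = {}, {}
for name in names:
    unique, stats = deduplicate(libs[name].reads)
    events = extract_crosslinks(unique)
    res = call_significant_positions(events, genome.annotation, seed=2)
    sig[name] = res.significant
    sizes[name] = stats.n_unique

dens = region_density(sig, genome.regions, genome.annotation,
                      library_sizes=sizes)
srsf3 = dens[dens.library == "SRSF3"].set_index("label")
for label in ("five_prime_utr", "cds", "three_prime_utr", "intron"):
    if label in srsf3.index:
        print(f"SRSF3 density in {label}: "
              f"{srsf3.loc[label, 'density_per_million']:.3f} "
              f"events/nt per million cDNAs")

exons = classify_exons(genome.annotation)
matrix = exon_binding_matrix(sig, exons, library_sizes=sizes)
cf = cobound_exon_fraction(matrix, names)
print("cobound-exon fractions:", dict(cf.round(3)))

clust = correlation_clustering(matrix.cpm, method="spearman")
print("clustering (same-motif pair should be sisters):", clust.newick())
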