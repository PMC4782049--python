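"""Splice-site metagene profile and spliced/unspliced read classification.

Reads that continue across an annotated 5' splice site into the intron are
unspliced pre-mRNA contacts; reads whose alignment gap matches the intron
exactly are contacts with already-spliced mRNA.  The pooled spliced
proportion estimates how much of a protein's binding happens after
splicing.
"""

import numpy as np

from srexport.annotation import splice_sites
from srexport.junctions import classify_junction_reads, splice_site_metaprofile
from srexport.simulate import SimulationConfig, simulate_genome, simulate_iclip
from srexport.xlink import deduplicate, extract_crosslinks

cfg = SimulationConfig(seed=7)
cfg.genome.n_genes = 60
genome = simulate_genome(cfg)
libs = simulate_iclip(cfg, genome, proteins=["SRSF1"])

jc, per_junction = classify_junction_reads(libs["SRSF1"].reads,
                                           genome.annotation, min_overhang=3)
print(f"spliced {jc.n_spliced}, unspliced {jc.n_unspliced}, "
      f"novel-junction {jc.n_novel}")
print(f"estimated spliced fraction: {jc.proportion_spliced:.3f} "
      f"(simulated truth {libs['SRSF1'].truth['spliced_fraction']})")

unique, _ = deduplicate(libs["SRSF1"].reads)
events = extract_crosslinks(unique)
sites = splice_sites(genome.annotation)
prof = splice_site_metaprofile(events, sites, window=300, kind="5ss",
                               library="SRSF1")
inner = np.abs(prof.offsets) <= 100
print(f"5'ss profile: {int(prof.counts.sum()):,} events in +/-300 nt of "
      f"{prof.n_anchors} sites; mean density +/-100 nt: "
      f"{prof.counts[inner].mean():.1f} events/offset")
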