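"""Export-target calling, exon usage and APA from fractionated counts.

A transcript is an export target when its cytoplasmic abundance drops
under knockdown significantly (BH q < 0.05) and beyond its whole-cell
change by at least 1.5-fold (net export decrease).  APA events are called
by a Beta-Binomial Bayes factor on distal vs proximal distinguishing-region
counts (BF > 5 and |dPsi| >= 0.20).
"""

import pandas as pd

from srexport.annotation import classify_exons, enumerate_apa_events
from srexport.diff import (
    apa_analysis, call_export_targets, classify_changed_exons,
    differential_abundance, exon_usage_test, normalize_counts,
)
from srexport.simulate import (
    SimulationConfig, simulate_fraction_counts, simulate_genome,
)

cfg = SimulationConfig(seed=7)
cfg.genome.n_genes = 300
cfg.genome.n_tandem = 20
cfg.genome.n_ale = 10
cfg.rnaseq.n_export_targets = 30
genome = simulate_genome(cfg)
fc = simulate_fraction_counts(cfg, genome)

factors, norm = normalize_counts(fc.transcripts, fc.samples)
res_c = differential_abundance(norm, fc.samples, "cytoplasmic")
res_w = differential_abundance(norm, fc.samples, "whole_cell")
calls = call_export_targets(res_c, res_w, alpha=0.05, delta=0.585)
truth = {t["transcript_id"] for t in fc.truth["export_targets"]}
called = set(calls.index[calls["is_target"]])
tp = len(called & truth)
print(f"export targets: {len(called)} called, {tp} of {len(truth)} planted "
      f"recovered (precision {tp / max(len(called), 1):.2f})")

# exon usage (cytoplasmic fraction)
is_apa = fc.exons.index.str.contains(":prox|:dist")
exon_rows = fc.exons.loc[~is_apa]
gene_of = pd.Series({e: e.split(".t")[0] for e in exon_rows.index})
usage = exon_usage_test(exon_rows, gene_of, fc.samples, "cytoplasmic",
                        fdr=0.1)
classes = classify_changed_exons(usage, classify_exons(genome.annotation))
n_changed = int(usage["significant"].sum())
print(f"exon usage: {n_changed} changed exons (FDR < 0.1)")
if len(classes):
    less = classes[classes.direction == "less_inclusion"]
    print(less.to_string(index=False))

events = enumerate_apa_events(genome.annotation)
apa = apa_analysis(fc.exons, events, fc.samples, fraction="cytoplasmic")
truth_apa = pd.DataFrame(fc.truth["apa"]).set_index("event_id")
merged = apa.join(truth_apa, rsuffix="_true")
called_apa = merged[merged.called]
print(f"APA: {len(called_apa)} of {len(events)} events called; "
      f"{int(called_apa['shifted'].sum())} are planted shifts "
      f"({int(truth_apa['shifted'].sum())} planted in total)")
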