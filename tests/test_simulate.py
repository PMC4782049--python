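import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srexport.annotation import enumerate_apa_events
from srexport.simulate import (
    ConfigError, ProteinSpec, SimulationConfig, simulate_fraction_counts,
    simulate_genome, simulate_iclip,
)
from srexport.xlink import deduplicate


def _small_cfg(seed=1, n_genes=20, **genome_kw):
    cfg = SimulationConfig(seed=seed)
    cfg.genome.n_genes = n_genes
    cfg.genome.n_tandem = genome_kw.pop("n_tandem", 4)
    cfg.genome.n_ale = genome_kw.pop("n_ale", 2)
    for k, v in genome_kw.items():
        setattr(cfg.genome, k, v)
    return cfg


class TestSimulateGenome:
    def test_deterministic_given_seed(self, tmp_path):
        cfgs = [_small_cfg(seed=5), _small_cfg(seed=5)]
        payloads = []
        for i, cfg in enumerate(cfgs):
            g = simulate_genome(cfg)
            fa = tmp_path / f"g{i}.fa"
            gtf = tmp_path / f"g{i}.gtf"
            g.write_fasta(str(fa))
            g.write_gtf(str(gtf))
            payloads.append((fa.read_bytes(), gtf.read_bytes()))
        assert payloads[0] == payloads[1]

    def test_seed_changes_output(self):
        a = simulate_genome(_small_cfg(seed=1))
        b = simulate_genome(_small_cfg(seed=2))
        assert a.sequence("chrS") != b.sequence("chrS")

    def test_planted_apa_events_enumerable(self):
        g = simulate_genome(_small_cfg(n_genes=30, n_tandem=10, n_ale=5))
        events = enumerate_apa_events(g.annotation)
        kinds = [e.kind for e in events]
        assert kinds.count("TandemUTR") >= 10
        assert kinds.count("ALE") >= 5

    def test_gc_content_near_half(self):
        cfg = _small_cfg(seed=3, n_genes=60)
        g = simulate_genome(cfg)
        seq = g.sequence("chrS")
        assert len(seq) > 100_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # binomial sd at this length is < 0.002; planted motifs shift GC
        # by well under 1%
        assert abs(gc - 0.5) < 0.02

    def test_infeasible_intron_rejected(self):
        cfg = _small_cfg()
        cfg.genome.intron_len = (10, 20)
        with pytest.raises(ConfigError, match="intron"):
            simulate_genome(cfg)

    def test_planted_motifs_present_in_sequence(self):
        cfg = _small_cfg(seed=4, n_genes=15)
        cfg.proteins = [ProteinSpec("P", ["ACGTACGT"],
                                    plant={"cds": 1.0})]
        g = simulate_genome(cfg)
        seq = g.sequence("chrS")
        for rec in g.truth["planted_motifs"]["ACGTACGT"]:
            written = seq[rec["start"]:rec["end"]]
            if rec["strand"] == "+":
                assert written == "ACGTACGT"
            else:
                assert written == "ACGTACGT"[::-1].translate(
                    str.maketrans("ACGT", "TGCA"))

    def test_truth_referential_integrity(self):
        cfg = _small_cfg(seed=6)
        g = simulate_genome(cfg)
        gene_ids = set(g.annotation.genes)
        for rec in g.truth["genes"]:
            assert rec["gene_id"] in gene_ids
        for placements in g.truth["planted_motifs"].values():
            for rec in placements:
                assert rec["gene_id"] in gene_ids


class TestSimulateIclip:
    def test_uniform_background_is_uniform(self):
        """lambda=1 placements pass a chi-square uniformity check on 1-kb
        bins within gene spans."""
        cfg = _small_cfg(seed=11, n_genes=40, n_tandem=0, n_ale=0)
        cfg.proteins = [ProteinSpec("NULL", [], enrichment=1.0,
                                    background_rate=0.5)]
        cfg.nxf1.utr3_site_rate = 0.0
        cfg.nxf1.five_prime_rate = 0.0
        cfg.pcr_duplication_rate = 0.0
        g = simulate_genome(cfg)
        libs = simulate_iclip(cfg, g, proteins=["NULL"])
        unique, _ = deduplicate(libs["NULL"].reads)
        # cross-link positions inside one long gene, binned at 1 kb
        gid = max(g.annotation.genes,
                  key=lambda x: g.annotation.gene_span(x)[3]
                  - g.annotation.gene_span(x)[2])
        _, strand, gs, ge = g.annotation.gene_span(gid)
        pos = np.where(unique["strand"] == "+", unique["start"] - 1,
                       unique["end"])
        pos = pos[(unique["strand"] == strand) & (pos >= gs) & (pos < ge)]
        nbins = max((ge - gs) // 1000, 2)
        histo, _ = np.histogram(pos, bins=nbins, range=(gs, gs + nbins * 1000))
        _, p = sps.chisquare(histo)
        assert p > 0.01

    def test_no_cobinding_when_rate_zero(self):
        cfg = _small_cfg(seed=12, n_genes=25, n_tandem=0, n_ale=0)
        cfg.proteins = [ProteinSpec("SRSF3", ["TCATCATC"], enrichment=10.0,
                                    background_rate=0.5,
                                    plant={"three_prime_utr": 1.0})]
        cfg.nxf1.cobind_rate = 0.0
        cfg.nxf1.utr3_site_rate = 1.0
        g = simulate_genome(cfg)
        libs = simulate_iclip(cfg, g)
        sites = libs["NXF1"].truth["sites"]
        assert sites and not any(s["cobound"] for s in sites)

    def test_pcr_duplication_recovers_unique_count(self):
        """Dedup recovers the simulator's unique-cDNA count within 5% at
        duplication rate 0.5 (geometric branching of copies)."""
        cfg = _small_cfg(seed=13, n_genes=10, n_tandem=0, n_ale=0)
        cfg.proteins = [ProteinSpec("P", [], enrichment=1.0,
                                    background_rate=0.05)]
        cfg.pcr_duplication_rate = 0.5
        g = simulate_genome(cfg)
        libs = simulate_iclip(cfg, g, proteins=["P"])
        lib = libs["P"]
        assert lib.n_unique > 500
        assert len(lib.reads) > 1.5 * lib.n_unique
        unique, stats = deduplicate(lib.reads)
        assert abs(stats.n_unique - lib.n_unique) / lib.n_unique < 0.05

    def test_motif_rate_enrichment_matches_lambda(self, small_sim):
        """Empirical per-base cross-link rate at motif occurrences over the
        background rate recovers the configured enrichment factor."""
        cfg, genome, libs = small_sim
        lib = libs["SRSF3"]
        unique, _ = deduplicate(lib.reads)
        pos = np.where(unique["strand"].to_numpy() == "+",
                       unique["start"].to_numpy() - 1,
                       unique["end"].to_numpy())
        motif_mask = np.zeros(len(genome.sequence("chrS")), dtype=bool)
        for o in lib.truth["occurrences"]:
            motif_mask[o["start"]:o["end"]] = True
        n_motif_nt = int(motif_mask.sum())
        in_motif = motif_mask[np.clip(pos, 0, len(motif_mask) - 1)]
        gene_nt = sum(genome.annotation.gene_span(g)[3]
                      - genome.annotation.gene_span(g)[2]
                      for g in genome.annotation.genes)
        rate_motif = in_motif.sum() / n_motif_nt
        rate_bg = (~in_motif).sum() / (gene_nt - n_motif_nt)
        ratio = rate_motif / rate_bg
        assert 0.8 * 12.0 <= ratio <= 1.2 * 12.0

    def test_spliced_reads_span_annotated_introns(self, small_sim):
        cfg, genome, libs = small_sim
        reads = libs["SRSF3"].reads
        gapped = reads[reads["blocks"].str.contains(",")]
        assert len(gapped) > 100
        introns = set()
        for t in genome.annotation.transcripts.values():
            for iv in t.introns:
                introns.add(iv)
        n_checked = 0
        for blocks in gapped["blocks"].head(200):
            parts = [tuple(map(int, b.split("-"))) for b in blocks.split(",")]
            gap = (parts[0][1], parts[1][0])
            assert gap in introns
            n_checked += 1
        assert n_checked == 200


class TestFractionCounts:
    def test_export_effect_cytoplasm_only(self):
        cfg = _small_cfg(seed=21, n_genes=100, n_tandem=0, n_ale=0)
        cfg.rnaseq.n_export_targets = 20
        cfg.rnaseq.dispersion = 1e-3
        g = simulate_genome(cfg)
        fc = simulate_fraction_counts(cfg, g)
        targets = [t["transcript_id"] for t in fc.truth["export_targets"]]
        assert len(targets) == 20
        sheet = fc.samples.set_index("sample")
        cyto_kd = [s for s in sheet.index
                   if sheet.loc[s, "fraction"] == "cytoplasmic"
                   and sheet.loc[s, "condition"] == "kd"]
        cyto_ct = [s for s in sheet.index
                   if sheet.loc[s, "fraction"] == "cytoplasmic"
                   and sheet.loc[s, "condition"] == "control"]
        whole_kd = [s for s in sheet.index
                    if sheet.loc[s, "fraction"] == "whole_cell"
                    and sheet.loc[s, "condition"] == "kd"]
        whole_ct = [s for s in sheet.index
                    if sheet.loc[s, "fraction"] == "whole_cell"
                    and sheet.loc[s, "condition"] == "control"]
        tdf = fc.transcripts.loc[targets]
        # depth factors differ by sample; compare depth-corrected means
        depth = dict(zip(sheet.index, cfg.rnaseq.depth_factors))
        def mean_corrected(cols):
            return np.mean([tdf[c].mean() / depth[c] for c in cols])
        ratio_cyto = mean_corrected(cyto_kd) / mean_corrected(cyto_ct)
        ratio_whole = mean_corrected(whole_kd) / mean_corrected(whole_ct)
        assert abs(ratio_cyto - 0.5) < 0.08
        assert abs(ratio_whole - 1.0) < 0.08

    def test_low_dispersion_approaches_poisson(self):
        cfg = _small_cfg(seed=22, n_genes=80, n_tandem=0, n_ale=0)
        cfg.rnaseq.dispersion = 1e-4
        cfg.rnaseq.depth_factors = (1.0,) * 8
        g = simulate_genome(cfg)
        fc = simulate_fraction_counts(cfg, g)
        cols = ["wh_control_1", "wh_control_2"]
        m = fc.transcripts[cols].to_numpy(dtype=float)
        # variance of the replicate difference ~ 2*mean under Poisson
        diff_var = ((m[:, 0] - m[:, 1]) ** 2 / (m.sum(axis=1) + 1)).mean()
        assert 0.7 < diff_var < 1.4

    def test_planted_dpsi_realized_in_counts(self):
        cfg = _small_cfg(seed=23, n_genes=60, n_tandem=20, n_ale=0)
        cfg.rnaseq.n_apa_shifted = 10
        cfg.rnaseq.dpsi = 0.3
        cfg.rnaseq.mean_counts = 400
        g = simulate_genome(cfg)
        fc = simulate_fraction_counts(cfg, g)
        truth = pd.DataFrame(fc.truth["apa"]).set_index("event_id")
        shifted = truth[truth["shifted"]]
        assert len(shifted) == 10
        deltas = []
        for eid, row in shifted.iterrows():
            lp = None
            # density ratio in cytoplasmic control vs kd pooled replicates
            prox_c = fc.exons.loc[f"{eid}:prox",
                                  ["cy_control_1", "cy_control_2"]].sum()
            dist_c = fc.exons.loc[f"{eid}:dist",
                                  ["cy_control_1", "cy_control_2"]].sum()
            prox_k = fc.exons.loc[f"{eid}:prox", ["cy_kd_1", "cy_kd_2"]].sum()
            dist_k = fc.exons.loc[f"{eid}:dist", ["cy_kd_1", "cy_kd_2"]].sum()
            deltas.append((row["psi_kd"] - row["psi_control"],
                           prox_c, dist_c, prox_k, dist_k))
        # at least direction is consistently realized
        n_consistent = 0
        for dps, pc, dc, pk, dk in deltas:
            obs = (dk / max(pk, 1)) - (dc / max(pc, 1))
            if np.sign(obs) == np.sign(dps):
                n_consistent += 1
        assert n_consistent >= 8

    def test_invalid_rates_rejected(self):
        cfg = _small_cfg()
        cfg.nxf1.cobind_rate = 1.5
        with pytest.raises(ConfigError):
            cfg.validate()


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = _small_cfg(seed=9)
        path = tmp_path / "cfg.yaml"
        import yaml
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = SimulationConfig.from_yaml(str(path))
        assert back.seed == cfg.seed
        assert back.genome.n_genes == cfg.genome.n_genes
        assert [p.name for p in back.proteins] == [p.name for p in cfg.proteins]

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            SimulationConfig.from_dict({"seeed": 1})
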