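"""Stage implementations behind the command-line interface.

Each stage reads its upstream artifacts from the run directory, writes its
outputs and a manifest (inputs, parameters, seed, sha256 checksums), and
is deterministic under a fixed seed.  Stages fail early with
:class:`MissingInputError` naming the subcommand that produces a missing
upstream artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotation import (
    GenomeAnnotation, classify_exons, derive_regions, enumerate_apa_events,
    load_annotation, splice_sites,
)
from .simulate import (
    SimulationConfig, simulate_fraction_counts, simulate_genome,
    simulate_iclip,
)
from .xlink import (
    call_significant_positions, deduplicate, extract_crosslinks,
    merge_binding_sites,
)
from .junctions import (
    classify_junction_reads, last_exon_profile, splice_site_metaprofile,
)
from .occupancy import (
    cobound_exon_fraction, correlation_clustering, exon_binding_matrix,
    region_density, sites_per_transcript, utr3_length_stats,
)
from .cowindows import cobinding_ratio, exclusive_cobinding, pairwise_cobinding
from .kmer import extract_windows, kmer_enrichment, top_motifs
from .diff import (
    apa_analysis, call_export_targets, classify_changed_exons,
    differential_abundance, exon_usage_test, integrate_targets_binding,
    normalize_counts,
)


class ConfigSchemaError(ValueError):
    pass


class MissingInputError(FileNotFoundError):
    def __init__(self, path: str, producer: str):
        super().__init__(
            f"missing input {path}; run the '{producer}' subcommand first")
        self.producer = producer


DEFAULTS: Dict[str, dict] = {
    "xlink": {"fdr": 0.05, "n_perm": 100, "min_events": 10, "max_gap": 15},
    "junctions": {"window": 300, "min_overhang": 3, "n_bins": 100,
                  "mapq_min": 10},
    "occupancy": {"methods": ["spearman", "distance_correlation"],
                  "bound_threshold": 1, "log_scale": False,
                  "max_features": 5000},
    "cobind": {"half_window": 30, "min_sites": 4, "nxf1_library": "NXF1",
               "control_library": "GFPNLS"},
    "motifs": {"k": 8, "flank": 20, "n_rand": 100,
               "libraries": ["SRSF3", "NXF1"],
               "regions": ["all", "5utr", "3utr"], "min_windows": 100},
    "diff": {"alpha": 0.05, "delta": 0.585, "shrink_weight": 0.2},
    "exonusage": {"fdr": 0.1},
    "apa": {"bf_threshold": 5.0, "dpsi_threshold": 0.2,
            "fraction": "cytoplasmic"},
}

TOP_KEYS = {"outdir", "seed", "log_level", "simulate", "reads_format"} | set(DEFAULTS)


class RunConfig:
    """Validated run configuration with per-stage parameter blocks."""

    def __init__(self, d: Optional[dict] = None):
        d = dict(d or {})
        unknown = set(d) - TOP_KEYS
        if unknown:
            raise ConfigSchemaError(f"unknown config keys: {sorted(unknown)}")
        self.outdir: str = d.get("outdir", "srexport_run")
        self.seed: int = int(d.get("seed", 1))
        self.log_level: str = d.get("log_level", "INFO")
        self.reads_format: str = d.get("reads_format", "bed12")
        if self.reads_format not in ("bed12", "bam"):
            raise ConfigSchemaError("reads_format must be bed12 or bam")
        sim = dict(d.get("simulate", {}))
        sim.setdefault("seed", self.seed)
        self.simulate = SimulationConfig.from_dict(sim)
        self.stages: Dict[str, dict] = {}
        for stage, defaults in DEFAULTS.items():
            block = dict(defaults)
            overrides = d.get(stage, {})
            unknown = set(overrides) - set(defaults)
            if unknown:
                raise ConfigSchemaError(
                    f"unknown keys in '{stage}': {sorted(unknown)}")
            block.update(overrides)
            self.stages[stage] = block

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {"outdir": self.outdir, "seed": self.seed,
                "reads_format": self.reads_format,
                "simulate": self.simulate.to_dict(), **self.stages}

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: RunConfig, stage: str, inputs: Sequence[str],
                   outputs: Sequence[str], params: dict) -> str:
    mdir = os.path.join(cfg.outdir, "manifests")
    os.makedirs(mdir, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "stage_seed": cfg.stage_seed(stage),
        "inputs": sorted(os.path.relpath(p, cfg.outdir) for p in inputs),
        "params": params,
        "outputs": {os.path.relpath(p, cfg.outdir): _sha256(p)
                    for p in sorted(outputs)},
    }
    path = os.path.join(mdir, f"{stage}.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise MissingInputError(path, producer)
    return path


def _p(cfg: RunConfig, *parts: str) -> str:
    return os.path.join(cfg.outdir, *parts)


def _load_annotation(cfg: RunConfig) -> GenomeAnnotation:
    return load_annotation(_require(_p(cfg, "sim", "annotation.gtf"),
                                    "simulate"))


def _load_genome(cfg: RunConfig) -> Dict[str, str]:
    import pyfaidx
    path = _require(_p(cfg, "sim", "genome.fa"), "simulate")
    fa = pyfaidx.Fasta(path)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _libraries(cfg: RunConfig) -> List[str]:
    return [p.name for p in cfg.simulate.proteins] + [cfg.simulate.nxf1.name]


def _reads_path(cfg: RunConfig, lib: str) -> str:
    ext = "bam" if cfg.reads_format == "bam" else "bed12"
    return _p(cfg, "sim", "reads", f"{lib}.{ext}")


def _library_sizes(cfg: RunConfig) -> Dict[str, int]:
    path = _require(_p(cfg, "xlink", "summary.tsv"), "callsites")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["n_unique"].to_dict()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> List[str]:
    sim = cfg.simulate
    outdir = _p(cfg, "sim")
    os.makedirs(os.path.join(outdir, "reads"), exist_ok=True)
    genome = simulate_genome(sim)
    outputs = []
    fasta = os.path.join(outdir, "genome.fa")
    gtf = os.path.join(outdir, "annotation.gtf")
    genome.write_fasta(fasta)
    genome.write_gtf(gtf)
    outputs += [fasta, gtf]
    libs = simulate_iclip(sim, genome)
    iclip_truth = {}
    stats = []
    chrom_lengths = {c: len(s) for c, s in genome.sequences.items()}
    for name, lib in libs.items():
        path = _reads_path(cfg, name)
        if cfg.reads_format == "bam":
            sio.write_reads_bam(lib.reads, path, chrom_lengths)
        else:
            sio.write_reads_bed12(lib.reads, path)
        outputs.append(path)
        iclip_truth[name] = lib.truth
        stats.append({"library": name, "n_reads": len(lib.reads),
                      "n_unique_true": lib.n_unique})
    counts = simulate_fraction_counts(sim, genome)
    for fname, df in [("counts_transcripts.tsv", counts.transcripts),
                      ("counts_exons.tsv", counts.exons)]:
        path = os.path.join(outdir, fname)
        sio.write_tsv(df, path)
        outputs.append(path)
    samples_path = os.path.join(outdir, "samples.tsv")
    sio.write_tsv(counts.samples, samples_path, index=False)
    outputs.append(samples_path)
    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump({"genome": genome.truth, "iclip": iclip_truth,
                   "rnaseq": counts.truth}, fh, indent=1, sort_keys=True)
    outputs.append(truth_path)
    stats_path = os.path.join(outdir, "library_stats.tsv")
    sio.write_tsv(pd.DataFrame(stats), stats_path, index=False)
    outputs.append(stats_path)
    write_manifest(cfg, "simulate", [], outputs,
                   {"simulate": sim.to_dict(),
                    "reads_format": cfg.reads_format})
    return outputs


def stage_callsites(cfg: RunConfig) -> List[str]:
    params = cfg.stages["xlink"]
    ann = _load_annotation(cfg)
    outdir = _p(cfg, "xlink")
    os.makedirs(outdir, exist_ok=True)
    outputs: List[str] = []
    inputs: List[str] = []
    summary = []
    seed = cfg.stage_seed("callsites")
    for lib in _libraries(cfg):
        rpath = _require(_reads_path(cfg, lib), "simulate")
        inputs.append(rpath)
        reads = sio.read_reads(rpath)
        unique, stats = deduplicate(reads)
        events = extract_crosslinks(unique)
        res = call_significant_positions(
            events, ann, fdr_threshold=params["fdr"],
            n_perm=params["n_perm"], seed=seed,
            min_events=params["min_events"])
        sig = res.significant
        sites = merge_binding_sites(sig, max_gap=params["max_gap"],
                                    protein=lib)
        ev_path = os.path.join(outdir, f"{lib}.events.bed")
        sig_path = os.path.join(outdir, f"{lib}.sig.bed")
        site_path = os.path.join(outdir, f"{lib}.sites.bed")
        sio.write_events_bed(events, ev_path, name=lib)
        sio.write_significant_bed(sig, sig_path)
        sio.write_sites_bed(sites, site_path)
        outputs += [ev_path, sig_path, site_path]
        summary.append({
            "library": lib, "n_reads": stats.n_reads,
            "n_unique": stats.n_unique,
            "n_missing_barcode": stats.n_missing_barcode,
            "n_events": len(events), "n_significant": len(sig),
            "n_sites": len(sites), "n_intergenic": res.n_intergenic,
            "n_genes_skipped": len(res.skipped_genes)})
    sum_path = os.path.join(outdir, "summary.tsv")
    sio.write_tsv(pd.DataFrame(summary).set_index("library"), sum_path)
    outputs.append(sum_path)
    write_manifest(cfg, "callsites", inputs, outputs, params)
    return outputs


def stage_junctions(cfg: RunConfig) -> List[str]:
    params = cfg.stages["junctions"]
    ann = _load_annotation(cfg)
    sites = splice_sites(ann)
    exons = classify_exons(ann)
    last = [x for x in exons if x.ordinal_class == "last"]
    outdir = _p(cfg, "junctions")
    os.makedirs(outdir, exist_ok=True)
    outputs: List[str] = []
    inputs: List[str] = []
    tallies = []
    for lib in _libraries(cfg):
        rpath = _require(_reads_path(cfg, lib), "simulate")
        ev_path = _require(_p(cfg, "xlink", f"{lib}.events.bed"), "callsites")
        sig_path = _require(_p(cfg, "xlink", f"{lib}.sig.bed"), "callsites")
        inputs += [rpath, ev_path]
        reads = sio.read_reads(rpath, mapq_min=params["mapq_min"]
                               if cfg.reads_format == "bam" else 0)
        events = sio.read_events_bed(ev_path)
        for kind in ("5ss", "3ss"):
            prof = splice_site_metaprofile(events, sites,
                                           window=params["window"],
                                           kind=kind, library=lib)
            path = os.path.join(outdir, f"profile_{kind}_{lib}.tsv")
            sio.write_tsv(prof.to_frame(), path, index=False)
            outputs.append(path)
        jc, per_junction = classify_junction_reads(
            reads, ann, min_overhang=params["min_overhang"], library=lib)
        tallies.append({"library": lib, "n_spliced": jc.n_spliced,
                        "n_unspliced": jc.n_unspliced, "n_novel": jc.n_novel,
                        "proportion_spliced": jc.proportion_spliced})
        # last-exon profile over significant positions
        sig = _read_bed6(sig_path)
        sigdf = pd.DataFrame({"chrom": sig["chrom"], "strand": sig["strand"],
                              "position": sig["start"], "count": 1})
        lp = last_exon_profile(sigdf, last, n_bins=params["n_bins"],
                               library=lib)
        path = os.path.join(outdir, f"last_exon_profile_{lib}.tsv")
        sio.write_tsv(lp.to_frame(), path, index=False)
        outputs.append(path)
    jc_path = os.path.join(outdir, "junction_counts.tsv")
    sio.write_tsv(pd.DataFrame(tallies).set_index("library"), jc_path)
    outputs.append(jc_path)
    write_manifest(cfg, "junctions", inputs, outputs, params)
    return outputs


def _read_bed6(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None,
                           names=["chrom", "start", "end", "gene", "score",
                                  "strand"], dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "gene",
                                     "score", "strand"])


def _read_sig_positions(cfg: RunConfig, lib: str) -> pd.DataFrame:
    """Significant positions with their cDNA counts from events + sig BEDs."""
    sig_path = _require(_p(cfg, "xlink", f"{lib}.sig.bed"), "callsites")
    ev_path = _require(_p(cfg, "xlink", f"{lib}.events.bed"), "callsites")
    sig = _read_bed6(sig_path)
    events = sio.read_events_bed(ev_path)
    merged = pd.merge(
        pd.DataFrame({"chrom": sig["chrom"], "strand": sig["strand"],
                      "position": sig["start"]}),
        events, on=["chrom", "strand", "position"], how="left")
    merged["count"] = merged["count"].fillna(1).astype(int)
    return merged


def stage_occupancy(cfg: RunConfig) -> List[str]:
    params = cfg.stages["occupancy"]
    ann = _load_annotation(cfg)
    regions = derive_regions(ann)
    exons = classify_exons(ann)
    rep_tids = set(regions.representative.values())
    rep_exons = [x for x in exons if x.transcript_id in rep_tids]
    outdir = _p(cfg, "occupancy")
    os.makedirs(outdir, exist_ok=True)
    outputs: List[str] = []
    sizes = _library_sizes(cfg)
    sig = {lib: _read_sig_positions(cfg, lib) for lib in _libraries(cfg)}
    dens = region_density(sig, regions, ann, library_sizes=sizes)
    path = os.path.join(outdir, "region_density.tsv")
    sio.write_tsv(dens, path, index=False)
    outputs.append(path)
    matrix = exon_binding_matrix(sig, rep_exons, library_sizes=sizes)
    for fname, df in [("exon_matrix_cpm.tsv", matrix.cpm),
                      ("exon_matrix_counts.tsv", matrix.counts),
                      ("exon_matrix_npos.tsv", matrix.n_positions)]:
        p = os.path.join(outdir, fname)
        sio.write_tsv(df, p)
        outputs.append(p)
    nxf1 = cfg.stages["cobind"]["nxf1_library"]
    control = cfg.stages["cobind"]["control_library"]
    sr_libs = [l for l in _libraries(cfg) if l not in (nxf1, control)]
    cf = cobound_exon_fraction(matrix, sr_libs,
                               bound_threshold=params["bound_threshold"])
    p = os.path.join(outdir, "cobound_fraction.tsv")
    sio.write_tsv(cf.to_frame(), p)
    outputs.append(p)
    for method in params["methods"]:
        res = correlation_clustering(matrix.cpm, method=method,
                                     log_scale=params["log_scale"],
                                     max_features=params["max_features"],
                                     seed=cfg.stage_seed("occupancy"))
        p1 = os.path.join(outdir, f"correlation_{method}.tsv")
        sio.write_tsv(res.correlation, p1)
        p2 = os.path.join(outdir, f"tree_{method}.nwk")
        with open(p2, "w") as fh:
            fh.write(res.newick() + "\n")
        outputs += [p1, p2]
    # NXF1 site placement and per-transcript counts
    site_path = _require(_p(cfg, "xlink", f"{nxf1}.sites.bed"), "callsites")
    nxf1_sites = sio.read_sites_bed(site_path)
    hist, crosstab = sites_per_transcript(nxf1_sites, regions, ann)
    p1 = os.path.join(outdir, "nxf1_sites_per_transcript.tsv")
    sio.write_tsv(hist.rename("n_transcripts").to_frame(), p1)
    p2 = os.path.join(outdir, "nxf1_site_regions.tsv")
    sio.write_tsv(crosstab, p2)
    outputs += [p1, p2]
    write_manifest(cfg, "occupancy", [site_path], outputs, params)
    return outputs


def stage_cobind(cfg: RunConfig) -> List[str]:
    params = cfg.stages["cobind"]
    ann = _load_annotation(cfg)
    exons = classify_exons(ann)
    nxf1 = params["nxf1_library"]
    control = params["control_library"]
    outdir = _p(cfg, "cobind")
    os.makedirs(outdir, exist_ok=True)
    site_path = _require(_p(cfg, "xlink", f"{nxf1}.sites.bed"), "callsites")
    nxf1_sites = sio.read_sites_bed(site_path)
    sr_libs = [l for l in _libraries(cfg) if l not in (nxf1, control)]
    sr_pos = {lib: _read_sig_positions(cfg, lib) for lib in sr_libs}
    res = cobinding_ratio(nxf1_sites, sr_pos, exons,
                          half_window=params["half_window"],
                          min_sites=params["min_sites"])
    outputs = []
    p = os.path.join(outdir, "ratios.tsv")
    sio.write_tsv(res.ratios, p, index=False)
    outputs.append(p)
    p = os.path.join(outdir, "exclusive.tsv")
    sio.write_tsv(exclusive_cobinding(res), p, index=False)
    outputs.append(p)
    for stratum in ("all", "first_exon", "last_exon"):
        p = os.path.join(outdir, f"pairs_{stratum}.tsv")
        sio.write_tsv(pairwise_cobinding(res, stratum=stratum), p)
        outputs.append(p)
    write_manifest(cfg, "cobind", [site_path], outputs, params)
    return outputs


def stage_motifs(cfg: RunConfig) -> List[str]:
    params = cfg.stages["motifs"]
    ann = _load_annotation(cfg)
    regions = derive_regions(ann)
    genome = _load_genome(cfg)
    outdir = _p(cfg, "motifs")
    os.makedirs(outdir, exist_ok=True)
    outputs: List[str] = []
    tops = []
    for lib in params["libraries"]:
        sig = _read_sig_positions(cfg, lib)
        for region in params["regions"]:
            try:
                w = extract_windows(sig, regions, ann, genome,
                                    region_filter=region,
                                    flank=params["flank"])
                table = kmer_enrichment(
                    w, k=params["k"], n_rand=params["n_rand"],
                    seed=cfg.stage_seed(f"motifs:{lib}:{region}"),
                    library=lib, min_windows=params["min_windows"])
            except ValueError as exc:
                tops.append({"library": lib, "region": region,
                             "top_kmer": None, "z": np.nan,
                             "consensus": None, "note": str(exc)})
                continue
            p = os.path.join(outdir, f"kmers_{lib}_{region}.tsv")
            sio.write_tsv(table.table, p, index=False)
            outputs.append(p)
            top, consensus = top_motifs(table)
            tops.append({"library": lib, "region": region,
                         "top_kmer": top["kmer"].iloc[0] if len(top) else None,
                         "z": top["z"].iloc[0] if len(top) else np.nan,
                         "consensus": consensus, "note": ""})
    p = os.path.join(outdir, "top_motifs.tsv")
    sio.write_tsv(pd.DataFrame(tops), p, index=False)
    outputs.append(p)
    write_manifest(cfg, "motifs", [], outputs, params)
    return outputs


def _load_counts(cfg: RunConfig):
    tpath = _require(_p(cfg, "sim", "counts_transcripts.tsv"), "simulate")
    epath = _require(_p(cfg, "sim", "counts_exons.tsv"), "simulate")
    spath = _require(_p(cfg, "sim", "samples.tsv"), "simulate")
    return (sio.read_count_matrix(tpath), sio.read_count_matrix(epath),
            sio.read_sample_sheet(spath))


def stage_diffexport(cfg: RunConfig) -> List[str]:
    params = cfg.stages["diff"]
    transcripts, _, samples = _load_counts(cfg)
    outdir = _p(cfg, "diff")
    os.makedirs(outdir, exist_ok=True)
    factors, norm = normalize_counts(transcripts, samples)
    outputs = []
    p = os.path.join(outdir, "size_factors.tsv")
    sio.write_tsv(factors.to_frame(), p)
    outputs.append(p)
    results = {}
    for fraction in ("cytoplasmic", "whole_cell"):
        res = differential_abundance(norm, samples, fraction,
                                     shrink_weight=params["shrink_weight"])
        results[fraction] = res
        p = os.path.join(outdir, f"abundance_{fraction}.tsv")
        sio.write_tsv(res, p)
        outputs.append(p)
    calls = call_export_targets(results["cytoplasmic"], results["whole_cell"],
                                alpha=params["alpha"], delta=params["delta"])
    p = os.path.join(outdir, "export_calls.tsv")
    sio.write_tsv(calls, p)
    outputs.append(p)
    write_manifest(cfg, "diffexport", [], outputs, params)
    return outputs


def _exon_table_parts(cfg: RunConfig, exon_counts: pd.DataFrame,
                      ann: GenomeAnnotation):
    """Split exon table into true exon rows and APA distinguishing rows."""
    is_apa = exon_counts.index.str.contains(":prox|:dist", regex=True)
    exon_rows = exon_counts.loc[~is_apa]
    gene_of_exon = {}
    for eid in exon_rows.index:
        tid = eid.rsplit(".E", 1)[0]
        t = ann.transcripts.get(tid)
        if t is not None:
            gene_of_exon[eid] = t.gene_id
    return exon_rows, pd.Series(gene_of_exon, name="gene_id")


def stage_exonusage(cfg: RunConfig) -> List[str]:
    params = cfg.stages["exonusage"]
    ann = _load_annotation(cfg)
    _, exon_counts, samples = _load_counts(cfg)
    exon_rows, gene_of_exon = _exon_table_parts(cfg, exon_counts, ann)
    exons = classify_exons(ann)
    outdir = _p(cfg, "exonusage")
    os.makedirs(outdir, exist_ok=True)
    outputs = []
    for fraction in ("whole_cell", "cytoplasmic"):
        res = exon_usage_test(exon_rows, gene_of_exon, samples, fraction,
                              fdr=params["fdr"])
        p = os.path.join(outdir, f"usage_{fraction}.tsv")
        sio.write_tsv(res, p)
        outputs.append(p)
        classes = classify_changed_exons(res, exons)
        p = os.path.join(outdir, f"changed_classes_{fraction}.tsv")
        sio.write_tsv(classes, p, index=False)
        outputs.append(p)
    write_manifest(cfg, "exonusage", [], outputs, params)
    return outputs


def stage_apa(cfg: RunConfig) -> List[str]:
    params = cfg.stages["apa"]
    ann = _load_annotation(cfg)
    _, exon_counts, samples = _load_counts(cfg)
    events = enumerate_apa_events(ann)
    outdir = _p(cfg, "apa")
    os.makedirs(outdir, exist_ok=True)
    res = apa_analysis(exon_counts, events, samples,
                       fraction=params["fraction"],
                       bf_threshold=params["bf_threshold"],
                       dpsi_threshold=params["dpsi_threshold"])
    p = os.path.join(outdir, f"apa_{params['fraction']}.tsv")
    sio.write_tsv(res, p)
    write_manifest(cfg, "apa", [], [p], params)
    return [p]


def stage_report(cfg: RunConfig) -> List[str]:
    ann = _load_annotation(cfg)
    regions = derive_regions(ann)
    outdir = _p(cfg, "report")
    os.makedirs(outdir, exist_ok=True)
    nxf1 = cfg.stages["cobind"]["nxf1_library"]
    control = cfg.stages["cobind"]["control_library"]

    export_path = _require(_p(cfg, "diff", "export_calls.tsv"), "diffexport")
    calls = pd.read_csv(export_path, sep="\t", index_col=0)
    apa_path = _require(
        _p(cfg, "apa", f"apa_{cfg.stages['apa']['fraction']}.tsv"), "apa")
    apa_res = pd.read_csv(apa_path, sep="\t", index_col=0)
    events = enumerate_apa_events(ann)
    sites = {}
    for lib in _libraries(cfg):
        path = _require(_p(cfg, "xlink", f"{lib}.sites.bed"), "callsites")
        sites[lib] = sio.read_sites_bed(path)
    integration = []
    for lib in _libraries(cfg):
        if lib in (nxf1, control):
            continue
        integration.append(integrate_targets_binding(
            calls, sites, ann, regions, apa_results=apa_res,
            sr_library=lib, nxf1_library=nxf1, events=events))
    int_df = pd.DataFrame(integration)
    p_int = os.path.join(outdir, "integration.tsv")
    sio.write_tsv(int_df, p_int, index=False)

    # 3'UTR lengths of export targets vs non-targets
    targets = [t for t in calls.index[calls["is_target"]]]
    others = [t for t in calls.index[~calls["is_target"]]]
    utr_summary, utr_tests = utr3_length_stats(
        {"export_targets": targets, "non_targets": others}, ann)
    p_utr = os.path.join(outdir, "utr3_lengths.tsv")
    sio.write_tsv(utr_summary, p_utr, index=False)

    stages_run = sorted(
        f[:-5] for f in os.listdir(_p(cfg, "manifests"))
        if f.endswith(".json")) if os.path.isdir(_p(cfg, "manifests")) else []
    summary = {
        "stages_run": stages_run,
        "n_export_targets": int(calls["is_target"].sum()),
        "n_apa_called": int(apa_res["called"].sum()) if len(apa_res) else 0,
        "n_binding_sites": {lib: int(len(df)) for lib, df in sites.items()},
        "integration": integration,
        "utr3_medians": utr_summary.set_index("set")["median"].to_dict(),
    }
    p_json = os.path.join(outdir, "summary.json")
    with open(p_json, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    lines = ["# srexport run summary", "",
             f"Stages run: {', '.join(stages_run)}", "",
             f"Export targets called: {summary['n_export_targets']}",
             f"APA events called: {summary['n_apa_called']}", "",
             "Binding sites per library:"]
    for lib, n in summary["n_binding_sites"].items():
        lines.append(f"  - {lib}: {n}")
    p_md = os.path.join(outdir, "summary.md")
    with open(p_md, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    outputs = [p_int, p_utr, p_json, p_md]
    write_manifest(cfg, "report", [export_path, apa_path], outputs, {})
    return outputs


STAGES = {
    "simulate": stage_simulate,
    "callsites": stage_callsites,
    "junctions": stage_junctions,
    "occupancy": stage_occupancy,
    "cobind": stage_cobind,
    "motifs": stage_motifs,
    "diffexport": stage_diffexport,
    "exonusage": stage_exonusage,
    "apa": stage_apa,
    "report": stage_report,
}

PIPELINE_ORDER = ["simulate", "callsites", "junctions", "occupancy",
                  "cobind", "motifs", "diffexport", "exonusage", "apa",
                  "report"]


def run_all(cfg: RunConfig) -> Dict[str, List[str]]:
    out = {}
    for name in PIPELINE_ORDER:
        out[name] = STAGES[name](cfg)
    return out
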