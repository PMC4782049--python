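"""Synthetic data with planted ground truth.

Three generators mirror the experimental design under study:

* :func:`simulate_genome` — a random genome with multi-exon genes on both
  strands, planted protein-binding motifs, and a subset of genes carrying
  tandem-3'UTR or alternative-last-exon isoform pairs.
* :func:`simulate_iclip` — per-protein cross-link events (truncation
  geometry: the read starts one nucleotide 3' of the cross-linked base),
  junction-spanning spliced/unspliced reads, and PCR duplicates sharing a
  random barcode.
* :func:`simulate_fraction_counts` — negative-binomial count tables for
  whole-cell and cytoplasmic fractions (control vs knockdown, two
  replicates) with planted export targets, exon-usage changes and APA
  Psi shifts.

Every generator is deterministic given the config seed.  All planted
structure is emitted as machine-readable ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    APAEvent, GenomeAnnotation, RegionSet, TranscriptModel, derive_regions,
    enumerate_apa_events, write_gtf,
)

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ProteinSpec:
    """One iCLIP library: motif preferences and placement rates.

    ``plant`` gives, per region label, the probability that a gene carries a
    planted motif occurrence in that region (values > 1 plant multiple
    occurrences).  ``enrichment`` is the cross-link rate multiplier at motif
    positions (lambda >= 1); ``background_rate`` the per-nucleotide
    cross-link rate elsewhere; ``spliced_fraction`` the probability that a
    junction-spanning read is spliced.
    """

    name: str
    motifs: List[str] = field(default_factory=list)
    enrichment: float = 8.0
    background_rate: float = 0.2
    spliced_fraction: float = 0.6
    plant: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.enrichment < 1:
            raise ConfigError(f"{self.name}: enrichment must be >= 1")
        if not (0 <= self.spliced_fraction <= 1):
            raise ConfigError(f"{self.name}: spliced_fraction outside [0,1]")
        if self.background_rate <= 0:
            raise ConfigError(f"{self.name}: background_rate must be > 0")
        for m in self.motifs:
            if set(m) - set("ACGT"):
                raise ConfigError(f"{self.name}: motif {m} not a DNA string")


@dataclass
class Nxf1Spec:
    """The export-receptor-like library: no sequence motif of its own.

    Binding sites are planted as bursts of cross-link events.  In 3'UTRs a
    site is anchored at a partner motif occurrence with probability
    ``cobind_rate`` (event offsets ~ Normal(0, offset_sd)), otherwise at a
    uniform 3'UTR position away from partner occurrences.  Independent sites
    are placed in 5'UTRs at ``five_prime_rate`` per gene.
    """

    name: str = "NXF1"
    partner: str = "SRSF3"
    cobind_rate: float = 0.5
    offset_sd: float = 10.0
    five_prime_rate: float = 0.5
    utr3_site_rate: float = 0.9
    site_strength: float = 60.0
    background_rate: float = 0.02
    spliced_fraction: float = 0.5
    # uncobound 3'UTR anchors stay this far from partner occurrences so the
    # planted cobind_rate is the true cobound fraction (window 30 nt +
    # site-center drift + motif footprint)
    exclusion_buffer: int = 80

    def validate(self) -> None:
        for r in (self.cobind_rate, self.five_prime_rate, self.utr3_site_rate):
            if not (0 <= r <= 1):
                raise ConfigError("nxf1 rates must lie in [0,1]")
        if self.offset_sd < 0:
            raise ConfigError("offset_sd must be >= 0")


@dataclass
class RnaseqSpec:
    mean_counts: float = 200.0
    dispersion: float = 0.05
    n_export_targets: int = 50
    export_log2fc: float = -1.0
    export_bound_rate: float = 0.6       # fraction of targets with partner 3'UTR motif
    n_apa_shifted: int = 20
    dpsi: float = 0.3
    apa_frac_shorten: float = 0.75
    n_usage_changed: int = 30
    usage_incl: Tuple[float, float] = (0.6, 0.3)   # control vs KD inclusion
    usage_frac_less: float = 0.75                   # fraction of changes that lose inclusion
    usage_less_last_frac: float = 0.75              # of those, fraction planted in last exons
    base_inclusion: float = 0.6                     # baseline inclusion of non-constitutive exons
    depth_factors: Tuple[float, ...] = (1.0, 1.15, 0.9, 1.05, 0.95, 1.1, 1.0, 0.85)

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if not (0 <= self.dpsi <= 1):
            raise ConfigError("dpsi outside [0,1]")


@dataclass
class GenomeSpec:
    n_genes: int = 200
    chrom: str = "chrS"
    intergenic: int = 400
    n_exons: Tuple[int, int] = (2, 10)
    exon_len: Tuple[int, int] = (80, 300)
    intron_len: Tuple[int, int] = (200, 1200)
    utr5_len: Tuple[int, int] = (60, 200)
    utr3_len: Tuple[int, int] = (500, 1500)
    cds_last_exon: int = 100     # coding nucleotides inside the last exon
    n_tandem: int = 20
    n_ale: int = 10
    gc: float = 0.5

    def validate(self) -> None:
        if self.intron_len[0] < 30:
            raise ConfigError("minimum intron length infeasible (< 30 nt)")
        if self.n_tandem + self.n_ale > self.n_genes:
            raise ConfigError("more APA genes than genes")
        if self.exon_len[0] < 20:
            raise ConfigError("minimum exon length infeasible (< 20 nt)")


def default_proteins() -> List[ProteinSpec]:
    """Eight libraries emulating the study design: seven SR-like binders with
    distinct 8-mer preferences (two same-motif pairs, a C-rich CNUC-core
    SRSF3-like binder) and a nonspecific control."""
    lam = 25.0
    return [
        ProteinSpec("SRSF1", ["GGAGGAAC"], enrichment=lam,
                    plant={"cds": 1.0, "five_prime_utr": 0.3}),
        ProteinSpec("SRSF2", ["TGGACTCT"], enrichment=lam, plant={"cds": 1.0}),
        ProteinSpec("SRSF3", ["TCATCATC"], enrichment=lam,
                    plant={"cds": 0.8, "three_prime_utr": 0.8}),
        ProteinSpec("SRSF4", ["GAAGGACT"], enrichment=lam, plant={"cds": 1.0}),
        ProteinSpec("SRSF5", ["TGGACTCT"], enrichment=lam, plant={"cds": 1.0}),
        ProteinSpec("SRSF6", ["GAAGGACT"], enrichment=lam, plant={"cds": 1.0}),
        ProteinSpec("SRSF7", ["ACGACGAC"], enrichment=lam,
                    plant={"cds": 1.0, "three_prime_utr": 0.3}),
        ProteinSpec("GFPNLS", [], enrichment=1.0, background_rate=0.05),
    ]


@dataclass
class SimulationConfig:
    seed: int = 1
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    proteins: List[ProteinSpec] = field(default_factory=default_proteins)
    nxf1: Nxf1Spec = field(default_factory=Nxf1Spec)
    rnaseq: RnaseqSpec = field(default_factory=RnaseqSpec)
    read_len: Tuple[int, int] = (20, 40)
    barcode_len: int = 9
    pcr_duplication_rate: float = 0.15

    def validate(self) -> None:
        if not (0 <= self.pcr_duplication_rate < 1):
            raise ConfigError("pcr_duplication_rate outside [0,1)")
        self.genome.validate()
        self.nxf1.validate()
        self.rnaseq.validate()
        for p in self.proteins:
            p.validate()

    # -- YAML round trip ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {"seed", "genome", "proteins", "nxf1", "rnaseq", "read_len",
                 "barcode_len", "pcr_duplication_rate"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "genome" in d:
            cfg.genome = GenomeSpec(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in d["genome"].items()})
        if "proteins" in d:
            cfg.proteins = [ProteinSpec(**{k: v for k, v in p.items()}) for p in d["proteins"]]
        if "nxf1" in d:
            cfg.nxf1 = Nxf1Spec(**d["nxf1"])
        if "rnaseq" in d:
            rd = {k: tuple(v) if isinstance(v, list) else v for k, v in d["rnaseq"].items()}
            cfg.rnaseq = RnaseqSpec(**rd)
        if "read_len" in d:
            cfg.read_len = tuple(d["read_len"])
        if "barcode_len" in d:
            cfg.barcode_len = int(d["barcode_len"])
        if "pcr_duplication_rate" in d:
            cfg.pcr_duplication_rate = float(d["pcr_duplication_rate"])
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Genome simulation


@dataclass
class SimulatedGenome:
    sequences: Dict[str, np.ndarray]          # chrom -> uint8 char array
    annotation: GenomeAnnotation
    regions: RegionSet
    truth: dict                                # planted structure

    def sequence(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode()

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gtf(self, path: str) -> None:
        write_gtf(self.annotation, path)

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Independent deterministic stream per stage (stable across processes)."""
    key = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_BYTES[rng.choice(4, size=n, p=p)]


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Random genome + annotation with planted motifs and APA isoform pairs."""
    config.validate()
    g = config.genome
    rng = _rng_for(config, "genome")

    models: List[TranscriptModel] = []
    cursor = g.intergenic
    gene_records = []
    apa_kinds = (["TandemUTR"] * g.n_tandem + ["ALE"] * g.n_ale
                 + [None] * (g.n_genes - g.n_tandem - g.n_ale))
    rng.shuffle(apa_kinds)

    for gi in range(g.n_genes):
        gid = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        kind = apa_kinds[gi]
        k = int(rng.integers(g.n_exons[0], g.n_exons[1] + 1))
        if kind is not None:
            k = max(k, 2)
        exon_lens = [int(rng.integers(*g.exon_len)) for _ in range(k - 1)]
        last_len = int(rng.integers(*g.utr3_len)) + g.cds_last_exon
        intron_lens = [int(rng.integers(*g.intron_len)) for _ in range(k - 1)]
        # build in transcript orientation, then map to genomic coords
        lens = exon_lens + [last_len]
        pos = 0
        t_exons = []
        for i, L in enumerate(lens):
            t_exons.append((pos, pos + L))
            pos += L
            if i < k - 1:
                pos += intron_lens[i]
        span_len = pos
        alt_t = None
        if kind == "ALE":
            alt_len = int(rng.integers(300, 700))
            gap = int(rng.integers(150, 400))
            alt_t = (span_len + gap, span_len + gap + alt_len)
        footprint = alt_t[1] if alt_t is not None else span_len
        gstart = cursor
        cursor += footprint + g.intergenic

        def to_genomic(iv: Tuple[int, int]) -> Tuple[int, int]:
            if strand == "+":
                return (gstart + iv[0], gstart + iv[1])
            return (gstart + footprint - iv[1], gstart + footprint - iv[0])

        genomic_exons = [to_genomic(iv) for iv in t_exons]
        # CDS in transcript coords: starts inside first exon, ends
        # cds_last_exon nt into the last exon (3'UTR = rest of last exon);
        # for ALE genes the CDS ends in the shared penultimate exon so both
        # isoforms contain it
        utr5 = int(rng.integers(*g.utr5_len))
        utr5 = min(utr5, lens[0] - 10)
        if kind == "ALE":
            cds_t = (utr5, t_exons[-2][1] - 3)
        else:
            cds_t = (utr5, t_exons[-1][0] + g.cds_last_exon)
        cds = tuple(sorted(to_genomic((cds_t[0], cds_t[1]))))

        tid = f"{gid}.t1"
        models.append(TranscriptModel(tid, gid, g.chrom, strand,
                                      list(genomic_exons), cds=cds))
        if kind == "TandemUTR":
            # short isoform: last exon truncated at 40-60% of the 3'UTR
            le_t = t_exons[-1]
            utr_start = le_t[0] + g.cds_last_exon
            cut = utr_start + int((le_t[1] - utr_start) * rng.uniform(0.4, 0.6))
            short_exons = [to_genomic(iv) for iv in t_exons[:-1]] + [to_genomic((le_t[0], cut))]
            models.append(TranscriptModel(f"{gid}.t2", gid, g.chrom, strand,
                                          short_exons, cds=cds))
        elif kind == "ALE":
            alt_exons = [to_genomic(iv) for iv in t_exons[:-1]] + [to_genomic(alt_t)]
            models.append(TranscriptModel(f"{gid}.t2", gid, g.chrom, strand,
                                          alt_exons, cds=cds))
        gene_records.append((gid, strand, kind))

    genome_len = cursor + g.intergenic

    seq = _random_sequence(rng, genome_len, g.gc)
    annotation = GenomeAnnotation(models)
    regions = derive_regions(annotation)

    # ---- motif planting ---------------------------------------------------
    planted: Dict[str, List[dict]] = {}
    occupied: Dict[str, List[Tuple[int, int]]] = {}   # gene -> planted footprints
    unique: Dict[str, Dict[str, float]] = {}          # motif -> label -> max rate
    for p in config.proteins:
        for m in p.motifs:
            for label, r in p.plant.items():
                unique.setdefault(m, {})[label] = max(unique.get(m, {}).get(label, 0.0), r)
    for motif in sorted(unique):
        planted[motif] = []
        for gid in annotation.genes:
            per_gene = regions.intervals.get(gid, {})
            strand = annotation.gene_span(gid)[1]
            occ = occupied.setdefault(gid, [])
            for label, rate in sorted(unique[motif].items()):
                ivs = per_gene.get(label, [])
                if not ivs:
                    continue
                n = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
                for _ in range(n):
                    # pick an interval weighted by length, then a position
                    lens = np.array([e - s for s, e in ivs], dtype=float)
                    lens[lens < 12] = 0
                    if lens.sum() == 0:
                        continue
                    for _attempt in range(20):
                        i = rng.choice(len(ivs), p=lens / lens.sum())
                        s, e = ivs[i]
                        if e - s < len(motif) + 2:
                            continue
                        pos = int(rng.integers(s, e - len(motif)))
                        if any(pos < oe + 2 and os_ - 2 < pos + len(motif)
                               for os_, oe in occ):
                            continue
                        written = motif if strand == "+" else revcomp(motif)
                        seq[pos:pos + len(motif)] = np.frombuffer(
                            written.encode(), dtype=np.uint8)
                        occ.append((pos, pos + len(motif)))
                        planted[motif].append(
                            {"gene_id": gid, "label": label, "start": pos,
                             "end": pos + len(motif), "strand": strand})
                        break
    truth = {
        "genes": [{"gene_id": gid, "strand": strand, "apa_kind": kind}
                  for gid, strand, kind in gene_records],
        "planted_motifs": planted,
        "protein_motifs": {p.name: p.motifs for p in config.proteins},
    }
    return SimulatedGenome(sequences={g.chrom: seq}, annotation=annotation,
                           regions=regions, truth=truth)


# ---------------------------------------------------------------------------
# iCLIP simulation


@dataclass
class IclipLibrary:
    name: str
    reads: pd.DataFrame        # chrom,start,end,name,score,strand,blocks
    n_unique: int              # unique cDNAs before PCR amplification
    truth: dict


def _scan_motif(oriented_seq: str, motif: str) -> List[int]:
    """All occurrence start offsets of motif in the oriented sequence."""
    out = []
    i = oriented_seq.find(motif)
    while i >= 0:
        out.append(i)
        i = oriented_seq.find(motif, i + 1)
    return out


def _barcodes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    raw = _BASE_BYTES[codes]
    return raw.view(f"S{length}").ravel().astype("U")


def simulate_iclip(config: SimulationConfig, genome: SimulatedGenome,
                   proteins: Optional[Sequence[str]] = None) -> Dict[str, IclipLibrary]:
    """Per-protein cross-link events and reads.

    Cross-links are drawn per nucleotide as Poisson(rate), with rate =
    lambda x background at motif positions and background elsewhere.  The
    NXF1-like library adds planted binding-site bursts (see
    :class:`Nxf1Spec`).  Each cross-link emits a read starting 1 nt 3' of
    the cross-linked base (length 20-40); reads crossing an annotated 5'
    splice site are spliced with probability ``spliced_fraction``.  PCR
    duplicates share barcode and position.
    """
    config.validate()
    ann = genome.annotation
    regions = genome.regions
    chrom = next(iter(genome.sequences))
    seq = genome.sequence(chrom)

    gene_info = []
    for gid in ann.genes:
        c, strand, s, e = ann.gene_span(gid)
        gene_info.append((gid, strand, s, e))

    libraries: Dict[str, IclipLibrary] = {}
    specs: List[Tuple[str, object]] = [(p.name, p) for p in config.proteins]
    specs.append((config.nxf1.name, config.nxf1))
    wanted = set(proteins) if proteins is not None else None

    partner_occ: Dict[str, List[Tuple[int, int]]] = {}  # gene -> partner 3'UTR occurrences
    partner_spec = next((p for p in config.proteins if p.name == config.nxf1.partner), None)
    if partner_spec is not None:
        for motif in partner_spec.motifs:
            for rec in genome.truth["planted_motifs"].get(motif, []):
                if rec["label"] == "three_prime_utr":
                    partner_occ.setdefault(rec["gene_id"], []).append(
                        (rec["start"], rec["end"]))

    for name, spec in specs:
        if wanted is not None and name not in wanted:
            continue
        rng = _rng_for(config, f"iclip:{name}")
        xl_pos: List[np.ndarray] = []
        xl_cnt: List[np.ndarray] = []
        xl_gene: List[str] = []
        site_truth: List[dict] = []
        occurrence_truth: List[dict] = []

        is_nxf1 = isinstance(spec, Nxf1Spec)
        b = spec.background_rate
        for gid, strand, gs, ge in gene_info:
            L = ge - gs
            rate = np.full(L, b)
            if not is_nxf1 and spec.motifs and spec.enrichment > 1:
                gseq = seq[gs:ge]
                oriented = gseq if strand == "+" else revcomp(gseq)
                for motif in spec.motifs:
                    for off in _scan_motif(oriented, motif):
                        if strand == "+":
                            a0, a1 = off, off + len(motif)
                        else:
                            a0, a1 = L - off - len(motif), L - off
                        rate[a0:a1] = b * spec.enrichment
                        occurrence_truth.append(
                            {"gene_id": gid, "start": gs + a0, "end": gs + a1,
                             "strand": strand})
            counts = rng.poisson(rate)
            if is_nxf1:
                counts = counts.astype(np.int64)
                per_gene = regions.intervals.get(gid, {})
                utr3 = per_gene.get("three_prime_utr", [])
                utr5 = per_gene.get("five_prime_utr", [])

                def add_site(anchor: int, where: str, cobound: bool,
                             partner_iv: Optional[Tuple[int, int]] = None) -> None:
                    n_ev = rng.poisson(spec.site_strength)
                    if n_ev == 0:
                        return
                    offs = np.rint(rng.normal(0.0, spec.offset_sd, size=n_ev)).astype(int)
                    pos = np.clip(anchor + offs, gs, ge - 1) - gs
                    np.add.at(counts, pos, 1)
                    site_truth.append({
                        "gene_id": gid, "anchor": int(anchor), "region": where,
                        "cobound": bool(cobound),
                        "partner_occurrence": list(partner_iv) if partner_iv else None})

                if utr3 and rng.random() < spec.utr3_site_rate:
                    occs = partner_occ.get(gid, [])
                    if occs and rng.random() < spec.cobind_rate:
                        iv = occs[int(rng.integers(len(occs)))]
                        add_site((iv[0] + iv[1]) // 2, "three_prime_utr", True, iv)
                    else:
                        # uniform in 3'UTR, excluding a buffer around partner
                        # occurrences so planted cobinding stays at its
                        # configured rate
                        for _attempt in range(50):
                            lens = np.array([e - s for s, e in utr3], dtype=float)
                            i = rng.choice(len(utr3), p=lens / lens.sum())
                            a = int(rng.integers(*utr3[i]))
                            if all(a < o0 - spec.exclusion_buffer
                                   or a > o1 + spec.exclusion_buffer
                                   for o0, o1 in occs):
                                add_site(a, "three_prime_utr", False)
                                break
                if utr5 and rng.random() < spec.five_prime_rate:
                    lens = np.array([e - s for s, e in utr5], dtype=float)
                    i = rng.choice(len(utr5), p=lens / lens.sum())
                    add_site(int(rng.integers(*utr5[i])), "five_prime_utr", False)
            nz = np.nonzero(counts)[0]
            if len(nz):
                xl_pos.append(nz + gs)
                xl_cnt.append(counts[nz])

        if xl_pos:
            positions = np.concatenate(xl_pos)
            counts_all = np.concatenate(xl_cnt)
        else:
            positions = np.array([], dtype=int)
            counts_all = np.array([], dtype=int)
        strands = _positions_strands(gene_info, positions)

        reads, n_unique = _emit_reads(
            config, ann, regions, chrom, positions, counts_all, strands,
            spec.spliced_fraction, rng)
        libraries[name] = IclipLibrary(
            name=name, reads=reads, n_unique=n_unique,
            truth={"sites": site_truth, "occurrences": occurrence_truth,
                   "spliced_fraction": spec.spliced_fraction,
                   "n_unique_cdnas": int(n_unique)})
    return libraries


def _positions_strands(gene_info, positions: np.ndarray) -> np.ndarray:
    """Strand of the gene each (sorted-by-construction) position falls in."""
    starts = np.array([s for _, _, s, _ in gene_info])
    strands = np.array([st for _, st, _, _ in gene_info])
    order = np.argsort(starts)
    starts = starts[order]
    strands = strands[order]
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    return strands[idx]


def _emit_reads(config: SimulationConfig, ann: GenomeAnnotation,
                regions: RegionSet, chrom: str,
                positions: np.ndarray, counts: np.ndarray, strands: np.ndarray,
                p_spliced: float, rng: np.random.Generator
                ) -> Tuple[pd.DataFrame, int]:
    """Reads from cross-link positions, with splicing and PCR duplication."""
    # representative-exon boundary lookup per strand for junction logic
    reps = {gid: ann.transcripts[tid]
            for gid, tid in regions.representative.items()}
    exon_list: Dict[str, List[Tuple[int, int, int]]] = {"+": [], "-": []}
    for ti, t in enumerate(reps.values()):
        exon_list[t.strand].extend((s, e, ti) for s, e in t.genomic_exons)
    exon_arr = {}
    for st in "+-":
        ex = sorted(exon_list[st])
        exon_arr[st] = (np.array([s for s, _, _ in ex] or [0]),
                        np.array([e for _, e, _ in ex] or [0]),
                        np.array([t for _, _, t in ex] or [-1]))

    # expand events to unique cDNAs
    cdna_pos = np.repeat(positions, counts)
    cdna_strand = np.repeat(strands, counts)
    n_unique = len(cdna_pos)
    if n_unique == 0:
        cols = ["chrom", "start", "end", "name", "score", "strand", "blocks"]
        return pd.DataFrame(columns=cols), 0
    lengths = rng.integers(config.read_len[0], config.read_len[1] + 1, size=n_unique)
    spliced_flip = rng.random(n_unique) < p_spliced
    barcodes = _barcodes(rng, n_unique, config.barcode_len)

    starts = np.empty(n_unique, dtype=int)
    ends = np.empty(n_unique, dtype=int)
    blocks: List[str] = [""] * n_unique

    for st in "+-":
        m = cdna_strand == st
        if not m.any():
            continue
        es, ee, et = exon_arr[st]
        xl = cdna_pos[m]
        ln = lengths[m]
        if st == "+":
            s0 = xl + 1
            e0 = s0 + ln
        else:
            e0 = xl          # half-open end; read 5' base at xl-1
            s0 = e0 - ln
        i = np.searchsorted(es, (s0 if st == "+" else e0 - 1), side="right") - 1
        i = np.clip(i, 0, len(es) - 1)
        anchor = s0 if st == "+" else e0 - 1
        in_exon = (anchor >= es[i]) & (anchor < ee[i])
        # a junction exists only when the neighbouring exon belongs to the
        # same transcript (i.e. this is a real 5' splice site)
        if st == "+":
            has_next = (i + 1 < len(es)) & (et[np.minimum(i + 1, len(es) - 1)] == et[i])
            crosses = in_exon & (e0 > ee[i]) & has_next
        else:
            has_next = (i - 1 >= 0) & (et[np.maximum(i - 1, 0)] == et[i])
            crosses = in_exon & (s0 < es[i]) & has_next
        spl = crosses & spliced_flip[m]

        sub_start = s0.copy()
        sub_end = e0.copy()
        sub_blocks = np.array([""] * m.sum(), dtype=object)
        idxs = np.nonzero(spl)[0]
        if len(idxs):
            k = i[idxs]
            if st == "+":
                rem = np.minimum(e0[idxs] - ee[k], ee[k + 1] - es[k + 1])
                b1s, b1e = s0[idxs], ee[k]
                b2s = es[k + 1]
                b2e = b2s + rem
            else:
                rem = np.minimum(es[k] - s0[idxs], ee[k - 1] - es[k - 1])
                b1e = ee[k - 1]
                b1s = b1e - rem
                b2s, b2e = es[k], e0[idxs]
            sub_start[idxs] = b1s
            sub_end[idxs] = b2e
            parts = np.char.add(np.char.add(b1s.astype("U12"), "-"),
                                b1e.astype("U12"))
            parts = np.char.add(np.char.add(parts, ","),
                                np.char.add(np.char.add(b2s.astype("U12"), "-"),
                                            b2e.astype("U12")))
            sub_blocks[idxs] = parts
        contiguous = ~spl
        sub_start[contiguous] = np.maximum(sub_start[contiguous], 0)
        starts[m] = sub_start
        ends[m] = sub_end
        blk = sub_blocks
        blk[contiguous] = ""
        out_idx = np.nonzero(m)[0]
        for j, oi in enumerate(out_idx):
            blocks[oi] = blk[j]

    # PCR duplication: copies per cDNA ~ Geometric(1 - d)
    d = config.pcr_duplication_rate
    if d > 0:
        copies = rng.geometric(1 - d, size=n_unique)
    else:
        copies = np.ones(n_unique, dtype=int)
    rep = np.repeat(np.arange(n_unique), copies)
    blocks_arr = np.asarray(blocks, dtype=object)
    # contiguous reads get their single block lazily (vectorised)
    empty = blocks_arr == ""
    if empty.any():
        single = np.char.add(np.char.add(starts[empty].astype("U12"), "-"),
                             ends[empty].astype("U12"))
        blocks_arr[empty] = single
    idx_str = np.arange(len(rep)).astype("U12")
    names = np.char.add(np.char.add(np.char.add("r", idx_str), ":"),
                        barcodes[rep])
    df = pd.DataFrame({
        "chrom": chrom,
        "start": starts[rep],
        "end": ends[rep],
        "name": names,
        "score": 0,
        "strand": cdna_strand[rep],
        "blocks": blocks_arr[rep],
    })
    # shuffle read order to emulate an unsorted library (deterministic)
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    return df, n_unique


# ---------------------------------------------------------------------------
# Fractionated RNA-seq counts


SAMPLES = [
    ("whole_cell", "control", 1), ("whole_cell", "control", 2),
    ("whole_cell", "kd", 1), ("whole_cell", "kd", 2),
    ("cytoplasmic", "control", 1), ("cytoplasmic", "control", 2),
    ("cytoplasmic", "kd", 1), ("cytoplasmic", "kd", 2),
]


def sample_sheet() -> pd.DataFrame:
    rows = [{"sample": f"{f[:2]}_{c}_{r}", "fraction": f, "condition": c,
             "replicate": r} for f, c, r in SAMPLES]
    return pd.DataFrame(rows)


@dataclass
class FractionCounts:
    transcripts: pd.DataFrame   # features x samples
    exons: pd.DataFrame         # exon + APA-region features x samples
    samples: pd.DataFrame
    truth: dict


def simulate_fraction_counts(config: SimulationConfig,
                             genome: SimulatedGenome) -> FractionCounts:
    """NB count tables (2 replicates x condition x fraction) with planted
    export targets, exon-usage changes and APA Psi shifts.

    Export targets receive the knockdown effect only in the cytoplasmic
    fraction.  Exon counts share gene-level NB noise (a Gamma multiplier per
    gene and sample) with Poisson counting noise on top, so exon/gene usage
    ratios carry only counting noise.
    """
    config.validate()
    r = config.rnaseq
    rng = _rng_for(config, "rnaseq")
    ann = genome.annotation
    regions = genome.regions
    reps = regions.representative
    sheet = sample_sheet()

    gene_ids = sorted(reps)
    tids = [reps[g] for g in gene_ids]
    n = len(gene_ids)
    base = rng.lognormal(mean=np.log(r.mean_counts), sigma=0.8, size=n)
    alpha = r.dispersion

    # --- planted export targets, coupled to partner 3'UTR motifs -----------
    partner = config.nxf1.partner
    partner_motifs = genome.truth["protein_motifs"].get(partner, [])
    bound_genes = set()
    for m in partner_motifs:
        for rec in genome.truth["planted_motifs"].get(m, []):
            if rec["label"] == "three_prime_utr":
                bound_genes.add(rec["gene_id"])
    # targets are planted among well-expressed transcripts (base mean at or
    # above the configured mean) so the planted effect is detectable
    eligible = {g for g, b in zip(gene_ids, base) if b >= r.mean_counts}
    bound = [g for g in gene_ids if g in bound_genes and g in eligible]
    unbound = [g for g in gene_ids if g not in bound_genes and g in eligible]
    n_b = min(int(round(r.n_export_targets * r.export_bound_rate)), len(bound))
    n_u = min(r.n_export_targets - n_b, len(unbound))
    targets = (list(rng.choice(bound, size=n_b, replace=False)) if n_b else []) + \
              (list(rng.choice(unbound, size=n_u, replace=False)) if n_u else [])
    target_set = set(targets)

    # --- transcript-level table --------------------------------------------
    cols = {}
    effect = np.ones(n)
    t_idx = {g: i for i, g in enumerate(gene_ids)}
    for g in targets:
        effect[t_idx[g]] = 2.0 ** r.export_log2fc
    shape = 1.0 / alpha
    gene_noise = {}   # (sample) -> per-gene Gamma multipliers (mean 1)
    for si, (frac, cond, repl) in enumerate(SAMPLES):
        sf = r.depth_factors[si % len(r.depth_factors)]
        mult = rng.gamma(shape, scale=alpha, size=n)
        gene_noise[sheet["sample"][si]] = mult
        mu = base * sf * mult
        if cond == "kd" and frac == "cytoplasmic":
            mu = mu * effect
        cols[sheet["sample"][si]] = rng.poisson(mu)
    transcripts = pd.DataFrame(cols, index=pd.Index(tids, name="feature"))

    # --- exon-level table ---------------------------------------------------
    exon_rows: List[str] = []
    exon_len: List[int] = []
    exon_gene: List[str] = []
    exon_incl_c: List[float] = []
    exon_incl_k: List[float] = []
    exon_class: List[str] = []
    usage_truth: List[dict] = []

    per_gene_exons: Dict[str, List[Tuple[str, int, str]]] = {}
    for g in gene_ids:
        t = ann.transcripts[reps[g]]
        lst = []
        nex = len(t.exons)
        for i, (s, e) in enumerate(t.exons):
            cls = ("single" if nex == 1 else
                   "first" if i == 0 else "last" if i == nex - 1 else "internal")
            lst.append((f"{reps[g]}.E{i + 1}", e - s, cls))
        per_gene_exons[g] = lst

    # choose exon-usage changes: a mix of less/more inclusion; the
    # less-included set is planted preferentially in last exons
    n_less = int(round(r.n_usage_changed * r.usage_frac_less))
    n_more = r.n_usage_changed - n_less
    candidates_last = [(g, x) for g in gene_ids for x in per_gene_exons[g]
                       if x[2] == "last"]
    candidates_internal = [(g, x) for g in gene_ids for x in per_gene_exons[g]
                           if x[2] == "internal"]
    rng.shuffle(candidates_last)
    rng.shuffle(candidates_internal)
    changed: Dict[str, Tuple[float, float, str]] = {}
    n_less_last = int(round(n_less * r.usage_less_last_frac))
    pool = (candidates_last[:n_less_last]
            + candidates_internal[:n_less - n_less_last])
    for g, (eid, _, cls) in pool:
        changed[eid] = (r.usage_incl[0], r.usage_incl[1], "less")
    for g, (eid, _, cls) in candidates_internal[n_less - n_less_last:
                                                n_less - n_less_last + n_more]:
        changed[eid] = (r.usage_incl[1], r.usage_incl[0], "more")

    for g in gene_ids:
        for eid, ln, cls in per_gene_exons[g]:
            exon_rows.append(eid)
            exon_len.append(ln)
            exon_gene.append(g)
            exon_class.append(cls)
            if eid in changed:
                ic, ik, direction = changed[eid]
                usage_truth.append({"exon_id": eid, "gene_id": g,
                                    "incl_control": ic, "incl_kd": ik,
                                    "direction": direction, "ordinal_class": cls})
            else:
                ic = ik = 1.0 if cls in ("first",) else r.base_inclusion
            exon_incl_c.append(ic)
            exon_incl_k.append(ik)

    # APA events and Psi truth
    events = enumerate_apa_events(ann)
    rng.shuffle(events)
    shifted = events[:min(r.n_apa_shifted, len(events))]
    shifted_ids = {ev.event_id for ev in shifted}
    psi_truth: List[dict] = []
    apa_rows: List[Tuple[str, APAEvent, float, float]] = []
    for ev in events:
        psi0 = float(rng.uniform(0.35, 0.75))
        if ev.event_id in shifted_ids:
            if rng.random() < r.apa_frac_shorten:
                psi1 = max(0.05, psi0 - r.dpsi)
            else:
                psi1 = min(0.95, psi0 + r.dpsi)
        else:
            psi1 = psi0
        apa_rows.append((ev.event_id, ev, psi0, psi1))
        psi_truth.append({"event_id": ev.event_id, "gene_id": ev.gene_id,
                          "kind": ev.kind, "psi_control": psi0, "psi_kd": psi1,
                          "shifted": ev.event_id in shifted_ids})

    exon_cols: Dict[str, np.ndarray] = {}
    ln_arr = np.array(exon_len, dtype=float)
    gidx = np.array([t_idx[g] for g in exon_gene])
    ic_arr = np.array(exon_incl_c)
    ik_arr = np.array(exon_incl_k)
    for si, (frac, cond, repl) in enumerate(SAMPLES):
        sname = sheet["sample"][si]
        sf = r.depth_factors[si % len(r.depth_factors)]
        mult = gene_noise[sname]
        g_abund = base * sf * mult
        if cond == "kd" and frac == "cytoplasmic":
            g_abund = g_abund * effect
        incl = ic_arr if cond == "control" else ik_arr
        mu = g_abund[gidx] * (ln_arr / 1000.0) * incl
        col = list(rng.poisson(mu))
        # APA distinguishing-region rows
        for eid, ev, psi0, psi1 in apa_rows:
            psi = psi0 if cond == "control" else psi1
            gi = t_idx[ev.gene_id]
            a = g_abund[gi]
            lp = ev.proximal_region[1] - ev.proximal_region[0]
            ld = ev.distal_region[1] - ev.distal_region[0]
            if ev.kind == "TandemUTR":
                mu_p = a * lp / 1000.0            # shared by both isoforms
                mu_d = a * psi * ld / 1000.0      # long isoform only
            else:
                mu_p = a * (1 - psi) * lp / 1000.0
                mu_d = a * psi * ld / 1000.0
            col.append(rng.poisson(mu_p))
            col.append(rng.poisson(mu_d))
        exon_cols[sname] = np.array(col)
    index = exon_rows + [x for eid, *_ in apa_rows for x in (f"{eid}:prox", f"{eid}:dist")]
    exons = pd.DataFrame(exon_cols, index=pd.Index(index, name="feature"))

    truth = {
        "export_targets": [{"transcript_id": reps[g], "gene_id": g,
                            "true_log2fc": r.export_log2fc,
                            "partner_bound": g in bound_genes}
                           for g in sorted(target_set)],
        "exon_usage": usage_truth,
        "apa": psi_truth,
        "depth_factors": list(r.depth_factors),
    }
    return FractionCounts(transcripts=transcripts, exons=exons,
                          samples=sheet, truth=truth)
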