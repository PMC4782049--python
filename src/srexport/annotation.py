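"""Genome annotation model: transcripts, regions, exon ordinals, splice sites, APA events.

All internal coordinates are 0-based half-open on the forward genomic strand.
GTF input/output converts to/from the 1-based closed GTF convention at the
boundary.  Exon lists inside :class:`TranscriptModel` are kept in transcript
5'->3' order, i.e. reversed genomic order on the minus strand.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np

Interval = Tuple[int, int]

REGION_LABELS = ("five_prime_utr", "cds", "three_prime_utr", "intron", "noncoding_exon")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class TranscriptModel:
    """A transcript with exons ordered along the transcript (5'->3')."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval]          # transcript order; each (start, end) half-open genomic
    cds: Optional[Interval] = None  # genomic span (start, end), None for noncoding
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript with zero exons")
        genomic = sorted(self.exons)
        for (s, e) in genomic:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        # normalise to transcript order
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.span[0] <= cs < ce <= self.span[1]):
                raise AnnotationError(f"{self.transcript_id}: CDS outside transcript span")

    @property
    def genomic_exons(self) -> List[Interval]:
        return sorted(self.exons)

    @property
    def span(self) -> Interval:
        ex = self.genomic_exons
        return (ex[0][0], ex[-1][1])

    @property
    def introns(self) -> List[Interval]:
        """Genomic intron intervals, sorted by coordinate."""
        ex = self.genomic_exons
        return [(e1, s2) for (_, e1), (s2, _) in zip(ex, ex[1:])]

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_in_exons(self) -> bool:
        """True if the CDS genomic span is covered by the exon union."""
        if self.cds is None:
            return True
        cs, ce = self.cds
        covered = 0
        for s, e in self.genomic_exons:
            covered += max(0, min(e, ce) - max(s, cs))
        # every intronic gap inside the CDS span is fine; we require the CDS
        # boundaries to fall inside exons and no exon-free CDS-only sequence
        inside = any(s <= cs < e for s, e in self.genomic_exons) and any(
            s < ce <= e for s, e in self.genomic_exons
        )
        return inside and covered > 0


@dataclass
class ExonFeature:
    exon_id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    span: Interval
    ordinal_class: str  # first | internal | last | single
    ordinal: int        # 0-based index in transcript order


@dataclass
class RegionSet:
    """Labeled genomic intervals of one representative transcript per gene."""

    # gene_id -> label -> list of genomic intervals
    intervals: Dict[str, Dict[str, List[Interval]]]
    representative: Dict[str, str]          # gene_id -> transcript_id
    flagged_genes: List[str] = field(default_factory=list)

    def total_lengths(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for per_gene in self.intervals.values():
            for label, ivs in per_gene.items():
                out[label] = out.get(label, 0) + sum(e - s for s, e in ivs)
        return out


@dataclass
class APAEvent:
    event_id: str
    gene_id: str
    kind: str                   # TandemUTR | ALE
    chrom: str
    strand: str
    proximal_region: Interval
    distal_region: Interval
    isoform_ids: Tuple[str, str]  # (proximal/short, distal/long)


class GenomeAnnotation:
    """Container indexing :class:`TranscriptModel` by transcript, gene and interval."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: Dict[str, TranscriptModel] = {}
        self.genes: Dict[str, List[str]] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise AnnotationError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._segment_index: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List[str]]] = {}
        self._build_gene_index()

    # -- gene spans and point-to-gene assignment ------------------------------

    def gene_span(self, gene_id: str) -> Tuple[str, str, int, int]:
        tids = self.genes[gene_id]
        starts = [self.transcripts[t].span[0] for t in tids]
        ends = [self.transcripts[t].span[1] for t in tids]
        t0 = self.transcripts[tids[0]]
        return t0.chrom, t0.strand, min(starts), max(ends)

    def _build_gene_index(self) -> None:
        """Disjoint per-(chrom,strand) segments; same-strand overlaps go to the
        gene with the longer span."""
        by_cs: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
        for g in self.genes:
            chrom, strand, s, e = self.gene_span(g)
            by_cs.setdefault((chrom, strand), []).append((s, e, g))
        for key, spans in by_cs.items():
            bounds = sorted({x for s, e, _ in spans for x in (s, e)})
            seg_starts: List[int] = []
            seg_ends: List[int] = []
            seg_gene: List[str] = []
            spans_sorted = sorted(spans, key=lambda t: (t[1] - t[0]), reverse=True)
            for b0, b1 in zip(bounds, bounds[1:]):
                owner = None
                for s, e, g in spans_sorted:  # longest span wins
                    if s <= b0 and b1 <= e:
                        owner = g
                        break
                if owner is not None:
                    if seg_gene and seg_gene[-1] == owner and seg_ends[-1] == b0:
                        seg_ends[-1] = b1
                    else:
                        seg_starts.append(b0)
                        seg_ends.append(b1)
                        seg_gene.append(owner)
            self._segment_index[key] = (
                np.asarray(seg_starts), np.asarray(seg_ends), seg_gene)

    def assign_genes(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised point-to-gene assignment (strand-specific).

        Returns an object array of gene ids; None for intergenic positions.
        """
        out = np.full(len(positions), None, dtype=object)
        idx = self._segment_index.get((chrom, strand))
        if idx is None or len(idx[0]) == 0:
            return out
        starts, ends, gene = idx
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < ends[np.clip(i, 0, len(ends) - 1)])
        for j in np.nonzero(ok)[0]:
            out[j] = gene[i[j]]
        return out


# ---------------------------------------------------------------------------
# GTF I/O


def _validate_gtf(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: bad coordinate range {start}-{end}")


def load_annotation(gtf_path: str) -> GenomeAnnotation:
    """Load an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    GTF 1-based closed intervals are converted to 0-based half-open.
    A transcript with zero exon records is rejected with its id.
    """
    _validate_gtf(gtf_path)
    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True)
    models: List[TranscriptModel] = []
    seen_tids = set()
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        seen_tids.add(tid)
        exons = [(f.start - 1, f.end) for f in db.children(tr, featuretype="exon")]
        if not exons:
            raise AnnotationError(f"transcript {tid} has zero exons")
        cds_parts = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
        cds = None
        if cds_parts:
            cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
        biotype = tr.attributes.get("transcript_biotype", ["protein_coding"])[0]
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=tr.seqid, strand=tr.strand,
            exons=exons, cds=cds, biotype=biotype))
    # transcripts referenced only by exon lines still count; gffutils needs the
    # transcript record in the Ensembl dialect, which our writer always emits.
    return GenomeAnnotation(models)


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Write models back to Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for gid in annotation.genes:
            chrom, strand, s, e = annotation.gene_span(gid)
            fh.write("\t".join([
                chrom, "srexport", "gene", str(s + 1), str(e), ".", strand, ".",
                f'gene_id "{gid}";']) + "\n")
            for tid in annotation.genes[gid]:
                t = annotation.transcripts[tid]
                ts, te = t.span
                attrs = f'gene_id "{gid}"; transcript_id "{tid}"; transcript_biotype "{t.biotype}";'
                fh.write("\t".join([
                    chrom, "srexport", "transcript", str(ts + 1), str(te), ".",
                    strand, ".", attrs]) + "\n")
                for i, (xs, xe) in enumerate(t.exons, start=1):
                    fh.write("\t".join([
                        chrom, "srexport", "exon", str(xs + 1), str(xe), ".",
                        strand, ".", attrs + f' exon_number "{i}";']) + "\n")
                if t.cds is not None:
                    cs, ce = t.cds
                    for xs, xe in t.genomic_exons:
                        os_, oe = max(xs, cs), min(xe, ce)
                        if os_ < oe:
                            fh.write("\t".join([
                                chrom, "srexport", "CDS", str(os_ + 1), str(oe),
                                ".", strand, "0", attrs]) + "\n")


def write_bed6(records: Iterable[Tuple[str, int, int, str, float, str]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# Derived structures


def representative_transcripts(
        annotation: GenomeAnnotation, policy: str = "longest_cds") -> Dict[str, str]:
    """One representative transcript per gene.

    ``longest_cds``: longest CDS, ties broken by longest transcript (mature
    length) then lexicographic transcript id.  Noncoding genes fall back to
    longest transcript.
    """
    if policy != "longest_cds":
        raise ValueError(f"unknown representative policy {policy!r}")
    reps: Dict[str, str] = {}
    for gid, tids in annotation.genes.items():
        def key(tid: str):
            t = annotation.transcripts[tid]
            cds_len = 0
            if t.cds is not None:
                cs, ce = t.cds
                cds_len = sum(max(0, min(e, ce) - max(s, cs)) for s, e in t.genomic_exons)
            return (-cds_len, -t.mature_length, tid)
        reps[gid] = sorted(tids, key=key)[0]
    return reps


def derive_regions(annotation: GenomeAnnotation, policy: str = "longest_cds") -> RegionSet:
    """Label the representative transcript of each gene into
    5'UTR / CDS / 3'UTR / intron (or noncoding_exon / intron).

    Genes whose CDS boundaries fall outside the exon union are flagged and
    excluded from region statistics.
    """
    reps = representative_transcripts(annotation, policy)
    intervals: Dict[str, Dict[str, List[Interval]]] = {}
    flagged: List[str] = []
    for gid, tid in reps.items():
        t = annotation.transcripts[tid]
        per: Dict[str, List[Interval]] = {}
        if t.cds is not None and not t.cds_in_exons():
            flagged.append(gid)
            continue
        per["intron"] = list(t.introns)
        if t.cds is None:
            per["noncoding_exon"] = list(t.genomic_exons)
        else:
            cs, ce = t.cds
            five, mid, three = [], [], []
            for xs, xe in t.genomic_exons:
                left = (xs, min(xe, cs))
                inside = (max(xs, cs), min(xe, ce))
                right = (max(xs, ce), xe)
                if left[0] < left[1]:
                    (five if t.strand == "+" else three).append(left)
                if inside[0] < inside[1]:
                    mid.append(inside)
                if right[0] < right[1]:
                    (three if t.strand == "+" else five).append(right)
            per["five_prime_utr"] = five
            per["cds"] = mid
            per["three_prime_utr"] = three
        intervals[gid] = {k: sorted(v) for k, v in per.items() if v}
    return RegionSet(intervals=intervals, representative=reps, flagged_genes=flagged)


def classify_exons(annotation: GenomeAnnotation) -> List[ExonFeature]:
    """Assign first/internal/last/single ordinals per transcript, strand-aware.

    On the minus strand "first" is the rightmost genomic exon.
    """
    out: List[ExonFeature] = []
    for tid, t in annotation.transcripts.items():
        n = len(t.exons)
        for i, span in enumerate(t.exons):  # transcript order
            if n == 1:
                cls = "single"
            elif i == 0:
                cls = "first"
            elif i == n - 1:
                cls = "last"
            else:
                cls = "internal"
            out.append(ExonFeature(
                exon_id=f"{tid}.E{i + 1}", transcript_id=tid, gene_id=t.gene_id,
                chrom=t.chrom, strand=t.strand, span=span,
                ordinal_class=cls, ordinal=i))
    return out


def splice_sites(annotation: GenomeAnnotation) -> List[Tuple[str, str, str, int]]:
    """All annotated splice sites, deduplicated across isoforms.

    Returns tuples (kind, chrom, strand, position) where kind is ``5ss``
    (first intronic nucleotide) or ``3ss`` (first exonic nucleotide of the
    downstream exon), both in transcript direction.
    """
    sites = set()
    for t in annotation.transcripts.values():
        for (up, down) in zip(t.exons, t.exons[1:]):  # transcript order
            if t.strand == "+":
                sites.add(("5ss", t.chrom, "+", up[1]))
                sites.add(("3ss", t.chrom, "+", down[0]))
            else:
                sites.add(("5ss", t.chrom, "-", up[0] - 1))
                sites.add(("3ss", t.chrom, "-", down[1] - 1))
    return sorted(sites)


def _last_exon(t: TranscriptModel) -> Interval:
    return t.exons[-1]


def enumerate_apa_events(annotation: GenomeAnnotation) -> List[APAEvent]:
    """Tandem-3'UTR and alternative-last-exon events from isoform pairs.

    TandemUTR: the two last exons share their 5' boundary and differ in 3'
    extent (distal_region = the extension of the longer one).  ALE: the two
    isoforms end in non-overlapping last exons.  Isoform pairs must agree on
    all exons upstream of the last; other 3' differences are ignored.
    """
    events: List[APAEvent] = []
    counter: Dict[str, int] = {}
    for gid, tids in annotation.genes.items():
        for a_i in range(len(tids)):
            for b_i in range(a_i + 1, len(tids)):
                ta = annotation.transcripts[tids[a_i]]
                tb = annotation.transcripts[tids[b_i]]
                if ta.strand != tb.strand or ta.chrom != tb.chrom:
                    continue
                if ta.exons[:-1] != tb.exons[:-1]:
                    continue
                la, lb = _last_exon(ta), _last_exon(tb)
                if la == lb:
                    continue
                strand = ta.strand
                kind = None
                if strand == "+" and la[0] == lb[0] and la[1] != lb[1]:
                    kind = "TandemUTR"
                    short, long_ = (ta, tb) if la[1] < lb[1] else (tb, ta)
                    ps, pe = _last_exon(short)
                    proximal = (ps, pe)
                    distal = (pe, _last_exon(long_)[1])
                elif strand == "-" and la[1] == lb[1] and la[0] != lb[0]:
                    kind = "TandemUTR"
                    short, long_ = (ta, tb) if la[0] > lb[0] else (tb, ta)
                    ps, pe = _last_exon(short)
                    proximal = (ps, pe)
                    distal = (_last_exon(long_)[0], ps)
                elif la[1] <= lb[0] or lb[1] <= la[0]:
                    kind = "ALE"
                    # proximal = the last exon closer in transcript direction
                    if strand == "+":
                        prox_t, dist_t = (ta, tb) if la[0] < lb[0] else (tb, ta)
                    else:
                        prox_t, dist_t = (ta, tb) if la[1] > lb[1] else (tb, ta)
                    proximal = _last_exon(prox_t)
                    distal = _last_exon(dist_t)
                    short, long_ = prox_t, dist_t
                if kind is None:
                    continue
                k = counter.get(gid, 0) + 1
                counter[gid] = k
                events.append(APAEvent(
                    event_id=f"{gid}:{kind}:{k}", gene_id=gid, kind=kind,
                    chrom=ta.chrom, strand=strand,
                    proximal_region=proximal, distal_region=distal,
                    isoform_ids=(short.transcript_id, long_.transcript_id)))
    return events
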