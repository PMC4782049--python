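"""Splice-site-anchored metagene profiles and junction-read classification.

Offset sign convention for anchored profiles: negative offsets are the
exonic side of a 5' splice site and the intronic side of a 3' splice site,
i.e. offsets increase in transcript direction through the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import ExonFeature, GenomeAnnotation


@dataclass
class MetaProfile:
    anchor: str                  # 5ss | 3ss | last_exon_scaled
    offsets: np.ndarray          # signed offsets or bin indices
    counts: np.ndarray           # summed event counts (or mass) per offset
    per_million: np.ndarray      # counts scaled to events per million cDNAs
    library: str = ""
    n_anchors: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "count": self.counts,
                             "per_million": self.per_million})


@dataclass
class JunctionCounts:
    library: str
    n_spliced: int
    n_unspliced: int
    n_novel: int = 0

    @property
    def proportion_spliced(self) -> float:
        total = self.n_spliced + self.n_unspliced
        return self.n_spliced / total if total else np.nan


def splice_site_metaprofile(events: pd.DataFrame,
                            sites: Sequence[Tuple[str, str, str, int]],
                            window: int = 300,
                            kind: str = "5ss",
                            library: str = "") -> MetaProfile:
    """Event counts at signed offsets around splice sites of one kind.

    ``sites`` are (kind, chrom, strand, position) tuples as produced by
    :func:`srexport.annotation.splice_sites`.  Counts at offset 0 are events
    on the anchor nucleotide itself.
    """
    use = [s for s in sites if s[0] == kind]
    if not use:
        raise ValueError(f"no {kind} sites supplied")
    width = 2 * window + 1
    acc = np.zeros(width, dtype=float)
    by_cs: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), sub in events.groupby(["chrom", "strand"], sort=True):
        sub = sub.sort_values("position")
        by_cs[(chrom, strand)] = (sub["position"].to_numpy(),
                                  sub["count"].to_numpy())
    for _, chrom, strand, spos in use:
        got = by_cs.get((chrom, strand))
        if got is None:
            continue
        pos, cnt = got
        lo = np.searchsorted(pos, spos - window, side="left")
        hi = np.searchsorted(pos, spos + window, side="right")
        if hi <= lo:
            continue
        off = pos[lo:hi] - spos
        if strand == "-":
            off = -off
        np.add.at(acc, off + window, cnt[lo:hi])
    total = events["count"].sum() if len(events) else 0
    pm = acc * (1e6 / total) if total else np.full(width, np.nan)
    return MetaProfile(anchor=kind, offsets=np.arange(-window, window + 1),
                       counts=acc, per_million=pm, library=library,
                       n_anchors=len(use))


def _read_blocks(blocks: str) -> List[Tuple[int, int]]:
    return [tuple(map(int, b.split("-"))) for b in blocks.split(",")]


def classify_junction_reads(reads: pd.DataFrame,
                            annotation: GenomeAnnotation,
                            min_overhang: int = 3,
                            library: str = "") -> Tuple[JunctionCounts, pd.DataFrame]:
    """Spliced / unspliced classification of reads at annotated 5' splice sites.

    A read is *unspliced* at a 5' splice site if its contiguous alignment
    covers at least ``min_overhang`` nt on both sides of the exon/intron
    boundary; *spliced* if a gap in its alignment matches an annotated
    intron exactly and the read covers at least ``min_overhang`` nt of both
    flanking exons.  Gapped reads whose gap matches no annotated intron are
    counted separately as novel junctions and excluded from the proportion.

    Returns the per-library tally and a per-junction table.
    """
    # annotated introns and the boundary ("cut") coordinate of each 5'ss;
    # cut = half-open coordinate between exon and intron, so the exonic side
    # is [cut - overhang, cut) on plus strand
    introns: Dict[Tuple[str, str, int, int], int] = {}
    cuts: Dict[Tuple[str, str], List[int]] = {}
    for t in annotation.transcripts.values():
        for (istart, iend) in t.introns:
            key = (t.chrom, t.strand, istart, iend)
            if key not in introns:
                cut = istart if t.strand == "+" else iend
                introns[key] = cut
                cuts.setdefault((t.chrom, t.strand), []).append(cut)
    for k in cuts:
        cuts[k] = sorted(set(cuts[k]))

    spliced: Dict[int, int] = {}
    unspliced: Dict[int, int] = {}
    n_spliced = n_unspliced = n_novel = 0

    has_gap = reads["blocks"].str.contains(",", regex=False)
    # contiguous reads: count per 5'ss cut c with start <= c - o and end >= c + o
    contig = reads.loc[~has_gap]
    for (chrom, strand), sub in contig.groupby(["chrom", "strand"], sort=True):
        cut_list = cuts.get((chrom, strand))
        if not cut_list:
            continue
        carr = np.asarray(cut_list)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(carr, starts + min_overhang, side="left")
        hi = np.searchsorted(carr, ends - min_overhang, side="right")
        for j in np.nonzero(hi > lo)[0]:
            for ci in range(lo[j], hi[j]):
                c = int(carr[ci])
                unspliced[c] = unspliced.get(c, 0) + 1
                n_unspliced += 1

    gapped = reads.loc[has_gap]
    for row in gapped.itertuples():
        blocks = _read_blocks(row.blocks)
        ok_any = False
        for (b1, b2) in zip(blocks, blocks[1:]):
            gap = (row.chrom, row.strand, b1[1], b2[0])
            cut = introns.get(gap)
            if cut is None:
                continue
            ok_any = True
            if (b1[1] - b1[0]) >= min_overhang and (b2[1] - b2[0]) >= min_overhang:
                spliced[cut] = spliced.get(cut, 0) + 1
                n_spliced += 1
        if not ok_any:
            n_novel += 1

    per_junction = pd.DataFrame(
        [{"cut": c, "n_spliced": spliced.get(c, 0),
          "n_unspliced": unspliced.get(c, 0)}
         for c in sorted(set(spliced) | set(unspliced))])
    return (JunctionCounts(library=library, n_spliced=n_spliced,
                           n_unspliced=n_unspliced, n_novel=n_novel),
            per_junction)


def last_exon_profile(significant: pd.DataFrame,
                      last_exons: Sequence[ExonFeature],
                      n_bins: int = 100,
                      library: str = "",
                      library_size: Optional[int] = None) -> MetaProfile:
    """Scaled metagene profile over last exons (last 3'ss to the poly(A) end).

    Each exon is scaled to ``n_bins``; every event spreads its count over
    the bins its nucleotide covers (fractional assignment), so total mass
    is conserved for exons shorter than ``n_bins``.
    """
    exons = [x for x in last_exons if x.ordinal_class == "last"]
    if not exons:
        raise ValueError("empty last-exon set")
    acc = np.zeros(n_bins, dtype=float)
    by_cs: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    if len(significant):
        for (chrom, strand), sub in significant.groupby(["chrom", "strand"],
                                                        sort=True):
            sub = sub.sort_values("position")
            by_cs[(chrom, strand)] = (sub["position"].to_numpy(),
                                      sub["count"].to_numpy())
    n_used = 0
    for x in exons:
        got = by_cs.get((x.chrom, x.strand))
        s, e = x.span
        L = e - s
        n_used += 1
        if got is None:
            continue
        pos, cnt = got
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        c = cnt[lo:hi].astype(float)
        rel = (p - s) if x.strand == "+" else (e - 1 - p)
        # nucleotide [rel, rel+1) covers bins [rel*B/L, (rel+1)*B/L)
        b0 = rel * n_bins / L
        b1 = (rel + 1) * n_bins / L
        for bb0, bb1, cc in zip(b0, b1, c):
            i0, i1 = int(np.floor(bb0)), int(np.ceil(bb1))
            for b in range(i0, min(i1, n_bins)):
                frac = (min(b + 1, bb1) - max(b, bb0)) / (bb1 - bb0)
                acc[b] += cc * frac
    total = library_size if library_size is not None else (
        significant["count"].sum() if len(significant) else 0)
    pm = acc * (1e6 / total) if total else np.full(n_bins, np.nan)
    return MetaProfile(anchor="last_exon_scaled", offsets=np.arange(n_bins),
                       counts=acc, per_million=pm, library=library,
                       n_anchors=n_used)
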