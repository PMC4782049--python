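"""Readers and writers for the pipeline's on-disk formats.

Reads travel as BED12 (block-resolved alignments, barcode in the name
field after the last ':') or as BAM/SAM via pysam; cross-link events,
significant positions and binding sites as BED6; coverage as bedGraph;
matrices and tables as TSV.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "blocks"]


# ---------------------------------------------------------------------------
# BED12 reads


def write_reads_bed12(reads: pd.DataFrame, path: str) -> None:
    """Reads (with 'blocks' like 's1-e1,s2-e2') as standard BED12."""
    df = reads.reset_index(drop=True)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    multi = df["blocks"].str.contains(",", regex=False).to_numpy()
    n_blocks = np.ones(len(df), dtype=int)
    sizes = (ends - starts).astype("U12").astype(object)
    offsets = np.zeros(len(df), dtype=int).astype("U1").astype(object)
    for j in np.nonzero(multi)[0]:
        blocks = [tuple(map(int, b.split("-")))
                  for b in df.at[j, "blocks"].split(",")]
        n_blocks[j] = len(blocks)
        sizes[j] = ",".join(str(e - s) for s, e in blocks)
        offsets[j] = ",".join(str(s - starts[j]) for s, _ in blocks)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": starts, "end": ends,
        "name": df["name"], "score": df["score"], "strand": df["strand"],
        "thick_start": starts, "thick_end": ends, "rgb": "0,0,0",
        "n_blocks": n_blocks, "sizes": sizes, "offsets": offsets})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed12(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "thick_start", "thick_end", "rgb",
                            "n_blocks", "sizes", "offsets"],
                     dtype={"chrom": str, "name": str, "sizes": str,
                            "offsets": str})
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    single = (df["n_blocks"] == 1).to_numpy()
    blocks = np.char.add(np.char.add(starts.astype("U12"), "-"),
                         ends.astype("U12")).astype(object)
    for j in np.nonzero(~single)[0]:
        sizes = [int(x) for x in df.at[j, "sizes"].rstrip(",").split(",")]
        offs = [int(x) for x in df.at[j, "offsets"].rstrip(",").split(",")]
        blocks[j] = ",".join(f"{starts[j] + o}-{starts[j] + o + s}"
                             for o, s in zip(offs, sizes))
    out = df[["chrom", "start", "end", "name", "score", "strand"]].copy()
    out["blocks"] = blocks
    return out


# ---------------------------------------------------------------------------
# SAM/BAM


def write_reads_bam(reads: pd.DataFrame, path: str,
                    chrom_lengths: Dict[str, int]) -> None:
    """Single-end alignments with N-CIGAR for spliced reads (SAM or BAM by
    extension)."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()]}
    tids = {c: i for i, c in enumerate(chrom_lengths)}
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as fh:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment()
            a.query_name = row.name
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tids[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 255
            blocks = [tuple(map(int, b.split("-")))
                      for b in row.blocks.split(",")]
            cig = []
            prev_end = None
            for s, e in blocks:
                if prev_end is not None:
                    cig.append((3, s - prev_end))       # N
                cig.append((0, e - s))                  # M
                prev_end = e
            a.cigartuples = cig
            length = sum(e - s for s, e in blocks)
            a.query_sequence = "N" * length
            fh.write(a)


def read_reads_bam(path: str, mapq_min: int = 0) -> pd.DataFrame:
    """Aligned single-end reads from BAM/SAM into the BED12-style frame."""
    rows = []
    with pysam.AlignmentFile(path) as fh:
        for a in fh:
            if a.is_unmapped or a.mapping_quality < mapq_min:
                continue
            blocks = a.get_blocks()
            rows.append({
                "chrom": a.reference_name,
                "start": a.reference_start,
                "end": a.reference_end,
                "name": a.query_name,
                "score": a.mapping_quality,
                "strand": "-" if a.is_reverse else "+",
                "blocks": ",".join(f"{s}-{e}" for s, e in blocks),
            })
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read_reads(path: str, mapq_min: int = 0) -> pd.DataFrame:
    if path.endswith((".bam", ".sam")):
        return read_reads_bam(path, mapq_min=mapq_min)
    return read_reads_bed12(path)


# ---------------------------------------------------------------------------
# BED6 / bedGraph for events, positions and sites


def write_events_bed(events: pd.DataFrame, path: str,
                     name: str = "xl") -> None:
    """Per-position events as BED6 with score = count."""
    out = pd.DataFrame({
        "chrom": events["chrom"], "start": events["position"],
        "end": events["position"] + 1, "name": name,
        "score": events["count"], "strand": events["strand"]})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_events_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "count",
                                "strand"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "strand", "position", "count"])
    return pd.DataFrame({"chrom": df["chrom"], "strand": df["strand"],
                         "position": df["start"], "count": df["count"]})


def write_significant_bed(positions: pd.DataFrame, path: str,
                          cap: float = 10.0) -> None:
    """Significant positions as BED6, score = -log10(FDR) capped."""
    with open(path, "w") as fh:
        for row in positions.itertuples(index=False):
            fdr = max(row.fdr, 10.0 ** -cap)
            score = min(-np.log10(fdr) if fdr > 0 else cap, cap)
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                     f"{row.gene_id}\t{score:.3f}\t{row.strand}\n")


def write_sites_bed(sites: pd.DataFrame, path: str) -> None:
    """Binding sites as BED6; the name field carries protein and center."""
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                     f"{row.protein}|center={row.center}|n={row.n_sig_positions}\t"
                     f"{row.total_count}\t{row.strand}\n")


SITE_COLUMNS = ["chrom", "strand", "start", "end", "center", "total_count",
                "n_sig_positions", "protein"]


def read_sites_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name",
                                "total_count", "strand"],
                         dtype={"chrom": str, "name": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if len(df) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)
    parts = df["name"].str.split("|", expand=True)
    protein = parts[0]
    center = parts[1].str.replace("center=", "", regex=False).astype(int)
    npos = parts[2].str.replace("n=", "", regex=False).astype(int)
    return pd.DataFrame({"chrom": df["chrom"], "strand": df["strand"],
                         "start": df["start"], "end": df["end"],
                         "center": center, "total_count": df["total_count"],
                         "n_sig_positions": npos, "protein": protein})


def write_bedgraph(events: pd.DataFrame, path: str, strand: str = "+") -> None:
    sub = events[events["strand"] == strand].sort_values(["chrom", "position"])
    out = pd.DataFrame({"chrom": sub["chrom"], "start": sub["position"],
                        "end": sub["position"] + 1, "value": sub["count"]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV matrices


def write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_count_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "fraction", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet
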