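"""From iCLIP reads to cross-link events, significant positions and binding sites.

The cross-linked nucleotide is inferred one nucleotide 5' of the read start
(truncation geometry).  Significance is assessed per gene against a
permutation null that redistributes the gene's total cDNA count uniformly
over the gene's positions; the false discovery rate at count height h is
the permutation-expected number of positions reaching h divided by the
observed number, made monotone non-increasing in h before thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

log = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "blocks"]


@dataclass
class DedupStats:
    n_reads: int = 0
    n_unique: int = 0
    n_missing_barcode: int = 0

    @property
    def n_duplicates(self) -> int:
        return self.n_reads - self.n_missing_barcode - self.n_unique


def _barcode_of(name: str) -> str:
    """Random barcode = suffix after the last ':' of the read name."""
    _, sep, bc = name.rpartition(":")
    return bc if sep else ""


def deduplicate(reads: pd.DataFrame) -> Tuple[pd.DataFrame, DedupStats]:
    """Collapse reads to unique cDNAs keyed by (chrom, strand, start, barcode).

    The 'start' key is the read 5' end: `start` for plus-strand reads,
    `end` for minus-strand reads.  Reads without a barcode are dropped and
    counted.
    """
    stats = DedupStats(n_reads=len(reads))
    if len(reads) == 0:
        return reads.copy(), stats
    bc = reads["name"].map(_barcode_of)
    missing = bc == ""
    stats.n_missing_barcode = int(missing.sum())
    df = reads.loc[~missing].copy()
    df["barcode"] = bc[~missing]
    key5 = np.where(df["strand"].to_numpy() == "+",
                    df["start"].to_numpy(), df["end"].to_numpy())
    df["_key5"] = key5
    unique = df.drop_duplicates(subset=["chrom", "strand", "_key5", "barcode"])
    stats.n_unique = len(unique)
    return unique.drop(columns=["_key5"]).reset_index(drop=True), stats


def extract_crosslinks(unique: pd.DataFrame) -> pd.DataFrame:
    """Per-position unique-cDNA counts at inferred cross-link sites.

    Plus strand: position = read start - 1; minus strand: position = read
    end (the base immediately 5' of the read on its own strand).  Events
    shifted below zero are dropped and counted in the log.
    """
    if len(unique) == 0:
        return pd.DataFrame(columns=["chrom", "strand", "position", "count"])
    pos = np.where(unique["strand"].to_numpy() == "+",
                   unique["start"].to_numpy() - 1,
                   unique["end"].to_numpy())
    df = pd.DataFrame({
        "chrom": unique["chrom"].to_numpy(),
        "strand": unique["strand"].to_numpy(),
        "position": pos,
    })
    n_neg = int((df["position"] < 0).sum())
    if n_neg:
        log.warning("dropped %d events shifted below position 0", n_neg)
        df = df[df["position"] >= 0]
    out = (df.groupby(["chrom", "strand", "position"], sort=True)
             .size().rename("count").reset_index())
    return out


@dataclass
class SignificanceResult:
    positions: pd.DataFrame          # chrom,strand,position,count,gene_id,fdr
    skipped_genes: List[str] = field(default_factory=list)
    n_intergenic: int = 0

    @property
    def significant(self) -> pd.DataFrame:
        return self.positions[self.positions["significant"]]


def _gene_fdr(counts: np.ndarray, gene_len: int, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """Per-position FDR for one gene.

    counts: observed per-position cDNA counts (positions with >= 1 cDNA).
    Permutations drop the gene's total count uniformly over gene_len
    positions; FDR(h) = E_perm[#positions >= h] / obs[#positions >= h],
    clipped to [0, 1] and made monotone non-increasing in h.
    """
    total = int(counts.sum())
    hmax = int(counts.max())
    # permutation tail counts, all permutations in one draw
    draws = rng.integers(0, gene_len, size=(n_perm, total))
    offset = (np.arange(n_perm) * gene_len)[:, None]
    flat = (draws + offset).ravel()
    per_pos = np.bincount(flat, minlength=n_perm * gene_len)
    height_hist = np.bincount(per_pos[per_pos > 0])
    # extend to hmax
    if len(height_hist) < hmax + 2:
        height_hist = np.pad(height_hist, (0, hmax + 2 - len(height_hist)))
    exp_tail = np.cumsum(height_hist[::-1])[::-1] / n_perm   # E[#pos >= h]
    obs_hist = np.bincount(counts, minlength=hmax + 2)
    obs_tail = np.cumsum(obs_hist[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_h = np.where(obs_tail > 0, exp_tail[:len(obs_tail)] / obs_tail, np.nan)
    fdr_h = np.minimum(fdr_h, 1.0)
    # monotone non-increasing in h: a taller height can never be less
    # significant than a lower one
    for h in range(2, len(fdr_h)):
        if not np.isnan(fdr_h[h]) and not np.isnan(fdr_h[h - 1]):
            fdr_h[h] = min(fdr_h[h], fdr_h[h - 1])
    return fdr_h[counts]


def call_significant_positions(
        events: pd.DataFrame, annotation: GenomeAnnotation,
        fdr_threshold: float = 0.05, n_perm: int = 100, seed: int = 0,
        min_events: int = 10) -> SignificanceResult:
    """Permutation-FDR significant cross-link positions, gene by gene.

    Events are assigned to genes strand-specifically over the pre-mRNA span
    (exons + introns); same-strand overlaps go to the gene with the longer
    span.  Genes with fewer than ``min_events`` events are skipped; events
    outside any gene are reported as intergenic and left untested.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if len(events) == 0:
        empty = events.assign(gene_id=None, fdr=np.nan, significant=False)
        return SignificanceResult(positions=empty)
    ev = events.reset_index(drop=True).copy()
    gene_ids = np.full(len(ev), None, dtype=object)
    for (chrom, strand), sub in ev.groupby(["chrom", "strand"], sort=True):
        gene_ids[sub.index.to_numpy()] = annotation.assign_genes(
            chrom, strand, sub["position"].to_numpy())
    ev["gene_id"] = gene_ids
    n_intergenic = int(pd.isna(ev["gene_id"]).sum())
    ev["fdr"] = np.nan
    ev["significant"] = False

    rng = np.random.default_rng(seed)
    skipped: List[str] = []
    gene_span_len = {g: annotation.gene_span(g)[3] - annotation.gene_span(g)[2]
                     for g in annotation.genes}
    tested = ev.dropna(subset=["gene_id"])
    for gid, sub in tested.groupby("gene_id", sort=True):
        counts = sub["count"].to_numpy()
        if counts.sum() < min_events:
            skipped.append(gid)
            continue
        fdr = _gene_fdr(counts.astype(int), gene_span_len[gid], n_perm, rng)
        ev.loc[sub.index, "fdr"] = fdr
        ev.loc[sub.index, "significant"] = fdr < fdr_threshold
    if skipped:
        log.info("skipped %d genes with < %d events", len(skipped), min_events)
    return SignificanceResult(positions=ev, skipped_genes=skipped,
                              n_intergenic=n_intergenic)


def merge_binding_sites(significant: pd.DataFrame, max_gap: int = 15,
                        protein: str = "") -> pd.DataFrame:
    """Merge significant positions <= max_gap apart into binding sites.

    The site center is the position of maximal count; ties break to the
    5'-most position on the site's strand.  Returns a DataFrame with
    chrom, strand, start, end (half-open), center, total_count,
    n_sig_positions, protein.
    """
    rows = []
    if len(significant):
        for (chrom, strand), sub in significant.groupby(["chrom", "strand"],
                                                        sort=True):
            sub = sub.sort_values("position")
            pos = sub["position"].to_numpy()
            cnt = sub["count"].to_numpy()
            breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
            for seg_pos, seg_cnt in zip(np.split(pos, breaks),
                                        np.split(cnt, breaks)):
                best = seg_cnt.max()
                cand = seg_pos[seg_cnt == best]
                center = cand.min() if strand == "+" else cand.max()
                rows.append({
                    "chrom": chrom, "strand": strand,
                    "start": int(seg_pos.min()), "end": int(seg_pos.max()) + 1,
                    "center": int(center), "total_count": int(seg_cnt.sum()),
                    "n_sig_positions": int(len(seg_pos)), "protein": protein})
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                       "center", "total_count",
                                       "n_sig_positions", "protein"])


def events_per_million(events: pd.DataFrame) -> float:
    """Library-size normalisation factor: unique cDNAs per million."""
    total = events["count"].sum() if len(events) else 0
    return 1e6 / total if total else np.nan
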