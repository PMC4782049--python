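"""Region-stratified k-mer enrichment around significant cross-link positions.

Observed windows are strand-oriented sequences centered on significant
positions; the background re-places the same number of windows uniformly at
random within the same region intervals, ``n_rand`` times.  Enrichment per
k-mer is the z-score of the observed occurrence count against the
background mean and standard deviation.  All sequence handling is in the
DNA alphabet; motifs can be printed in RNA (U for T) on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, RegionSet
from .simulate import revcomp

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

REGION_FILTERS = {
    "all": ("five_prime_utr", "cds", "three_prime_utr", "noncoding_exon"),
    "5utr": ("five_prime_utr",),
    "3utr": ("three_prime_utr",),
}


@dataclass
class RegionWindows:
    """Extracted windows plus the interval universe they came from."""

    sequences: List[str]                   # oriented, length 2*flank+1
    intervals: List[Tuple[str, str, int, int]]   # (chrom, strand, start, end)
    interval_seqs: List[str]               # oriented sequence per interval
    flank: int
    region: str
    n_discarded: int = 0


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def extract_windows(significant: pd.DataFrame, regions: RegionSet,
                    annotation: GenomeAnnotation,
                    genome: Dict[str, str],
                    region_filter: str = "all",
                    flank: int = 20) -> RegionWindows:
    """Strand-oriented sequence windows around significant positions.

    Windows of length ``2*flank+1`` centered on each position, reverse
    complemented on the minus strand.  Windows that would cross the edge of
    the region interval containing their center are discarded and counted,
    which keeps observed and background windows in the same sequence space.
    """
    if region_filter not in REGION_FILTERS:
        raise ValueError(f"unknown region filter {region_filter!r}")
    labels = REGION_FILTERS[region_filter]
    # collect region intervals per (chrom,strand)
    ivs: List[Tuple[str, str, int, int]] = []
    for gid, per_gene in regions.intervals.items():
        chrom, strand, _, _ = annotation.gene_span(gid)
        for label in labels:
            for s, e in per_gene.get(label, []):
                if e - s >= 2 * flank + 1:
                    ivs.append((chrom, strand, s, e))
    ivs.sort()
    interval_seqs = [_oriented(genome[c][s:e], st) for c, st, s, e in ivs]
    by_cs: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for idx, (c, st, s, e) in enumerate(ivs):
        by_cs.setdefault((c, st), ([], [], []))
        by_cs[(c, st)][0].append(s)
        by_cs[(c, st)][1].append(e)
        by_cs[(c, st)][2].append(idx)
    for key in by_cs:
        a, b, i = by_cs[key]
        by_cs[key] = (np.array(a), np.array(b), np.array(i))

    windows: List[str] = []
    n_discarded = 0
    if len(significant):
        for (chrom, strand), sub in significant.groupby(["chrom", "strand"],
                                                        sort=True):
            got = by_cs.get((chrom, strand))
            if got is None:
                continue
            starts, ends, idxs = got
            p = sub["position"].to_numpy()
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            for j in np.nonzero(ok)[0]:
                s, e = starts[i[j]], ends[i[j]]
                pos = p[j]
                if pos - flank < s or pos + flank + 1 > e:
                    n_discarded += 1
                    continue
                iv_idx = idxs[i[j]]
                seq = interval_seqs[iv_idx]
                off = (pos - s) if strand == "+" else (e - 1 - pos)
                windows.append(seq[off - flank:off + flank + 1])
    return RegionWindows(sequences=windows, intervals=ivs,
                         interval_seqs=interval_seqs, flank=flank,
                         region=region_filter, n_discarded=n_discarded)


def _count_kmers(seqs: Sequence[str], k: int) -> np.ndarray:
    """Occurrence counts over all 4^k k-mers (ambiguous frames skipped)."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    if not seqs:
        return counts
    mult = 4 ** np.arange(k - 1, -1, -1)
    for s in seqs:
        codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
        n = len(codes) - k + 1
        if n <= 0:
            continue
        window = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (window >= 0).all(axis=1)
        ids = (window[valid] * mult).sum(axis=1)
        np.add.at(counts, ids, 1)
    return counts


def _decode(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


@dataclass
class KmerTable:
    table: pd.DataFrame       # kmer, observed, bg_mean, bg_sd, z
    region: str
    library: str
    params: dict = field(default_factory=dict)


def kmer_enrichment(windows: RegionWindows, k: int = 8, n_rand: int = 100,
                    seed: int = 0, library: str = "",
                    min_windows: int = 100) -> KmerTable:
    """k-mer z-scores of observed windows against randomized placement.

    Background: ``len(windows)`` windows placed uniformly at random within
    the same region intervals, repeated ``n_rand`` times;
    z = (observed - bg_mean) / sqrt(bg_sd^2 + bg_mean + 1), the +1
    regularizing the sparse-count regime (see inline note).
    """
    if n_rand < 10:
        raise ValueError("n_rand < 10 gives unstable background sd; refused")
    W = len(windows.sequences)
    if W < min_windows:
        raise ValueError(f"need >= {min_windows} windows, got {W}")
    flank = windows.flank
    width = 2 * flank + 1
    obs = _count_kmers(windows.sequences, k)

    # valid center offsets per interval: [flank, len - flank)
    lens = np.array([len(s) for s in windows.interval_seqs])
    n_centers = lens - 2 * flank
    n_centers = np.maximum(n_centers, 0)
    cum = np.concatenate([[0], np.cumsum(n_centers)])
    total = cum[-1]
    if total == 0:
        raise ValueError("no valid background positions")
    rng = np.random.default_rng(seed)
    bg_sum = np.zeros(4 ** k)
    bg_sumsq = np.zeros(4 ** k)
    for _ in range(n_rand):
        draws = rng.integers(0, total, size=W)
        iv = np.searchsorted(cum, draws, side="right") - 1
        off = draws - cum[iv] + flank
        seqs = [windows.interval_seqs[i][o - flank:o + flank + 1]
                for i, o in zip(iv, off)]
        c = _count_kmers(seqs, k)
        bg_sum += c
        bg_sumsq += c * c
    mean = bg_sum / n_rand
    var = bg_sumsq / n_rand - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    # regularized denominator: the empirical background sd plus the Poisson
    # scale of the count itself (+1). Without it, a k-mer observed once
    # against a background mean of ~1/n_rand would get an arbitrarily large
    # z from discreteness alone; with it, z stays ~N(0,1) under the null
    # and is essentially unchanged for well-sampled k-mers.
    z = (obs - mean) / np.sqrt(sd ** 2 + mean + 1.0)
    keep = (obs > 0) | (mean > 0)
    idx = np.nonzero(keep)[0]
    df = pd.DataFrame({
        "kmer": [_decode(i, k) for i in idx],
        "observed": obs[idx],
        "bg_mean": mean[idx],
        "bg_sd": sd[idx],
        "z": z[idx],
    })
    df = df.sort_values(["z", "kmer"], ascending=[False, True],
                        na_position="last").reset_index(drop=True)
    return KmerTable(table=df, region=windows.region, library=library,
                     params={"k": k, "flank": flank, "n_rand": n_rand,
                             "seed": seed, "n_windows": W,
                             "n_discarded": windows.n_discarded})


def consensus_string(kmers: Sequence[str], min_major: float = 0.5,
                     min_incl: float = 0.25) -> str:
    """Ungapped majority consensus: per column, the base reaching
    ``min_major``, else the IUPAC letter for bases above ``min_incl``."""
    if not kmers:
        return ""
    k = len(kmers[0])
    out = []
    for i in range(k):
        col = [m[i] for m in kmers]
        freqs = {b: col.count(b) / len(col) for b in "ACGT"}
        best = max(freqs, key=freqs.get)
        if freqs[best] >= min_major:
            out.append(best)
        else:
            incl = frozenset(b for b, f in freqs.items() if f >= min_incl)
            out.append(IUPAC.get(incl or frozenset("ACGT"), "N"))
    return "".join(out)


def top_motifs(table: KmerTable, n: int = 10, rna: bool = False
               ) -> Tuple[pd.DataFrame, str]:
    """Top-n k-mers by z (ties broken lexicographically) and their consensus."""
    df = table.table.dropna(subset=["z"]).head(n).copy()
    consensus = consensus_string(list(df["kmer"]))
    if rna:
        df["kmer"] = df["kmer"].str.replace("T", "U")
        consensus = consensus.replace("T", "U")
    return df.reset_index(drop=True), consensus
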