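"""Cobinding of SR-protein cross-link sites around NXF1 binding-site centers.

An SR library "cobinds" an NXF1 site when it has at least ``min_sites``
(default 4, i.e. "more than three") distinct significant cross-link
positions within +/- ``half_window`` nt of the site center on the same
strand.  Ratios are reported per stratum: sites whose center lies in a
first exon, in a last exon, or all sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import ExonFeature

STRATA = ("first_exon", "last_exon", "all")


def _exon_stratum_index(exons: Sequence[ExonFeature]):
    per_cs: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for x in exons:
        if x.ordinal_class in ("first", "last"):
            per_cs.setdefault((x.chrom, x.strand), []).append(
                (x.span[0], x.span[1], x.ordinal_class))
    out = {}
    for key, ivs in per_cs.items():
        ivs.sort()
        out[key] = (np.array([s for s, _, _ in ivs]),
                    np.array([e for _, e, _ in ivs]),
                    [c for _, _, c in ivs])
    return out


def assign_strata(sites: pd.DataFrame,
                  exons: Sequence[ExonFeature]) -> pd.Series:
    """Stratum of each NXF1 site by its center: first_exon, last_exon or other.

    A site whose window crosses an exon boundary stays in the stratum of its
    center.
    """
    idx = _exon_stratum_index(exons)
    out = np.full(len(sites), "other", dtype=object)
    sites = sites.reset_index(drop=True)
    for (chrom, strand), sub in sites.groupby(["chrom", "strand"], sort=True):
        got = idx.get((chrom, strand))
        if got is None:
            continue
        starts, ends, classes = got
        c = sub["center"].to_numpy()
        i = np.searchsorted(starts, c, side="right") - 1
        ok = (i >= 0) & (c < ends[np.clip(i, 0, len(ends) - 1)])
        for j in np.nonzero(ok)[0]:
            out[sub.index.to_numpy()[j]] = classes[i[j]] + "_exon"
    return pd.Series(out, index=sites.index, name="stratum")


def _window_counts(centers: pd.DataFrame, positions: pd.DataFrame,
                   half_window: int) -> np.ndarray:
    """Distinct significant positions of one library within the inclusive
    window [center - half_window, center + half_window] of each site."""
    counts = np.zeros(len(centers), dtype=int)
    centers = centers.reset_index(drop=True)
    by_cs = {}
    for (chrom, strand), sub in positions.groupby(["chrom", "strand"],
                                                  sort=True):
        by_cs[(chrom, strand)] = np.sort(sub["position"].to_numpy())
    for (chrom, strand), sub in centers.groupby(["chrom", "strand"],
                                                sort=True):
        pos = by_cs.get((chrom, strand))
        if pos is None:
            continue
        c = sub["center"].to_numpy()
        lo = np.searchsorted(pos, c - half_window, side="left")
        hi = np.searchsorted(pos, c + half_window, side="right")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


@dataclass
class CobindingResult:
    ratios: pd.DataFrame        # stratum x library -> n_cobound, ratio
    n_sites: Dict[str, int]     # stratum -> total NXF1 sites
    cobind_matrix: pd.DataFrame  # site x library boolean
    strata: pd.Series           # per-site stratum
    half_window: int = 30
    min_sites: int = 4


def cobinding_ratio(nxf1_sites: pd.DataFrame,
                    sr_positions: Dict[str, pd.DataFrame],
                    exons: Sequence[ExonFeature],
                    half_window: int = 30,
                    min_sites: int = 4) -> CobindingResult:
    """Per-stratum cobinding ratios of each SR library at NXF1 sites.

    ``sr_positions`` maps library name to its significant positions.
    The window is inclusive at both ends (61 positions for half_window 30).
    Strata with zero NXF1 sites get NaN ratios.
    """
    sites = nxf1_sites.reset_index(drop=True)
    strata = assign_strata(sites, exons)
    cob = pd.DataFrame(index=sites.index, columns=sorted(sr_positions),
                       dtype=bool)
    for lib, pos in sr_positions.items():
        cob[lib] = _window_counts(sites, pos, half_window) >= min_sites
    rows = []
    n_sites = {}
    for stratum in STRATA:
        mask = np.ones(len(sites), dtype=bool) if stratum == "all" else \
            (strata == stratum).to_numpy()
        n = int(mask.sum())
        n_sites[stratum] = n
        for lib in cob.columns:
            n_cob = int(cob.loc[mask, lib].sum())
            rows.append({"stratum": stratum, "library": lib,
                         "n_cobound": n_cob, "n_sites": n,
                         "ratio": n_cob / n if n else np.nan})
    return CobindingResult(ratios=pd.DataFrame(rows), n_sites=n_sites,
                           cobind_matrix=cob, strata=strata,
                           half_window=half_window, min_sites=min_sites)


def exclusive_cobinding(result: CobindingResult) -> pd.DataFrame:
    """NXF1 sites where exactly one SR library cobinds, per stratum.

    Returns stratum x library counts of exclusively cobound sites.
    """
    cob = result.cobind_matrix
    n_cobinders = cob.sum(axis=1)
    exclusive = cob.loc[n_cobinders == 1]
    rows = []
    for stratum in STRATA:
        mask = np.ones(len(cob), dtype=bool) if stratum == "all" else \
            (result.strata == stratum).to_numpy()
        sel = exclusive.loc[exclusive.index.isin(np.nonzero(mask)[0])]
        for lib in cob.columns:
            rows.append({"stratum": stratum, "library": lib,
                         "n_exclusive": int(sel[lib].sum())})
    return pd.DataFrame(rows)


def pairwise_cobinding(result: CobindingResult,
                       stratum: str = "all") -> pd.DataFrame:
    """Symmetric SR-pair co-occurrence counts at NXF1 sites.

    Off-diagonal [i, j]: sites where libraries i and j both cobind.
    Diagonal [i, i]: sites where library i is the sole cobinder.
    """
    cob = result.cobind_matrix
    if stratum != "all":
        mask = (result.strata == stratum).to_numpy()
        cob = cob.loc[np.nonzero(mask)[0]]
    libs = list(cob.columns)
    arr = cob.to_numpy().astype(int)
    mat = arr.T @ arr
    solo = arr[arr.sum(axis=1) == 1]
    np.fill_diagonal(mat, solo.sum(axis=0))
    return pd.DataFrame(mat, index=libs, columns=libs)
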