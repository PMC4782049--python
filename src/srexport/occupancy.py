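"""Region occupancy, exon cobinding and protein clustering statistics.

Densities are significant cross-link events per nucleotide of a region
label, scaled to events per million unique cDNAs so libraries of different
depth are comparable.  Exon-level matrices use the exons of the
representative transcript per gene (one disjoint tiling of each gene), so
no event is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats as sps

from .annotation import ExonFeature, GenomeAnnotation, RegionSet


# ---------------------------------------------------------------------------
# interval label lookup


class _LabelIndex:
    """Flattened (chrom,strand) -> sorted disjoint labeled intervals."""

    def __init__(self, regions: RegionSet, annotation: GenomeAnnotation):
        per_cs: Dict[Tuple[str, str], List[Tuple[int, int, str, str]]] = {}
        for gid, per_gene in regions.intervals.items():
            chrom, strand, _, _ = annotation.gene_span(gid)
            for label, ivs in per_gene.items():
                for s, e in ivs:
                    per_cs.setdefault((chrom, strand), []).append((s, e, label, gid))
        self._idx = {}
        for key, ivs in per_cs.items():
            ivs.sort()
            self._idx[key] = (
                np.array([s for s, *_ in ivs]),
                np.array([e for _, e, *_ in ivs]),
                [lab for *_, lab, _ in ivs],
                [g for *_, g in ivs],
            )

    def lookup(self, chrom: str, strand: str, positions: np.ndarray
               ) -> Tuple[List[Optional[str]], List[Optional[str]]]:
        got = self._idx.get((chrom, strand))
        labels: List[Optional[str]] = [None] * len(positions)
        genes: List[Optional[str]] = [None] * len(positions)
        if got is None:
            return labels, genes
        starts, ends, labs, gids = got
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < ends[np.clip(i, 0, len(ends) - 1)])
        for j in np.nonzero(ok)[0]:
            labels[j] = labs[i[j]]
            genes[j] = gids[i[j]]
        return labels, genes


def assign_region_labels(events: pd.DataFrame, regions: RegionSet,
                         annotation: GenomeAnnotation) -> pd.DataFrame:
    """Events with 'label' and 'region_gene' columns (None = unassigned)."""
    ev = events.reset_index(drop=True).copy()
    idx = _LabelIndex(regions, annotation)
    labels = np.full(len(ev), None, dtype=object)
    genes = np.full(len(ev), None, dtype=object)
    for (chrom, strand), sub in ev.groupby(["chrom", "strand"], sort=True):
        lab, gid = idx.lookup(chrom, strand, sub["position"].to_numpy())
        labels[sub.index.to_numpy()] = lab
        genes[sub.index.to_numpy()] = gid
    ev["label"] = labels
    ev["region_gene"] = genes
    return ev


def region_density(events_by_library: Dict[str, pd.DataFrame],
                   regions: RegionSet,
                   annotation: GenomeAnnotation,
                   library_sizes: Optional[Dict[str, int]] = None
                   ) -> pd.DataFrame:
    """Significant events per nucleotide of each region label, per library,
    scaled to events per million unique cDNAs.

    Each event lands in exactly one label of the representative transcript
    of its gene; events outside any labeled region count as 'unassigned'.
    Returns a tidy frame: library, label, n_events, length, density,
    density_per_million.
    """
    lengths = regions.total_lengths()
    rows = []
    for lib, ev in events_by_library.items():
        labeled = assign_region_labels(ev, regions, annotation)
        size = (library_sizes or {}).get(lib) or ev["count"].sum()
        tally = (labeled.assign(label=labeled["label"].fillna("unassigned"))
                 .groupby("label")["count"].sum())
        for label, n in tally.items():
            L = lengths.get(label, np.nan)
            dens = n / L if L and not np.isnan(L) else np.nan
            rows.append({"library": lib, "label": label, "n_events": int(n),
                         "length": L, "density": dens,
                         "density_per_million": dens * 1e6 / size
                         if size and not np.isnan(dens) else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exon binding matrix


@dataclass
class ExonBindingMatrix:
    counts: pd.DataFrame     # exons x libraries, raw significant counts
    cpm: pd.DataFrame        # per-million normalised
    n_positions: pd.DataFrame  # distinct significant positions per exon
    meta: pd.DataFrame       # exon_id -> ordinal_class, length, gene_id


def exon_binding_matrix(positions_by_library: Dict[str, pd.DataFrame],
                        exons: Sequence[ExonFeature],
                        library_sizes: Optional[Dict[str, int]] = None
                        ) -> ExonBindingMatrix:
    """Per-exon summed significant cross-link counts per library.

    ``positions_by_library`` holds significant positions (chrom, strand,
    position, count).  Normalisation is per million unique cDNAs of the
    library (falling back to the sum of significant counts).
    """
    ex_sorted: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List[str]]] = {}
    per_cs: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for x in exons:
        per_cs.setdefault((x.chrom, x.strand), []).append(
            (x.span[0], x.span[1], x.exon_id))
    for key, ivs in per_cs.items():
        ivs.sort()
        ex_sorted[key] = (np.array([s for s, _, _ in ivs]),
                          np.array([e for _, e, _ in ivs]),
                          [i for _, _, i in ivs])
    exon_ids = [x.exon_id for x in exons]
    counts = pd.DataFrame(0.0, index=pd.Index(exon_ids, name="exon_id"),
                          columns=sorted(positions_by_library))
    npos = counts.copy()
    for lib, pos_df in positions_by_library.items():
        for (chrom, strand), sub in pos_df.groupby(["chrom", "strand"],
                                                   sort=True):
            got = ex_sorted.get((chrom, strand))
            if got is None:
                continue
            starts, ends, ids = got
            p = sub["position"].to_numpy()
            c = sub["count"].to_numpy()
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            for j in np.nonzero(ok)[0]:
                counts.loc[ids[i[j]], lib] += c[j]
                npos.loc[ids[i[j]], lib] += 1
    sizes = {lib: (library_sizes or {}).get(lib)
             or positions_by_library[lib]["count"].sum()
             for lib in positions_by_library}
    cpm = counts.copy()
    for lib in cpm.columns:
        s = sizes[lib]
        cpm[lib] = cpm[lib] * 1e6 / s if s else np.nan
    meta = pd.DataFrame(
        [{"exon_id": x.exon_id, "gene_id": x.gene_id,
          "ordinal_class": x.ordinal_class, "length": x.span[1] - x.span[0]}
         for x in exons]).set_index("exon_id")
    return ExonBindingMatrix(counts=counts, cpm=cpm, n_positions=npos, meta=meta)


def cobound_exon_fraction(matrix: ExonBindingMatrix,
                          sr_libraries: Sequence[str],
                          bound_threshold: int = 1) -> pd.Series:
    """Per SR library: of its bound exons, the fraction also bound by at
    least one *other* SR library.

    'Bound' means >= ``bound_threshold`` significant positions.  Libraries
    outside ``sr_libraries`` (the receptor, controls) are ignored.
    Libraries with zero bound exons get NaN.
    """
    bound = matrix.n_positions[list(sr_libraries)] >= bound_threshold
    out = {}
    for lib in sr_libraries:
        mine = bound[lib]
        if mine.sum() == 0:
            out[lib] = np.nan
            continue
        others = bound.drop(columns=[lib]).any(axis=1)
        out[lib] = float((mine & others).sum() / mine.sum())
    return pd.Series(out, name="cobound_fraction")


# ---------------------------------------------------------------------------
# correlation clustering


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Szekely-Rizzo distance correlation (biased sample version, O(n^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return np.nan
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


@dataclass
class ClusteringResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    leaves: List[str]
    method: str
    dropped: List[str] = field(default_factory=list)

    def newick(self) -> str:
        """Linkage tree as a Newick string with merge heights as branch lengths."""
        n = len(self.leaves_order_names)
        labels = self.leaves_order_names

        def build(node_id: int, parent_h: float) -> str:
            if node_id < n:
                return f"{labels[node_id]}:{parent_h:.6g}"
            row = self.linkage[node_id - n]
            h = row[2]
            left = build(int(row[0]), h)
            right = build(int(row[1]), h)
            return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

        if n == 1:
            return f"{labels[0]};"
        root_h = self.linkage[-1][2]
        row = self.linkage[-1]
        left = build(int(row[0]), root_h)
        right = build(int(row[1]), root_h)
        return f"({left},{right});"

    @property
    def leaves_order_names(self) -> List[str]:
        return list(self.correlation.columns)


def correlation_clustering(matrix: pd.DataFrame,
                           method: str = "spearman",
                           log_scale: bool = False,
                           max_features: int = 5000,
                           seed: int = 0) -> ClusteringResult:
    """Average-linkage clustering of libraries on 1 - correlation over exons.

    ``method`` is 'spearman' (rank correlation, scale-free) or
    'distance_correlation' (computed on a seeded subsample of at most
    ``max_features`` exons for O(n^2) tractability).  Constant columns are
    reported and excluded from the tree.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 libraries to cluster")
    data = np.log1p(matrix) if log_scale else matrix.copy()
    dropped = [c for c in data.columns if data[c].nunique() <= 1]
    data = data.drop(columns=dropped)
    cols = list(data.columns)
    k = len(cols)
    if k < 2:
        raise ValueError("fewer than 2 non-constant libraries")
    if method == "spearman":
        corr, _ = sps.spearmanr(data.to_numpy())
        if k == 2:  # scipy returns a scalar for two columns
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    elif method == "distance_correlation":
        arr = data.to_numpy()
        if arr.shape[0] > max_features:
            rng = np.random.default_rng(seed)
            sel = rng.choice(arr.shape[0], size=max_features, replace=False)
            arr = arr[np.sort(sel)]
        corr = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                corr[i, j] = corr[j, i] = distance_correlation(arr[:, i], arr[:, j])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    cdf = pd.DataFrame(corr, index=cols, columns=cols)
    dissim = 1.0 - cdf.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2, 0.0, None)
    condensed = dissim[np.triu_indices(k, 1)]
    linkage = sch.linkage(condensed, method="average")
    leaves = [cols[i] for i in sch.leaves_list(linkage)]
    return ClusteringResult(correlation=cdf, linkage=linkage, leaves=leaves,
                            method=method, dropped=dropped)


def sister_pairs(result: ClusteringResult) -> List[Tuple[str, str]]:
    """Leaf pairs that merge directly (cherries of the tree)."""
    n = len(result.leaves_order_names)
    names = result.leaves_order_names
    out = []
    for row in result.linkage:
        a, b = int(row[0]), int(row[1])
        if a < n and b < n:
            out.append(tuple(sorted((names[a], names[b]))))
    return out


# ---------------------------------------------------------------------------
# per-transcript site statistics and 3'UTR lengths


def sites_per_transcript(sites: pd.DataFrame, regions: RegionSet,
                         annotation: GenomeAnnotation) -> Tuple[pd.Series, pd.DataFrame]:
    """Distribution of binding-site counts per mRNA and site region placement.

    Sites are assigned by their center to the representative transcript's
    labeled regions.  Returns (histogram of sites/transcript including the
    zero bucket, cross-tab of region labels).
    """
    idx = _LabelIndex(regions, annotation)
    rows = []
    for (chrom, strand), sub in sites.groupby(["chrom", "strand"], sort=True):
        lab, gid = idx.lookup(chrom, strand, sub["center"].to_numpy())
        for l_, g_ in zip(lab, gid):
            rows.append({"gene_id": g_, "label": l_ or "unassigned"})
    per_site = pd.DataFrame(rows, columns=["gene_id", "label"])
    counts = per_site.dropna(subset=["gene_id"]).groupby("gene_id").size()
    all_genes = pd.Series(0, index=pd.Index(sorted(regions.representative),
                                            name="gene_id"))
    all_genes.update(counts)
    hist = all_genes.value_counts().sort_index()
    hist.index.name = "n_sites"
    crosstab = per_site.groupby("label").size().rename("n_sites").to_frame()
    return hist, crosstab


def utr3_length_stats(transcript_sets: Dict[str, Sequence[str]],
                      annotation: GenomeAnnotation
                      ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """3'UTR length distributions per transcript set + pairwise rank-sum tests.

    Transcripts without an annotated 3'UTR (no CDS, or CDS reaching the
    transcript end) are excluded and counted.
    """
    lengths: Dict[str, np.ndarray] = {}
    summary_rows = []
    for name, tids in transcript_sets.items():
        vals = []
        n_excluded = 0
        for tid in tids:
            t = annotation.transcripts.get(tid)
            if t is None or t.cds is None:
                n_excluded += 1
                continue
            cs, ce = t.cds
            if t.strand == "+":
                utr = sum(max(0, e - max(s, ce)) for s, e in t.genomic_exons)
            else:
                utr = sum(max(0, min(e, cs) - s) for s, e in t.genomic_exons)
            if utr <= 0:
                n_excluded += 1
                continue
            vals.append(utr)
        lengths[name] = np.asarray(vals)
        summary_rows.append({"set": name, "n": len(vals),
                             "n_excluded": n_excluded,
                             "median": float(np.median(vals)) if vals else np.nan})
    tests = []
    names = sorted(lengths)
    for i, a in enumerate(names):
        for b_ in names[i + 1:]:
            if len(lengths[a]) and len(lengths[b_]):
                stat, p = sps.mannwhitneyu(lengths[a], lengths[b_],
                                           alternative="two-sided")
            else:
                stat, p = np.nan, np.nan
            tests.append({"set_a": a, "set_b": b_, "u_stat": stat, "p": p})
    return pd.DataFrame(summary_rows), pd.DataFrame(tests)
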