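"""Fractionated differential analysis: export targets, exon usage and APA.

The design has two fractions (whole_cell, cytoplasmic), two conditions
(control, kd) and two replicates.  Export targets are transcripts whose
cytoplasmic abundance drops under knockdown beyond their whole-cell change
(net export decrease).  All tests here are deliberately simple, defined
statistics:

* transcript level — a negative-binomial Wald test on group means with
  method-of-moments dispersions shrunk toward a mean-dispersion trend;
* exon usage — a pooled 2x2 test of exon vs rest-of-gene counts between
  conditions;
* APA — a Beta-Binomial Bayes factor comparing condition-specific vs
  shared Psi on informative (distinguishing-region) read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import betaln
from statsmodels.stats.multitest import multipletests

from .annotation import APAEvent, ExonFeature


# ---------------------------------------------------------------------------
# normalisation


def normalize_counts(matrix: pd.DataFrame, samples: pd.DataFrame
                     ) -> Tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors, computed within each fraction.

    Features with a zero count in any sample of a fraction are excluded
    from that fraction's geometric-mean reference.  If no feature is
    nonzero everywhere, falls back to total-count scaling with a warning
    in the returned factors' attrs.
    """
    factors = pd.Series(1.0, index=matrix.columns, name="size_factor")
    fallback = []
    for fraction, sub in samples.groupby("fraction"):
        cols = list(sub["sample"])
        m = matrix[cols].to_numpy(dtype=float)
        nonzero = (m > 0).all(axis=1)
        if nonzero.sum() == 0:
            tot = m.sum(axis=0)
            factors[cols] = tot / tot.mean() if tot.sum() > 0 else 1.0
            fallback.append(fraction)
            continue
        logs = np.log(m[nonzero])
        ref = logs.mean(axis=1)
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
        factors[cols] = sf
    factors.attrs["fallback_fractions"] = fallback
    normalized = matrix / factors
    return factors, normalized


# ---------------------------------------------------------------------------
# NB two-group test


def differential_abundance(normalized: pd.DataFrame, samples: pd.DataFrame,
                           fraction: str,
                           shrink_weight: float = 0.2) -> pd.DataFrame:
    """Knockdown vs control within one fraction.

    log2FC of group means with pseudocount 1.  The test is a Wald test on
    log counts: the per-feature log-scale variance (delta method,
    1/mu + alpha for an NB with dispersion alpha) is estimated
    method-of-moments from the replicates and shrunk toward the trend
    v(mu) = b0 + b1/mu fitted across all features, with weight
    ``shrink_weight`` on the per-feature estimate.  q by
    Benjamini-Hochberg.  All-zero features are reported NA.
    """
    sub = samples[samples["fraction"] == fraction]
    kd_cols = list(sub.loc[sub["condition"] == "kd", "sample"])
    ct_cols = list(sub.loc[sub["condition"] == "control", "sample"])
    if len(kd_cols) < 2 or len(ct_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    kd = normalized[kd_cols].to_numpy(dtype=float)
    ct = normalized[ct_cols].to_numpy(dtype=float)
    m_kd, m_ct = kd.mean(axis=1), ct.mean(axis=1)
    mean_all = (m_kd + m_ct) / 2

    # per-feature log-scale variance, pooled over both groups (df = n1+n2-2)
    yk = np.log(kd + 1)
    yc = np.log(ct + 1)
    n1, n2 = kd.shape[1], ct.shape[1]
    ss = yk.var(axis=1, ddof=1) * (n1 - 1) + yc.var(axis=1, ddof=1) * (n2 - 1)
    v_feat = ss / (n1 + n2 - 2)
    # trend: v(mu) = b0 + b1/mu  (b0 plays the role of the NB dispersion)
    ok = (mean_all > 0) & np.isfinite(v_feat)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(int(ok.sum())), 1.0 / (mean_all[ok] + 1)])
        coef, *_ = np.linalg.lstsq(X, v_feat[ok], rcond=None)
        b0, b1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    else:
        b0, b1 = max(float(np.nanmedian(v_feat)), 1e-6), 1.0
    v_trend = b0 + b1 / (mean_all + 1)
    v_hat = shrink_weight * v_feat + (1 - shrink_weight) * v_trend
    alpha = np.maximum(v_hat - 1.0 / (mean_all + 1), 1e-8)

    log2fc = np.log2(m_kd + 1) - np.log2(m_ct + 1)
    se = np.sqrt(v_hat * (1.0 / n1 + 1.0 / n2))
    z = (yk.mean(axis=1) - yc.mean(axis=1)) / se
    p = 2 * sps.norm.sf(np.abs(z))
    untested = (m_kd == 0) & (m_ct == 0)
    p[untested] = np.nan
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "feature": normalized.index, "mean_control": m_ct, "mean_kd": m_kd,
        "log2fc": np.where(untested, np.nan, log2fc),
        "dispersion": alpha, "p": p, "q": q,
    }).set_index("feature")


def call_export_targets(results_cyto: pd.DataFrame,
                        results_whole: pd.DataFrame,
                        alpha: float = 0.05,
                        delta: float = 0.585) -> pd.DataFrame:
    """Export targets: significant cytoplasmic decrease beyond the
    whole-cell change.

    is_target iff q_cyto < alpha AND log2fc_cyto < 0 AND
    (log2fc_cyto - log2fc_whole) <= -delta.  Features present in only one
    fraction are untested.
    """
    common = results_cyto.index.intersection(results_whole.index)
    cy = results_cyto.loc[common]
    wh = results_whole.loc[common]
    d = cy["log2fc"] - wh["log2fc"]
    is_target = ((cy["q"] < alpha) & (cy["log2fc"] < 0) & (d <= -delta)
                 ).fillna(False)
    return pd.DataFrame({
        "log2fc_cyto": cy["log2fc"], "log2fc_whole": wh["log2fc"],
        "delta": d, "p_cyto": cy["p"], "q_cyto": cy["q"],
        "is_target": is_target,
    })


# ---------------------------------------------------------------------------
# exon usage


def exon_usage_test(exon_counts: pd.DataFrame, gene_of_exon: pd.Series,
                    samples: pd.DataFrame, fraction: str,
                    fdr: float = 0.1) -> pd.DataFrame:
    """Differential exon usage (exon vs rest-of-gene), pooled 2x2 per exon.

    Counts are pooled over replicates per condition; the 2x2 table is
    [exon, rest-of-gene] x [kd, control], tested two-sided (chi-square, or
    Fisher's exact when any expected cell < 5).  Direction is the sign of
    the usage change (kd vs control); defined only for q < ``fdr``.
    Exons of genes with zero counts in either condition are untested.
    """
    sub = samples[samples["fraction"] == fraction]
    kd_cols = list(sub.loc[sub["condition"] == "kd", "sample"])
    ct_cols = list(sub.loc[sub["condition"] == "control", "sample"])
    exon_ids = [e for e in exon_counts.index if e in gene_of_exon.index]
    ec = exon_counts.loc[exon_ids]
    genes = gene_of_exon.loc[exon_ids]
    kd_exon = ec[kd_cols].sum(axis=1)
    ct_exon = ec[ct_cols].sum(axis=1)
    kd_gene = kd_exon.groupby(genes).transform("sum")
    ct_gene = ct_exon.groupby(genes).transform("sum")

    rows = []
    for eid in exon_ids:
        ke, ce = int(kd_exon[eid]), int(ct_exon[eid])
        kg, cg = int(kd_gene[eid]), int(ct_gene[eid])
        if kg == 0 or cg == 0:
            rows.append({"exon_id": eid, "gene_id": genes[eid],
                         "usage_control": np.nan, "usage_kd": np.nan,
                         "p": np.nan})
            continue
        kr, cr = kg - ke, cg - ce
        table = np.array([[ke, kr], [ce, cr]])
        if table.sum() == 0:
            p = np.nan
        else:
            expected = (table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :]
                        / table.sum())
            if (expected < 5).any():
                _, p = sps.fisher_exact(table, alternative="two-sided")
            else:
                _, p, _, _ = sps.chi2_contingency(table, correction=False)
        rows.append({"exon_id": eid, "gene_id": genes[eid],
                     "usage_control": ce / cg, "usage_kd": ke / kg, "p": p})
    res = pd.DataFrame(rows).set_index("exon_id")
    res["q"] = np.nan
    ok = res["p"].notna()
    if ok.any():
        res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["significant"] = res["q"] < fdr
    res["direction"] = pd.Series(np.nan, index=res.index, dtype=object)
    sig = res["significant"]
    res.loc[sig & (res["usage_kd"] < res["usage_control"]), "direction"] = "less_inclusion"
    res.loc[sig & (res["usage_kd"] > res["usage_control"]), "direction"] = "more_inclusion"
    res["compartment"] = fraction
    return res


def classify_changed_exons(results: pd.DataFrame,
                           exon_features: Sequence[ExonFeature]) -> pd.DataFrame:
    """Proportions of first/internal/last exons among changed exons, by
    direction."""
    cls = {x.exon_id: x.ordinal_class for x in exon_features}
    changed = results[results["significant"].fillna(False)
                      & results["direction"].notna()].copy()
    if len(changed) == 0:
        return pd.DataFrame(columns=["direction", "ordinal_class",
                                     "n", "proportion"])
    changed["ordinal_class"] = [cls.get(e, "unknown") for e in changed.index]
    rows = []
    for direction, sub in changed.groupby("direction"):
        tab = sub.groupby("ordinal_class").size()
        for ocls, n in tab.items():
            rows.append({"direction": direction, "ordinal_class": ocls,
                         "n": int(n), "proportion": n / len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# APA: Psi and Bayes factor


def psi_estimate(counts: pd.Series, event: APAEvent) -> float:
    """Long/distal isoform fraction from distinguishing-region densities.

    TandemUTR: the proximal region is shared by both isoforms, so
    Psi = distal_density / proximal_density (capped to [0,1]).
    ALE: the regions are isoform-exclusive, Psi = d / (d + p).
    NaN when both regions have zero counts.
    """
    cp = float(counts.get(f"{event.event_id}:prox", np.nan))
    cd = float(counts.get(f"{event.event_id}:dist", np.nan))
    if np.isnan(cp) or np.isnan(cd):
        return np.nan
    lp = event.proximal_region[1] - event.proximal_region[0]
    ld = event.distal_region[1] - event.distal_region[0]
    dp = cd / ld
    pp = cp / lp
    if cp == 0 and cd == 0:
        return np.nan
    if event.kind == "TandemUTR":
        if pp == 0:
            return 1.0
        return float(np.clip(dp / pp, 0.0, 1.0))
    return float(dp / (dp + pp))


def _log_marginal(k: int, n: int) -> float:
    """log integral of theta^k (1-theta)^(n-k) dtheta with uniform prior."""
    return betaln(k + 1, n - k + 1)


def bayes_factor(k_ctrl: int, n_ctrl: int, k_kd: int, n_kd: int) -> float:
    """Beta-Binomial evidence for condition-specific vs shared proportion.

    Uniform Beta(1,1) priors; BF = m(separate) / m(shared) on the
    distinguishing-region read counts.
    """
    log_sep = _log_marginal(k_ctrl, n_ctrl) + _log_marginal(k_kd, n_kd)
    log_shared = _log_marginal(k_ctrl + k_kd, n_ctrl + n_kd)
    return float(np.exp(log_sep - log_shared))


def apa_call(exon_counts: pd.DataFrame, event: APAEvent,
             samples: pd.DataFrame, fraction: str = "cytoplasmic",
             bf_threshold: float = 5.0, dpsi_threshold: float = 0.20,
             min_informative: int = 20) -> dict:
    """Psi per condition, Bayes factor and the lengthening/shortening call.

    Replicates are pooled per condition.  The Bayes factor is computed on
    distal vs total distinguishing-region counts; called iff BF >
    ``bf_threshold`` and |dPsi| >= ``dpsi_threshold``.  Events with fewer
    than ``min_informative`` informative reads are flagged low-coverage and
    never called.
    """
    sub = samples[samples["fraction"] == fraction]
    out = {"event_id": event.event_id, "kind": event.kind, "gene_id": event.gene_id}
    pooled = {}
    for cond in ("control", "kd"):
        cols = list(sub.loc[sub["condition"] == cond, "sample"])
        pooled[cond] = exon_counts[cols].sum(axis=1)
    psi_c = psi_estimate(pooled["control"], event)
    psi_k = psi_estimate(pooled["kd"], event)
    kc = int(pooled["control"].get(f"{event.event_id}:dist", 0))
    nc = kc + int(pooled["control"].get(f"{event.event_id}:prox", 0))
    kk = int(pooled["kd"].get(f"{event.event_id}:dist", 0))
    nk = kk + int(pooled["kd"].get(f"{event.event_id}:prox", 0))
    informative = nc + nk
    bf = bayes_factor(kc, nc, kk, nk) if informative > 0 else np.nan
    dpsi = psi_k - psi_c if not (np.isnan(psi_c) or np.isnan(psi_k)) else np.nan
    low = informative < min_informative
    called = (not low and not np.isnan(dpsi) and bf > bf_threshold
              and abs(dpsi) >= dpsi_threshold)
    out.update({
        "psi_control": psi_c, "psi_kd": psi_k, "dpsi": dpsi,
        "bayes_factor": bf, "n_informative": informative,
        "low_coverage": bool(low), "called": bool(called),
        "direction": ("lengthening" if called and psi_k > psi_c else
                      "shortening" if called else None),
    })
    return out


def apa_analysis(exon_counts: pd.DataFrame, events: Sequence[APAEvent],
                 samples: pd.DataFrame, fraction: str = "cytoplasmic",
                 bf_threshold: float = 5.0,
                 dpsi_threshold: float = 0.20) -> pd.DataFrame:
    rows = [apa_call(exon_counts, ev, samples, fraction,
                     bf_threshold, dpsi_threshold) for ev in events]
    return pd.DataFrame(rows).set_index("event_id") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# integration with binding


def integrate_targets_binding(export_calls: pd.DataFrame,
                              sites_by_library: Dict[str, pd.DataFrame],
                              annotation, regions,
                              apa_results: Optional[pd.DataFrame] = None,
                              sr_library: str = "SRSF3",
                              nxf1_library: str = "NXF1",
                              events: Optional[Sequence[APAEvent]] = None
                              ) -> dict:
    """Overlap of export targets with cognate SR and NXF1 binding sites.

    Reports, for the given SR library: total targets, targets with cognate
    sites, with sites in last exons / 3'UTRs, the same for NXF1, and
    targets undergoing called APA shortening whose distal region contains
    an NXF1 site center (cleavage before the site removes it).
    """
    from .occupancy import _LabelIndex  # shared interval lookup

    targets = export_calls[export_calls["is_target"]]
    target_genes = set()
    tid_to_gene = {tid: t.gene_id for tid, t in annotation.transcripts.items()}
    for tid in targets.index:
        g = tid_to_gene.get(tid)
        if g:
            target_genes.add(g)

    idx = _LabelIndex(regions, annotation)
    # last-exon spans of representative transcripts
    last_spans: Dict[str, Tuple[int, int]] = {}
    for gid, tid in regions.representative.items():
        t = annotation.transcripts[tid]
        if len(t.exons) > 1:
            last_spans[gid] = t.exons[-1]

    def site_hits(sites: pd.DataFrame) -> Tuple[set, set]:
        """gene ids with any site; gene ids with a site in last exon/3'UTR."""
        any_g, end_g = set(), set()
        for (chrom, strand), sub in sites.groupby(["chrom", "strand"],
                                                  sort=True):
            lab, gid = idx.lookup(chrom, strand, sub["center"].to_numpy())
            for center, l_, g_ in zip(sub["center"], lab, gid):
                if g_ is None:
                    continue
                any_g.add(g_)
                in_last = (g_ in last_spans
                           and last_spans[g_][0] <= center < last_spans[g_][1])
                if l_ == "three_prime_utr" or in_last:
                    end_g.add(g_)
        return any_g, end_g

    sr_any, sr_end = site_hits(sites_by_library.get(sr_library, pd.DataFrame(
        columns=["chrom", "strand", "center"])))
    nx_any, nx_end = site_hits(sites_by_library.get(nxf1_library, pd.DataFrame(
        columns=["chrom", "strand", "center"])))

    n_apa_removed = 0
    if apa_results is not None and events is not None and len(apa_results):
        ev_by_id = {e.event_id: e for e in events}
        nxf1_sites = sites_by_library.get(nxf1_library)
        called = apa_results[apa_results["called"].fillna(False)
                             & (apa_results["direction"] == "shortening")]
        for eid, row in called.iterrows():
            ev = ev_by_id.get(eid)
            if ev is None or ev.gene_id not in target_genes:
                continue
            ds, de = ev.distal_region
            hit = nxf1_sites[(nxf1_sites["chrom"] == ev.chrom)
                             & (nxf1_sites["strand"] == ev.strand)
                             & (nxf1_sites["center"] >= ds)
                             & (nxf1_sites["center"] < de)]
            if len(hit):
                n_apa_removed += 1
    return {
        "sr_library": sr_library,
        "n_targets": len(target_genes),
        "n_targets_bound": len(target_genes & sr_any),
        "n_targets_bound_3end": len(target_genes & sr_end),
        "n_targets_nxf1": len(target_genes & nx_any),
        "n_targets_nxf1_3end": len(target_genes & nx_end),
        "n_targets_apa_removes_nxf1": n_apa_removed,
    }
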