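import numpy as np
import pandas as pd
import pytest

from srexport.annotation import (
    GenomeAnnotation, TranscriptModel, classify_exons, derive_regions,
)
from srexport.occupancy import (
    ExonBindingMatrix, cobound_exon_fraction, correlation_clustering,
    distance_correlation, exon_binding_matrix, region_density, sister_pairs,
    sites_per_transcript, utr3_length_stats,
)


@pytest.fixture()
def coding_gene():
    t = TranscriptModel("t1", "g1", "c", "+",
                        exons=[(0, 500), (1000, 3000)], cds=(100, 2000))
    return GenomeAnnotation([t])


def _events(rows, strand="+"):
    return pd.DataFrame([{"chrom": "c", "strand": strand, "position": p,
                          "count": n} for p, n in rows])


class TestRegionDensity:
    def test_density_arithmetic(self, coding_gene):
        regions = derive_regions(coding_gene)
        # 3'UTR is (2000, 3000): 1000 nt; put 100 events inside
        ev = _events([(p, 1) for p in range(2000, 2100)])
        dens = region_density({"L": ev}, regions, coding_gene,
                              library_sizes={"L": 1_000_000})
        row = dens[(dens.library == "L") & (dens.label == "three_prime_utr")]
        assert np.isclose(row["density"].iloc[0], 0.1)
        assert np.isclose(row["density_per_million"].iloc[0], 0.1)

    def test_event_conservation(self, coding_gene):
        regions = derive_regions(coding_gene)
        ev = _events([(50, 2), (600, 3), (2500, 1), (9000, 4)])
        dens = region_density({"L": ev}, regions, coding_gene)
        assert dens["n_events"].sum() == ev["count"].sum()
        assert "unassigned" in set(dens["label"])

    def test_absent_label_means_no_events(self, coding_gene):
        regions = derive_regions(coding_gene)
        ev = _events([(2500, 5)])
        dens = region_density({"L": ev}, regions, coding_gene)
        assert "five_prime_utr" not in set(dens["label"])


class TestExonBindingMatrix:
    def test_zero_row_and_normalization(self, coding_gene):
        exons = classify_exons(coding_gene)
        pos = _events([(1200, 4)])
        m1 = exon_binding_matrix({"L": pos}, exons,
                                 library_sizes={"L": 1000})
        m2 = exon_binding_matrix({"L": _events([(1200, 8)])}, exons,
                                 library_sizes={"L": 2000})
        assert m1.counts.loc["t1.E1", "L"] == 0
        assert m1.counts.loc["t1.E2", "L"] == 4
        # doubling events and library size leaves per-million unchanged
        assert np.isclose(m1.cpm.loc["t1.E2", "L"], m2.cpm.loc["t1.E2", "L"])

    def test_same_motif_libraries_correlate(self, small_sim):
        _, genome, libs = small_sim
        from srexport.xlink import (call_significant_positions, deduplicate,
                                    extract_crosslinks)
        unique, _ = deduplicate(libs["SRSF3"].reads)
        events = extract_crosslinks(unique)
        res = call_significant_positions(events, genome.annotation, seed=3)
        exons = classify_exons(genome.annotation)
        sig = res.significant
        half_a = sig.iloc[::2]
        half_b = sig.iloc[1::2]
        m = exon_binding_matrix({"A": half_a, "B": half_b}, exons)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(m.cpm["A"], m.cpm["B"])
        assert rho >= 0.8


class TestCoboundFraction:
    def _matrix(self, npos: pd.DataFrame) -> ExonBindingMatrix:
        zeros = npos * 0.0
        meta = pd.DataFrame(index=npos.index)
        return ExonBindingMatrix(counts=npos.astype(float), cpm=zeros,
                                 n_positions=npos, meta=meta)

    def test_disjoint_binding_gives_zero(self):
        npos = pd.DataFrame({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]})
        cf = cobound_exon_fraction(self._matrix(npos), ["A", "B"])
        assert cf["A"] == 0 and cf["B"] == 0

    def test_identical_binding_gives_one(self):
        npos = pd.DataFrame({"A": [1, 2, 0], "B": [3, 1, 0]})
        cf = cobound_exon_fraction(self._matrix(npos), ["A", "B"])
        assert cf["A"] == 1 and cf["B"] == 1

    def test_half_overlap(self):
        npos = pd.DataFrame({"A": [1] * 10, "B": [1] * 5 + [0] * 5})
        cf = cobound_exon_fraction(self._matrix(npos), ["A", "B"])
        assert np.isclose(cf["A"], 0.5)
        assert np.isclose(cf["B"], 1.0)

    def test_unbound_library_is_nan(self):
        npos = pd.DataFrame({"A": [1, 1], "B": [0, 0]})
        cf = cobound_exon_fraction(self._matrix(npos), ["A", "B"])
        assert np.isnan(cf["B"])


class TestDistanceCorrelation:
    def test_perfect_dependence(self):
        x = np.arange(50, dtype=float)
        assert np.isclose(distance_correlation(x, 3 * x + 1), 1.0)

    def test_independence_small(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=400), rng.normal(size=400)
        assert distance_correlation(x, y) < 0.2

    def test_detects_nonmonotone_dependence(self):
        x = np.linspace(-1, 1, 200)
        assert distance_correlation(x, x ** 2) > 0.3


class TestClustering:
    def test_duplicated_column_merges_first(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5.0, size=200).astype(float)
        m = pd.DataFrame({"A": base, "B": base,
                          "C": rng.poisson(5.0, size=200).astype(float)})
        res = correlation_clustering(m, method="spearman")
        assert res.correlation.loc["A", "B"] == pytest.approx(1.0)
        assert ("A", "B") in sister_pairs(res)
        first_merge = res.linkage[0]
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"A": rng.normal(size=50),
                          "B": rng.normal(size=50),
                          "K": np.ones(50)})
        res = correlation_clustering(m, method="spearman")
        assert res.dropped == ["K"]
        assert "K" not in res.correlation.columns

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.poisson(4.0, size=(300, 4)).astype(float),
                         columns=list("ABCD"))
        r1 = correlation_clustering(m, method="distance_correlation", seed=5)
        r2 = correlation_clustering(m, method="distance_correlation", seed=5)
        assert r1.newick() == r2.newick()

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("XYZ"))
        nwk = correlation_clustering(m).newick()
        for leaf in "XYZ":
            assert leaf in nwk
        assert nwk.endswith(";")


class TestSitesPerTranscript:
    def test_counts_and_regions(self, coding_gene):
        regions = derive_regions(coding_gene)
        sites = pd.DataFrame([
            {"chrom": "c", "strand": "+", "center": 50},    # 5'UTR
            {"chrom": "c", "strand": "+", "center": 2500},  # 3'UTR
        ])
        hist, crosstab = sites_per_transcript(sites, regions, coding_gene)
        assert hist.loc[2] == 1           # one gene with two sites
        assert crosstab.loc["five_prime_utr", "n_sites"] == 1
        assert crosstab.loc["three_prime_utr", "n_sites"] == 1

    def test_zero_bucket_present(self, coding_gene):
        regions = derive_regions(coding_gene)
        sites = pd.DataFrame(columns=["chrom", "strand", "center"])
        hist, _ = sites_per_transcript(sites, regions, coding_gene)
        assert hist.loc[0] == 1


class TestUtr3Lengths:
    def _ann(self):
        # 3'UTR lengths 100, 200, 300, 1000, 2000
        ts = []
        for i, utr in enumerate([100, 200, 300, 1000, 2000]):
            ts.append(TranscriptModel(
                f"t{i}", f"g{i}", "c", "+",
                exons=[(i * 10_000, i * 10_000 + 3000)],
                cds=(i * 10_000, i * 10_000 + 3000 - utr)))
        return GenomeAnnotation(ts)

    def test_medians(self):
        ann = self._ann()
        summary, _ = utr3_length_stats(
            {"short": ["t0", "t1", "t2"], "long": ["t3", "t4"]}, ann)
        med = summary.set_index("set")["median"]
        assert med["short"] == 200
        assert med["long"] == 1500

    def test_identical_sets_not_significant(self):
        ann = self._ann()
        tids = ["t0", "t1", "t2", "t3", "t4"]
        _, tests = utr3_length_stats({"a": tids, "b": tids}, ann)
        assert tests["p"].iloc[0] >= 0.9

    def test_transcripts_without_utr_excluded(self):
        ann = self._ann()
        summary, _ = utr3_length_stats({"s": ["t0", "missing"]}, ann)
        assert summary.iloc[0]["n"] == 1
        assert summary.iloc[0]["n_excluded"] == 1
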