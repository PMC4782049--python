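import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from srexport.annotation import APAEvent, ExonFeature
from srexport.diff import (
    apa_call, bayes_factor, call_export_targets, classify_changed_exons,
    differential_abundance, exon_usage_test, normalize_counts, psi_estimate,
)
from srexport.simulate import SAMPLES, sample_sheet


@pytest.fixture()
def samples():
    return sample_sheet()


def _matrix(rng, n=300, mean=200.0, alpha=0.05, factors=None):
    sheet = sample_sheet()
    base = rng.lognormal(np.log(mean), 0.4, size=n)
    cols = {}
    for i, s in enumerate(sheet["sample"]):
        f = 1.0 if factors is None else factors[i]
        mu = base * f
        cols[s] = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
    return pd.DataFrame(cols, index=[f"t{i}" for i in range(n)])


class TestNormalize:
    def test_doubled_sample_factor_two(self, samples):
        rng = np.random.default_rng(0)
        m = _matrix(rng, alpha=1e-3)
        m["cy_control_1"] = m["cy_control_2"] * 2
        factors, norm = normalize_counts(m, samples)
        ratio = factors["cy_control_1"] / factors["cy_control_2"]
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_identical_samples_unit_factors(self, samples):
        rng = np.random.default_rng(1)
        m = _matrix(rng, alpha=1e-3)
        for s in m.columns:
            m[s] = m["wh_control_1"]
        factors, _ = normalize_counts(m, samples)
        assert np.allclose(factors, 1.0)

    def test_gradient_recovered_within_two_percent(self, samples):
        rng = np.random.default_rng(2)
        factors_true = [1.0, 1.2, 0.8, 1.1, 0.9, 1.3, 1.0, 0.7]
        m = _matrix(rng, n=2000, alpha=1e-3, factors=factors_true)
        factors, _ = normalize_counts(m, samples)
        # size factors are identifiable up to a per-fraction constant
        for fraction, sub in samples.groupby("fraction"):
            cols = list(sub["sample"])
            idx = [list(samples["sample"]).index(c) for c in cols]
            true = np.array([factors_true[i] for i in idx])
            est = factors[cols].to_numpy()
            est = est / np.exp(np.mean(np.log(est)))
            true = true / np.exp(np.mean(np.log(true)))
            assert np.allclose(est, true, rtol=0.02)

    def test_all_zero_feature_fallback(self, samples):
        m = pd.DataFrame(0, index=["t0", "t1"],
                         columns=list(sample_sheet()["sample"]))
        m.iloc[0, 0] = 5
        factors, _ = normalize_counts(m, samples)
        assert factors.attrs["fallback_fractions"]


class TestDifferentialAbundance:
    def test_identical_groups_zero_lfc(self, samples):
        sheet = sample_sheet()
        m = pd.DataFrame({s: [100, 50] for s in sheet["sample"]},
                         index=["a", "b"])
        res = differential_abundance(m, samples, "cytoplasmic")
        assert np.allclose(res["log2fc"], 0.0)

    def test_all_zero_feature_untested(self, samples):
        sheet = sample_sheet()
        m = pd.DataFrame({s: [100, 0] for s in sheet["sample"]},
                         index=["a", "b"])
        res = differential_abundance(m, samples, "cytoplasmic")
        assert np.isnan(res.loc["b", "p"])

    def test_null_calibration(self, samples):
        fracs = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            m = _matrix(rng, n=400)
            _, norm = normalize_counts(m, samples)
            res = differential_abundance(norm, samples, "whole_cell")
            fracs.append((res["p"].dropna() < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_q_monotone_in_p(self, samples):
        rng = np.random.default_rng(3)
        m = _matrix(rng)
        res = differential_abundance(m, samples, "cytoplasmic").dropna()
        srt = res.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
        assert ((res["q"] >= 0) & (res["q"] <= 1)).all()

    def test_planted_effect_detected_at_low_dispersion(self, samples):
        rng = np.random.default_rng(4)
        sheet = sample_sheet()
        base = np.full(200, 400.0)
        effect = np.ones(200)
        effect[:20] = 0.5
        cols = {}
        for s in sheet["sample"]:
            row = sheet[sheet["sample"] == s].iloc[0]
            mu = base * (effect if (row["condition"] == "kd"
                                    and row["fraction"] == "cytoplasmic")
                         else 1.0)
            cols[s] = rng.poisson(mu)
        m = pd.DataFrame(cols, index=[f"t{i}" for i in range(200)])
        res = differential_abundance(m, samples, "cytoplasmic")
        hits = res.iloc[:20]
        assert (hits["q"] < 0.05).mean() >= 0.9


class TestCallExportTargets:
    def _results(self, rows):
        return pd.DataFrame(rows).set_index("feature")

    def test_definition(self):
        cy = self._results([{"feature": "t", "log2fc": -1.0, "p": 1e-4,
                             "q": 0.01}])
        wh = self._results([{"feature": "t", "log2fc": 0.0, "p": 0.5,
                             "q": 0.9}])
        calls = call_export_targets(cy, wh)
        assert calls.loc["t", "is_target"]

    def test_matched_whole_cell_change_excluded(self):
        cy = self._results([{"feature": "t", "log2fc": -1.0, "p": 1e-4,
                             "q": 0.01}])
        wh = self._results([{"feature": "t", "log2fc": -1.0, "p": 1e-4,
                             "q": 0.01}])
        calls = call_export_targets(cy, wh)
        assert not calls.loc["t", "is_target"]

    def test_feature_missing_in_one_fraction_untested(self):
        cy = self._results([{"feature": "t", "log2fc": -1.0, "p": 1e-4,
                             "q": 0.01},
                            {"feature": "u", "log2fc": -2.0, "p": 1e-5,
                             "q": 0.001}])
        wh = self._results([{"feature": "t", "log2fc": 0.0, "p": 0.5,
                             "q": 0.9}])
        calls = call_export_targets(cy, wh)
        assert "u" not in calls.index


class TestExonUsage:
    def _counts(self, rng, usage_kd, usage_ct, gene_total=2000, n_exons=5):
        sheet = sample_sheet()
        genes = {}
        rows = {}
        gene_of_exon = {}
        for g in range(8):
            for e in range(n_exons):
                eid = f"g{g}.E{e}"
                gene_of_exon[eid] = f"g{g}"
                frac_ct = usage_ct if (g == 0 and e == 0) else 1.0 / n_exons
                frac_kd = usage_kd if (g == 0 and e == 0) else 1.0 / n_exons
                rows[eid] = {}
                for s in sheet["sample"]:
                    cond = sheet.loc[sheet["sample"] == s, "condition"].iloc[0]
                    frac = frac_kd if cond == "kd" else frac_ct
                    rows[eid][s] = rng.poisson(gene_total * frac / 2)
        counts = pd.DataFrame(rows).T
        return counts, pd.Series(gene_of_exon)

    def test_equal_usage_not_significant(self, samples):
        rng = np.random.default_rng(5)
        counts, gene_of = self._counts(rng, 0.2, 0.2)
        res = exon_usage_test(counts, gene_of, samples, "cytoplasmic")
        assert not res.loc["g0.E0", "significant"]

    def test_planted_drop_detected_with_direction(self, samples):
        rng = np.random.default_rng(6)
        counts, gene_of = self._counts(rng, 0.3, 0.6)
        res = exon_usage_test(counts, gene_of, samples, "cytoplasmic")
        assert res.loc["g0.E0", "significant"]
        assert res.loc["g0.E0", "direction"] == "less_inclusion"

    def test_zero_gene_condition_untested(self, samples):
        sheet = sample_sheet()
        counts = pd.DataFrame({s: [0, 0] for s in sheet["sample"]},
                              index=["g0.E0", "g0.E1"])
        gene_of = pd.Series({"g0.E0": "g0", "g0.E1": "g0"})
        res = exon_usage_test(counts, gene_of, samples, "cytoplasmic")
        assert res["p"].isna().all()


class TestClassifyChangedExons:
    def _feat(self, eid, cls):
        return ExonFeature(exon_id=eid, transcript_id="t", gene_id="g",
                           chrom="c", strand="+", span=(0, 10),
                           ordinal_class=cls, ordinal=0)

    def test_proportions(self):
        res = pd.DataFrame({
            "significant": [True, True, True, False],
            "direction": ["less_inclusion", "less_inclusion",
                          "more_inclusion", np.nan],
        }, index=["e1", "e2", "e3", "e4"])
        feats = [self._feat("e1", "last"), self._feat("e2", "last"),
                 self._feat("e3", "internal"), self._feat("e4", "first")]
        tab = classify_changed_exons(res, feats)
        less_last = tab[(tab.direction == "less_inclusion")
                        & (tab.ordinal_class == "last")]
        assert less_last["proportion"].iloc[0] == 1.0

    def test_empty_results_no_crash(self):
        res = pd.DataFrame(columns=["significant", "direction"])
        tab = classify_changed_exons(res, [])
        assert len(tab) == 0


def _tandem_event():
    return APAEvent(event_id="g:TandemUTR:1", gene_id="g", kind="TandemUTR",
                    chrom="c", strand="+", proximal_region=(0, 1000),
                    distal_region=(1000, 1500), isoform_ids=("s", "l"))


def _ale_event():
    return APAEvent(event_id="g:ALE:1", gene_id="g", kind="ALE",
                    chrom="c", strand="+", proximal_region=(0, 500),
                    distal_region=(2000, 3000), isoform_ids=("p", "d"))


class TestPsiEstimate:
    def test_zero_distal_is_zero(self):
        ev = _tandem_event()
        counts = pd.Series({"g:TandemUTR:1:prox": 100, "g:TandemUTR:1:dist": 0})
        assert psi_estimate(counts, ev) == 0.0

    def test_equal_densities_tandem_is_one(self):
        ev = _tandem_event()
        counts = pd.Series({"g:TandemUTR:1:prox": 1000,
                            "g:TandemUTR:1:dist": 500})  # same per-nt density
        assert psi_estimate(counts, ev) == pytest.approx(1.0)

    def test_ale_density_share(self):
        ev = _ale_event()
        counts = pd.Series({"g:ALE:1:prox": 500, "g:ALE:1:dist": 1000})
        # densities 1.0 each -> Psi = 0.5
        assert psi_estimate(counts, ev) == pytest.approx(0.5)

    def test_both_zero_undefined(self):
        ev = _ale_event()
        counts = pd.Series({"g:ALE:1:prox": 0, "g:ALE:1:dist": 0})
        assert np.isnan(psi_estimate(counts, ev))

    def test_binomial_sampling_accuracy(self):
        """ALE Psi at 500 informative reads: mean |error| under 0.05."""
        rng = np.random.default_rng(8)
        ev = _ale_event()
        errs = []
        for _ in range(300):
            psi = 0.4
            # densities: prox len 500 at (1-psi), dist len 1000 at psi
            k = rng.binomial(500, psi * 1000 / (psi * 1000 + (1 - psi) * 500))
            counts = pd.Series({"g:ALE:1:prox": 500 - k, "g:ALE:1:dist": k})
            errs.append(abs(psi_estimate(counts, ev) - psi))
        assert np.mean(errs) <= 0.05


class TestBayesFactor:
    def test_identical_counts_bf_below_one(self):
        assert bayes_factor(50, 100, 50, 100) < 1.0

    def test_extreme_shift_called(self, samples):
        sheet = sample_sheet()
        ev = _ale_event()
        cols = {}
        for s in sheet["sample"]:
            cond = sheet.loc[sheet["sample"] == s, "condition"].iloc[0]
            k = 0 if cond == "control" else 100
            cols[s] = pd.Series({"g:ALE:1:prox": 100 - k, "g:ALE:1:dist": k})
        counts = pd.DataFrame(cols)
        out = apa_call(counts, ev, samples, fraction="cytoplasmic")
        assert out["called"]
        assert out["dpsi"] == pytest.approx(1.0, abs=0.05)
        assert out["direction"] == "lengthening"

    def test_low_coverage_never_called(self, samples):
        sheet = sample_sheet()
        ev = _ale_event()
        cols = {s: pd.Series({"g:ALE:1:prox": 1, "g:ALE:1:dist": 1})
                for s in sheet["sample"]}
        out = apa_call(pd.DataFrame(cols), ev, samples)
        assert out["low_coverage"] and not out["called"]

    def test_agrees_with_numeric_integration(self):
        """Closed-form Beta marginals match direct numeric integration of
        the binomial likelihood (the independent oracle) within 5%."""
        rng = np.random.default_rng(9)

        def marginal(k, n):
            # integrate the likelihood scaled by its mode so quad keeps
            # precision on sharply peaked integrands
            mode = k / n if 0 < k < n else 0.5
            def loglik(th):
                with np.errstate(divide="ignore"):
                    return k * np.log(th) + (n - k) * np.log1p(-th)
            peak = loglik(mode) if 0 < k < n else 0.0
            val, _ = quad(lambda t: np.exp(loglik(t) - peak), 0, 1,
                          points=[mode], limit=200)
            return val, peak

        for _ in range(100):
            n1, n2 = rng.integers(10, 200, size=2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            m1, p1 = marginal(k1, n1)
            m2, p2 = marginal(k2, n2)
            m0, p0 = marginal(k1 + k2, n1 + n2)
            oracle = (m1 * m2 / m0) * np.exp(p1 + p2 - p0)
            ours = bayes_factor(int(k1), int(n1), int(k2), int(n2))
            assert ours == pytest.approx(oracle, rel=0.05)

    def test_null_call_rate_low(self, samples):
        rng = np.random.default_rng(10)
        sheet = sample_sheet()
        ev = _ale_event()
        n_called = 0
        n_events = 150
        for _ in range(n_events):
            psi = rng.uniform(0.3, 0.7)
            cols = {}
            for s in sheet["sample"]:
                n = 300
                k = rng.binomial(n, psi * 1000 / (psi * 1000 + (1 - psi) * 500))
                cols[s] = pd.Series({"g:ALE:1:prox": n - k,
                                     "g:ALE:1:dist": k})
            out = apa_call(pd.DataFrame(cols), ev, samples)
            n_called += out["called"]
        assert n_called / n_events <= 0.05
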