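import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reprodyn import de
from reprodyn.io import CountMatrix
from reprodyn.simulate import SimConfig, generate_timecourse_counts

from conftest import make_design


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle, computed the slow way."""
    ref = []
    for row in counts:
        if all(c > 0 for c in row):
            ref.append(np.prod([float(c) for c in row]) ** (1.0 / len(row)))
        else:
            ref.append(None)
    factors = []
    for j in range(counts.shape[1]):
        ratios = [counts[i, j] / ref[i] for i in range(counts.shape[0]) if ref[i]]
        factors.append(np.median(ratios))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestSizeFactors:
    def test_doubled_column(self):
        cm = CountMatrix(["g1", "g2"], ["a", "b"], np.array([[10, 20], [30, 60]]))
        sf = de.estimate_size_factors(cm)
        np.testing.assert_allclose(sf.factors, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_columns(self):
        cm = CountMatrix(["g1", "g2"], ["a", "b"], np.array([[7, 7], [3, 3]]))
        np.testing.assert_allclose(de.estimate_size_factors(cm).factors, 1.0)

    def test_matches_oracle_on_random_nb(self, rng):
        counts = rng.negative_binomial(5, 0.1, size=(100, 4)) + 1
        cm = CountMatrix([f"g{i}" for i in range(100)], list("abcd"), counts)
        np.testing.assert_allclose(
            de.estimate_size_factors(cm).factors, brute_force_size_factors(counts), rtol=1e-12
        )

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(50, size=(50, 6)) + 1
        sf = de.estimate_size_factors(CountMatrix([f"g{i}" for i in range(50)], list("abcdef"), counts))
        assert np.exp(np.mean(np.log(sf.factors))) == pytest.approx(1.0, abs=1e-9)

    @given(k=st.sampled_from([0.25, 0.5, 2, 3, 4]))
    @settings(max_examples=5, deadline=None)
    def test_scale_equivariance(self, k):
        """Scaling one column by k scales its factor by k, up to the
        global geometric-mean renormalization."""
        base = np.array([[12, 11, 9], [40, 38, 41], [100, 99, 104], [8, 8, 7]])
        scaled = base.copy()
        scaled[:, 0] = (base[:, 0] * k).astype(int)
        f0 = de.estimate_size_factors(CountMatrix(list("wxyz"), list("abc"), base)).factors
        f1 = de.estimate_size_factors(CountMatrix(list("wxyz"), list("abc"), scaled)).factors
        # ratios between untouched samples are invariant...
        assert f1[1] / f1[2] == pytest.approx(f0[1] / f0[2], rel=1e-9)
        # ...and the scaled sample's factor moves by exactly k
        assert f1[0] / f1[1] == pytest.approx(k * f0[0] / f0[1], rel=1e-9)

    def test_no_all_positive_feature_rejected(self):
        cm = CountMatrix(["g1"], ["a", "b"], np.array([[0, 5]]))
        with pytest.raises(ValueError, match="nonzero"):
            de.estimate_size_factors(cm)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value(self):
        np.testing.assert_allclose(de.bh_adjust([1.0]), [1.0])

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=1000)
        m = p.size
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(de.bh_adjust(p), oracle, rtol=1e-12, atol=0)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.uniform(size=200))
        q = de.bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestDifferential:
    def _unit_sf(self, cm):
        return de.SizeFactors(cm.sample_ids, np.ones(cm.n_samples))

    def test_identical_means_null(self):
        counts = np.tile([[50, 50, 50, 50]], (5, 1))
        cm, sheet = make_design(np.asarray(counts))
        res = de.test_differential(cm, sheet, self._unit_sf(cm), "dox", 24.0)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_all_zero_feature_sentinel(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 11, 13]])
        cm, sheet = make_design(counts)
        res = de.test_differential(cm, sheet, self._unit_sf(cm), "dox", 24.0)
        assert np.isnan(res.loc[0, "log2fc"]) and res.loc[0, "p"] == 1.0

    def test_requires_two_replicates(self):
        from reprodyn.io import CountMatrix, SampleSheet

        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c"],
                    "condition": ["dox"] * 3,
                    "time_h": [0.0, 0.0, 24.0],
                    "replicate": [1, 2, 1],
                }
            )
        )
        cm = CountMatrix(["g0"], ["a", "b", "c"], np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="replicates"):
            de.test_differential(cm, sheet, self._unit_sf(cm), "dox", 24.0)

    def test_planted_gene_detected_in_most_replicates(self):
        """An 8-fold induced gene among 500 nulls reaches q < 0.05 in at
        least 95 of 100 simulations (dispersion 0.05, 3 replicates)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_genes, disp = 501, 0.05
        for _ in range(100):
            base = rng.lognormal(4, 1, n_genes)
            mu = np.tile(base[:, None], (1, 6))
            mu[0, 3:] *= 8.0  # planted gene, later stratum
            size = 1 / disp
            counts = rng.negative_binomial(size, size / (size + mu))
            cm, sheet = make_design(counts, times=(0.0, 24.0), replicates=3)
            res = de.test_differential(cm, sheet, self._unit_sf(cm), "dox", 24.0)
            hits += res.loc[0, "q"] < 0.05
        assert hits >= 95

    def test_type_i_error_under_global_null(self):
        """Fraction of q < 0.05 calls on null NB data stays at or below
        the nominal level (within Monte-Carlo error)."""
        rng = np.random.default_rng(7)
        n_genes, disp = 2000, 0.05
        base = rng.lognormal(4, 1, n_genes)
        size = 1 / disp
        mu = np.tile(base[:, None], (1, 4))
        counts = rng.negative_binomial(size, size / (size + mu))
        cm, sheet = make_design(counts)
        res = de.test_differential(cm, sheet, self._unit_sf(cm), "dox", 24.0)
        # under the global null any rejection is false; BH keeps the
        # family-wise rejection fraction near alpha
        assert (res["q"] < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_genes)


class TestFoldChangeRatio:
    def _setup(self):
        # dox: 10 -> 40; control: flat 10 (both replicates)
        counts = np.array([[10, 10, 40, 40, 10, 10, 10, 10]])
        cm, sheet = make_design(counts, times=(0.0, 24.0), conditions=("dox", "control"))
        sf = de.SizeFactors(cm.sample_ids, np.ones(8))
        return cm, sheet, sf

    def test_pseudocount_arithmetic(self):
        cm, sheet, sf = self._setup()
        rec = de.fold_change_ratio(cm, sheet, sf, "g0", 24.0)
        expected = (40.5 / 10.5) / (10.5 / 10.5)
        np.testing.assert_allclose(rec.r_values, expected, rtol=1e-12)

    def test_identical_trajectories_give_unity(self):
        counts = np.array([[10, 10, 40, 40, 10, 10, 40, 40]])
        cm, sheet = make_design(counts, times=(0.0, 24.0), conditions=("dox", "control"))
        sf = de.SizeFactors(cm.sample_ids, np.ones(8))
        rec = de.fold_change_ratio(cm, sheet, sf, "g0", 24.0)
        np.testing.assert_allclose(rec.r_values, 1.0)

    def test_all_pairs_pairing(self):
        cm, sheet, sf = self._setup()
        table = de.fold_change_ratios(cm, sheet, sf, 24.0, pairing="all")
        assert sum(c.startswith("r") for c in table.columns) == 4

    def test_unknown_feature(self):
        cm, sheet, sf = self._setup()
        with pytest.raises(KeyError):
            de.fold_change_ratio(cm, sheet, sf, "nope", 24.0)


class TestRatioCI:
    def test_zero_variance_point_interval(self):
        lo, hi, flagged = de.ratio_ci([2.0, 2.0])
        assert (lo, hi) == (2.0, 2.0) and flagged

    def test_symmetric_pair_not_flagged(self):
        lo, hi, flagged = de.ratio_ci([0.5, 2.0])
        assert lo < 1.0 < hi and not flagged
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_t_interval_arithmetic(self):
        """r = (2, 4): mean log2 r = 1.5, half-width t(.975,1)*sd/sqrt(2)
        = 12.706*0.7071/1.4142 = 6.353 log2 units; CI straddles 1."""
        lo, hi, flagged = de.ratio_ci([2.0, 4.0])
        half = stats.t.ppf(0.975, 1) * np.std(np.log2([2.0, 4.0]), ddof=1) / np.sqrt(2)
        assert half == pytest.approx(6.3531, abs=1e-3)
        assert lo == pytest.approx(2 ** (1.5 - half), rel=1e-9)
        assert hi == pytest.approx(2 ** (1.5 + half), rel=1e-9)
        assert not flagged

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            de.ratio_ci([2.0])
        with pytest.raises(ValueError):
            de.ratio_ci([2.0, -1.0])

    def test_null_calibration_two_replicates(self, rng):
        """Null log-normal ratios with n = 2 are flagged at ~5% at 95%
        confidence: the t-interval is exact under log-normality."""
        n = 20000
        r = np.exp(rng.normal(0, 0.3, size=(n, 2)))
        table = pd.DataFrame(r, columns=["r1", "r2"])
        table.insert(0, "feature_id", [f"g{i}" for i in range(n)])
        table.insert(1, "time_h", 3.0)
        out = de.ratio_ci_table(table, 0.95)
        rate = out["osk_affected"].mean()
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n))


class TestAffectedGenes:
    def _tables(self):
        det = pd.DataFrame({"feature_id": ["a", "b", "c"], "q": [0.01, 0.01, 0.5]})
        ratios = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "osk_affected": [True, False, True],
            }
        )
        return det, ratios

    def test_intersection_rule(self):
        det, ratios = self._tables()
        assert de.osk_affected_genes(det, ratios) == ["a"]

    def test_universe_mismatch_rejected(self):
        det, ratios = self._tables()
        with pytest.raises(ValueError):
            de.osk_affected_genes(det, ratios.iloc[:2])

    def test_recovery_on_synthetic_run(self):
        """Affected-gene calls on the default synthetic time course have
        high precision against planted truth (sensitivity is limited by
        the width of the df=1 t-interval with two replicates)."""
        cfg = SimConfig(seed=11)
        cm, sheet, truth = generate_timecourse_counts(cfg, "aml-like")
        sf = de.estimate_size_factors(cm)
        det = de.test_differential(cm, sheet, sf, "dox", 24.0)
        ratios = de.ratio_ci_table(de.fold_change_ratios(cm, sheet, sf, 24.0))
        called = set(de.osk_affected_genes(det, ratios))
        true = set(truth.affected_genes)
        assert called, "no genes recovered"
        precision = len(called & true) / len(called)
        assert precision >= 0.6
        # drift genes pass the DE test but survive the ratio filter only
        # at the null flag rate (the CI on r cancels the shared drift)
        drift_sig = truth.drift_genes & set(det.loc[det["q"] < 0.05, "feature_id"])
        assert drift_sig, "drift term produced no DE signal to filter"
        leak = len(called & truth.drift_genes) / len(drift_sig)
        assert leak <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(drift_sig))
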