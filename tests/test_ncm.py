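import numpy as np
import pytest
from scipy import integrate, stats

from microassembly.errors import FitError, InsufficientDataError, ParameterError
from microassembly.io_tables import CountTable
from microassembly.ncm import (
    SloanNCM,
    classify_taxa,
    fit_ncm,
    fit_occupancy,
    occurrence_stats,
    predicted_frequency,
    wilson_interval,
)
from microassembly.synthetic import make_metacommunity, simulate_neutral_samples


class TestOccurrenceStats:
    def test_mean_relative_abundance(self):
        # one taxon at proportions 0.1 / 0.2 / 0.3 of three samples
        counts = np.array([[10, 20, 30], [90, 80, 70]])
        table = CountTable(counts, ["a", "b"], ["s1", "s2", "s3"])
        st = occurrence_stats(table)
        row = st[st.taxon_id == "a"].iloc[0]
        assert row.p == pytest.approx(0.2)
        assert row.f_obs == 1.0

    def test_detection_fraction(self):
        table = CountTable([[0, 5, 0], [1, 1, 1]], ["a", "b"], ["s1", "s2", "s3"])
        st = occurrence_stats(table, detection_count=1)
        assert st[st.taxon_id == "a"].iloc[0].f_obs == pytest.approx(1 / 3)

    def test_never_detected_taxa_excluded(self):
        table = CountTable([[0, 0], [1, 1]], ["gone", "b"], ["s1", "s2"])
        st = occurrence_stats(table)
        assert list(st.taxon_id) == ["b"]

    def test_matches_loop_oracle(self, random_table):
        st = occurrence_stats(random_table, detection_count=1).set_index("taxon_id")
        sums = random_table.sample_sums()
        for i, taxon in enumerate(random_table.taxon_ids):
            row = random_table.counts[i]
            f = sum(c >= 1 for c in row) / len(row)
            if f == 0:
                assert taxon not in st.index
                continue
            p = np.mean([c / s for c, s in zip(row, sums)])
            assert st.loc[taxon, "p"] == pytest.approx(p, abs=1e-15)
            assert st.loc[taxon, "f_obs"] == pytest.approx(f, abs=1e-15)

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            occurrence_stats(CountTable([[1]], ["a"], ["s"]))


class TestPredictedFrequency:
    def test_small_nm_limit_is_p(self):
        # Beta(a, b) with a + b -> 0 concentrates on {0, 1} with mass p at 1
        assert abs(predicted_frequency(0.3, 1e-4, 1e-4) - 0.3) < 1e-3

    def test_large_nm_limit_is_one_above_detection(self):
        assert predicted_frequency(0.01, 1e7, 1e-4) > 0.999

    def test_quadrature_oracle(self):
        # compare against numerical integration of the beta density
        for p, nm, x in [(0.01, 500, 1e-4), (0.2, 50, 1e-3), (0.5, 5, 0.01)]:
            a, b = nm * p, nm * (1 - p)
            dens = stats.beta(a, b).pdf
            tail, _ = integrate.quad(dens, x, 1, epsabs=1e-13, epsrel=1e-13)
            assert predicted_frequency(p, nm, x) == pytest.approx(tail, abs=1e-10)

    def test_monotone_in_p_and_nm(self):
        ps = np.linspace(0.001, 0.9, 40)
        f = predicted_frequency(ps, 1000, 1e-4)
        assert np.all(np.diff(f) >= -1e-12)
        # increasing m never decreases f_pred for taxa above detection
        f1 = predicted_frequency(0.01, 500, 1e-4)
        f2 = predicted_frequency(0.01, 5000, 1e-4)
        assert f2 >= f1

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            predicted_frequency(1.5, 100, 1e-4)
        with pytest.raises(ParameterError):
            predicted_frequency(0.5, -1, 1e-4)


class TestWilsonInterval:
    def test_closed_form_value(self):
        low, high = wilson_interval(0.5, 10)
        assert low == pytest.approx(0.2366, abs=5e-4)
        assert high == pytest.approx(0.7634, abs=5e-4)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for count, n in [(3, 21), (0, 21), (21, 21), (10, 40)]:
            ours = wilson_interval(count / n, n)
            ref = proportion_confint(count, n, method="wilson")
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_boundaries(self):
        low, _ = wilson_interval(0.0, 7)
        assert low == 0.0
        _, high = wilson_interval(1.0, 7)
        assert high == 1.0

    def test_width_shrinks_with_n(self):
        widths = [np.diff(wilson_interval(0.3, n))[0] for n in (5, 20, 80, 320)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestFit:
    def test_self_consistency_exact(self):
        # frequencies generated from the model itself must be recovered exactly
        rng = np.random.default_rng(0)
        p = np.sort(rng.lognormal(-6, 1.5, 300))
        p = np.clip(p, 1e-6, 0.5)
        N, nm0 = 10_000, 1500.0
        f_obs = predicted_frequency(p, nm0, 1 / N)
        fit = fit_occupancy(p, f_obs, N)
        assert fit["Nm"] == pytest.approx(nm0, abs=1.0)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_objective_unimodal_on_grid(self):
        # the bounded minimizer must land on the dense-grid argmin
        pool = make_metacommunity(100, 1.5, 3)
        table = simulate_neutral_samples(pool, 2000, 0.2, 15, 2000, seed=3)
        fit = fit_ncm(table)
        st = occurrence_stats(table)
        p = np.clip(st.p.to_numpy(), 1e-12, 1 - 1e-12)
        f_obs = st.f_obs.to_numpy()
        grid = np.logspace(-6, 0, 4000)
        sse = [np.sum((f_obs - predicted_frequency(p, fit.N_ * m, 1 / fit.N_)) ** 2)
               for m in grid]
        m_grid = grid[int(np.argmin(sse))]
        assert abs(np.log(fit.m_) - np.log(m_grid)) < 2 * np.log(grid[1] / grid[0])

    def test_recovery_order_of_magnitude(self):
        # occupancy fits on read-sampled data recover Nm within a factor ~2
        pool = make_metacommunity(300, 1.5, 11)
        table = simulate_neutral_samples(pool, 10_000, 0.2, 21, 10_000, seed=11)
        fit = fit_ncm(table)
        assert 1000 < fit.Nm_ < 4000
        assert fit.r_squared_ >= 0.8

    def test_estimator_api(self):
        pool = make_metacommunity(60, 1.0, 1)
        table = simulate_neutral_samples(pool, 2000, 0.3, 12, 3000, seed=1)
        est = SloanNCM(detection_count=1)
        assert est.get_params()["detection_count"] == 1
        est.fit(table)
        assert est.Nm_ == pytest.approx(est.N_ * est.m_)
        assert est.r_squared_ <= 1
        assert sum(est.partition_counts_.values()) == est.n_taxa_
        rec = est.records_
        assert ((rec.ci_low <= rec.f_pred) & (rec.f_pred <= rec.ci_high)).all()
        # predict matches the records' f_pred
        assert est.predict(rec.p.iloc[0]) == pytest.approx(rec.f_pred.iloc[0], abs=1e-9)

    def test_constant_frequencies_undefined_r2(self):
        table = CountTable(np.ones((12, 5), dtype=int), [f"t{i}" for i in range(12)],
                           [f"s{j}" for j in range(5)])
        with pytest.raises(FitError):
            fit_ncm(table)

    def test_few_taxa_warns(self):
        table = CountTable([[5, 0, 3], [2, 4, 1], [0, 1, 2]], ["a", "b", "c"],
                           ["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="taxa"):
            fit_ncm(table)


class TestClassification:
    def test_all_neutral_when_obs_equals_pred(self):
        f = np.array([0.2, 0.5, 0.9])
        partition, counts = classify_taxa(f, f, n_samples=21)
        assert counts == {"above": 0, "neutral": 3, "below": 0}

    def test_far_outside_band_is_above(self):
        partition, _ = classify_taxa([1.0], [0.2], n_samples=21)
        assert partition[0] == "above"

    def test_neutral_simulation_mostly_inside_band(self):
        # the Wilson band is a prediction band for f_obs under the model;
        # with read sampling on top, the bulk of taxa should still fall inside
        pool = make_metacommunity(300, 1.5, 21)
        table = simulate_neutral_samples(pool, 10_000, 0.2, 21, 10_000, seed=21)
        fit = fit_ncm(table)
        assert fit.partition_counts_["neutral"] / fit.n_taxa_ > 0.5
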