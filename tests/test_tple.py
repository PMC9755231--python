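import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microtpl as m
from microtpl.tple import InsufficientDataError, MeanVariancePair, MeanVarianceSet

from conftest import make_table


def ols_oracle(x, y):
    """Closed-form two-variable least squares via the normal equations."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def mv_set(points, level="type_III"):
    pairs = [
        MeanVariancePair(M=p[0], V=p[1], unit_id=f"u{i}", n_values=10)
        for i, p in enumerate(points)
    ]
    return MeanVarianceSet(level=level, group_label="all", pairs=pairs, n_dropped=0)


class TestMeanVarianceConstruction:
    def test_type1_hand_values(self):
        # one sample whose 3 OTU abundances are 1, 2, 3: M=2, V=1 (n-1)
        t = make_table([[1], [2], [3]])
        mv = m.type1_mean_variance(t)
        assert len(mv.pairs) == 1
        assert mv.pairs[0].M == 2 and mv.pairs[0].V == 1

    def test_type1_constant_and_zero_columns_dropped(self):
        t = make_table([[5, 0, 1], [5, 0, 2], [5, 0, 3]])
        mv = m.type1_mean_variance(t)
        assert len(mv.pairs) == 1 and mv.n_dropped == 2

    def test_type1_needs_two_otus(self):
        with pytest.raises(InsufficientDataError):
            m.type1_mean_variance(make_table([[1, 2, 3]]))

    def test_type3_hand_values(self):
        t = make_table([[1, 3]])
        mv = m.type3_mean_variance(t)
        assert mv.pairs[0].M == 2 and mv.pairs[0].V == 2

    def test_type3_absent_and_constant_otus_dropped(self):
        t = make_table([[0, 0, 0], [4, 4, 4], [1, 2, 3]])
        mv = m.type3_mean_variance(t)
        assert len(mv.pairs) == 1 and mv.n_dropped == 2

    def test_type3_needs_two_samples(self):
        with pytest.raises(InsufficientDataError):
            m.type3_mean_variance(make_table([[1], [2]]))

    def test_population_variance_option(self):
        t = make_table([[1, 3]])
        assert m.type3_mean_variance(t, ddof=0).pairs[0].V == 1

    def test_min_prevalence_filter(self):
        t = make_table([[1, 0, 0, 2], [1, 2, 3, 4]])
        mv = m.type3_mean_variance(t, min_prevalence=3)
        assert [p.unit_id for p in mv.pairs] == ["OTU_2"]

    def test_subsetting_consistency(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.poisson(10, (20, 8)))
        subset = t.sample_ids[:4]
        direct = m.type1_mean_variance(t, sample_subset=subset)
        full = m.type1_mean_variance(t)
        by_filter = [p for p in full.pairs if p.unit_id in subset]
        assert [(p.unit_id, p.M, p.V) for p in direct.pairs] == [
            (p.unit_id, p.M, p.V) for p in by_filter]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.poisson(8, (15, 10)))
        perm = rng.permutation(t.otu_ids).tolist()
        shuffled = t.subset_otus(perm)
        f1 = m.fit_ple(m.type3_mean_variance(t))
        f2 = m.fit_ple(m.type3_mean_variance(shuffled))
        assert f1.b == pytest.approx(f2.b, abs=1e-12)
        assert f1.ln_a == pytest.approx(f2.ln_a, abs=1e-12)


class TestFitPle:
    def test_identity_line(self):
        fit = m.fit_ple(mv_set([(1, 1), (2, 2), (4, 4)]))
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.ln_a == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_quadratic_law(self):
        fit = m.fit_ple(mv_set([(1, 2), (2, 8), (4, 32)]))  # V = 2 M^2
        assert fit.b == pytest.approx(2.0, abs=1e-12)
        assert fit.ln_a == pytest.approx(math.log(2), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 40)
            M = np.exp(rng.uniform(-2, 5, n))
            V = np.exp(rng.uniform(-2, 5, n))
            fit = m.fit_ple(mv_set(list(zip(M, V))))
            slope, intercept = ols_oracle(np.log(M), np.log(V))
            assert fit.b == pytest.approx(slope, abs=1e-10)
            assert fit.ln_a == pytest.approx(intercept, abs=1e-10)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(12)
        M = np.exp(rng.uniform(0, 4, 30))
        V = M**1.7 * np.exp(rng.normal(0, 0.3, 30))
        fit = m.fit_ple(mv_set(list(zip(M, V))))
        assert fit.b_ci[0] <= fit.b <= fit.b_ci[1]
        assert 0 <= fit.r_squared <= 1

    def test_too_few_pairs_error_carries_group(self):
        with pytest.raises(InsufficientDataError) as exc:
            m.fit_ple(mv_set([(1, 1), (2, 2)]))
        assert exc.value.group_label == "all"

    @given(
        b=st.floats(0.2, 3.0), ln_a=st.floats(-2, 2),
        c=st.floats(0.01, 100), seed=st.integers(0, 2**16),
    )
    def test_scale_covariance(self, b, ln_a, c, seed):
        # multiplying abundances by c maps (M, V) -> (cM, c^2 V):
        # slope unchanged, intercept shifts by (2 - b) ln c
        rng = np.random.default_rng(seed)
        M = np.exp(rng.uniform(0, 4, 12))
        V = np.exp(ln_a) * M**b
        base = m.fit_ple(mv_set(list(zip(M, V))))
        scaled = m.fit_ple(mv_set(list(zip(c * M, c**2 * V))))
        assert scaled.b == pytest.approx(base.b, abs=1e-6)
        assert scaled.ln_a == pytest.approx(base.ln_a + (2 - base.b) * math.log(c), abs=1e-6)

    def test_exact_recovery_invariant(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            b, ln_a = rng.uniform(0.3, 3), rng.uniform(-3, 3)
            M = np.exp(rng.uniform(-1, 5, rng.integers(3, 50)))
            fit = m.fit_ple(mv_set(list(zip(M, np.exp(ln_a) * M**b))))
            assert fit.b == pytest.approx(b, abs=1e-9)
            assert fit.ln_a == pytest.approx(ln_a, abs=1e-9)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestGroupedFits:
    def test_two_species_two_fits(self, small_study):
        study, _ = small_study
        res = m.grouped_fits(study, "type_III", "host_species")
        labels = {f.group_label for f in res.fits}
        assert labels == set(study.species_groups())
        assert res.failures == {}

    def test_group_by_all_single_fit(self, small_study):
        study, _ = small_study
        res = m.grouped_fits(study, "type_I", "all")
        assert len(res.fits) == 1 and res.fits[0].group_label == "all"

    def test_unfittable_group_reported(self):
        # species Y has two identical samples: every Type-III pair has V=0
        t = make_table([[1, 2, 5, 5], [3, 1, 7, 7], [2, 4, 1, 1], [6, 2, 3, 3]])
        meta = [
            m.SampleMetadata("S1", "X", "A", m.Morphometrics(1, 1, 2)),
            m.SampleMetadata("S2", "X", "A", m.Morphometrics(1, 1, 2)),
            m.SampleMetadata("S3", "Y", "A", m.Morphometrics(1, 1, 2)),
            m.SampleMetadata("S4", "Y", "A", m.Morphometrics(1, 1, 2)),
        ]
        study = m.join_tables(t, meta)
        res = m.grouped_fits(study, "type_III", "host_species")
        assert "Y" in res.failures and all(f.group_label == "X" for f in res.fits)

    def test_every_group_failing_is_error(self):
        t = make_table([[5, 5], [5, 5]])
        meta = [
            m.SampleMetadata("S1", "X", "A", m.Morphometrics(1, 1, 2)),
            m.SampleMetadata("S2", "X", "A", m.Morphometrics(1, 1, 2)),
        ]
        with pytest.raises(InsufficientDataError):
            m.grouped_fits(m.join_tables(t, meta), "type_III", "host_species")


class TestClassification:
    def fit(self, b, lo, hi):
        return m.PleFit("type_I", "g", b, 0.0, 0.9, (lo, hi), 10, 0.001)

    def test_aggregated_by_ci(self):
        hc = m.classify_heterogeneity(self.fit(1.8, 1.5, 2.1), "ci_test")
        assert hc.category == "aggregated"

    def test_random_point_estimate_at_unity(self):
        hc = m.classify_heterogeneity(self.fit(1.0, 0.8, 1.2), "point_estimate")
        assert hc.category == "random"

    def test_uniform_by_ci(self):
        hc = m.classify_heterogeneity(self.fit(0.6, 0.4, 0.8), "ci_test")
        assert hc.category == "uniform"

    def test_ci_straddling_unity_is_random(self):
        hc = m.classify_heterogeneity(self.fit(1.3, 0.9, 1.7), "ci_test")
        assert hc.category == "random"

    @pytest.mark.parametrize("b,expected", [(0.4, "uniform"), (2.3, "aggregated")])
    def test_point_estimate_sides(self, b, expected):
        hc = m.classify_heterogeneity(self.fit(b, b - 0.1, b + 0.1), "point_estimate")
        assert hc.category == expected
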