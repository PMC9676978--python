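"""Kaplan-Meier estimation, the log-rank test, and the batch prognostic screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from herbnet.geneset_ops import GeneSet
from herbnet.survival_screen import (
    DegenerateSplitError,
    SurvivalCohort,
    km_estimate,
    logrank_test,
    median_split,
    survival_screen,
)

from _oracles import oracle_logrank


class TestMedianSplit:
    def test_even_distinct_values(self):
        high = median_split([1, 2, 3, 4])
        assert high.tolist() == [False, False, True, True]

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_split([5, 5, 5])

    def test_ties_at_top_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            median_split([1, 2, 2])  # nothing exceeds the median

    def test_group_sizes_match_sort_and_partition_oracle(self, rng):
        v = rng.normal(size=1001)
        high = median_split(v)
        expected_high = (np.sort(v)[::-1] > np.median(v)).sum()
        assert high.sum() == expected_high
        assert (~high).sum() == 1001 - expected_high
        assert v[high].min() > v[~high].max()


class TestKMEstimate:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert km.empty  # no event times, S(t) = 1 everywhere

    def test_product_limit_by_hand_all_events(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_removes_from_risk_set(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        # after t=1: 2/3; the censored subject leaves; at t=3 risk set is 1
        assert km["survival"].tolist() == pytest.approx([2 / 3, 0.0])
        assert km["n_at_risk"].tolist() == [3, 1]

    def test_step_function_invariants(self, rng):
        t = rng.exponential(100, size=200)
        e = rng.integers(0, 2, size=200)
        km = km_estimate(t, e)
        s = km["survival"].to_numpy()
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()  # nonincreasing

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(100, size=150)
        e = rng.integers(0, 2, size=150)
        km = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for ti, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx(kmf.predict(ti), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrankTest:
    def test_identical_groups_null(self):
        t, e = [1, 3, 5, 7], [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_worked_oev_table(self):
        # A events at 1,2; B events at 3,4: O_A=2, E_A=1/2+1/3, V=1/4+2/9
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-12)
        from scipy.stats import chi2 as chi2_dist
        assert p == pytest.approx(float(chi2_dist.sf(49 / 17, 1)), abs=1e-12)

    def test_zero_events_convention(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_symmetric_under_group_swap(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(20, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        assert logrank_test(ta, ea, tb, eb)[0] == pytest.approx(logrank_test(tb, eb, ta, ea)[0])

    def test_matches_independent_oev_oracle(self, rng):
        for _ in range(30):
            na, nb = int(rng.integers(3, 30)), int(rng.integers(3, 30))
            ta, tb = rng.exponential(10, na), rng.exponential(15, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            got = logrank_test(ta, ea, tb, eb)
            exp = oracle_logrank(ta, ea, tb, eb)
            assert got[0] == pytest.approx(exp[0], abs=1e-10)
            assert got[1] == pytest.approx(exp[1], abs=1e-10)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank
        for _ in range(10):
            ta, tb = rng.exponential(10, 40), rng.exponential(25, 40)
            ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_rank_consistent_with_permutation_reference(self, rng):
        """On tiny cohorts the chi-square p must order datasets like an exact
        permutation distribution of the statistic."""
        results = []
        for _ in range(50):
            ta, tb = rng.exponential(5, 4), rng.exponential(15, 4)
            ea = eb = np.ones(4, dtype=int)
            chi2, p = logrank_test(ta, ea, tb, eb)
            pooled = np.concatenate([ta, tb])
            stats = []
            for idx in itertools.combinations(range(8), 4):
                mask = np.zeros(8, dtype=bool)
                mask[list(idx)] = True
                stats.append(logrank_test(pooled[mask], np.ones(4, int),
                                          pooled[~mask], np.ones(4, int))[0])
            perm_p = np.mean(np.array(stats) >= chi2 - 1e-12)
            results.append((p, perm_p))
        asym = np.array([r[0] for r in results])
        perm = np.array([r[1] for r in results])
        rho = np.corrcoef(np.argsort(np.argsort(asym)), np.argsort(np.argsort(perm)))[0, 1]
        assert rho > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])


def _cohort_from(rng, n, genes, hr_genes=()):
    from herbnet.synthetic_data import SynthConfig, gen_survival

    cfg = SynthConfig(seed=int(rng.integers(2**31)), n_patients=n,
                      hazard_ratios=tuple(hr_genes), n_null_genes=len(genes))
    return gen_survival(cfg)[0]


class TestSurvivalScreen:
    def test_vacuous_alpha_returns_every_nondegenerate_gene(self, rng):
        cohort = _cohort_from(rng, 50, [f"g{i}" for i in range(5)])
        out = survival_screen(cohort, list(cohort.expression.columns), alpha=1.0)
        assert len(out.passing) == len(cohort.expression.columns)
        assert out.skipped == ()

    def test_missing_gene_reported_not_fatal(self, rng):
        cohort = _cohort_from(rng, 30, ["g0"])
        out = survival_screen(cohort, ["NULL0000", "ABSENT"], alpha=1.0)
        assert "ABSENT" in out.skipped
        assert len(out.passing) == 1

    def test_stricter_alpha_is_subset(self, rng):
        cohort = _cohort_from(rng, 100, [f"g{i}" for i in range(20)])
        genes = list(cohort.expression.columns)
        loose = {r.gene for r in survival_screen(cohort, genes, alpha=0.5).passing}
        strict = {r.gene for r in survival_screen(cohort, genes, alpha=0.05).passing}
        assert strict <= loose

    def test_full_table_carries_both_threshold_flags(self, rng):
        cohort = _cohort_from(rng, 60, [f"g{i}" for i in range(6)])
        out = survival_screen(cohort, list(cohort.expression.columns), alpha=0.05)
        t = out.table
        assert list(t.columns) == ["gene", "n_low", "n_high", "chi2", "p", "pass_0.05", "pass_0.01"]
        assert (t["pass_0.05"] == (t["p"] < 0.05)).all()
        assert (t["n_low"] + t["n_high"] == cohort.n_patients).all()
        assert t["gene"].is_monotonic_increasing

    def test_planted_hazard_gene_detected(self):
        from herbnet.synthetic_data import SynthConfig, gen_survival

        hits = 0
        for seed in range(20):
            cohort, planted = gen_survival(SynthConfig(seed=seed, n_patients=200,
                                                       hazard_ratios=(("PLANTED1", 3.0),)))
            out = survival_screen(cohort, planted, alpha=0.05)
            hits += any(r.gene == "PLANTED1" for r in out.passing)
        assert hits >= 16  # >= 80% power at HR 3, n = 200

    def test_cohort_validation(self):
        clin = pd.DataFrame({"patient_id": ["a"], "time": [-1.0], "event": [1]})
        expr = pd.DataFrame({"g": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="nonnegative"):
            SurvivalCohort(clin, expr)
        clin2 = pd.DataFrame({"patient_id": ["a"], "time": [1.0], "event": [2]})
        with pytest.raises(ValueError, match="0/1"):
            SurvivalCohort(clin2, expr)

    def test_accepts_geneset_input(self, rng):
        cohort = _cohort_from(rng, 40, ["g0"])
        out = survival_screen(cohort, GeneSet("g", frozenset({"null0000"})), alpha=1.0)
        assert out.passing[0].gene == "NULL0000"
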