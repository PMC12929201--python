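"""Contingency building and the four disproportionality statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from gapvigil.disproportionality import (
    ContingencyTable,
    MgpsPrior,
    ReportDatabase,
    build_contingency,
    contingency_tables,
    ebgm_with_bound,
    fit_mgps_prior,
    fit_mgps_prior_counts,
    ic_with_bound,
    prr_with_bound,
    ror_with_bound,
    screen_signals,
)


def _db(rows):
    return ReportDatabase([
        (f"r{i}", "0-2y", frozenset(d), frozenset(e))
        for i, (d, e) in enumerate(rows)
    ])


class TestContingency:
    def test_singleton_report(self):
        t = build_contingency(_db([({"D"}, {"E"})]), "D", "E")
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 0, 0, 0)

    def test_cells_partition_reports(self):
        db = _db([({"D"}, {"E"}), ({"D"}, {"X"}), ({"Y"}, {"E"}),
                  ({"Y"}, {"X"}), ({"D", "Y"}, {"E", "X"})])
        t = build_contingency(db, "D", "E")
        assert t.total == len(db)
        assert (t.n11, t.n10, t.n01, t.n00) == (2, 1, 1, 1)

    def test_absent_drug_gives_zero_n11(self):
        t = build_contingency(_db([({"D"}, {"E"})]), "Q", "E")
        assert t.n11 == 0

    def test_vectorized_tables_match_single(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(200):
            drugs = {f"d{i}" for i in rng.choice(5, rng.integers(1, 4),
                                                 replace=False)}
            events = {f"e{i}" for i in rng.choice(6, rng.integers(1, 4),
                                                  replace=False)}
            rows.append((drugs, events))
        db = _db(rows)
        tables = contingency_tables(db)
        for pair in [("d0", "e0"), ("d3", "e5"), ("d1", "e2")]:
            assert tables[pair] == build_contingency(db, *pair)

    def test_duplicate_report_ids_rejected(self):
        with pytest.raises(ValueError):
            ReportDatabase([("r", "", frozenset("a"), frozenset("b"))] * 2)

    def test_empty_drugset_rejected(self):
        with pytest.raises(ValueError):
            ReportDatabase([("r", "", frozenset(), frozenset("b"))])


class TestPrr:
    def test_direct_formula_example(self):
        prr, _ = prr_with_bound(ContingencyTable(25, 75, 25, 875))
        assert prr == pytest.approx(9.0)

    def test_equal_proportions_give_one(self):
        prr, _ = prr_with_bound(ContingencyTable(10, 90, 50, 450))
        assert prr == pytest.approx(1.0)

    def test_scaling_cells_preserves_prr_and_tightens_bound(self):
        t1 = ContingencyTable(5, 15, 20, 60)
        t10 = ContingencyTable(50, 150, 200, 600)
        p1, lo1 = prr_with_bound(t1)
        p10, lo10 = prr_with_bound(t10)
        assert p1 == pytest.approx(p10)
        assert lo10 > lo1

    def test_matches_log_scale_bound_formula(self):
        t = ContingencyTable(12, 88, 40, 860)
        prr, lo = prr_with_bound(t)
        se = math.sqrt(1 / 12 - 1 / 100 + 1 / 40 - 1 / 900)
        assert lo == pytest.approx(math.exp(math.log(prr) - 1.959963984540054 * se))

    def test_zero_cell_bound_undefined_without_correction(self):
        prr, lo = prr_with_bound(ContingencyTable(0, 10, 5, 85))
        assert prr == 0.0 and math.isnan(lo)

    def test_continuity_correction_defines_bound(self):
        prr, lo = prr_with_bound(ContingencyTable(0, 10, 5, 85),
                                 continuity_correction=True)
        assert math.isfinite(lo)


class TestRor:
    def test_proportional_table_gives_one(self):
        ror, _ = ror_with_bound(ContingencyTable(10, 20, 30, 60))
        assert ror == pytest.approx(1.0)

    def test_direct_formula_example(self):
        ror, _ = ror_with_bound(ContingencyTable(20, 10, 10, 20))
        assert ror == pytest.approx(4.0)

    def test_transpose_symmetry(self):
        t = ContingencyTable(7, 13, 29, 451)
        tt = ContingencyTable(7, 29, 13, 451)
        assert ror_with_bound(t)[0] == pytest.approx(ror_with_bound(tt)[0])

    def test_rare_event_prr_ror_equivalence(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n11 = int(rng.integers(5, 30))
            n10 = int(rng.integers(5000, 20000))
            n01 = int(rng.integers(5, 60))
            n00 = int(rng.integers(50000, 200000))
            t = ContingencyTable(n11, n10, n01, n00)
            prr, _ = prr_with_bound(t)
            ror, _ = ror_with_bound(t)
            assert ror == pytest.approx(prr, rel=0.05)


class TestIc:
    def test_observed_equals_expected_gives_zero(self):
        # margins chosen so E = n11 exactly: E = 20*50/100 = 10
        t = ContingencyTable(10, 10, 40, 40)
        ic, ic025 = ic_with_bound(t)
        assert ic == 0.0
        assert ic025 < ic

    def test_lower_bound_below_point_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 500, 4)))
            ic, ic025 = ic_with_bound(t)
            assert ic025 < ic

    def test_matches_monte_carlo_posterior(self):
        t = ContingencyTable(100, 900, 400, 48600)
        ic, ic025 = ic_with_bound(t)
        rng = np.random.default_rng(3)
        draws = rng.gamma(t.n11 + 0.5, 1.0, 1_000_000) / (t.expected + 0.5)
        assert ic025 == pytest.approx(np.quantile(np.log2(draws), 0.025),
                                      abs=0.01)

    def test_monotone_in_n11_with_margins_fixed(self):
        # raising n11 while holding margins raises every point estimate
        def table(n11):
            return ContingencyTable(n11, 100 - n11, 200 - n11, 10000 + n11)

        stats_seq = []
        prior = MgpsPrior(1.0, 1.0, 2.0, 2.0, 0.5)
        for n11 in (10, 30, 60, 90):
            t = table(n11)
            stats_seq.append((
                prr_with_bound(t)[0], ror_with_bound(t)[0],
                ic_with_bound(t)[0], ebgm_with_bound(t, prior)[0]))
        arr = np.array(stats_seq)
        assert (np.diff(arr, axis=0) > 0).all()


class TestMgps:
    def test_parameter_recovery_from_known_prior(self):
        # average estimates over a few seeds to tame sampling noise in the
        # heavy-tail rate parameter
        fits = []
        for seed in range(3):
            rng = np.random.default_rng(7 + seed)
            e = np.exp(rng.uniform(np.log(0.5), np.log(100), 5000))
            comp = rng.choice(2, size=5000, p=[1 / 3, 2 / 3])
            shape = np.where(comp == 0, 0.2, 2.0)
            rate = np.where(comp == 0, 0.1, 4.0)
            n = rng.poisson(rng.gamma(shape, 1.0 / rate) * e)
            fits.append(fit_mgps_prior_counts(n, e).as_tuple())
        mean = np.mean(fits, axis=0)
        # canonical order puts the low-mean component first
        truth = (2.0, 4.0, 0.2, 0.1, 2 / 3)
        for got, want in zip(mean, truth):
            assert got == pytest.approx(want, rel=0.25)

    def test_null_poisson_data_concentrates_near_one(self):
        rng = np.random.default_rng(8)
        e = np.exp(rng.uniform(np.log(1), np.log(200), 4000))
        n = rng.poisson(e)  # lambda = 1 everywhere
        prior = fit_mgps_prior_counts(n, e)
        assert 0.8 <= prior.mean <= 1.2

    def test_single_component_reduces_to_one_gamma_fit(self):
        rng = np.random.default_rng(9)
        e = np.exp(rng.uniform(np.log(1), np.log(50), 4000))
        lam = rng.gamma(2.0, 1.0 / 2.0, 4000)
        n = rng.poisson(lam * e)
        prior = fit_mgps_prior_counts(n, e)
        # both fitted components should describe the single true gamma:
        # mixture mean matches the true mean alpha/beta = 1
        assert prior.mean == pytest.approx(1.0, rel=0.1)

    def test_fit_requires_multiple_pairs(self):
        with pytest.raises(ValueError):
            fit_mgps_prior([ContingencyTable(1, 2, 3, 4)])


class TestEbgm:
    def test_degenerate_prior_pins_ebgm_to_one(self):
        prior = MgpsPrior(1e6, 1e6, 1e6, 1e6, 0.5)
        t = ContingencyTable(200, 300, 100, 5000)
        ebgm, eb05 = ebgm_with_bound(t, prior)
        assert ebgm == pytest.approx(1.0, abs=0.01)

    def test_large_count_limit_approaches_observed_ratio(self):
        prior = MgpsPrior(0.5, 0.5, 1.0, 1.0, 0.5)  # diffuse
        t = ContingencyTable(10_000, 10_000, 1000, 979_000)
        # E = 20000*11000/10**6 = 220 -> ratio ~ 45; use explicit E ratio
        ebgm, _ = ebgm_with_bound(t, prior)
        assert ebgm == pytest.approx(t.n11 / t.expected, rel=0.01)

    def test_eb05_below_ebgm_and_matches_monte_carlo(self):
        from gapvigil.disproportionality import _posterior_mixture

        prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 400, 4)))
            ebgm, eb05 = ebgm_with_bound(t, prior)
            assert eb05 < ebgm
            a, b, w = _posterior_mixture(t, prior)
            comp = rng.choice(2, size=400_000, p=w)
            draws = rng.gamma(a[comp], 1.0) / b[comp]
            assert eb05 == pytest.approx(np.quantile(draws, 0.05), abs=0.02)

    def test_shrinkage_toward_prior_between_bounds(self):
        prior = MgpsPrior(2.0, 2.0, 2.0, 2.0, 0.5)  # prior mean 1
        t = ContingencyTable(30, 70, 10, 890)  # observed ratio n11/E = 7.5
        ebgm, _ = ebgm_with_bound(t, prior)
        assert 1.0 < ebgm < t.n11 / t.expected


class TestScreen:
    def test_signal_rule_is_conjunction_of_strict_inequalities(self):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(3000):
            drugs = {f"d{i}" for i in rng.choice(4, rng.integers(1, 3),
                                                 replace=False)}
            events = {f"e{i}" for i in rng.choice(5, rng.integers(1, 3),
                                                  replace=False)}
            rows.append((drugs, events))
        db = _db(rows)
        for d in screen_signals(db):
            s = d.stats
            if d.reason is None:
                expected = (s.ic025 > 0 and s.prr025 > 1 and s.ror025 > 1
                            and s.eb05 > 1)
                assert d.is_signal == expected
            else:
                assert not d.is_signal

    def test_injected_pair_is_flagged(self):
        from gapvigil.simulate import SimConfig, gen_report_database

        cfg = SimConfig(seed=21, n_reports=20_000,
                        injected_signals=(("drugalfa", "event rash", 10.0),))
        db, truth = gen_report_database(cfg)
        decisions = {(d.drug, d.event): d for d in screen_signals(db)}
        assert decisions[("drugalfa", "event rash")].is_signal
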