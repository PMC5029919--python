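from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adindex import (
    PollutantSeries,
    adi,
    adi_naive,
    build_fraction_table,
    build_stl,
    evaluate,
    evaluate_vectors,
    select_term_set,
    term_stats,
    znormalize,
)
from adindex.adi_index import FinalTermSet
from adindex.ngrams import TermFractionTable

from conftest import CITY, DAY0, make_corpus


def _dates(n):
    return [DAY0 + timedelta(days=i) for i in range(n)]


def _table_from_fracs(frac_by_term, base=100):
    """Build a fraction table directly from {term: [fractions...]} with a common base."""
    n = len(next(iter(frac_by_term.values())))
    dates = _dates(n)
    counts = {
        t: {d: int(round(f * base)) for d, f in zip(dates, fr) if f > 0}
        for t, fr in frac_by_term.items()
    }
    return TermFractionTable(city=CITY, base_post_count={d: base for d in dates}, counts=counts)


class TestZnormalize:
    def test_hand_computed_example(self):
        # population sd of (1,2,3) is sqrt(2/3); z = (-1.2247, 0, 1.2247)
        z = znormalize([1.0, 2.0, 3.0])
        assert z == pytest.approx([-1.224744871391589, 0.0, 1.224744871391589], abs=1e-9)

    def test_already_standardized_unchanged(self):
        v = np.array([-1.0, 1.0, -1.0, 1.0])
        assert znormalize(v) == pytest.approx(v, abs=1e-12)

    def test_constant_gives_zero_vector_with_flag(self):
        z, flag = znormalize([5.0, 5.0, 5.0], return_flag=True)
        assert flag
        assert z == pytest.approx([0.0, 0.0, 0.0])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200).filter(
            lambda v: max(v) - min(v) > 1e-6 * (1 + max(abs(x) for x in v))
        )
    )
    def test_mean_zero_variance_one(self, v):
        z = znormalize(v)
        assert abs(float(z.mean())) < 1e-12
        assert abs(float(np.mean(z**2)) - 1.0) < 1e-10

    def test_too_short(self):
        with pytest.raises(ValueError):
            znormalize([1.0])


class TestAdiNaive:
    def test_single_positive_term(self):
        table = _table_from_fracs({"t": [0.05, 0.10]})
        series = adi_naive(table, [("t", +1)])
        assert series.values[DAY0] == pytest.approx(0.05)

    def test_opposite_terms_cancel(self):
        table = _table_from_fracs({"a": [0.04, 0.02], "b": [0.04, 0.02]})
        series = adi_naive(table, [("a", +1), ("b", -1)])
        assert all(v == pytest.approx(0.0) for v in series.values.values())

    def test_three_term_hand_sum(self):
        table = _table_from_fracs(
            {"a": [0.10, 0.20, 0.30], "b": [0.05, 0.05, 0.05], "c": [0.02, 0.01, 0.04]}
        )
        series = adi_naive(table, [("a", +1), ("b", +1), ("c", -1)])
        dates = _dates(3)
        assert series.values[dates[0]] == pytest.approx(0.10 + 0.05 - 0.02)
        assert series.values[dates[1]] == pytest.approx(0.20 + 0.05 - 0.01)
        assert series.values[dates[2]] == pytest.approx(0.30 + 0.05 - 0.04)


class TestAdi:
    def test_single_positive_term_equals_znormalize(self):
        fr = [0.01, 0.05, 0.03, 0.08]
        table = _table_from_fracs({"t": fr})
        series = adi(table, [("t", +1)])
        assert series.vector(_dates(4)) == pytest.approx(znormalize(fr), abs=1e-12)

    def test_opposite_signs_cancel_exactly(self):
        fr = [0.01, 0.05, 0.03]
        table = _table_from_fracs({"a": fr, "b": fr})
        series = adi(table, [("a", +1), ("b", -1)])
        assert series.vector() == pytest.approx(np.zeros(3), abs=1e-12)

    def test_five_term_brute_force_oracle(self, rng):
        fracs = {f"t{i}": rng.uniform(0.0, 0.2, size=12).round(2) for i in range(5)}
        signs = [+1, -1, +1, +1, -1]
        table = _table_from_fracs(fracs)
        term_set = list(zip(fracs, signs))
        series = adi(table, term_set)
        # independent recomputation: plain loops over z-scores
        dates = _dates(12)
        expected = np.zeros(12)
        for (t, s) in term_set:
            v = np.array([table.fraction(t, d) for d in dates])
            sd = np.sqrt(np.mean((v - v.mean()) ** 2))
            if sd > 0:
                expected += s * (v - v.mean()) / sd
        assert series.vector(dates) == pytest.approx(expected, abs=1e-10)

    def test_reference_period_stats_applied_elsewhere(self):
        fr = [0.02, 0.04, 0.06, 0.10, 0.20]
        table = _table_from_fracs({"t": fr})
        dates = _dates(5)
        stats = term_stats(table, ["t"], dates[:3])  # mean 0.04, pop sd of (.02,.04,.06)
        series = adi(table, [("t", +1)], dates=dates, stats=stats)
        mean, sd = stats["t"]
        assert mean == pytest.approx(0.04)
        assert series.values[dates[4]] == pytest.approx((0.20 - mean) / sd)

    def test_missing_term_named_in_error(self):
        table = _table_from_fracs({"t": [0.1, 0.2]})
        with pytest.raises(KeyError, match="ghost"):
            adi(table, [("ghost", +1)])

    def test_empty_term_set_all_zero(self):
        table = _table_from_fracs({"t": [0.1, 0.2]})
        assert adi(table, []).vector() == pytest.approx(np.zeros(2))

    def test_degenerate_term_contributes_nothing(self):
        table = _table_from_fracs({"flat": [0.1, 0.1, 0.1], "t": [0.1, 0.2, 0.3]})
        both = adi(table, [("t", +1), ("flat", +1)])
        alone = adi(table, [("t", +1)])
        assert both.vector() == pytest.approx(alone.vector(), abs=1e-12)


def brute_force_evaluate(adi_vec, p_vec, folds=4):
    """From-scratch reimplementation with statsmodels fits and explicit slicing."""
    import statsmodels.api as sm
    from scipy import stats

    a = np.asarray(adi_vec, float)
    p = np.asarray(p_vec, float)
    n = len(a)
    sizes = [n // folds + (1 if i < n % folds else 0) for i in range(folds)]
    edges = np.cumsum([0] + sizes)
    rs = []
    for i in range(folds):
        sec = list(range(edges[i], edges[i + 1]))
        rest = [j for j in range(n) if j not in sec]
        res = sm.OLS(p[rest], sm.add_constant(a[rest])).fit()
        pred = res.params[0] + res.params[1] * a[sec]
        if np.ptp(pred) == 0 or np.ptp(p[sec]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(pred, p[sec]).statistic))
    return rs, float(np.mean(rs))


class TestEvaluate:
    def test_identical_series_scores_one(self, rng):
        p = rng.uniform(20, 300, size=16)
        section_r, mean_r = evaluate_vectors(p.copy(), p)
        assert section_r == pytest.approx([1.0] * 4)
        assert mean_r == pytest.approx(1.0)

    def test_independent_index_scores_near_zero(self, rng):
        p = rng.uniform(20, 300, size=200)
        a = rng.normal(size=200)
        _, mean_r = evaluate_vectors(a, p)
        assert abs(mean_r) < 0.3

    def test_twelve_day_fixture_matches_independent_oracle(self, rng):
        a = rng.normal(size=12)
        p = 60 + 25 * a + rng.normal(scale=10, size=12)
        section_r, mean_r = evaluate_vectors(a, p)
        rs, want = brute_force_evaluate(a, p)
        assert section_r == pytest.approx(rs, abs=1e-10)
        assert mean_r == pytest.approx(want, abs=1e-10)

    def test_affine_invariance(self, rng):
        a = rng.normal(size=40)
        p = 60 + 25 * a + rng.normal(scale=15, size=40)
        _, base = evaluate_vectors(a, p)
        _, scaled = evaluate_vectors(4.2 * a + 17.0, p)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_degenerate_section_scores_zero(self):
        a = np.concatenate([np.zeros(4), np.arange(12, dtype=float)])
        p = np.arange(16, dtype=float)
        section_r, _ = evaluate_vectors(a, p)
        assert section_r[0] == 0.0  # constant predictions on the first section

    def test_section_boundaries_partition_dates(self, rng):
        fr = rng.uniform(0, 0.2, size=13)
        table = _table_from_fracs({"t": fr})
        dates = _dates(13)
        pm = dict(zip(dates, rng.uniform(10, 200, size=13)))
        series = PollutantSeries(city=CITY, observations=pm)
        res = evaluate([("t", +1)], table, series)
        covered = []
        for i, b in enumerate(res.section_boundaries):
            assert b.start <= b.end
            if i:
                assert b.start > res.section_boundaries[i - 1].end
            covered.extend(d for d in dates if d in b)
        assert covered == dates
        assert res.mean_r == pytest.approx(float(np.mean(res.section_r)))

    def test_too_few_days(self):
        with pytest.raises(ValueError):
            evaluate_vectors(np.arange(7.0), np.arange(7.0))


class TestSelectTermSet:
    def _setup(self, rng, n_days=40):
        pm = rng.uniform(20, 300, size=n_days)
        good = 0.001 * pm  # perfectly predictive fraction
        noise = {f"n{i}": rng.uniform(0, 0.1, size=n_days) for i in range(6)}
        table = _table_from_fracs({"good": good, **noise}, base=1000)
        dates = _dates(n_days)
        series = PollutantSeries(city=CITY, observations=dict(zip(dates, map(float, pm))))
        return table, series

    def test_single_perfect_term_selected(self, rng):
        table, series = self._setup(rng)
        stl = build_stl(table, series, list(table.counts))
        fts = select_term_set(stl, table, series, top_n=7)
        assert stl.entries[0].term == "good"
        assert "good" in fts.terms
        assert fts.best_score > 0.99

    def test_acceptance_trace_monotone(self, rng):
        table, series = self._setup(rng)
        stl = build_stl(table, series, list(table.counts))
        fts = select_term_set(stl, table, series, top_n=7)
        trace = np.array(fts.trace)
        assert len(trace) == 7
        assert np.all(np.diff(trace) >= 0)
        assert fts.best_score == pytest.approx(trace[-1])

    def test_selected_set_evaluation_equals_best_score(self, rng):
        table, series = self._setup(rng)
        stl = build_stl(table, series, list(table.counts))
        fts = select_term_set(stl, table, series, top_n=7)
        res = evaluate(fts.term_set, table, series, dates=_dates(40))
        assert res.mean_r == pytest.approx(fts.best_score, abs=1e-10)

    def test_constant_pm_accepts_nothing(self, rng):
        table, _ = self._setup(rng)
        dates = _dates(40)
        series = PollutantSeries(city=CITY, observations={d: 77.0 for d in dates})
        stl = build_stl(table, series, list(table.counts))
        fts = select_term_set(stl, table, series, top_n=7)
        assert fts.entries == []
        assert fts.best_score == 0.0

    def test_tsv_roundtrip(self, tmp_path, rng):
        table, series = self._setup(rng)
        stl = build_stl(table, series, list(table.counts))
        fts = select_term_set(stl, table, series, top_n=7)
        fts.write_tsv(tmp_path / "fts.tsv")
        back = FinalTermSet.read_tsv(tmp_path / "fts.tsv", city=CITY)
        assert back.entries == fts.entries
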