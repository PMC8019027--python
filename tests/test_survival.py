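"""Staggered-entry KM, known-fate likelihood, AICc ranking and averaging."""

import math

import numpy as np
import pytest

from bearvitals.data import ValidationError
from bearvitals.survival import (aicc_table, build_risk_table, fit_known_fate,
                                 kaplan_meier, model_average)
from conftest import make_history


def _grid_mle(alive, dead, lo=0.5, hi=1.0, step=1e-4):
    """Brute-force grid maximizer of the Bernoulli interval likelihood."""
    best_s, best_ll = None, -np.inf
    for s in np.arange(lo, hi, step):
        ll = alive * math.log(s) + (dead * math.log(1 - s) if dead else 0.0)
        if ll > best_ll:
            best_s, best_ll = s, ll
    return best_s


class TestRiskTable:
    def test_hand_tally_with_death_and_censor(self):
        hists = [make_history("b1", "aad"), make_history("b2", "aaaac")]
        risk = build_risk_table(hists)
        tab = risk.set_index("interval")
        assert list(tab["n_at_risk"]) == [2, 2, 2, 1, 1]
        assert tab.loc[3, "n_deaths"] == 1
        assert tab.loc[5, "n_censored"] == 1

    def test_empty_input_gives_empty_table(self):
        assert build_risk_table([]).empty

    def test_column_sum_equals_total_monitored_intervals(self):
        hists = [make_history(f"b{i}", "a" * (i + 3)) for i in range(5)]
        risk = build_risk_table(hists)
        assert risk["n_at_risk"].sum() == sum(h.n_monitored_intervals
                                              for h in hists)

    def test_population_grouping_splits_rows(self):
        hists = [make_history("b1", "aa", population="MM"),
                 make_history("b2", "aa", population="NSN")]
        risk = build_risk_table(hists, grouping="population")
        assert set(risk["group"]) == {"MM", "NSN"}


class TestKaplanMeier:
    def test_matches_hand_computed_product_limit(self):
        # intervals: n=(3,3,2), d=(1,0,1) -> S = (2/3)(1)(1/2) = 1/3
        hists = [make_history("b1", "daa"[:1]),  # dies interval 1
                 make_history("b2", "aad"),
                 make_history("b3", "aaa")]
        est = kaplan_meier(build_risk_table(hists))["all"]
        assert est.annual_s == pytest.approx((2 / 3) * 1.0 * (1 / 2))

    def test_no_censoring_equals_empirical_survivor_fraction(self):
        # 10 bears each monitored one interval, 3 die
        hists = [make_history(f"b{i}", "d" if i < 3 else "a")
                 for i in range(10)]
        est = kaplan_meier(build_risk_table(hists))["all"]
        assert est.annual_s == pytest.approx(0.7)

    def test_zero_deaths_boundary_ci(self, example_encounters):
        mm = [h for h in example_encounters if h.population == "MM"]
        est = kaplan_meier(build_risk_table(mm))["all"]
        assert est.annual_s == 1.0
        assert est.ci_high == 1.0
        assert round(est.ci_low, 2) == 0.96  # 345 intervals, 0 deaths

    def test_all_die_first_interval(self):
        hists = [make_history(f"b{i}", "d") for i in range(4)]
        est = kaplan_meier(build_risk_table(hists))["all"]
        assert est.annual_s == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(ValidationError):
            kaplan_meier(build_risk_table([]))


class TestKnownFate:
    def test_closed_form_binomial_mle(self):
        # 26 bear-intervals, 5 deaths -> s = 21/26
        hists = [make_history(f"b{i}", "aaaad") for i in range(5)]
        hists.append(make_history("c0", "a"))
        m = fit_known_fate(hists, "null")
        cell = m.cells["all"]
        assert cell.n == 26 and cell.deaths == 5
        assert cell.s_interval == pytest.approx(21 / 26)

    def test_mle_matches_grid_search_oracle(self):
        hists = [make_history(f"b{i}", "aaaaad" if i < 3 else "aaaa")
                 for i in range(6)]
        m = fit_known_fate(hists, "null")
        alive = sum(1 for h in hists for r in h.records if r.status == "alive")
        dead = sum(1 for h in hists for r in h.records if r.status == "dead")
        assert m.cells["all"].s_interval == pytest.approx(
            _grid_mle(alive, dead), abs=1e-3)

    def test_saturated_grouping_equals_per_cell_proportion(self):
        hists = [make_history("b1", "aaad", population="MM"),
                 make_history("b2", "ad", population="NSN"),
                 make_history("b3", "aaaa", population="NSN")]
        m = fit_known_fate(hists, "pop")
        assert m.cells["MM"].s_interval == pytest.approx(3 / 4)
        assert m.cells["NSN"].s_interval == pytest.approx(5 / 6)

    def test_censored_intervals_excluded_from_likelihood(self):
        with_c = [make_history("b1", "aaac")]
        m = fit_known_fate(with_c, "null")
        assert m.n_eff == 3  # censored record contributes nothing

    def test_annual_s_monotone_in_deaths(self):
        base = [make_history(f"b{i}", "a" * 8) for i in range(10)]
        more_deaths = base[:-1] + [make_history("b9", "a" * 7 + "d")]
        s0 = fit_known_fate(base, "null").cells["all"].annual_s
        s1 = fit_known_fate(more_deaths, "null").cells["all"].annual_s
        assert s1 < s0 == 1.0


class TestModelSelection:
    def _models(self):
        # strong population effect, ages balanced across populations so the
        # age model cannot absorb it: S(~Pop) separates decisively
        hists = [make_history(f"m{i}", "a" * 16, population="MM",
                              birth_year=1995 if i % 2 else 2002)
                 for i in range(10)]
        hists += [make_history(f"n{i}", "a" * 7 + ("d" if i < 6 else "a"),
                               population="NSN",
                               birth_year=1995 if i % 2 else 2002)
                  for i in range(10)]
        return [fit_known_fate(hists, name) for name in ("pop", "null", "age")]

    def test_identical_models_share_weight(self):
        models = self._models()
        pair = [models[1], models[1]]
        tab = aicc_table(pair)
        assert list(tab["delta"]) == [0.0, 0.0]
        assert np.allclose(tab["weight"], 0.5)

    def test_weights_match_closed_form(self):
        models = self._models()
        tab = aicc_table(models)
        rel = np.exp(-0.5 * tab["delta"].to_numpy())
        assert np.allclose(tab["weight"], rel / rel.sum())

    def test_differing_data_rejected(self):
        m1 = self._models()[0]
        other = fit_known_fate([make_history("x", "aaaa")], "null")
        with pytest.raises(ValidationError, match="differing data"):
            aicc_table([m1, other])

    def test_single_qualifying_model_returned_verbatim(self):
        models = self._models()
        tab = aicc_table(models)
        assert float(tab["delta"].iloc[1]) > 2.0  # only the top model qualifies
        top = {m.name: m for m in models}[tab["model"].iloc[0]]
        avg = model_average(models)
        for g, est in avg.items():
            assert est.annual_s == pytest.approx(
                top.annual_survival(*g).annual_s)

    def test_two_model_average_is_weighted_mean(self):
        models = self._models()
        null, age = models[1], models[2]
        tab = aicc_table([null, age])
        w = tab.set_index("model")["weight"]
        avg = model_average([null, age], threshold=np.inf)
        g = ("MM", "adult")
        expect = (w["S(~1)"] * null.annual_survival(*g).annual_s
                  + w["S(~Age)"] * age.annual_survival(*g).annual_s)
        assert avg[g].annual_s == pytest.approx(expect)
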