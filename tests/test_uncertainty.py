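"""Tornado DSA, Monte Carlo PSA, CEAC and CE-plane summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fpcea.exceptions import ModelError
from fpcea.model import DecisionModel
from fpcea.uncertainty import (
    ce_plane,
    ceac,
    ceac_crossing,
    default_threshold_grid,
    run_psa,
    tornado,
)


@pytest.fixture(scope="module")
def entries(model):
    return tornado(model)


@pytest.fixture(scope="module")
def psa(model):
    return run_psa(model, iterations=400, seed=17)


class TestTornado:
    def test_every_bar_brackets_the_base_icer(self, model, entries):
        base = model.base_case().icers["dalys_averted"]
        for e in entries:
            assert e.low - 1e-9 <= base <= e.high + 1e-9, e.name

    def test_entries_sorted_by_descending_width(self, entries):
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_societally_neutral_fees_give_zero_width_bars(self, entries):
        fee_bars = [e for e in entries if e.name.startswith("fee.")]
        assert fee_bars and all(e.width < 1e-9 for e in fee_bars)

    def test_personnel_and_phone_costs_rank_high(self, entries):
        top = {e.name for e in entries[:8]}
        assert "cost.personnel.counsellor_hourly" in top
        assert "cost.delivery.call_airtime" in top

    def test_overhead_proportion_included(self, entries):
        assert any(e.name == "structural.overhead_proportion" for e in entries)

    def test_degenerate_range_gives_zero_width(self, model, params):
        doc = params.to_mapping()
        row = next(r for r in doc["parameters"] if r["name"] == "cost.delivery.phone")
        row["lo"] = row["hi"] = row["base"]
        row["family"] = "fixed"
        from fpcea.params import ParameterSet

        m = DecisionModel(params=ParameterSet.from_mapping(doc))
        bar = next(e for e in tornado(m) if e.name == "cost.delivery.phone")
        assert bar.width == 0.0


class TestPsa:
    def test_row_count_matches_iterations(self, psa):
        assert len(psa) == 400
        assert psa["iteration"].tolist() == list(range(400))

    def test_reproducible_under_seed(self, model):
        a = run_psa(model, iterations=50, seed=5)
        b = run_psa(model, iterations=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_incremental_cost_near_base_case(self, model):
        psa = run_psa(model, iterations=1000, seed=2)
        assert psa["delta_cost"].mean() == pytest.approx(8160.49, rel=0.10)

    def test_all_fixed_families_degenerate_to_base_case(self, model, params):
        doc = params.to_mapping()
        for row in doc["parameters"]:
            row["family"] = "fixed"
            row["lo"] = row["hi"] = row["base"]
        from fpcea.params import ParameterSet

        m = DecisionModel(params=ParameterSet.from_mapping(doc))
        psa = run_psa(m, iterations=1, seed=0)
        base = m.base_case()
        assert psa.loc[0, "delta_cost"] == pytest.approx(base.delta_cost, rel=1e-12)
        assert psa.loc[0, "delta_dalys"] == pytest.approx(
            base.delta_effects["dalys_averted"], rel=1e-12
        )

    def test_nonpositive_iterations_rejected(self, model):
        with pytest.raises(ModelError):
            run_psa(model, iterations=0, seed=1)

    def test_sampled_marginals_match_calibrated_distributions(self, model):
        # KS test of the PSA's own parameter stream against each calibrated CDF
        rng = np.random.default_rng(23)
        draws = {name: [] for name in model.params.names}
        for _ in range(1000):
            for name, v in model.params.sample_values(rng).items():
                draws[name].append(v)
        # Bonferroni: one joint test at alpha=0.01 across all parameters
        alpha = 0.01 / len(model.params.names)
        for name in model.params.names:
            d = model.params.calibrated(name)
            res = stats.kstest(np.asarray(draws[name]), d.cdf)
            assert res.pvalue > alpha, name


class TestCeac:
    def test_monotone_when_all_effects_positive(self, psa):
        sub = psa[psa["delta_dalys"] > 0]
        curve = ceac(sub, default_threshold_grid(300.0, 5.0))
        assert (curve["probability"].diff().dropna() >= 0).all()

    def test_zero_threshold_probability_is_share_of_cost_saving_draws(self, psa):
        curve = ceac(psa, np.array([0.0]))
        assert curve.loc[0, "probability"] == (psa["delta_cost"] < 0).mean()

    def test_large_threshold_limit_is_share_of_effective_draws(self, psa):
        curve = ceac(psa, np.array([1e9]))
        assert curve.loc[0, "probability"] == (psa["delta_dalys"] > 0).mean()

    def test_crossing_at_empirical_median_icer(self, psa):
        icers = psa["delta_cost"] / psa["delta_dalys"]
        med = float(np.median(icers))
        curve = ceac(psa, np.array([med * 0.99, med * 1.01]))
        assert curve["probability"].iloc[0] <= 0.5 + 1.0 / len(psa)
        assert curve["probability"].iloc[1] >= 0.5 - 1.0 / len(psa)

    def test_crossing_helper_returns_first_grid_hit(self, psa):
        curve = ceac(psa)
        lam = ceac_crossing(curve, 0.5)
        below = curve[curve["threshold"] < lam]
        assert (below["probability"] < 0.5).all()

    def test_empty_results_rejected(self, psa):
        with pytest.raises(ModelError):
            ceac(psa.iloc[:0])


class TestCePlane:
    def test_summary_fractions_and_rays(self, psa):
        plane = ce_plane(psa, thresholds=(58.0, 176.0))
        assert plane["rays"] == {"lower": 58.0, "upper": 176.0}
        assert len(plane["points"]) == len(psa)
        assert 0.9 <= plane["fraction_below_upper"] <= 1.0
        assert plane["fraction_within"] <= plane["fraction_below_upper"]

    def test_cyp_scale_about_five_times_daly_scale(self, psa):
        # the effects chain yields roughly five CYPs per DALY averted
        ratio = psa["delta_cyps"].mean() / psa["delta_dalys"].mean()
        assert ratio == pytest.approx(5.2, abs=0.5)

    def test_empty_results_rejected(self, psa):
        with pytest.raises(ModelError):
            ce_plane(psa.iloc[:0])
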