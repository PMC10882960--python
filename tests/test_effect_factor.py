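import numpy as np
import pandas as pd
import pytest

from invacf.effect_factor import (
    DD_OPTIONS,
    build_effect_rows,
    check_loss,
    compute_pdf,
    country_asf,
    effect_factor,
    weighted_quantile_fit,
    weighted_quantile_line,
)
from invacf.synthetic_world import synthetic_effect_inputs
from oracles import quantile_vertex_search


def threat_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "country",
            "category",
            "threat_code",
            "severity",
            "dd_predicted_threatened",
        ],
    )


class TestComputePdf:
    def test_hand_count(self):
        rows = [(f"s{k}", "X", "LC", "2.1", "slow_significant", "") for k in range(8)]
        rows += [
            ("t1", "X", "EN", "8.1", "rapid", ""),
            ("t2", "X", "VU", "8.1", "very_rapid", ""),
        ]
        pdf, denom = compute_pdf(threat_table(rows), "X")
        assert denom == 10
        assert pdf == pytest.approx(0.2)

    def test_all_least_concern_gives_zero(self):
        rows = [(f"s{k}", "X", "LC", "8.1", "rapid", "") for k in range(5)]
        pdf, _ = compute_pdf(threat_table(rows), "X")
        assert pdf == 0.0

    def test_unknown_severity_excluded_from_denominator(self):
        rows = [
            ("a", "X", "EN", "8.1", "rapid", ""),
            ("b", "X", "LC", "2.1", "slow_significant", ""),
            ("c", "X", "LC", "2.1", "unknown", ""),
        ]
        pdf, denom = compute_pdf(threat_table(rows), "X")
        assert denom == 2
        assert pdf == pytest.approx(0.5)

    def test_threatened_without_alien_threat_not_counted(self):
        rows = [
            ("a", "X", "CR", "2.1", "rapid", ""),  # threatened, other cause
            ("b", "X", "LC", "2.1", "none", ""),
        ]
        pdf, _ = compute_pdf(threat_table(rows), "X")
        assert pdf == 0.0

    def test_dd_options_differ_by_exactly_one_over_denominator(self):
        rows = [
            ("a", "X", "DD", "8.1", "rapid", "True"),
            ("b", "X", "EN", "8.1", "rapid", ""),
            ("c", "X", "LC", "2.1", "none", ""),
            ("d", "X", "LC", "2.1", "none", ""),
        ]
        table = threat_table(rows)
        by_opt = {opt: compute_pdf(table, "X", opt)[0] for opt in DD_OPTIONS}
        assert by_opt["dd_not_threatened"] == pytest.approx(0.25)
        assert by_opt["dd_predicted"] == pytest.approx(0.5)
        assert by_opt["dd_threatened"] == pytest.approx(0.5)
        # flip the prediction: predicted option tracks the flag
        table.loc[0, "dd_predicted_threatened"] = "False"
        assert compute_pdf(table, "X", "dd_predicted")[0] == pytest.approx(0.25)

    def test_dd_monotonicity_on_synthetic_rows(self):
        threats, nat, alien, area = synthetic_effect_inputs(
            n_countries=30, seed=3, dd_fraction=0.2
        )
        rows = build_effect_rows(threats, nat, alien, area)
        assert (rows["PDF_dd_not_threatened"] <= rows["PDF_dd_predicted"] + 1e-12).all()
        assert (rows["PDF_dd_predicted"] <= rows["PDF_dd_threatened"] + 1e-12).all()

    def test_no_assessed_species_raises(self):
        rows = [("a", "X", "LC", "2.1", "unknown", "")]
        with pytest.raises(ValueError):
            compute_pdf(threat_table(rows), "X")


class TestCountryAsf:
    @pytest.mark.parametrize(
        "native,alien,expected", [(50, 50, 0.5), (100, 0, 0.0), (30, 10, 0.25)]
    )
    def test_shared_definition(self, native, alien, expected):
        assert country_asf(native, alien) == pytest.approx(expected)


class TestWeightedQuantileLine:
    def test_points_exactly_on_line_recovered_for_any_tau(self):
        x = np.linspace(0.05, 0.6, 12)
        y = 0.04 * x
        w = np.ones_like(x)
        for tau in (0.05, 0.5, 0.9):
            a, b = weighted_quantile_line(x, y, w, tau)
            assert a == pytest.approx(0.0, abs=1e-10)
            assert b == pytest.approx(0.04, abs=1e-9)

    @pytest.mark.parametrize("tau", [0.05, 0.25, 0.5, 0.75])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_lp_equals_vertex_enumeration_oracle(self, tau, seed):
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.uniform(0, 1, n)
        y = rng.uniform(0, 1, n)
        w = rng.uniform(0.5, 3.0, n)
        a, b = weighted_quantile_line(x, y, w, tau)
        loss_lp = check_loss(x, y, w, tau, a, b)
        _, _, loss_vertex = quantile_vertex_search(x, y, w, tau)
        assert loss_lp == pytest.approx(loss_vertex, abs=1e-9)

    def test_median_regression_matches_statsmodels_quantreg(self):
        # weight-scaled data reduces weighted to unweighted check loss
        import statsmodels.api as sm
        from statsmodels.regression.quantile_regression import QuantReg

        rng = np.random.default_rng(5)
        n = 60
        x = rng.uniform(0, 1, n)
        y = 0.1 + 0.5 * x + rng.normal(0, 0.1, n)
        w = rng.uniform(0.5, 2.0, n)
        a, b = weighted_quantile_line(x, y, w, 0.5)
        X = np.column_stack([np.ones(n), x])
        qr = QuantReg(w * y, w[:, None] * X).fit(q=0.5)
        mine = check_loss(x, y, w, 0.5, a, b)
        theirs = check_loss(x, y, w, 0.5, qr.params[0], qr.params[1])
        assert mine <= theirs + 1e-7

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="slope undefined"):
            weighted_quantile_line(
                np.ones(5), np.arange(5.0), np.ones(5), 0.5
            )

    def test_optimality_condition_weighted_fractions(self):
        threats, nat, alien, area = synthetic_effect_inputs(n_countries=80, seed=7)
        rows = build_effect_rows(threats, nat, alien, area)
        for tau in (0.05, 0.15):
            ef = weighted_quantile_fit(rows, tau, n_boot=0)
            x = rows["ASF"].to_numpy()
            y = rows["PDF_dd_predicted"].to_numpy()
            w = rows["weight"].to_numpy()
            r = y - ef.intercept - ef.slope * x
            below = w[r < -1e-9].sum() / w.sum()
            above = w[r > 1e-9].sum() / w.sum()
            assert below <= tau + 1e-9
            assert above <= 1 - tau + 1e-9


class TestEffectFactor:
    def test_no_dd_species_gives_identical_factors_across_options(self):
        threats, nat, alien, area = synthetic_effect_inputs(
            n_countries=40, seed=11, dd_fraction=0.0
        )
        rows = build_effect_rows(threats, nat, alien, area)
        efs = effect_factor(rows, taus=(0.05,), n_boot=0)
        slopes = {ef.dd_option: ef.slope for ef in efs}
        assert len(set(slopes.values())) == 1

    def test_zero_slope_world_recovers_null(self):
        threats, nat, alien, area = synthetic_effect_inputs(
            n_countries=60, ef_slope=0.0, confounder_scale=0.01, seed=13
        )
        rows = build_effect_rows(threats, nat, alien, area)
        ef = weighted_quantile_fit(rows, 0.05, n_boot=200, seed=1)
        assert abs(ef.slope) < 0.01
        assert ef.ci_lower <= 0.0 <= ef.ci_upper or abs(ef.slope) < 5e-3

    def test_planted_slope_recovered_at_headline_quantile(self):
        slopes = []
        for seed in range(5):
            threats, nat, alien, area = synthetic_effect_inputs(seed=seed)
            rows = build_effect_rows(threats, nat, alien, area)
            slopes.append(weighted_quantile_fit(rows, 0.05, n_boot=0).slope)
        assert np.mean(slopes) == pytest.approx(0.038, rel=0.15)

    def test_tau_sweep_weakly_increasing_under_one_sided_noise(self):
        increments = []
        for seed in range(3):
            threats, nat, alien, area = synthetic_effect_inputs(seed=100 + seed)
            rows = build_effect_rows(threats, nat, alien, area)
            slopes = [
                weighted_quantile_fit(rows, tau, n_boot=0).slope
                for tau in (0.05, 0.10, 0.15)
            ]
            increments.extend(np.diff(slopes))
        assert np.mean(increments) > -1e-3

    def test_bootstrap_ci_brackets_slope_and_is_seed_deterministic(self):
        threats, nat, alien, area = synthetic_effect_inputs(n_countries=50, seed=17)
        rows = build_effect_rows(threats, nat, alien, area)
        ef1 = weighted_quantile_fit(rows, 0.05, n_boot=100, seed=42)
        ef2 = weighted_quantile_fit(rows, 0.05, n_boot=100, seed=42)
        assert ef1 == ef2
        assert ef1.ci_lower <= ef1.slope <= ef1.ci_upper
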