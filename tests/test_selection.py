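"""Term pruning and the deviation audit."""

import numpy as np
import pandas as pd
import pytest

import quechers_rsm as q
from quechers_rsm.basis import expand_terms
from quechers_rsm.design import coded_matrix, generate_ccf_design
from quechers_rsm.selection import CONFIDENCE_LEVELS


@pytest.fixture()
def noisy_fit(space, citrate_models):
    """A model fitted to a noisy synthetic citrate table, with its data."""
    spec = q.SimulationSpec(
        space=space,
        true_coefficients={"alloxydim": citrate_models["alloxydim"].coef_},
        noise_sd=2.0,
        seed=7,
    )
    table = q.simulate_recoveries(spec)
    model = q.fit_full_model(table.design, table.observations, "alloxydim")
    X = coded_matrix(table.design)
    y = table.observations["alloxydim"].to_numpy()
    return model, X, y


class TestPrune:
    def test_level_zero_is_identity(self, noisy_fit):
        model, X, _ = noisy_fit
        pruned = q.prune_model(model, 0)
        np.testing.assert_array_equal(pruned.coef_, model.coef_)
        np.testing.assert_allclose(pruned.predict(X), model.predict(X))
        assert pruned.n_retained == 31

    def test_published_citrate_alloxydim_letters_at_95(self, citrate_models):
        pruned = q.prune_model(citrate_models["alloxydim"], 95)
        assert pruned.retained_terms == ["b0", "b_AM"]

    def test_published_acetate_alloxydim_letters_at_95(self, acetate_models):
        pruned = q.prune_model(acetate_models["alloxydim"], 95)
        assert pruned.retained_terms == [
            "b0", "b_SW", "b_AM", "b_SW-WC", "b_AM-ET", "b_AM-AM",
        ]

    def test_retained_sets_nest_across_levels(self, noisy_fit, acetate_models):
        models = [noisy_fit[0], *acetate_models.values()]
        for model in models:
            previous: set[str] | None = None
            for level in (95, 90, 80, 70, 0):
                retained = set(q.prune_model(model, level).retained_terms)
                if previous is not None:
                    assert previous <= retained
                previous = retained

    def test_intercept_never_pruned(self, noisy_fit):
        model, _, _ = noisy_fit
        for level in CONFIDENCE_LEVELS:
            assert "b0" in q.prune_model(model, level).retained_terms

    def test_truncate_keeps_full_fit_values(self, noisy_fit):
        model, _, _ = noisy_fit
        pruned = q.prune_model(model, 95, mode="truncate")
        kept = pruned.retained
        np.testing.assert_array_equal(pruned.coef_[kept], model.coef_[kept])
        assert np.all(pruned.coef_[~kept] == 0)

    def test_invalid_arguments(self, noisy_fit, citrate_models):
        model, _, _ = noisy_fit
        with pytest.raises(ValueError):
            q.prune_model(model, 85)
        with pytest.raises(ValueError):
            q.prune_model(model, 95, mode="drop")
        bare = q.RecoveryPolynomial.from_coefficients(np.zeros(31))
        with pytest.raises(ValueError, match="letters"):
            q.prune_model(bare, 95)

    def test_sse_monotonicity_both_modes(self, noisy_fit):
        """OLS minimizes SSE over the full basis, so any pruned model —
        truncated or refitted — can only do worse."""
        model, X, y = noisy_fit
        full_sse = model.sse_
        for mode in ("truncate", "refit"):
            for level in CONFIDENCE_LEVELS:
                pruned = q.prune_model(model, level, mode=mode)
                sse = float(np.sum((pruned.predict(X) - y) ** 2))
                assert sse >= full_sse - 1e-8
        # refit never beats truncate's own richer fit at the same level
        for level in (95, 90, 80, 70):
            t_sse = np.sum((q.prune_model(model, level).predict(X) - y) ** 2)
            r_sse = np.sum(
                (q.prune_model(model, level, mode="refit").predict(X) - y) ** 2
            )
            assert r_sse <= t_sse + 1e-8

    def test_refit_r_bounded_by_full_r(self, noisy_fit):
        model, X, y = noisy_fit
        for level in CONFIDENCE_LEVELS:
            pruned = q.prune_model(model, level, mode="refit")
            q.deviation_range(pruned, X, y)
            assert pruned.r_pruned <= model.r_ + 1e-12


class TestDeviationRange:
    def test_level_zero_equals_full_model_residual_range(self, noisy_fit):
        model, X, y = noisy_fit
        pruned = q.prune_model(model, 0)
        dmin, dmax = q.deviation_range(pruned, X, y)
        resid = np.abs(model.predict(X) - y)
        assert dmin == pytest.approx(resid.min())
        assert dmax == pytest.approx(resid.max())
        assert pruned.r_pruned == pytest.approx(model.r_, abs=1e-10)

    def test_perfect_fit_gives_zero_range(self, space, citrate_models):
        spec = q.SimulationSpec(
            space=space,
            true_coefficients={"c": citrate_models["alloxydim"].coef_},
            noise_sd=0.0,
            seed=0,
        )
        t = q.simulate_recoveries(spec)
        m = q.fit_full_model(t.design, t.observations, "c")
        pruned = q.prune_model(m, 0)
        dmin, dmax = q.deviation_range(
            pruned, coded_matrix(t.design), t.observations["c"].to_numpy()
        )
        assert (dmin, dmax) == (pytest.approx(0, abs=1e-8), pytest.approx(0, abs=1e-8))

    def test_matches_brute_force_recomputation(self, noisy_fit):
        """Oracle: per-run scan with explicit feature products."""
        model, X, y = noisy_fit
        pruned = q.prune_model(model, 90)
        dmin, dmax = q.deviation_range(pruned, X, y)
        devs = []
        for run, obs in zip(X, y):
            pred = float(expand_terms(run) @ pruned.coef_)
            devs.append(abs(pred - obs))
        assert dmin == pytest.approx(min(devs))
        assert dmax == pytest.approx(max(devs))

    def test_mismatched_table_rejected(self, noisy_fit):
        model, X, y = noisy_fit
        pruned = q.prune_model(model, 95)
        with pytest.raises(ValueError):
            q.deviation_range(pruned, X[:10], y)


class TestSelectionReport:
    def test_report_shape_and_level_zero_column(self, space, noisy_fit):
        model, X, y = noisy_fit
        obs = pd.DataFrame({"alloxydim": y})
        report = q.selection_report({"alloxydim": model}, X, obs)
        assert len(report) == len(CONFIDENCE_LEVELS)
        row0 = report[report["confidence_level"] == 0].iloc[0]
        resid = np.abs(model.predict(X) - y)
        assert row0["deviation_min"] == pytest.approx(resid.min())
        assert row0["deviation_max"] == pytest.approx(resid.max())
        assert row0["R"] == pytest.approx(model.r_, abs=1e-10)

    def test_all_constant_observations(self, space):
        d = generate_ccf_design(space, 3)
        X = coded_matrix(d)
        obs = pd.DataFrame({"c": np.full(len(d), 100.0)})
        m = q.fit_full_model(d, obs, "c")
        report = q.selection_report({"c": m}, X, obs)
        assert np.allclose(report["deviation_min"], 0, atol=1e-9)
        assert np.allclose(report["deviation_max"], 0, atol=1e-9)

    def test_two_compound_report_matches_per_compound_oracle(
        self, space, citrate_models
    ):
        spec = q.SimulationSpec(
            space=space,
            true_coefficients={
                c: citrate_models[c].coef_ for c in ("alloxydim", "profoxydim")
            },
            noise_sd=2.0,
            seed=11,
        )
        t = q.simulate_recoveries(spec)
        X = coded_matrix(t.design)
        models = {c: q.fit_full_model(t.design, t.observations, c) for c in t.compounds}
        report = q.selection_report(models, X, t.observations)
        for _, row in report.iterrows():
            pruned = q.prune_model(models[row["compound"]], row["confidence_level"])
            y = t.observations[row["compound"]].to_numpy()
            dmin, dmax = q.deviation_range(pruned, X, y)
            assert row["deviation_min"] == pytest.approx(dmin)
            assert row["deviation_max"] == pytest.approx(dmax)

    def test_high_r_can_hide_large_deviations(self, space):
        """Goodness of fit alone is not sufficient: a wide response range
        with one outlier run yields high R *and* a large max deviation,
        and the report exposes both."""
        d = generate_ccf_design(space, 3)
        X = coded_matrix(d)
        # wide true surface dominated by one strong linear effect
        coef = np.zeros(31)
        coef[0], coef[2] = 100.0, 30.0
        y = expand_terms(X) @ coef
        y[44] += 25.0  # aberrant centre replicate: low leverage, stays in residual
        obs = pd.DataFrame({"c": y})
        m = q.fit_full_model(d, obs, "c")
        report = q.selection_report({"c": m}, X, obs)
        row0 = report[report["confidence_level"] == 0].iloc[0]
        assert row0["R"] > 0.9
        assert row0["deviation_max"] > 10.0
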