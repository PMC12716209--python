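import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lamscreen import (
    ControlModel,
    PopulationSpec,
    classify_cells,
    fit_control_model,
    lamin_ratio,
    prediction_band,
    screen_experiment,
    screen_timecourse,
    simulate_population,
    simulate_timecourse,
)
from lamscreen.screen import timecourse_condition_means
from lamscreen.synth import LogisticKinetics
from lamscreen.errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    InsufficientControlError,
)
from .conftest import make_line_control


def brute_force_labels(cells: pd.DataFrame, model: ControlModel) -> list[str]:
    """Independent per-cell re-evaluation of the three senescence rules."""
    labels = []
    tcrit = stats.t.ppf(1 - model.alpha / 2, model.n_control - 2)
    for _, row in cells.iterrows():
        a, b1 = row["lamin_a"], row["lamin_b1"]
        rule_a = a > model.mean_a + 2 * model.sd_a
        rule_b1 = b1 > model.mean_b1 + 2 * model.sd_b1
        y_hat = model.slope * a + model.intercept
        half = tcrit * model.resid_sd * np.sqrt(
            1 + 1 / model.n_control + (a - model.x_mean) ** 2 / model.sxx
        )
        rule_band = (b1 < y_hat - half) or (b1 > y_hat + half)
        labels.append("senescent" if (rule_a or rule_b1 or rule_band) else "non_senescent")
    return labels


class TestFitControlModel:
    def test_exact_line(self):
        model = fit_control_model(make_line_control())
        assert model.slope == pytest.approx(0.8)
        assert model.intercept == pytest.approx(5.0)
        assert model.r_squared == pytest.approx(1.0)
        assert model.resid_sd == pytest.approx(0.0, abs=1e-10)
        assert not model.correction_applied

    def test_threshold_identity(self, control_table):
        model = fit_control_model(control_table)
        assert model.thr_a - model.mean_a == pytest.approx(2 * model.sd_a)
        assert model.thr_b1 - model.mean_b1 == pytest.approx(2 * model.sd_b1)

    def test_slope_recovery_coverage(self):
        hits = 0
        for seed in range(20):
            t = simulate_population(PopulationSpec(n_cells=500, resid_sd=2.0, seed=seed))
            model = fit_control_model(t)
            a = t["lamin_a"].to_numpy()
            se = model.resid_sd / np.sqrt(((a - a.mean()) ** 2).sum())
            if abs(model.slope - 0.8) <= 3 * se:
                hits += 1
        assert hits >= 19

    def test_heterogeneity_correction(self):
        # 95% on-line cells + 5% decorrelated high-intensity contaminants
        rng = np.random.default_rng(21)
        clean = simulate_population(PopulationSpec(n_cells=950, resid_sd=3.0, seed=21))
        contam = pd.DataFrame(
            {
                "lamin_a": rng.normal(300, 30, 50),
                "lamin_b1": rng.normal(60, 40, 50).clip(min=1.0),
            }
        )
        mixed = pd.concat(
            [clean[["lamin_a", "lamin_b1"]], contam], ignore_index=True
        )
        raw_r2 = fit_control_model(mixed, max_iter=0).r_squared
        assert raw_r2 < 0.95  # contamination breaks the fit

        model = fit_control_model(mixed)
        assert model.correction_applied
        # oracle: OLS on the known clean subset
        oracle = fit_control_model(clean)
        a = clean["lamin_a"].to_numpy()
        se = oracle.resid_sd / np.sqrt(((a - a.mean()) ** 2).sum())
        assert abs(model.slope - oracle.slope) <= 3 * se

    def test_insufficient_control_error(self):
        with pytest.raises(InsufficientControlError):
            fit_control_model(make_line_control(n=5))

    def test_zero_variance_error(self):
        df = make_line_control(n=20)
        df["lamin_a"] = 100.0
        with pytest.raises(DegenerateInputError):
            fit_control_model(df)

    def test_json_round_trip(self, tmp_path, control_table):
        model = fit_control_model(control_table)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ControlModel.from_json(path)
        assert back == model


class TestPredictionBand:
    def test_zero_residual_collapses_to_line(self):
        model = fit_control_model(make_line_control())
        lower, upper = prediction_band(model, 100.0)
        assert lower == pytest.approx(85.0, abs=1e-6)
        assert upper == pytest.approx(85.0, abs=1e-6)

    def test_half_width_minimized_at_x_mean(self, control_table):
        model = fit_control_model(control_table)
        grid = np.linspace(model.x_mean - 50, model.x_mean + 50, 101)
        lower, upper = prediction_band(model, grid)
        widths = upper - lower
        assert np.argmin(widths) == 50  # the x_mean gridpoint
        lo_m, up_m = prediction_band(model, model.x_mean)
        expected = (
            stats.t.ppf(0.975, model.n_control - 2)
            * model.resid_sd
            * np.sqrt(1 + 1 / model.n_control)
        )
        assert (up_m - lo_m) / 2 == pytest.approx(expected)

    def test_frozen_half_width_example(self):
        # n=100, s=2, x_mean=100, sxx=40000, a=150:
        # t_{0.975,98} * 2 * sqrt(1 + 0.01 + 2500/40000) = 4.110291537669131
        model = ControlModel(
            slope=0.8, intercept=5.0, n_control=100, r_squared=0.99,
            resid_sd=2.0, x_mean=100.0, sxx=40000.0, alpha=0.05,
            mean_a=100.0, sd_a=20.0, mean_b1=85.0, sd_b1=16.0,
        )
        lower, upper = prediction_band(model, 150.0)
        assert (upper - lower) / 2 == pytest.approx(4.110291537669131, abs=1e-9)


class TestClassifyCells:
    def test_on_line_mid_cell_is_non_senescent(self, control_table):
        model = fit_control_model(control_table)
        cell = pd.DataFrame(
            {"lamin_a": [model.mean_a],
             "lamin_b1": [model.slope * model.mean_a + model.intercept]}
        )
        res = classify_cells(cell, model)
        assert res.cells["screen_label"].iloc[0] == "non_senescent"

    def test_high_b1_flag(self, control_table):
        model = fit_control_model(control_table)
        cell = pd.DataFrame(
            {"lamin_a": [model.mean_a], "lamin_b1": [model.mean_b1 + 3 * model.sd_b1]}
        )
        res = classify_cells(cell, model)
        assert res.cells["screen_label"].iloc[0] == "senescent"
        assert res.cells["high_b1"].iloc[0]

    def test_missing_channel_error(self, control_table):
        model = fit_control_model(control_table)
        with pytest.raises(InputError):
            classify_cells(pd.DataFrame({"lamin_a": [1.0]}), model)

    def test_brute_force_oracle_equivalence(self, control_table):
        model = fit_control_model(control_table)
        mixed = simulate_population(
            PopulationSpec(n_cells=2000, frac_senescent=0.5, decorrelate_prob=0.5, seed=13)
        )
        res = classify_cells(mixed, model)
        assert list(res.cells["screen_label"]) == brute_force_labels(mixed, model)

    def test_every_senescent_has_reason(self, control_table):
        model = fit_control_model(control_table)
        mixed = simulate_population(
            PopulationSpec(n_cells=2000, frac_senescent=0.3, seed=5)
        )
        cells = classify_cells(mixed, model).cells
        sen = cells[cells["screen_label"] == "senescent"]
        assert (sen[["high_a", "high_b1", "off_line"]].any(axis=1)).all()

    def test_summary_counts_conserve(self, control_table):
        model = fit_control_model(control_table)
        mixed = simulate_population(PopulationSpec(n_cells=777, frac_senescent=0.2, seed=2))
        res = classify_cells(mixed, model)
        assert res.summary["n_cells"].sum() == 777
        assert ((res.summary["fraction_senescent"] >= 0)
                & (res.summary["fraction_senescent"] <= 1)).all()


class TestScreenExperiment:
    def test_missing_control_error(self):
        t = simulate_population(PopulationSpec(n_cells=100, seed=0))
        with pytest.raises(ConfigurationError):
            screen_experiment(t, control_key="does_not_exist")

    def test_mapping_input(self, control_table):
        treated = simulate_population(
            PopulationSpec(n_cells=500, frac_senescent=0.9, seed=8, condition="treated")
        )
        res = screen_experiment(
            {"control": control_table, "treated": treated}, control_key="control"
        )
        frac = res.summary.set_index("condition")["fraction_senescent"]
        assert frac["treated"] >= 0.85
        assert frac["control"] < 0.12

    def test_identical_conditions_indistinguishable(self):
        tables = {
            name: simulate_population(
                PopulationSpec(n_cells=2000, resid_sd=3.0, seed=seed, condition=name)
            )
            for name, seed in [("control", 31), ("condA", 32), ("condB", 33)]
        }
        res = screen_experiment(tables, control_key="control")
        fracs = res.summary["fraction_senescent"]
        assert fracs.max() - fracs.min() < 0.03

    def test_monotone_in_true_fraction(self):
        control = simulate_population(PopulationSpec(n_cells=2000, resid_sd=3.0, seed=41))
        observed = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            t = simulate_population(
                PopulationSpec(n_cells=2000, frac_senescent=frac, seed=42)
            )
            res = screen_experiment(
                {"control": control, "treated": t}, control_key="control"
            )
            observed.append(
                res.summary.set_index("condition")["fraction_senescent"]["treated"]
            )
        assert all(b >= a for a, b in zip(observed, observed[1:]))


class TestScreenTimecourse:
    KIN = {0.0: LogisticKinetics(base=0.02, plateau=0.02, rate_per_h=0.1, t50_h=84.0),
           50.0: LogisticKinetics(base=0.02, plateau=0.9, rate_per_h=0.1, t50_h=84.0)}

    def _table(self, doses, n=500, seed=0, wells=1):
        spec = PopulationSpec(n_cells=n, resid_sd=3.0, decorrelate_prob=0.5, seed=seed)
        return simulate_timecourse(doses, [0.0, 84.0, 156.0], self.KIN, spec,
                                   wells_per_dose=wells)

    def test_missing_t0_error(self):
        t = self._table([50.0])
        with pytest.raises(ConfigurationError):
            screen_timecourse(t[t["timepoint_h"] > 0])

    def test_flat_for_null_kinetics(self):
        res = screen_timecourse(self._table([0.0], n=1000, seed=5))
        fracs = res.summary["fraction_senescent"]
        assert fracs.max() - fracs.min() < 0.05

    def test_monotone_endpoint_induction(self):
        for seed in (1, 2, 3):
            res = screen_timecourse(self._table([50.0], n=800, seed=seed))
            s = res.summary.sort_values("timepoint_h")
            assert s["fraction_senescent"].iloc[-1] >= s["fraction_senescent"].iloc[0]

    def test_condition_means_shape(self):
        res = screen_timecourse(self._table([0.0, 50.0], n=300, seed=9, wells=2))
        means = timecourse_condition_means(res)
        assert set(means.columns) == {"condition", "timepoint_h", "fraction_senescent"}
        assert len(means) == 6  # 2 conditions x 3 timepoints


class TestLaminRatio:
    def test_simple_ratio(self):
        cells = pd.DataFrame({"lamin_a": [100.0], "lamin_b1": [80.0]})
        assert lamin_ratio(cells).iloc[0] == pytest.approx(0.8)

    def test_on_line_zero_intercept_equals_slope(self):
        cells = make_line_control(intercept=0.0)
        np.testing.assert_allclose(lamin_ratio(cells), 0.8)

    def test_decorrelated_fold_raises_mean_ratio(self):
        control = simulate_population(PopulationSpec(n_cells=2000, seed=3))
        sen = control.copy()
        sen["lamin_b1"] = sen["lamin_b1"] * 3.0  # fold on B1 only
        assert lamin_ratio(sen).mean() > lamin_ratio(control).mean()

    def test_nonpositive_error(self):
        with pytest.raises(InputError):
            lamin_ratio(pd.DataFrame({"lamin_a": [0.0], "lamin_b1": [1.0]}))
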