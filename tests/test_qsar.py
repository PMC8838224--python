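"""MLR QSAR fitting, prediction and validation diagnostics."""

import numpy as np
import pandas as pd
import pytest

from vanchar import fit_mlr, gen_qsar_table, predict, validate
from vanchar.qsar import QsarError, RankDeficiencyError

TRUTH = {"ASA_P": 0.5, "ASA_H": -0.2, "h_pkp": 3.0, "dipole": 1.0}


class TestFitMlr:
    def test_zero_noise_exact_recovery(self):
        table = gen_qsar_table(n=100, noise_sd=0.0, seed=3)
        model = fit_mlr(table)
        for name, b in TRUTH.items():
            assert model.coefficients[name] == pytest.approx(b, abs=1e-8)
        assert model.intercept == pytest.approx(7.0, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_r_squared_is_r_squared(self):
        model = fit_mlr(gen_qsar_table(n=60, noise_sd=10.0, seed=4))
        assert model.r_squared == pytest.approx(model.r**2, abs=1e-10)
        assert model.residuals.mean() == pytest.approx(0.0, abs=1e-8)

    def test_residuals_orthogonal_to_descriptors(self):
        table = gen_qsar_table(n=80, noise_sd=8.0, seed=5)
        model = fit_mlr(table)
        for name in TRUTH:
            dot = float(np.dot(model.residuals, table[name]))
            assert abs(dot) < 1e-6 * abs(float(table[name].abs().sum()))

    def test_constant_response_flagged_degenerate(self):
        table = gen_qsar_table(n=20, noise_sd=0.0, seed=6)
        table["IC50"] = 5.0
        model = fit_mlr(table)
        assert model.degenerate
        assert model.intercept == pytest.approx(5.0)
        assert all(b == 0.0 for b in model.coefficients.values())
        assert np.isnan(model.r_squared)

    def test_duplicated_descriptor_rejected(self):
        table = gen_qsar_table(n=30, noise_sd=0.0, seed=7)
        table["ASA_H"] = table["ASA_P"]
        with pytest.raises(RankDeficiencyError, match="ASA"):
            fit_mlr(table)

    def test_too_few_records_rejected(self):
        with pytest.raises(QsarError):
            fit_mlr(gen_qsar_table(n=6, noise_sd=0.0, seed=8).head(5))

    def test_alias_header_accepted(self):
        table = gen_qsar_table(n=30, noise_sd=0.0, seed=9).rename(
            columns={"h_pkp": "h_pkb"}
        )
        model = fit_mlr(table)
        assert model.coefficients["h_pkp"] == pytest.approx(3.0, abs=1e-8)

    def test_coefficient_shift_equivariance(self):
        # shifting a descriptor by c moves the intercept by -b*c and
        # leaves predictions unchanged
        table = gen_qsar_table(n=50, noise_sd=4.0, seed=10)
        model = fit_mlr(table)
        shifted = table.copy()
        shifted["dipole"] = shifted["dipole"] + 100.0
        model2 = fit_mlr(shifted)
        assert model2.coefficients["dipole"] == pytest.approx(
            model.coefficients["dipole"], abs=1e-8
        )
        assert model2.intercept == pytest.approx(
            model.intercept - 100.0 * model.coefficients["dipole"], abs=1e-6
        )
        np.testing.assert_allclose(
            predict(model2, shifted), predict(model, table), rtol=1e-10
        )


class TestPredict:
    def test_training_predictions_equal_activity_minus_residuals(self):
        table = gen_qsar_table(n=40, noise_sd=6.0, seed=11)
        model = fit_mlr(table)
        preds = predict(model, table)
        np.testing.assert_allclose(
            preds, table["IC50"] - model.residuals, rtol=1e-10
        )

    def test_all_zero_descriptors_predict_intercept(self):
        model = fit_mlr(gen_qsar_table(n=40, noise_sd=0.0, seed=12))
        row = pd.DataFrame(
            {"ASA_P": [0.0], "ASA_H": [0.0], "h_pkp": [0.0], "dipole": [0.0]}
        )
        assert predict(model, row).iloc[0] == pytest.approx(model.intercept)

    def test_held_out_zero_noise_exact(self):
        model = fit_mlr(gen_qsar_table(n=60, noise_sd=0.0, seed=13))
        held_out = gen_qsar_table(n=10, noise_sd=0.0, seed=99)
        np.testing.assert_allclose(
            predict(model, held_out), held_out["IC50"], atol=1e-8
        )

    def test_missing_value_rejected_per_record(self):
        model = fit_mlr(gen_qsar_table(n=30, noise_sd=0.0, seed=14))
        frame = gen_qsar_table(n=6, noise_sd=0.0, seed=15).head(3).copy()
        frame.loc[1, "dipole"] = np.nan
        preds = predict(model, frame)
        assert np.isnan(preds.iloc[1])
        assert np.isfinite(preds.iloc[0]) and np.isfinite(preds.iloc[2])

    def test_log10_transform_round_trip(self):
        # log-linear ground truth with positive activities
        coeffs = {"ASA_P": 0.002, "ASA_H": -0.001, "h_pkp": 0.05, "dipole": 0.01}
        table = gen_qsar_table(n=50, coefficients=coeffs, intercept=0.5, noise_sd=0.0, seed=16)
        table["IC50"] = 10.0 ** table["IC50"]
        model = fit_mlr(table, response_transform="log10")
        np.testing.assert_allclose(predict(model, table), table["IC50"], rtol=1e-8)


class TestValidate:
    def test_zero_noise_perfect_fit_and_q2(self):
        table = gen_qsar_table(n=30, noise_sd=0.0, seed=17)
        model = fit_mlr(table)
        report = validate(model, table)
        assert report.r_squared == pytest.approx(1.0, abs=1e-8)
        assert report.q_squared == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_q2_below_r2(self):
        table = gen_qsar_table(
            n=40, coefficients={k: 0.0 for k in TRUTH}, intercept=10.0,
            noise_sd=5.0, seed=18,
        )
        model = fit_mlr(table)
        report = validate(model, table)
        assert report.q_squared < report.r_squared
        assert report.q_squared <= 0.2

    def test_residual_table_shape(self):
        table = gen_qsar_table(n=25, noise_sd=2.0, seed=19)
        model = fit_mlr(table)
        report = validate(model, table)
        assert list(report.residual_table.columns) == [
            "compound_id", "observed", "predicted", "residual",
        ]
        assert len(report.residual_table) == 25
        assert report.residual_table.residual.mean() == pytest.approx(0.0, abs=1e-8)
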