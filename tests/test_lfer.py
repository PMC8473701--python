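"""Model fitting, prediction, presets and serialization."""

import numpy as np
import pandas as pd
import pytest

import lferkit as lk
from conftest import ols_normal_equations


def make_table(X, y, cols):
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "id", [f"c{i}" for i in range(len(df))])
    df["y"] = y
    return df


class TestFit:
    def test_exact_recovery_at_zero_noise(self):
        rng = np.random.default_rng(3)
        sm = rng.uniform(2, 25, size=12)
        df = make_table(sm[:, None], 2.0 * sm + 1.0, ["Sm"])
        model = lk.fit(df, "y", ["Sm"])
        assert model.coefficients["Sm"] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.stats.r2 == pytest.approx(1.0, abs=1e-12)

    def test_five_point_simple_regression_matches_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 5.0, 7.0, 9.1])
        # closed form: slope = Sxy/Sxx, intercept = ybar - slope*xbar
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope, intercept = sxy / sxx, y.mean() - (sxy / sxx) * x.mean()
        model = lk.fit(make_table(x[:, None], y, ["x"]), "y", ["x"])
        assert model.coefficients["x"] == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(intercept, abs=1e-12)

    def test_matches_normal_equations_oracle(self, random_tables):
        for df, cols in random_tables(25):
            model = lk.fit(df, "y", cols)
            c0, beta = ols_normal_equations(df[cols], df["y"])
            assert model.intercept == pytest.approx(c0, abs=1e-10)
            for j, col in enumerate(cols):
                assert model.coefficients[col] == pytest.approx(beta[j], abs=1e-10)

    def test_residuals_orthogonal_to_descriptors(self, random_tables):
        for df, cols in random_tables(10):
            reg = lk.LFERRegressor().fit(df[cols], df["y"])
            resid = reg.residuals_
            assert abs(resid.sum()) < 1e-8
            X = df[cols].to_numpy()
            scale = np.abs(X).sum(axis=0) * np.abs(resid).max() + 1e-30
            assert (np.abs(resid @ X) / scale < 1e-8).all()

    def test_r2_never_decreases_when_adding_descriptor(self, random_tables):
        for df, cols in random_tables(10, p_max=3):
            rng = np.random.default_rng(len(df))
            df = df.copy()
            df["extra"] = rng.normal(size=len(df))
            small = lk.fit(df, "y", cols)
            big = lk.fit(df, "y", cols + ["extra"])
            assert big.stats.r2 >= small.stats.r2 - 1e-12

    def test_collinear_descriptors_reported(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        df = make_table(np.column_stack([x, 2 * x]), x, ["a", "b"])
        with pytest.raises(lk.CollinearDescriptors) as exc:
            lk.fit(df, "y", ["a", "b"])
        assert set(exc.value.columns) & {"a", "b"}

    def test_insufficient_rows_states_minimum(self):
        df = make_table(np.ones((2, 1)) * [[1.0], [2.0]], [1.0, 2.0], ["a"])
        with pytest.raises(lk.LFERKitError, match="at least 3"):
            lk.fit(df, "y", ["a"])

    def test_rows_with_missing_values_excluded(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 10)
        df = make_table(x[:, None], 3 * x - 1, ["x"])
        df.loc[4, "x"] = np.nan
        model = lk.fit(df, "y", ["x"])
        assert model.stats.n == 9
        assert model.coefficients["x"] == pytest.approx(3.0, abs=1e-10)

    def test_sd_and_f_definitions(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, -0.5] + rng.normal(scale=0.3, size=15)
        reg = lk.LFERRegressor().fit(X, y)
        resid = reg.residuals_
        n, p = 15, 2
        sse = float((resid**2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert reg.stats_.sd == pytest.approx(np.sqrt(sse / (n - p - 1)), abs=1e-12)
        assert reg.stats_.f == pytest.approx(((sst - sse) / p) / (sse / (n - p - 1)), abs=1e-9)


class TestPredict:
    def test_all_zero_vector_returns_intercept(self):
        for model in lk.preset_models():
            values = {c: 0.0 for c in model.coefficients}
            assert lk.predict(model, values) == pytest.approx(model.intercept)

    def test_hand_arithmetic_on_skin_permeability_model(self):
        model = lk.get_preset("logKp/logPoct")
        v = lk.DescriptorVector(s_m=10, flex=1, h_m_hbd=0, logp_basis=2, basis_name="logPoct")
        # 0.6157*2 + 0.0156*10 − 0.0626*0 − 0.0988*1 − 5.646
        assert model.predict_vector(v) == pytest.approx(-4.3574, abs=1e-10)

    def test_basis_mismatch_rejected(self):
        model = lk.get_preset("logKp/logPoct")
        v = lk.DescriptorVector(s_m=10, logp_basis=2, basis_name="logP16")
        with pytest.raises(lk.BasisMismatch):
            model.predict_vector(v)

    def test_missing_descriptor_column_rejected(self):
        model = lk.get_preset("logKbrain/logP16")
        with pytest.raises(lk.LFERKitError, match="Flex"):
            model.predict_mapping({"logP16": 1.0, "Sm": 8.0, "HM_HBD": 0.0})

    def test_frame_prediction_matches_row_prediction(self):
        model = lk.get_preset("logKbrain/logP16")
        df = pd.DataFrame({
            "logP16": [0.5, 2.0], "Sm": [8.0, 12.0], "HM_HBD": [0.0, 3.0], "Flex": [1.0, 2.5],
        })
        frame_pred = model.predict_frame(df)
        for i in range(len(df)):
            assert frame_pred.iloc[i] == pytest.approx(model.predict_mapping(df.iloc[i].to_dict()))


class TestPresets:
    def test_registry_size(self):
        assert len(lk.preset_models()) == 6

    def test_skin_permeability_coefficients(self):
        m = lk.get_preset("logKp/logPoct")
        assert m.coefficients == {
            "logPoct": 0.6157, "Sm": 0.0156, "HM_HBD": -0.0626, "Flex": -0.0988,
        }
        assert m.intercept == -5.646
        assert (m.stats.n, m.stats.r2, m.stats.q2_ext, m.stats.sd, m.stats.f) == (
            32, 0.953, 0.966, 0.178, 136.7,
        )

    def test_brain_air_models(self):
        m16 = lk.get_preset("logKbrain/logP16")
        assert m16.coefficients == {
            "logP16": -0.5129, "Sm": 0.5006, "HM_HBD": 0.1009, "Flex": -0.1893,
        }
        assert (m16.intercept, m16.stats.n, m16.stats.q2_loo) == (-1.64, 34, 0.947)
        moct = lk.get_preset("logKbrain/logPoct")
        assert moct.basis_name == "logPoct"
        assert moct.coefficients["logPoct"] == -0.7755
        assert (moct.stats.r2, moct.stats.q2_loo, moct.stats.sd, moct.stats.f) == (
            0.931, 0.914, 0.368, 87.4,
        )
        slim = lk.get_preset("logKbrain/logP16-noHBD")
        assert slim.coefficients == {"logP16": -0.6194, "Sm": 0.5446, "Flex": -0.1928}
        assert slim.intercept == -1.637

    def test_aniline_models(self):
        full = lk.get_preset("logPaln/logP16")
        assert full.coefficients == {"logP16": 0.4695, "Sm": 0.1506}
        assert full.intercept == 0.010
        simple = lk.get_preset("logPaln/simple")
        assert simple.coefficients == {"logP16": 0.6416}
        assert simple.intercept == 0.726
        assert simple.stats.f == 524.9

    def test_presets_flagged_as_literature(self):
        assert all(m.provenance == "literature" for m in lk.preset_models())


class TestSerialization:
    def test_preset_round_trip(self):
        for model in lk.preset_models():
            again = lk.deserialize_model(lk.serialize_model(model))
            assert again == model

    def test_fitted_model_round_trips_to_full_precision(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 3))
        y = X @ [0.3, -1.2, 0.8] + rng.normal(size=20)
        df = make_table(X, y, ["a", "b", "c"])
        model = lk.fit(df, "y", ["a", "b", "c"])
        again = lk.deserialize_model(lk.serialize_model(model))
        for col in model.coefficients:
            assert again.coefficients[col] == model.coefficients[col]  # bitwise
        assert again.intercept == model.intercept
        assert again.training_meta["ids"] == model.training_meta["ids"]

    def test_truncated_text_reports_field(self):
        text = lk.serialize_model(lk.get_preset("logPaln/simple"))
        truncated = text[: len(text) // 2]
        with pytest.raises(lk.ModelFormatError):
            lk.deserialize_model(truncated)

    def test_unknown_field_rejected(self):
        import json

        payload = json.loads(lk.serialize_model(lk.get_preset("logPaln/simple")))
        payload["surprise"] = 1
        with pytest.raises(lk.ModelFormatError, match="surprise"):
            lk.deserialize_model(json.dumps(payload))

    def test_schema_version_mismatch_reported(self):
        import json

        payload = json.loads(lk.serialize_model(lk.get_preset("logPaln/simple")))
        payload["schema"] = "lfer-model/99"
        with pytest.raises(lk.ModelFormatError, match="schema"):
            lk.deserialize_model(json.dumps(payload))
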