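import numpy as np
import pandas as pd
import pytest

from qsarkit.descriptors import DescriptorMatrix
from qsarkit.metrics import pearson_r
from qsarkit.model import (
    ModelBundle,
    ModelError,
    ProtocolConfig,
    SvrConfig,
    cross_validate,
    run_protocol,
    train_svr,
)


def matrix_from(df: pd.DataFrame) -> DescriptorMatrix:
    return DescriptorMatrix(
        data=df, provenance={c: "chemical_continuous" for c in df.columns}
    )


def linear_data(rng, n=60, noise=0.0):
    X = rng.normal(size=(n, 3))
    y = X @ np.array([1.5, -1.0, 0.5]) + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=["a", "b", "c"], index=[f"c{i}" for i in range(n)])
    return matrix_from(df), y


class TestTrainSvr:
    def test_realizable_linear_target(self, rng):
        m, y = linear_data(rng)
        bundle = train_svr(m, y, SvrConfig(kernel="linear", C=100.0, epsilon=0.01))
        assert pearson_r(y, bundle.predict(m)) >= 0.999

    def test_pure_noise_cv_r_near_zero(self, rng):
        n = 100
        X = rng.normal(size=(n, 5))
        y = rng.normal(size=n)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)], index=[f"c{i}" for i in range(n)])
        rep = cross_validate(matrix_from(df), y, SvrConfig(seed=4))
        assert abs(rep.R) < 0.3

    def test_deterministic_support_coefficients(self, rng):
        m, y = linear_data(rng, noise=0.2)
        cfg = SvrConfig(seed=0)
        b1 = train_svr(m, y, cfg)
        b2 = train_svr(m, y, cfg)
        np.testing.assert_array_equal(b1.dual_coef, b2.dual_coef)
        np.testing.assert_array_equal(b1.support_vectors, b2.support_vectors)

    def test_zero_variance_feature_rejected(self, rng):
        m, y = linear_data(rng)
        m.data["dead"] = 1.0
        m.provenance["dead"] = "chemical_continuous"
        with pytest.raises(ModelError, match="dead"):
            train_svr(matrix_from(m.data), y)

    @pytest.mark.parametrize("kernel", ["linear", "polynomial", "rbf"])
    def test_manual_kernel_matches_sklearn(self, rng, kernel):
        # the bundle evaluates kernels itself; parity with the fitted engine
        from sklearn.svm import SVR

        m, y = linear_data(rng, noise=0.3)
        cfg = SvrConfig(kernel=kernel, seed=0)
        bundle = train_svr(m, y, cfg)
        X = m.values
        Xs = (X - bundle.center) / bundle.scale
        sk = SVR(
            kernel={"linear": "linear", "polynomial": "poly", "rbf": "rbf"}[kernel],
            C=cfg.C,
            epsilon=cfg.epsilon,
            gamma=bundle.gamma,
            degree=cfg.degree,
            coef0=cfg.coef0,
        ).fit(Xs, y)
        np.testing.assert_allclose(bundle.predict(m), sk.predict(Xs), atol=1e-10)


class TestPredict:
    def test_column_order_invariance(self, rng):
        m, y = linear_data(rng)
        bundle = train_svr(m, y)
        permuted = matrix_from(m.data[["c", "a", "b"]])
        np.testing.assert_allclose(bundle.predict(permuted), bundle.predict(m), atol=1e-12)

    def test_missing_feature_named(self, rng):
        m, y = linear_data(rng)
        bundle = train_svr(m, y)
        with pytest.raises(ModelError, match="'b'"):
            bundle.predict(matrix_from(m.data[["a", "c"]]))

    def test_training_residuals_near_zero_for_perfect_fit(self, rng):
        m, y = linear_data(rng)
        bundle = train_svr(m, y, SvrConfig(kernel="linear", C=1000.0, epsilon=0.001))
        assert np.abs(bundle.predict(m) - y).max() < 0.01


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        m, y = linear_data(rng, noise=0.2)
        bundle = train_svr(m, y, SvrConfig(seed=1), model_scope="hybrid")
        path = tmp_path / "model.json"
        bundle.save(path)
        back = ModelBundle.load(path)
        np.testing.assert_allclose(back.predict(m), bundle.predict(m), atol=1e-9)
        assert back.model_scope == "hybrid"
        assert back.feature_names == bundle.feature_names

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"something": 1}')
        with pytest.raises(ModelError):
            ModelBundle.load(p)


class TestCrossValidate:
    def test_learnable_relation_high_pooled_r(self, rng):
        m, y = linear_data(rng, n=80, noise=0.05)
        rep = cross_validate(m, y, SvrConfig(kernel="linear", seed=2))
        assert rep.R >= 0.99

    def test_shuffled_labels_destroy_signal(self, rng):
        m, y = linear_data(rng, n=80, noise=0.05)
        y_shuffled = rng.permutation(y)
        rep = cross_validate(m, y_shuffled, SvrConfig(kernel="linear", seed=2))
        assert abs(rep.R) < 0.35

    def test_fold_assignment_deterministic(self, rng):
        m, y = linear_data(rng, n=40, noise=0.2)
        r1 = cross_validate(m, y, SvrConfig(seed=9))
        r2 = cross_validate(m, y, SvrConfig(seed=9))
        assert r1.fold_assignment == r2.fold_assignment
        assert r1.R == r2.R

    def test_too_many_folds(self, rng):
        m, y = linear_data(rng, n=4)
        with pytest.raises(ModelError):
            cross_validate(m, y, SvrConfig(cv_folds=10))


@pytest.fixture
def protocol_cfg():
    return ProtocolConfig(seed=5, svr=SvrConfig(seed=5), run_f_stepping=False)


class TestRunProtocol:

    def test_single_class_returns_three_reports(self, synth_small, protocol_cfg):
        compounds, _, _ = synth_small
        res = run_protocol(compounds, None, "wild", protocol_cfg)
        assert set(res.reports) == {"whole", "train", "valid"}
        assert res.reports["whole"].n == 32
        assert res.reports["train"].n + res.reports["valid"].n == 32

    def test_hybrid_trains_on_union(self, synth_small, protocol_cfg):
        compounds, _, _ = synth_small
        res = run_protocol(compounds, None, "hybrid", protocol_cfg)
        assert res.reports["whole"].n == 64
        assert res.bundle.model_scope == "hybrid"

    def test_energy_columns_can_enter_the_model(self, synth_small):
        # with a strongly activity-linked binding energy the selected feature
        # set differs from the chemistry-only run by retained energy terms
        from qsarkit.synthdata import SynthConfig, generate_dataset

        compounds, energies, _ = generate_dataset(
            SynthConfig(n_per_class=48, n_class_b=0, energy_signal=0.9, seed=21)
        )
        cfg = ProtocolConfig(seed=5, svr=SvrConfig(seed=5), run_f_stepping=False)
        plain = run_protocol(compounds, None, "wild", cfg)
        fused = run_protocol(compounds, energies, "wild", cfg)
        extra = set(fused.selected_features) - set(plain.selected_features)
        assert "E_FreeBind" in extra

    def test_wrong_scope_errors(self, synth_small, protocol_cfg):
        compounds, _, _ = synth_small
        wild_only = [c for c in compounds if c.target_class == "wild"]
        with pytest.raises(ModelError):
            run_protocol(wild_only, None, "mutant", protocol_cfg)

    def test_noise_energies_do_not_degrade_cv(self):
        # selection filters uninformative docking columns: pooled CV R moves
        # by less than 0.05 when pure-noise energies are offered
        from qsarkit.synthdata import SynthConfig, generate_dataset

        compounds, energies, _ = generate_dataset(
            SynthConfig(n_per_class=48, n_class_b=0, energy_signal=0.0, seed=6)
        )
        cfg = ProtocolConfig(seed=6, svr=SvrConfig(seed=6), run_f_stepping=False)
        plain = run_protocol(compounds, None, "wild", cfg)
        noisy = run_protocol(compounds, energies, "wild", cfg)
        assert noisy.reports["train"].R >= plain.reports["train"].R - 0.05
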