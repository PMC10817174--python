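"""AE-NN model: threshold grid, fold protocol, autoencoder capacity,
determinism, and recovery of the planted signal."""

import numpy as np
import pytest

import rmsrepurpose as rr
from rmsrepurpose._nn import Autoencoder
from rmsrepurpose.aenn import (
    SingleClassDrugError,
    best_f1_threshold,
    panel_layers,
    predict_external,
)
from rmsrepurpose.metrics import ConfusionCounts, f1
from tests.conftest import AENN_PARAMS


def grid_scan_oracle(probs, labels, step=0.01):
    """Independent exhaustive scan over the threshold grid."""
    best_t, best = 0.0, -1.0
    n = round(1 / step)
    for i in range(n + 1):
        t = i * step
        pred = [1 if p > t else 0 for p in probs]
        score = f1(ConfusionCounts.from_calls(pred, labels))
        if score > best + 1e-15:
            best_t, best = t, score
    return best_t


class TestBestF1Threshold:
    def test_first_grid_value_reaching_perfect_f1(self):
        assert best_f1_threshold([0.2, 0.6, 0.7], [0, 1, 1]) == pytest.approx(0.20)

    def test_anti_separated_returns_zero(self):
        assert best_f1_threshold([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1]) == 0.0

    def test_no_positives_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert best_f1_threshold([0.2, 0.4], [0, 0]) == 0.0

    def test_step_must_divide_one(self):
        with pytest.raises(ValueError):
            best_f1_threshold([0.5], [1], step=0.03)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            p = np.round(rng.random(n), 3)
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            assert best_f1_threshold(p, y) == pytest.approx(grid_scan_oracle(p, y))


class TestAutoencoder:
    def test_linear_full_width_reconstructs(self, rng):
        X = rng.normal(size=(40, 6))
        ae = Autoencoder(bottleneck_dim=6, hidden_dims=(), learning_rate=0.02,
                         epochs=300, batch_size=40, seed=0).fit(X)
        assert ae.reconstruction_mse(X) < 0.05

    def test_capacity_monotone_on_rank_two_data(self, rng):
        basis = rng.normal(size=(2, 8))
        X = rng.normal(size=(60, 2)) @ basis
        mses = []
        for k in (1, 2):
            ae = Autoencoder(bottleneck_dim=k, hidden_dims=(), learning_rate=0.02,
                             epochs=200, batch_size=30, seed=1).fit(X)
            mses.append(ae.reconstruction_mse(X))
        assert mses[1] < mses[0]

    def test_fixed_seed_identical(self, rng):
        X = rng.normal(size=(30, 5))
        a = Autoencoder(bottleneck_dim=2, epochs=5, seed=3).fit(X)
        b = Autoencoder(bottleneck_dim=2, epochs=5, seed=3).fit(X)
        for wa, wb in zip(a.net_.params, b.net_.params):
            np.testing.assert_array_equal(wa, wb)

    def test_rejects_non_finite(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            Autoencoder(bottleneck_dim=1).fit(X)

    def test_loss_trace_recorded_and_finite(self, rng):
        X = rng.normal(size=(30, 5))
        ae = Autoencoder(bottleneck_dim=2, epochs=4, seed=0).fit(X)
        assert len(ae.loss_trace_) == 4
        assert np.isfinite(ae.loss_trace_).all()


@pytest.fixture(scope="module")
def fitted(small_panel):
    panel, responses, _ = small_panel
    y = responses.iloc[0].to_numpy()
    model = rr.AENNClassifier(
        bottleneck_dim=8, ae_hidden_dims=(16,), classifier_hidden_dims=(8,),
        ae_epochs=5, learning_rate=0.01, batch_size=16, seed=1,
    )
    model.fit(panel_layers(panel, ("expression", "cn_binary")), y)
    return model


class TestFoldProtocol:
    def test_five_fold_thresholds_mean(self, fitted):
        assert len(fitted.fold_thresholds_) == 5
        assert fitted.threshold_ == np.mean(fitted.fold_thresholds_)

    def test_every_sample_held_out_once(self, fitted):
        assert not np.isnan(fitted.cv_probabilities_).any()
        assert (fitted.fold_assignments_ >= 0).all()
        assert len(np.unique(fitted.fold_assignments_)) == 5

    def test_cv_metrics_in_unit_interval(self, fitted):
        assert 0.0 <= fitted.cv_auc_ <= 1.0
        assert 0.0 <= fitted.cv_f1_ <= 1.0

    def test_threshold_equality_maps_to_resistant(self, fitted, small_panel):
        panel, _, _ = small_panel
        layers = panel_layers(panel, ("expression", "cn_binary"))
        X = [layer[:1] for layer in layers]
        p = fitted.predict_proba(X)[0, 1]
        fitted_eq = rr.AENNClassifier(**fitted.get_params())
        fitted_eq.__dict__.update(fitted.__dict__)
        fitted_eq.threshold_ = float(p)
        assert fitted_eq.predict(X)[0] == 0
        records = predict_external(fitted_eq, X, ["cell"], "drug")
        assert records[0].call == "resistant"

    def test_nan_labels_dropped(self, small_panel):
        panel, responses, _ = small_panel
        y = responses.iloc[0].to_numpy().astype(float)
        y[:10] = np.nan
        model = rr.AENNClassifier(bottleneck_dim=4, ae_hidden_dims=(8,),
                                  classifier_hidden_dims=(8,), ae_epochs=3, seed=0)
        model.fit(panel_layers(panel, ("expression",)), y)
        assert len(model.cv_probabilities_) == len(y) - 10

    def test_single_class_raises_skip_error(self, small_panel):
        panel, _, _ = small_panel
        y = np.zeros(panel.n_cell_lines)
        with pytest.raises(SingleClassDrugError):
            rr.AENNClassifier().fit(panel_layers(panel, ("expression",)), y)

    def test_fixed_seed_reproducible(self, small_panel):
        panel, responses, _ = small_panel
        y = responses.iloc[0].to_numpy()
        layers = panel_layers(panel, ("expression",))
        kw = dict(bottleneck_dim=4, ae_hidden_dims=(8,), classifier_hidden_dims=(8,),
                  ae_epochs=3, seed=9)
        a = rr.AENNClassifier(**kw).fit(layers, y)
        b = rr.AENNClassifier(**kw).fit(layers, y)
        np.testing.assert_array_equal(a.cv_probabilities_, b.cv_probabilities_)
        assert a.fold_thresholds_ == b.fold_thresholds_

    def test_best_epoch_mode_runs(self, small_panel):
        panel, responses, _ = small_panel
        y = responses.iloc[0].to_numpy()
        model = rr.AENNClassifier(bottleneck_dim=4, ae_hidden_dims=(8,),
                                  classifier_hidden_dims=(8,), ae_epochs=3,
                                  epoch_mode="best", seed=0)
        model.fit(panel_layers(panel, ("expression",)), y)
        assert 0.0 <= model.cv_auc_ <= 1.0


class TestSignalRecovery:
    def test_strong_signal_recovered(self, aenn_strong):
        assert aenn_strong.cv_auc_ >= 0.80

    def test_permuted_labels_give_null_auc(self, strong_panel, strong_drug):
        panel, responses, _ = strong_panel
        # reduced size keeps the permutation loop quick
        sub = slice(0, 250)
        layers = [layer[sub] for layer in panel_layers(panel, ("expression",))]
        y = responses.loc[strong_drug].to_numpy()[sub]
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(10):
            yp = rng.permutation(y)
            model = rr.AENNClassifier(
                bottleneck_dim=8, ae_hidden_dims=(16,), classifier_hidden_dims=(8,),
                ae_epochs=5, learning_rate=0.01, batch_size=16, seed=2,
            ).fit(layers, yp)
            aucs.append(model.cv_auc_)
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_cv_auc_nondecreasing_in_effect_size(self):
        aucs = []
        for effect in (0.0, 1.0, 3.0):
            config = rr.PanelConfig(
                n_cell_lines=300, n_genes=100, n_drugs=1, n_informative_genes=8,
                effect_size=effect, sensitive_prevalence=0.2, seed=21,
            )
            panel, responses, _ = rr.generate_panel(config)
            pre = rr.preprocess_panel(panel, keep_fraction=None)
            model = rr.AENNClassifier(
                bottleneck_dim=12, ae_hidden_dims=(32,), classifier_hidden_dims=(16,),
                ae_epochs=10, learning_rate=0.01, batch_size=16, seed=5,
            ).fit(panel_layers(pre, ("expression", "cn_binary")),
                  responses.iloc[0].to_numpy())
            aucs.append(model.cv_auc_)
        assert aucs[1] >= aucs[0] - 0.05
        assert aucs[2] >= aucs[1] - 0.05

    def test_external_sensitive_line_recovered(self, strong_panel, strong_drug,
                                               aenn_strong):
        pre, _, truth = strong_panel
        hits = 0
        for seed in range(10):
            ext, labels = rr.make_external_lines(pre, truth, 30, 0.1, seed=seed)
            sensitive = labels.loc[strong_drug] == 1
            X = panel_layers(
                rr.preprocess_panel(ext, keep_fraction=None),
                ("expression", "cn_binary"),
            )
            calls = aenn_strong.predict(X)
            # the clearly sensitive lines of this draw should be called
            if calls[np.flatnonzero(sensitive.to_numpy())].mean() > 0.5:
                hits += 1
        assert hits >= 8
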