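"""Per-drug AE-NN drug-response classifier.

For one drug, each omics layer (log expression, binary copy-number
calls) is compressed by its own autoencoder; the bottleneck codes are
concatenated and fed to a small fully connected network with a sigmoid
output that scores the probability of the "sensitive" class.

Training runs stratified five-fold cross-validation. Within each fold
the classifier is trained for a small number of epochs and the fold's
held-out probabilities are the average of the per-epoch predictions
(an "average-epoch" scheme; a best-epoch variant is available). The
decision threshold of each fold maximizes F1 over a fixed grid of
cutoffs (0, 0.01, ..., 1); the final decision threshold is the mean of
the five fold thresholds. External samples are scored by averaging the
five fold models' probabilities and calling "sensitive" strictly above
the final threshold (a probability exactly equal to the threshold is
called resistant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._nn import Autoencoder, SigmoidClassifier
from .metrics import ConfusionCounts, f1, roc_auc

logger = logging.getLogger(__name__)

RESISTANT, SENSITIVE = "resistant", "sensitive"


class SingleClassDrugError(ValueError):
    """Raised when a drug's labels contain only one class (drug skipped)."""


@dataclass(frozen=True)
class PredictionRecord:
    """One model's call for one (drug, cell line) pair."""

    drug_id: str
    cell_id: str
    probability: float
    call: str
    threshold_used: float


def best_f1_threshold(probabilities, labels, step: float = 0.01) -> float:
    """Grid cutoff in {0, step, ..., 1} maximizing F1 of "sensitive iff p > t".

    Ties resolve to the smallest such cutoff. With no positive labels
    F1 is 0 everywhere; 0 is returned with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("threshold_grid_step must divide 1 evenly")
    if (y == 1).sum() == 0:
        warnings.warn("no positive labels; returning threshold 0", stacklevel=2)
        return 0.0
    grid = np.arange(n_steps + 1) * step
    best_t, best_f1 = 0.0, -1.0
    for t in grid:
        pred = (p > t).astype(int)
        score = f1(ConfusionCounts.from_calls(pred, y))
        if score > best_f1 + 1e-15:
            best_t, best_f1 = float(t), score
    return best_t


def _layers_list(X) -> list[np.ndarray]:
    if isinstance(X, (list, tuple)):
        layers = [np.asarray(layer, dtype=float) for layer in X]
    else:
        layers = [np.asarray(X, dtype=float)]
    n = layers[0].shape[0]
    if any(layer.shape[0] != n for layer in layers):
        raise ValueError("omics layers disagree on the number of cell lines")
    return layers


@dataclass
class _FoldModel:
    autoencoders: list[Autoencoder]
    classifier: SigmoidClassifier

    def predict_proba(self, layers: list[np.ndarray]) -> np.ndarray:
        codes = [ae.encode(layer) for ae, layer in zip(self.autoencoders, layers)]
        return self.classifier.predict_proba(np.hstack(codes))


class AENNClassifier(ClassifierMixin, BaseEstimator):
    """Autoencoder + neural-network drug-response classifier.

    Parameters
    ----------
    bottleneck_dim : int
        Autoencoder code size per omics layer.
    ae_hidden_dims, classifier_hidden_dims : tuple of int
        Hidden-layer widths of the autoencoders / the classifier head.
    ae_epochs : int
        Autoencoder training epochs per fold.
    epochs_per_fold : int
        Classifier epochs per fold; held-out probabilities are averaged
        over these epochs when ``epoch_mode='average'``.
    epoch_mode : {'average', 'best'}
        'best' instead keeps the epoch with the highest held-out AUC.
    threshold_grid_step : float
        Spacing of the F1 threshold grid; must divide 1 evenly.

    Attributes
    ----------
    fold_models_ : list
        The ``n_folds`` fitted (autoencoders, classifier) bundles.
    fold_thresholds_ : list of float
    threshold_ : float
        Mean of the fold thresholds; final decision cutoff.
    cv_auc_, cv_f1_ : float
        Fold-averaged held-out ROC AUC / F1 at the fold threshold.
    """

    def __init__(
        self,
        bottleneck_dim: int = 64,
        ae_hidden_dims: tuple[int, ...] = (256,),
        classifier_hidden_dims: tuple[int, ...] = (64,),
        ae_epochs: int = 20,
        epochs_per_fold: int = 3,
        n_folds: int = 5,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
        threshold_grid_step: float = 0.01,
        epoch_mode: str = "average",
    ):
        self.bottleneck_dim = bottleneck_dim
        self.ae_hidden_dims = ae_hidden_dims
        self.classifier_hidden_dims = classifier_hidden_dims
        self.ae_epochs = ae_epochs
        self.epochs_per_fold = epochs_per_fold
        self.n_folds = n_folds
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.threshold_grid_step = threshold_grid_step
        self.epoch_mode = epoch_mode

    # ------------------------------------------------------------ fitting

    def fit(self, X, y) -> "AENNClassifier":
        """Fit per-fold autoencoders and classifier heads.

        ``X`` is a single cell-line x feature matrix or a list of such
        matrices (one per omics layer); ``y`` holds 0/1 labels, NaN for
        unscreened lines (dropped).
        """
        if self.epochs_per_fold < 1 or self.n_folds < 2:
            raise ValueError("epochs_per_fold must be >= 1 and n_folds >= 2")
        if self.epoch_mode not in ("average", "best"):
            raise ValueError("epoch_mode must be 'average' or 'best'")
        layers = _layers_list(X)
        y = np.asarray(y, dtype=float)
        mask = ~np.isnan(y)
        layers = [layer[mask] for layer in layers]
        yv = y[mask].astype(int)
        counts = np.bincount(yv, minlength=2)
        if counts.min() < 2:
            raise SingleClassDrugError(
                f"need >= 2 cell lines per class, got {counts.tolist()}"
            )

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed % (2**32 - 1)
        )
        self.fold_models_ = []
        self.fold_thresholds_ = []
        fold_aucs, fold_f1s = [], []
        n = len(yv)
        self.cv_probabilities_ = np.full(n, np.nan)
        self.fold_assignments_ = np.full(n, -1)
        for fold, (tr, te) in enumerate(skf.split(layers[0], yv)):
            aes = []
            for li, layer in enumerate(layers):
                seed = int(
                    np.random.SeedSequence([self.seed, fold, li]).generate_state(1)[0]
                    % 2**31
                )
                ae = Autoencoder(
                    bottleneck_dim=min(self.bottleneck_dim, layer.shape[1]),
                    hidden_dims=self.ae_hidden_dims,
                    learning_rate=self.learning_rate,
                    batch_size=self.batch_size,
                    epochs=self.ae_epochs,
                    seed=seed,
                ).fit(layer[tr])
                aes.append(ae)
            H_tr = np.hstack([ae.encode(layer[tr]) for ae, layer in zip(aes, layers)])
            H_te = np.hstack([ae.encode(layer[te]) for ae, layer in zip(aes, layers)])
            clf_seed = int(
                np.random.SeedSequence([self.seed, fold, 997]).generate_state(1)[0]
                % 2**31
            )
            clf = SigmoidClassifier(
                hidden_dims=self.classifier_hidden_dims,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                seed=clf_seed,
            )
            epoch_probs = []
            for _ in range(self.epochs_per_fold):
                clf.partial_fit(H_tr, yv[tr].astype(float))
                epoch_probs.append(clf.predict_proba(H_te))
            if self.epoch_mode == "average":
                probs = np.mean(epoch_probs, axis=0)
            else:
                aucs = [roc_auc(p, yv[te]) for p in epoch_probs]
                probs = epoch_probs[int(np.nanargmax(aucs))]
            t = best_f1_threshold(probs, yv[te], self.threshold_grid_step)
            self.fold_thresholds_.append(t)
            fold_aucs.append(roc_auc(probs, yv[te]))
            fold_f1s.append(
                f1(ConfusionCounts.from_calls((probs > t).astype(int), yv[te]))
            )
            self.fold_models_.append(_FoldModel(aes, clf))
            self.cv_probabilities_[te] = probs
            self.fold_assignments_[te] = fold

        self.threshold_ = float(np.mean(self.fold_thresholds_))
        self.cv_auc_ = float(np.nanmean(fold_aucs))
        self.cv_f1_ = float(np.mean(fold_f1s))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = sum(layer.shape[1] for layer in layers)
        return self

    # ---------------------------------------------------------- prediction

    def predict_proba(self, X) -> np.ndarray:
        """Mean of the fold models' sensitive-class probabilities, as
        an (n, 2) array ordered [resistant, sensitive]."""
        layers = _layers_list(X)
        p = np.mean([fm.predict_proba(layers) for fm in self.fold_models_], axis=0)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        """Binary calls: 1 (sensitive) iff probability strictly exceeds
        the final threshold."""
        p = self.predict_proba(X)[:, 1]
        return (p > self.threshold_).astype(int)


def predict_external(
    model: AENNClassifier, X, cell_ids: list[str], drug_id: str
) -> list[PredictionRecord]:
    """Score external samples and emit one record per cell line."""
    probs = model.predict_proba(X)[:, 1]
    return [
        PredictionRecord(
            drug_id=drug_id,
            cell_id=cid,
            probability=float(p),
            call=SENSITIVE if p > model.threshold_ else RESISTANT,
            threshold_used=model.threshold_,
        )
        for cid, p in zip(cell_ids, probs)
    ]


def panel_layers(panel, layer_names=("expression", "cn_binary")) -> list[np.ndarray]:
    """Extract aligned numeric layer matrices from a preprocessed panel."""
    return [panel.layer(name).to_numpy(dtype=float) for name in layer_names]
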