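"""Super.FELT-style drug-response classifier (second ensemble member).

Each omics layer (expression, binary copy number, binary mutation) is
embedded by a supervised encoder trained with a margin triplet loss so
that same-class cell lines land close together; the concatenated
embeddings feed a sigmoid classifier head.

Training runs stratified five-fold cross-validation. Each fold keeps
its own decision threshold, chosen among the distinct operating points
of the fold-test ROC curve as the one maximizing F1 (ties resolve to
the largest cutoff). An external sample receives five binary calls —
fold member ``i`` calls "sensitive" when its probability is at least
its own threshold — and the final call is the majority vote. With an
even number of folds a tie resolves to "resistant".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from ._nn import SigmoidClassifier, TripletEncoder
from .aenn import RESISTANT, SENSITIVE, SingleClassDrugError, PredictionRecord, _layers_list
from .metrics import ConfusionCounts, f1, roc_auc

logger = logging.getLogger(__name__)


def roc_f1_threshold(probabilities, labels) -> float:
    """F1-optimal cutoff among the ROC curve's operating points.

    Candidates are the distinct attained score values (the thresholds
    of ``sklearn.metrics.roc_curve``); the rule is "sensitive iff
    p >= t". Ties on F1 resolve to the largest cutoff (most
    conservative toward "resistant").
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _, _, thresholds = roc_curve(y, p)
    cutpoints = np.unique(thresholds[np.isfinite(thresholds)])[::-1]  # descending
    best_t, best_f1 = None, -1.0
    for t in cutpoints:  # largest first, so strict improvement keeps largest
        pred = (p >= t).astype(int)
        score = f1(ConfusionCounts.from_calls(pred, y))
        if score > best_f1 + 1e-15:
            best_t, best_f1 = float(t), score
    return best_t


@dataclass
class _FoldMember:
    encoders: list[TripletEncoder]
    classifier: SigmoidClassifier
    threshold: float

    def predict_proba(self, layers: list[np.ndarray]) -> np.ndarray:
        emb = [enc.transform(layer) for enc, layer in zip(self.encoders, layers)]
        return self.classifier.predict_proba(np.hstack(emb))

    def predict(self, layers: list[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(layers) >= self.threshold).astype(int)


class SuperFeltClassifier(ClassifierMixin, BaseEstimator):
    """Triplet-loss feature extraction + classifier with per-fold
    thresholds and majority-vote prediction.

    Attributes
    ----------
    fold_members_ : list
        ``n_folds`` fitted (encoders, classifier, threshold) members.
    cv_auc_, cv_f1_ : float
        Fold-averaged held-out metrics (F1 at each fold's own cutoff).
    """

    def __init__(
        self,
        embedding_dim: int = 32,
        encoder_hidden_dims: tuple[int, ...] = (64,),
        classifier_hidden_dims: tuple[int, ...] = (32,),
        triplet_margin: float = 1.0,
        encoder_epochs: int = 10,
        classifier_epochs: int = 10,
        n_folds: int = 5,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        seed: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.encoder_hidden_dims = encoder_hidden_dims
        self.classifier_hidden_dims = classifier_hidden_dims
        self.triplet_margin = triplet_margin
        self.encoder_epochs = encoder_epochs
        self.classifier_epochs = classifier_epochs
        self.n_folds = n_folds
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y) -> "SuperFeltClassifier":
        """Fit fold members on a list of omics layers and 0/1/NaN labels."""
        if self.triplet_margin <= 0:
            raise ValueError("triplet_margin must be positive")
        layers = _layers_list(X)
        y = np.asarray(y, dtype=float)
        mask = ~np.isnan(y)
        layers = [layer[mask] for layer in layers]
        yv = y[mask].astype(int)
        if np.bincount(yv, minlength=2).min() < 2:
            raise SingleClassDrugError("need >= 2 cell lines per class")

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed % (2**32 - 1)
        )
        self.fold_members_ = []
        fold_aucs, fold_f1s = [], []
        for fold, (tr, te) in enumerate(skf.split(layers[0], yv)):
            encoders = []
            for li, layer in enumerate(layers):
                seed = int(
                    np.random.SeedSequence([self.seed, 7, fold, li]).generate_state(1)[0]
                    % 2**31
                )
                enc = TripletEncoder(
                    embedding_dim=min(self.embedding_dim, layer.shape[1]),
                    hidden_dims=self.encoder_hidden_dims,
                    margin=self.triplet_margin,
                    learning_rate=self.learning_rate,
                    batch_size=self.batch_size,
                    epochs=self.encoder_epochs,
                    seed=seed,
                ).fit(layer[tr], yv[tr])
                encoders.append(enc)
            E_tr = np.hstack([e.transform(layer[tr]) for e, layer in zip(encoders, layers)])
            E_te = np.hstack([e.transform(layer[te]) for e, layer in zip(encoders, layers)])
            clf_seed = int(
                np.random.SeedSequence([self.seed, 7, fold, 997]).generate_state(1)[0]
                % 2**31
            )
            clf = SigmoidClassifier(
                hidden_dims=self.classifier_hidden_dims,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                seed=clf_seed,
            ).fit(E_tr, yv[tr].astype(float), epochs=self.classifier_epochs)
            probs = clf.predict_proba(E_te)
            t = roc_f1_threshold(probs, yv[te])
            fold_aucs.append(roc_auc(probs, yv[te]))
            fold_f1s.append(
                f1(ConfusionCounts.from_calls((probs >= t).astype(int), yv[te]))
            )
            self.fold_members_.append(_FoldMember(encoders, clf, t))

        self.cv_auc_ = float(np.nanmean(fold_aucs))
        self.cv_f1_ = float(np.mean(fold_f1s))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = sum(layer.shape[1] for layer in layers)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Mean member probability, (n, 2) ordered [resistant, sensitive].

        Reported for reference; the binary decision is the majority
        vote of the members' own thresholded calls, not a cut on this
        mean.
        """
        layers = _layers_list(X)
        p = np.mean([m.predict_proba(layers) for m in self.fold_members_], axis=0)
        return np.column_stack([1 - p, p])

    def member_calls(self, X) -> np.ndarray:
        """(n_folds, n_samples) binary calls, one row per fold member."""
        layers = _layers_list(X)
        return np.vstack([m.predict(layers) for m in self.fold_members_])

    def predict(self, X) -> np.ndarray:
        """Majority vote over fold members; even-split ties -> resistant."""
        calls = self.member_calls(X)
        votes = calls.sum(axis=0)
        return (votes > calls.shape[0] / 2).astype(int)


def predict_majority(
    model: SuperFeltClassifier, X, cell_ids: list[str], drug_id: str
) -> list[PredictionRecord]:
    """Majority-vote records for external samples.

    ``threshold_used`` is NaN: each fold member applied its own cutoff.
    """
    probs = model.predict_proba(X)[:, 1]
    calls = model.predict(X)
    return [
        PredictionRecord(
            drug_id=drug_id,
            cell_id=cid,
            probability=float(p),
            call=SENSITIVE if c else RESISTANT,
            threshold_used=float("nan"),
        )
        for cid, p, c in zip(cell_ids, probs, calls)
    ]
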