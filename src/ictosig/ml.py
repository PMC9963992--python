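"""Machine-learning procedures over compound transcriptomic features.

Two classifiers are provided. (a) One-vs-rest classification of compound
categories on rank-transformed normalized counts: per-sample rank
transform, per-gene median over replicates, z-scoring, an F-ratio feature
filter, and a regularized linear / max-margin classifier tuned by nested
cross-validation with an inner leave-one-out loop. (b) A single-feature
logistic classifier separating FAERS-positive from FAERS-negative
compounds, where the feature is the number of tool compounds sharing at
least one upregulated DE gene (after noise subtraction), evaluated by
leave-one-out cross-validation with a no-information-rate binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .similarity import negative_noise_union, subtract_noise
from .types import ClassificationReport, DEGeneSet

__all__ = [
    "FeatureMatrix",
    "rank_median_standardize",
    "RankMedianStandardizer",
    "f_values",
    "f_value_select",
    "FRatioSelector",
    "ovr_nested_cv",
    "tool_sharing_feature",
    "loocv_shared_feature",
    "SharedSignatureClassifier",
    "classification_metrics",
    "concordance_auc",
]

DEFAULT_MODEL_GRID: tuple[dict, ...] = tuple(
    [
        {"model": "lr", "penalty": p, "C": C, "k": k}
        for p in ("l1", "l2")
        for C in (0.1, 1.0)
        for k in (50, None)
    ]
    + [
        {"model": "svm", "kernel": kern, "C": 1.0, "k": k}
        for kern in ("linear", "rbf")
        for k in (50, None)
    ]
)


@dataclass
class FeatureMatrix:
    """Compounds × features matrix with provenance and labels."""

    values: pd.DataFrame
    provenance: str
    labels: Optional[pd.Series] = None


# ---------------------------------------------------------------------------
# Rank / median / standardize feature construction


def _rank_median(counts_by_compound: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = {}
    index = None
    for cid, counts in counts_by_compound.items():
        if index is None:
            index = counts.index
        elif not counts.index.equals(index):
            raise ValueError(f"{cid}: gene index differs from other compounds")
        ranks = np.apply_along_axis(
            stats.rankdata, 0, counts.to_numpy(dtype=float)
        )
        rows[cid] = np.median(ranks, axis=1)
    return pd.DataFrame.from_dict(rows, orient="index", columns=index)


class RankMedianStandardizer(BaseEstimator, TransformerMixin):
    """Z-score per-gene rank-median features over compounds.

    Input X is a compounds × genes matrix of per-compound rank medians (see
    :func:`rank_median_standardize` for construction from raw counts); the
    transformer standardizes each gene to zero mean and unit variance over
    the compounds seen in ``fit`` and drops zero-variance genes.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        self.keep_ = self.scale_ > 0
        self.dropped_ = int((~self.keep_).sum())
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep_] - self.mean_[self.keep_]) / self.scale_[self.keep_]


def rank_median_standardize(
    counts_by_compound: Mapping[str, pd.DataFrame],
    labels: Optional[Mapping[str, str]] = None,
) -> FeatureMatrix:
    """Build standardized rank-median features from replicate count matrices.

    Per sample, counts are replaced by average ranks over genes (ties
    averaged); per compound, the per-gene median over replicates is taken;
    each gene is then z-scored over the dataset. Zero-variance genes are
    dropped. Rank transformation makes the features invariant to any
    monotone per-sample normalization.
    """
    med = _rank_median(counts_by_compound)
    tf = RankMedianStandardizer().fit(med.to_numpy())
    vals = pd.DataFrame(
        tf.transform(med.to_numpy()),
        index=med.index,
        columns=med.columns[tf.keep_],
    )
    lab = (
        pd.Series({c: labels[c] for c in med.index}) if labels is not None else None
    )
    return FeatureMatrix(values=vals, provenance="rank_median_standardized",
                         labels=lab)


# ---------------------------------------------------------------------------
# F-ratio feature selection


def f_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature ratio of the variance of group means to the mean
    within-group variance (sample variances, ddof=1).

    This is the screening ratio as defined for the pipeline, not the
    df-scaled ANOVA F statistic; a feature with zero within-group variance
    but distinct group means scores +inf, identical group means score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = [X[y == g] for g in np.unique(y)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    means = np.stack([g.mean(axis=0) for g in groups])
    between = means.var(axis=0, ddof=1)
    within = np.stack([g.var(axis=0, ddof=1) for g in groups]).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = between / within
    F = np.where((within == 0) & (between > 0), np.inf, F)
    F = np.where((within == 0) & (between == 0), 0.0, F)
    return F


class FRatioSelector(BaseEstimator, TransformerMixin):
    """Keep the k features with the highest F-ratio (ties: lower index wins).

    ``k=None`` disables filtering.
    """

    def __init__(self, k: Optional[int] = None):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n_features = X.shape[1]
        if self.k is None:
            self.support_ = np.ones(n_features, dtype=bool)
            return self
        if not 0 < self.k <= n_features:
            raise ValueError(
                f"k={self.k} out of range for {n_features} features"
            )
        self.scores_ = f_values(X, y)
        order = np.argsort(-self.scores_, kind="stable")[: self.k]
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[order] = True
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


def f_value_select(features: FeatureMatrix, k: int) -> FeatureMatrix:
    """Return the feature matrix restricted to the top-k F-ratio features."""
    if features.labels is None:
        raise ValueError("feature matrix has no labels for grouping")
    sel = FRatioSelector(k=k).fit(
        features.values.to_numpy(), features.labels.to_numpy()
    )
    vals = features.values.loc[:, features.values.columns[sel.support_]]
    return FeatureMatrix(values=vals, provenance=features.provenance,
                         labels=features.labels)


# ---------------------------------------------------------------------------
# Metric kernel


def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by all-pairs concordance; tied scores count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def classification_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> ClassificationReport:
    """Pooled binary classification metrics with NIR and exact binomial test.

    The no-information rate (NIR) is the larger class proportion; the
    binomial p is the exact one-sided probability of at least the observed
    number of correct calls under chance accuracy equal to the NIR.
    """
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction and label vectors differ in length")
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    n = len(y_true)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    degenerate = len(np.unique(y_true)) < 2
    if scores is not None and not degenerate:
        auc = concordance_auc(np.asarray(scores, dtype=float), y_true)
    else:
        auc = float("nan")
    nir = max(np.mean(y_true), 1 - np.mean(y_true))
    binom_p = float(
        stats.binomtest(tp + tn, n, p=nir, alternative="greater").pvalue
    )
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        auc=auc, nir=float(nir), binom_p=binom_p, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Shared-DE-gene feature classifier


def tool_sharing_feature(compound: DEGeneSet, tools: Sequence[DEGeneSet]) -> int:
    """Number of tool compounds sharing >= 1 upregulated DE gene."""
    return sum(1 for t in tools if compound.up & t.up)


class SharedSignatureClassifier(BaseEstimator, ClassifierMixin):
    """Logistic classifier on the tool-sharing count feature.

    The scalar feature of a compound is the number of tool compounds with
    which it shares at least one upregulated DE gene after the pooled
    FAERS-negative genes are subtracted from every set. ``fit`` takes the
    training DE gene sets (X) and binary labels; tool and negative sets are
    fixed at construction.
    """

    def __init__(
        self,
        tools: Sequence[DEGeneSet] = (),
        negatives: Sequence[DEGeneSet] = (),
    ):
        self.tools = tools
        self.negatives = negatives

    def _prepare(self) -> tuple[frozenset[str], list[DEGeneSet]]:
        noise = negative_noise_union(list(self.negatives))
        tools = [subtract_noise(t, noise) for t in self.tools]
        return noise, tools

    def features(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        noise, tools = self._prepare()
        return np.array(
            [tool_sharing_feature(subtract_noise(s, noise), tools) for s in X],
            dtype=float,
        ).reshape(-1, 1)

    def fit(self, X: Sequence[DEGeneSet], y):
        y = np.asarray(y).astype(int)
        f = self.features(X)
        self.degenerate_ = bool(np.all(f == f[0]))
        if self.degenerate_ or len(np.unique(y)) < 2:
            self.prior_ = float(np.mean(y))
            self.model_ = None
        else:
            # near-unpenalized logistic fit with intercept
            self.model_ = LogisticRegression(C=1e6, solver="lbfgs").fit(f, y)
        return self

    def predict_proba(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        f = self.features(X)
        if self.model_ is None:
            p = np.full(len(f), self.prior_)
            return np.column_stack([1 - p, p])
        return self.model_.predict_proba(f)

    def predict(self, X: Sequence[DEGeneSet]) -> np.ndarray:
        return self.predict_proba(X)[:, 1] > 0.5


def loocv_shared_feature(
    positives: Sequence[DEGeneSet],
    negatives: Sequence[DEGeneSet],
    tools: Sequence[DEGeneSet],
    seed: int | None = None,
) -> ClassificationReport:
    """Leave-one-out evaluation of the shared-signature logistic classifier.

    Each FAERS-positive / FAERS-negative compound is held out in turn; a
    logistic model with intercept is fit on the remaining compounds'
    tool-sharing counts and the held-out compound is called positive when
    its predicted probability exceeds 0.5. Pooled probabilities give the
    concordance AUC; accuracy is tested against the no-information rate
    with an exact one-sided binomial test. The result is independent of
    compound ordering and of ``seed`` (kept for interface symmetry).
    """
    if len(positives) < 2 or len(negatives) < 2:
        raise ValueError("need >= 2 compounds per class")
    compounds = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    clf = SharedSignatureClassifier(tools=tools, negatives=negatives)
    feats = clf.features(compounds)
    if np.all(feats == feats[0]):
        rep = classification_metrics(y, np.zeros_like(y), scores=feats[:, 0])
        rep.degenerate = True
        rep.auc = 0.5
        return rep
    probs = np.empty(len(compounds))
    order = np.argsort([c.compound_id for c in compounds], kind="stable")
    for i in order:  # order-invariant by construction; loop order irrelevant
        mask = np.ones(len(compounds), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            probs[i] = float(np.mean(y[mask]))
            continue
        model = LogisticRegression(C=1e6, solver="lbfgs").fit(
            feats[mask], y[mask]
        )
        probs[i] = model.predict_proba(feats[i:i + 1])[0, 1]
    pred = probs > 0.5
    rep = classification_metrics(y, pred, scores=probs)
    rep.predictions = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "label": y,
            "feature": feats[:, 0],
            "probability": probs,
            "predicted": pred,
        }
    ).set_index("compound_id")
    return rep


# ---------------------------------------------------------------------------
# One-vs-rest nested cross-validation on count features


def _make_model(spec: dict, rng_seed: int):
    if spec["model"] == "lr":
        l1 = spec.get("penalty") == "l1"
        return LogisticRegression(
            C=spec.get("C", 1.0), l1_ratio=1.0 if l1 else 0.0,
            solver="liblinear" if l1 else "lbfgs",
            max_iter=2000, random_state=rng_seed,
        )
    if spec["model"] == "svm":
        return SVC(
            kernel=spec.get("kernel", "linear"), C=spec.get("C", 1.0),
            random_state=rng_seed,
        )
    raise ValueError(f"unknown model {spec['model']!r}")


def _fit_predict(
    spec: dict,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    standardize: bool,
):
    """Fit scaler → F-ratio filter → classifier on training data only."""
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    k = spec.get("k")
    if k is not None:
        k = min(k, X_train.shape[1])
        sel = FRatioSelector(k=k).fit(X_train, y_train)
        X_train = sel.transform(X_train)
        X_test = sel.transform(X_test)
    model = _make_model(spec, seed)
    model.fit(X_train, y_train)
    pred = model.predict(X_test)
    if hasattr(model, "decision_function"):
        score = model.decision_function(X_test)
    else:
        score = model.predict_proba(X_test)[:, 1]
    return pred, score


def _inner_loocv_accuracy(
    spec: dict, X: np.ndarray, y: np.ndarray, seed: int, standardize: bool
) -> float:
    correct = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            pred = np.array([int(np.round(np.mean(y[mask])))])
        else:
            pred, _ = _fit_predict(
                spec, X[mask], y[mask], X[i:i + 1], seed, standardize
            )
        correct += int(pred[0] == y[i])
    return correct / len(y)


def ovr_nested_cv(
    features: FeatureMatrix,
    target_group: str,
    outer_reps: int = 1,
    seed: int | None = None,
    model_grid: Sequence[dict] = DEFAULT_MODEL_GRID,
    global_standardize: bool = False,
    n_test_others: tuple[int, int] = (3, 4),
) -> ClassificationReport:
    """One-vs-rest nested cross-validation over compounds.

    Outer loop: each target-group compound in turn (repeated ``outer_reps``
    times) forms a test set together with 3–4 randomly sampled non-target
    compounds; a classifier tuned by inner leave-one-out CV on the training
    compounds predicts the test set, and predictions are pooled over all
    outer folds. By default, feature standardization is fit inside each
    training fold; ``global_standardize=True`` standardizes once over the whole
    dataset before splitting (a leaky but sometimes-reported variant).
    """
    if not model_grid:
        raise ValueError("model_grid must be non-empty")
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    X = features.values.to_numpy(dtype=float)
    labels = features.labels.to_numpy()
    y = (labels == target_group).astype(int)
    target_idx = np.flatnonzero(y == 1)
    other_idx = np.flatnonzero(y == 0)
    if len(target_idx) < 2:
        raise ValueError("target group must contain >= 2 compounds")
    if global_standardize:
        X = StandardScaler().fit_transform(X)
    rng = np.random.default_rng(seed)
    pooled_true, pooled_pred, pooled_score = [], [], []
    for _ in range(outer_reps):
        for ti in target_idx:
            n_extra = int(rng.choice(range(n_test_others[0], n_test_others[1] + 1)))
            extra = rng.choice(other_idx, size=min(n_extra, len(other_idx)),
                               replace=False)
            test = np.concatenate([[ti], extra])
            train = np.setdiff1d(np.arange(len(y)), test)
            inner_seed = int(rng.integers(2**31 - 1))
            accs = [
                _inner_loocv_accuracy(
                    spec, X[train], y[train], inner_seed,
                    standardize=not global_standardize,
                )
                for spec in model_grid
            ]
            best = model_grid[int(np.argmax(accs))]
            pred, score = _fit_predict(
                best, X[train], y[train], X[test], inner_seed,
                standardize=not global_standardize,
            )
            pooled_true.extend(y[test])
            pooled_pred.extend(pred)
            pooled_score.extend(np.atleast_1d(score))
    return classification_metrics(pooled_true, pooled_pred, scores=pooled_score)
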