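"""Binary random-forest discrimination of VOC profiles.

Workflow (per pairwise contrast, e.g. fibrotic group vs controls):

1.  :func:`duplex_split` — the Duplex algorithm (Snee's alternating
    farthest-point partition) assigns each class's samples to train/test
    deterministically, test quota 20% per class (round half up).
2.  :func:`train_forest` — a random forest on the training set; the OOB
    error internally validates the profile (accuracy = 1 - error), variable
    importance is the Breiman permutation importance (mean decrease in OOB
    accuracy per tree), and the forest's proximity matrix (fraction of trees
    in which two samples co-land in a terminal node) gives a learned
    similarity over samples.
3.  :func:`select_discriminatory_vocs` — cut the sorted importance curve at
    its largest consecutive gap: the VOCs standing clearly above the rest.
4.  :func:`refit_and_validate` — refit on the selected VOCs only; report
    test accuracy/sensitivity/specificity at vote threshold 0.5 and the ROC
    over all vote thresholds.
5.  :func:`proximity_embed` — classical multidimensional scaling of
    D = 1 - proximity (a PCA on the proximity structure); out-of-sample
    points enter via the Gower/Nystrom extension (:func:`project_sample`).

Proximity convention: large proximity = similar (samples co-land in leaves),
distance = 1 - proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .io import FeatureMatrix, ValidationError

logger = logging.getLogger("breathdisc")


# ---------------------------------------------------------------------------
# Duplex split


@dataclass
class SplitPlan:
    """Deterministic train/test partition from the Duplex algorithm."""

    train_ids: list
    test_ids: list
    class_counts: dict            # class -> {"train": n, "test": n}
    metric: str = "euclidean (z-scored features)"
    trace: list = field(default_factory=list)  # (set, sample_id) in order

    def train_mask(self, fm: FeatureMatrix) -> np.ndarray:
        t = set(self.train_ids)
        return np.array([s in t for s in fm.sample_ids])

    def test_mask(self, fm: FeatureMatrix) -> np.ndarray:
        t = set(self.test_ids)
        return np.array([s in t for s in fm.sample_ids])


def _duplex_one_class(dist: np.ndarray, quota: int):
    """Duplex on one class given its pairwise distances.

    Snee's pair alternation: the two mutually farthest points seed TRAIN, the
    two farthest among the rest seed TEST, and thereafter the farthest
    remaining pair goes alternately to TRAIN and TEST until TEST reaches its
    quota; the remainder joins TRAIN (excess over an odd quota is returned to
    TRAIN). Ties break to the smaller index. Alternating whole pairs keeps
    the TEST set representative of the class's spread instead of a purely
    interpolative interior sample, which would make held-out validation
    optimistic.
    """
    n = dist.shape[0]
    unassigned = set(range(n))

    def farthest_pair(cands):
        best = (-1.0, None)
        cl = sorted(cands)
        for ai, a in enumerate(cl):
            for b in cl[ai + 1:]:
                if dist[a, b] > best[0] + 1e-12:
                    best = (dist[a, b], (a, b))
        return best[1]

    train, test = [], []
    turn = 0  # 0 -> train, 1 -> test
    while unassigned and len(test) < quota:
        pair = farthest_pair(unassigned) if len(unassigned) >= 2 else tuple(unassigned)
        target = train if turn == 0 else test
        target.extend(pair)
        unassigned -= set(pair)
        turn ^= 1
    if len(test) > quota:  # odd quota: the last-added excess returns to TRAIN
        train.extend(test[quota:])
        test = test[:quota]
    train.extend(sorted(unassigned))
    return train, test


def duplex_split(fm: FeatureMatrix, classes, test_frac: float = 0.2) -> SplitPlan:
    """Per-class Duplex partition on z-scored features, Euclidean distance."""
    classes = tuple(classes)
    groups = np.asarray(fm.groups)
    for c in classes:
        if (groups == c).sum() < 5:
            raise ValidationError(f"class {c!r}: fewer than 5 samples")
    mask = np.isin(groups, classes)
    X = fm.areas[mask]
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    ids = [s for s, m in zip(fm.sample_ids, mask) if m]
    sub_groups = groups[mask]

    train_ids, test_ids, counts, trace = [], [], {}, []
    for c in classes:
        rows = np.flatnonzero(sub_groups == c)
        quota = int(np.floor(test_frac * rows.size + 0.5))  # round half up
        if quota < 1:
            raise ValidationError(f"class {c!r}: test quota is 0 at test_frac={test_frac}")
        D = np.sqrt(((Z[rows, None, :] - Z[None, rows, :]) ** 2).sum(-1))
        tr, te = _duplex_one_class(D, quota)
        train_ids += [ids[rows[i]] for i in tr]
        test_ids += [ids[rows[i]] for i in te]
        counts[c] = {"train": len(tr), "test": len(te)}
        trace += [("train", ids[rows[i]]) for i in tr] + [("test", ids[rows[i]]) for i in te]
    return SplitPlan(train_ids, test_ids, counts, trace=trace)


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney form)


def auc(scores_pos, scores_neg) -> float:
    """AUC as the Mann-Whitney U statistic / (n_pos * n_neg); ties count 1/2."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("auc: both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# proximity forest


class ProximityForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with OOB error, per-tree OOB permutation importance and
    proximity computation.

    Thin estimator over sklearn's RandomForestClassifier; adds the pieces
    the discrimination workflow needs that sklearn does not expose: the
    Breiman mean-decrease-in-accuracy importance (each feature permuted in
    each tree's OOB samples) and the proximity matrix over arbitrary samples
    pushed through the fitted forest.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValidationError("training set contains a single class")
        mtry = self.mtry or max(1, int(np.sqrt(X.shape[1])))
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=min(mtry, X.shape[1]),
            oob_score=True,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.oob_error_ = 1.0 - float(self.forest_.oob_score_)
        self.X_train_, self.y_train_ = X, y
        # per-tree OOB membership of each training sample
        mask = np.ones((X.shape[0], self.n_trees), dtype=bool)
        for t, inbag in enumerate(self.forest_.estimators_samples_):
            mask[np.unique(inbag), t] = False
        self.oob_mask_ = mask
        self.importances_ = self._permutation_importance()
        return self

    def _permutation_importance(self) -> np.ndarray:
        """Mean decrease in per-tree OOB accuracy when a feature is permuted.

        Only trees that actually split on the feature are evaluated (others
        contribute exactly zero decrease).
        """
        X, y = self.X_train_, self.y_train_
        n, p = X.shape
        rng = np.random.default_rng(self.seed)
        totals = np.zeros(p)
        all_idx = np.arange(n)
        # individual trees predict encoded class indices, not labels
        y_enc = np.searchsorted(self.forest_.classes_, y).astype(float)
        for tree, inbag in zip(self.forest_.estimators_, self.forest_.estimators_samples_):
            oob = np.setdiff1d(all_idx, inbag, assume_unique=False)
            if oob.size == 0:
                continue
            Xo = X[oob]
            base = (tree.predict(Xo) == y_enc[oob]).mean()
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            perm = rng.permutation(oob.size)
            for f in used:
                Xp = Xo.copy()
                Xp[:, f] = Xo[perm, f]
                acc = (tree.predict(Xp) == y_enc[oob]).mean()
                totals[f] += base - acc
        return totals / self.n_trees

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, dtype=float))

    def vote_fraction(self, X, positive) -> np.ndarray:
        """Fraction of trees voting for the given positive class."""
        proba = self.forest_.predict_proba(np.asarray(X, dtype=float))
        return proba[:, list(self.forest_.classes_).index(positive)]

    def proximity(self, X, Y=None, mask_x=None, mask_y=None) -> np.ndarray:
        """Fraction of trees in which samples co-land in a terminal node.

        ``mask_x``/``mask_y`` restrict which trees may count for each sample
        (boolean, n_samples x n_trees). Training samples should be evaluated
        only on trees where they were out of bag — in-bag co-landing encodes
        the fitted labels and would fabricate class structure even under a
        label-free null. Pairs with no admissible tree in common fall back to
        all trees.
        """
        leaves_x = self.forest_.apply(np.asarray(X, dtype=float))
        leaves_y = leaves_x if Y is None else self.forest_.apply(np.asarray(Y, dtype=float))
        same = leaves_x[:, None, :] == leaves_y[None, :, :]
        if mask_x is None and mask_y is None:
            return same.mean(axis=2)
        if mask_x is None:
            mask_x = np.ones(leaves_x.shape, dtype=bool)
        if mask_y is None:
            mask_y = np.ones(leaves_y.shape, dtype=bool)
        pair_ok = mask_x[:, None, :] & mask_y[None, :, :]
        denom = pair_ok.sum(axis=2)
        num = (same & pair_ok).sum(axis=2)
        with np.errstate(invalid="ignore"):
            prox = np.where(denom > 0, num / np.maximum(denom, 1), same.mean(axis=2))
        return prox


# ---------------------------------------------------------------------------
# model container and workflow operations


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending vote fractions
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class BinaryDiscriminantModel:
    """A trained two-class VOC discrimination model."""

    class_pair: tuple
    positive_class: str
    split: SplitPlan
    forest: ProximityForestClassifier
    feature_indices: np.ndarray     # columns of the source matrix used
    oob_error: float
    importance: np.ndarray | None = None
    selected_vocs: np.ndarray | None = None
    test_metrics: dict | None = None
    oob_metrics: dict | None = None
    roc: RocCurve | None = None
    proximity: np.ndarray | None = None    # over all samples of the pair
    proximity_ids: list | None = None
    embedding: dict | None = None          # eigvals, eigvecs, scores, row_means

    @property
    def oob_accuracy(self) -> float:
        return 1.0 - self.oob_error


def _pair_arrays(fm: FeatureMatrix, classes):
    groups = np.asarray(fm.groups)
    mask = np.isin(groups, tuple(classes))
    return mask, fm.areas[mask], groups[mask], [s for s, m in zip(fm.sample_ids, mask) if m]


def train_forest(
    fm: FeatureMatrix, classes, split: SplitPlan,
    n_trees: int = 500, mtry: int | None = None, seed: int = 0,
) -> BinaryDiscriminantModel:
    """Fit the all-features forest on the training half of the split."""
    classes = tuple(classes)
    mask, X, g, ids = _pair_arrays(fm, classes)
    in_train = np.array([s in set(split.train_ids) for s in ids])
    clf = ProximityForestClassifier(n_trees=n_trees, mtry=mtry, seed=seed)
    clf.fit(X[in_train], g[in_train])
    mask = np.ones((X.shape[0], clf.n_trees), dtype=bool)
    mask[in_train] = clf.oob_mask_
    prox = clf.proximity(X, mask_x=mask, mask_y=mask)
    model = BinaryDiscriminantModel(
        class_pair=classes,
        positive_class=_positive_class(classes),
        split=split,
        forest=clf,
        feature_indices=np.arange(fm.n_peaks),
        oob_error=clf.oob_error_,
        importance=clf.importances_,
        proximity=prox,
        proximity_ids=ids,
    )
    model._embed_X = X
    model._embed_mask = mask
    return model


def _positive_class(classes) -> str:
    """The disease class is positive; for disease-disease pairs, the first."""
    non_control = [c for c in classes if c != "control"]
    return non_control[0] if non_control else classes[0]


def select_discriminatory_vocs(
    model: BinaryDiscriminantModel, max_considered: int = 50,
    fallback_count: int = 10, floor_frac: float = 0.1,
) -> np.ndarray:
    """Cut the sorted importance curve at the gap separating the VOCs that
    stand out from the noise floor.

    Candidate cut points are gaps whose lower side already sits in the floor
    (below ``floor_frac`` of the top importance); among those the largest
    consecutive gap wins. Without the floor condition the largest gap is
    almost always the one right after the single best feature — a cut that
    would discard the rest of a genuinely discriminatory cluster.

    Falls back to a fixed count (with a warning) when no eligible gap
    dominates (largest < 2x the median gap) — the profile then has no clear
    shoulder to cut at.
    """
    imp = model.importance
    if imp is None or np.all(imp <= 0):
        raise ValidationError("no discriminatory signal: all importances <= 0")
    order = np.argsort(-imp, kind="stable")
    top = order[: min(max_considered, imp.size)]
    vals = imp[top]
    gaps = -np.diff(vals)
    selected = None
    if gaps.size:
        med = np.median(gaps)
        eligible = np.flatnonzero(vals[1:] < floor_frac * vals[0])
        if eligible.size:
            k = eligible[int(np.argmax(gaps[eligible]))]
            if gaps[k] >= 2 * med:
                selected = top[: k + 1]
    else:
        selected = top
    if selected is None:
        logger.warning(
            "no importance gap stands clear of the floor; "
            "falling back to top %d features", fallback_count,
        )
        selected = top[:fallback_count]
    model.selected_vocs = np.sort(selected)
    return model.selected_vocs


def _metrics_at_threshold(votes, truth, positive, negative, threshold=0.5):
    pred_pos = votes >= threshold
    is_pos = truth == positive
    tp = int((pred_pos & is_pos).sum())
    tn = int((~pred_pos & ~is_pos).sum())
    fp = int((pred_pos & ~is_pos).sum())
    fn = int((~pred_pos & is_pos).sum())
    return {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
    }


def roc_curve_from_votes(votes, truth, positive) -> RocCurve:
    """Sensitivity/specificity over descending vote-fraction thresholds."""
    votes = np.asarray(votes, dtype=float)
    is_pos = np.asarray(truth) == positive
    thresholds = np.r_[np.inf, np.sort(np.unique(votes))[::-1]]
    sens = np.array([(votes >= t)[is_pos].mean() for t in thresholds])
    spec = np.array([(~(votes >= t))[~is_pos].mean() for t in thresholds])
    a = auc(votes[is_pos], votes[~is_pos])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=a)


def refit_and_validate(
    fm: FeatureMatrix, classes, split: SplitPlan, selected_vocs,
    n_trees: int = 500, mtry: int | None = None, seed: int = 0,
) -> BinaryDiscriminantModel:
    """Refit on the selected VOCs only; validate on the held-out test set."""
    selected = np.asarray(selected_vocs, dtype=int)
    if selected.size == 0:
        raise ValidationError("selected_vocs is empty")
    classes = tuple(classes)
    mask, X, g, ids = _pair_arrays(fm, classes)
    Xs = X[:, selected]
    in_train = np.array([s in set(split.train_ids) for s in ids])
    clf = ProximityForestClassifier(n_trees=n_trees, mtry=mtry, seed=seed)
    clf.fit(Xs[in_train], g[in_train])
    positive = _positive_class(classes)
    negative = [c for c in classes if c != positive][0]

    test_votes = clf.vote_fraction(Xs[~in_train], positive)
    test_truth = g[~in_train]
    test_metrics = _metrics_at_threshold(test_votes, test_truth, positive, negative)
    roc = roc_curve_from_votes(test_votes, test_truth, positive)

    # OOB-side metrics on the training samples, reported alongside
    oob_dec = clf.forest_.oob_decision_function_
    pos_col = list(clf.forest_.classes_).index(positive)
    oob_votes = np.nan_to_num(oob_dec[:, pos_col], nan=0.5)
    oob_metrics = _metrics_at_threshold(oob_votes, g[in_train], positive, negative)

    model = BinaryDiscriminantModel(
        class_pair=classes,
        positive_class=positive,
        split=split,
        forest=clf,
        feature_indices=selected,
        oob_error=clf.oob_error_,
        importance=clf.importances_,
        selected_vocs=selected,
        test_metrics=test_metrics,
        oob_metrics=oob_metrics,
        roc=roc,
        proximity=None,
        proximity_ids=ids,
    )
    mask = np.ones((Xs.shape[0], clf.n_trees), dtype=bool)
    mask[in_train] = clf.oob_mask_
    model.proximity = clf.proximity(Xs, mask_x=mask, mask_y=mask)
    model._embed_X = Xs
    model._embed_mask = mask
    return model


# ---------------------------------------------------------------------------
# proximity embedding (classical scaling) and out-of-sample projection


def classical_mds(proximity: np.ndarray, n_components: int = 3):
    """Classical scaling of D = 1 - proximity.

    B = -1/2 J D^2 J; scores = eigenvectors * sqrt(eigenvalues). Negative
    eigenvalues are truncated at zero (their count is logged).
    """
    P = np.asarray(proximity, dtype=float)
    D2 = (1.0 - P) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -1e-10).sum())
    if n_neg:
        logger.info("classical scaling: %d negative eigenvalues truncated at 0", n_neg)
    eigvals = np.clip(eigvals, 0.0, None)
    n_pos = int((eigvals > 1e-12).sum())
    if n_components > n_pos:
        logger.warning(
            "requested %d components but only %d positive eigenvalues; reducing",
            n_components, n_pos,
        )
        n_components = max(n_pos, 1)
    lam = eigvals[:n_components]
    vec = eigvecs[:, :n_components]
    scores = vec * np.sqrt(lam)
    return {
        "eigvals": lam,
        "eigvecs": vec,
        "scores": scores,
        "row_means": D2.mean(axis=1),
        "n_components": n_components,
    }


def proximity_embed(model: BinaryDiscriminantModel, n_components: int = 3) -> np.ndarray:
    """Embed the model's samples by classical scaling of its proximities."""
    if model.proximity is None:
        raise ValidationError("model has no proximity matrix")
    model.embedding = classical_mds(model.proximity, n_components)
    return model.embedding["scores"]


def project_sample(model: BinaryDiscriminantModel, sample_features) -> np.ndarray:
    """Gower/Nystrom out-of-sample coordinates in the proximity-PCA space.

    score_k = -(d^2 - rowmean(D^2))^T v_k / (2 sqrt(lambda_k)), with d the
    1 - proximity distances from the new sample to the model's samples.
    """
    if model.embedding is None:
        raise ValidationError("model not embedded; call proximity_embed first")
    x = np.atleast_2d(np.asarray(sample_features, dtype=float))
    if x.shape[1] != model.feature_indices.size:
        raise ValidationError(
            f"sample has {x.shape[1]} features; model expects {model.feature_indices.size}"
        )
    # a sample that IS one of the model's samples keeps its embedding row:
    # the extension is defined to agree exactly on the embedded set
    hits = np.flatnonzero(np.all(model._embed_X == x[0], axis=1))
    if hits.size:
        return model.embedding["scores"][hits[0]].copy()
    # proximity of the new sample to all samples the embedding was built on
    prox = model.forest.proximity(x, model._embed_X, mask_y=model._embed_mask)
    d2 = (1.0 - prox) ** 2  # (1, n)
    emb = model.embedding
    b = -0.5 * (d2 - emb["row_means"])  # (1, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = b @ emb["eigvecs"] / np.sqrt(emb["eigvals"])
    return np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)[0]
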