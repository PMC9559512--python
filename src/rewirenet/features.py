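"""Supervised biomarker discovery.

Information-gain feature ranking, a small registry of classifier families
(linear SVM trained by stochastic sub-gradient descent, plain and
distance-weighted k-nearest neighbours, and a single-rule classifier),
multi-scheme performance estimation (10-fold CV, LOOCV, holdout, repeated
holdout, bootstrap and the 0.632+ bootstrap), and model selection by the
average Matthews correlation coefficient across schemes (AVG_MCC) subject to
a stability cap on its standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SplitSpec",
    "RankedFeature",
    "ModelReport",
    "split_train_test",
    "information_gain",
    "rank_features",
    "mcc",
    "make_classifier",
    "CLASSIFIER_NAMES",
    "evaluate",
    "bootstrap_632plus_weight",
    "search_models",
    "select_best_models",
    "extract_biomarkers",
    "discover_biomarkers",
]

EVAL_SCHEMES = ("cv10", "loocv", "holdout", "repeated_holdout", "bootstrap", "bootstrap_632plus")
OPTIMIZATION_METRICS = ("MCC", "FDR", "BER", "AUC")
_MINIMIZED = {"FDR", "BER"}


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 2 / 3
    seed: int = 0
    per_class_train: dict[str, int] | None = None  # explicit override of counts

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(samples: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Class-stratified random split into train/test sample ids.

    The per-class training count is ``round(train_fraction * n_class)``
    (banker's rounding at exact halves) unless ``spec.per_class_train``
    overrides it. Split is disjoint and exhaustive; same seed, same split.
    """
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for cls, grp in samples.groupby("class", sort=True):
        ids = grp["sample"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        if spec.per_class_train is not None:
            n_train = spec.per_class_train[str(cls)]
        else:
            n_train = int(round(spec.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return train, test


# ---------------------------------------------------------------------------
# information gain

def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _side_entropy(counts: np.ndarray) -> float:
    nn = counts.sum()
    p = counts[counts > 0] / nn
    return float(-(p * np.log2(p)).sum())


def information_gain(x: np.ndarray, y: np.ndarray, mdl_gate: bool = True) -> float:
    """Entropy reduction (bits) of the best single binary split of ``x``.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; a constant vector has zero gain. With ``mdl_gate`` (the default)
    the best split must additionally pass the Fayyad-Irani minimum
    description length criterion, otherwise the gain is 0: without this gate
    the maximum over n-1 candidate thresholds is optimistically biased and
    ranks pure-noise features well above any fixed threshold at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0] or x.shape[0] < 2:
        raise ValueError("x and y must have equal length >= 2")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    distinct = np.nonzero(np.diff(xs))[0]
    if distinct.size == 0:
        return 0.0
    h_y = _entropy_bits(y)
    n = len(y)
    # cumulative class counts along the sorted order allow O(n) split scan
    classes, y_codes = np.unique(ys, return_inverse=True)
    onehot = np.zeros((n, len(classes)))
    onehot[np.arange(n), y_codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    best = h_y
    best_left = best_right = None
    for i in distinct:  # split between position i and i+1
        left = cum[i]
        right = total - left
        h = (left.sum() / n) * _side_entropy(left) + (right.sum() / n) * _side_entropy(right)
        if h < best:
            best, best_left, best_right = h, left, right
    gain = max(h_y - best, 0.0)
    if not mdl_gate or best_left is None:
        return gain
    # Fayyad-Irani MDL acceptance: the split must buy more entropy than its
    # coding cost, gain > (log2(n-1) + delta) / n
    k = int((total > 0).sum())
    k1 = int((best_left > 0).sum())
    k2 = int((best_right > 0).sum())
    delta = (
        np.log2(3**k - 2)
        - (k * h_y - k1 * _side_entropy(best_left) - k2 * _side_entropy(best_right))
    )
    if gain > (np.log2(n - 1) + delta) / n:
        return gain
    return 0.0


@dataclass(frozen=True)
class RankedFeature:
    gene_id: str
    information_gain: float
    rank: int


def rank_features(
    norm: pd.DataFrame, samples: pd.DataFrame, ig_threshold: float = 0.01
) -> list[RankedFeature]:
    """Rank genes by information gain against the class label; keep IG > threshold.

    ``norm`` must already be restricted to the training samples. Ties in IG
    are broken by gene id (lexicographic), ranks run 1..n_kept.
    """
    y = samples.set_index("sample").loc[list(norm.columns), "class"].to_numpy()
    gains = {g: information_gain(norm.loc[g].to_numpy(), y) for g in norm.index}
    kept = sorted(
        ((g, ig) for g, ig in gains.items() if ig > ig_threshold),
        key=lambda t: (-t[1], t[0]),
    )
    if not kept:
        raise ValueError(
            f"no gene exceeds information gain {ig_threshold}; lower ig_threshold"
        )
    return [RankedFeature(g, ig, i + 1) for i, (g, ig) in enumerate(kept)]


# ---------------------------------------------------------------------------
# metrics

def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def _positive_label(labels) -> str:
    labels = list(labels)
    return "P" if "P" in labels else sorted(labels)[-1]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: str = "P"):
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, tn, fp, fn


def _metrics(y_true, y_pred, scores=None, positive: str | None = None) -> dict[str, float]:
    if positive is None:
        positive = _positive_label(np.unique(y_true))
    tp, tn, fp, fn = _confusion(np.asarray(y_true), np.asarray(y_pred), positive)
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    ber = 1.0 - 0.5 * (sens + spec)
    if scores is not None and len(np.unique(y_true)) == 2:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score((np.asarray(y_true) == positive).astype(int), scores))
    else:
        auc = 0.5 * (sens + spec)  # AUC of the hard classifier
    return {
        "MCC": mcc(tp, tn, fp, fn),
        "accuracy": acc,
        "FDR": fdr,
        "BER": ber,
        "AUC": auc,
    }


# ---------------------------------------------------------------------------
# classifiers

class OneRuleClassifier(BaseEstimator, ClassifierMixin):
    """Single-feature, single-threshold rule classifier.

    Picks the (feature, threshold) pair minimizing training error, predicting
    the majority class on each side of the threshold. Serves as the rules
    family in the model registry.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        best = (np.inf, 0, -np.inf, None, None)
        majority = self.classes_[np.argmax([(y == c).sum() for c in self.classes_])]
        for j in range(X.shape[1]):
            xs = np.unique(X[:, j])
            if xs.size < 2:
                continue
            for t in (xs[:-1] + xs[1:]) / 2:
                left = X[:, j] <= t
                for side in (self.classes_ if len(self.classes_) == 2 else [majority]):
                    pred = np.where(left, side, _other(self.classes_, side))
                    err = float(np.mean(pred != y))
                    if err < best[0]:
                        best = (err, j, t, side, _other(self.classes_, side))
        if best[3] is None:  # all features constant
            self.rule_ = (0, -np.inf, majority, majority)
        else:
            self.rule_ = best[1:]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        j, t, left_label, right_label = self.rule_
        return np.where(X[:, j] <= t, left_label, right_label)


def _other(classes, c):
    if len(classes) != 2:
        return c
    return classes[0] if c == classes[1] else classes[1]


def _gaussian_weights(dist: np.ndarray) -> np.ndarray:
    return np.exp(-(dist**2))


def make_classifier(name: str, seed: int = 0, n_neighbors: int = 3):
    """Instantiate a classifier family by name.

    ``pegasos_linear``: hinge-loss linear SVM trained by stochastic
    sub-gradient descent; ``knn`` / ``knn_weighted``: k-nearest neighbours,
    the weighted variant with Gaussian distance weighting; ``one_rule``:
    single-rule classifier.
    """
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=n_neighbors))
    if name == "knn_weighted":
        return make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(n_neighbors=n_neighbors, weights=_gaussian_weights),
        )
    if name == "pegasos_linear":
        return make_pipeline(
            StandardScaler(),
            SGDClassifier(loss="hinge", penalty="l2", random_state=seed, max_iter=2000, tol=1e-4),
        )
    if name == "one_rule":
        return OneRuleClassifier()
    raise ValueError(f"unknown classifier {name!r}")


CLASSIFIER_NAMES = ("knn", "knn_weighted", "pegasos_linear", "one_rule")


def _scores(model, X) -> np.ndarray | None:
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X))
        except Exception:
            return None
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos = list(model.classes_).index(_positive_label(model.classes_))
        return np.asarray(proba[:, pos])
    return None


# ---------------------------------------------------------------------------
# evaluation schemes

def bootstrap_632plus_weight(err_train: float, err_oob: float, gamma: float) -> float:
    """0.632+ blending weight w = 0.632 / (1 - 0.368 R) with the relative
    overfitting rate R = (err_oob - err_train) / (gamma - err_train) clipped
    to [0, 1]; R = 0 whenever err_oob <= err_train or gamma <= err_train."""
    if err_oob <= err_train or gamma <= err_train:
        r = 0.0
    else:
        r = min((err_oob - err_train) / (gamma - err_train), 1.0)
    return 0.632 / (1.0 - 0.368 * r)


def _fit_predict(clf, Xtr, ytr, Xte):
    model = clone(clf)
    model.fit(Xtr, ytr)
    return model.predict(Xte), _scores(model, Xte)


def _stratified_indices(y: np.ndarray, frac: float, rng: np.random.Generator):
    test_idx: list[int] = []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        n_test = max(int(round(frac * len(idx))), 1)
        test_idx.extend(rng.choice(idx, size=n_test, replace=False))
    mask = np.zeros(len(y), dtype=bool)
    mask[test_idx] = True
    return ~mask, mask


def evaluate(clf, X: np.ndarray, y: np.ndarray, scheme: str, seed: int = 0,
             n_repeats: int = 10, n_boot: int = 25) -> dict[str, float]:
    """Estimate classification metrics under one resampling scheme.

    Schemes: stratified 10-fold CV, leave-one-out CV, a single stratified 1/3
    holdout, 10 repeated 1/3 holdouts (averaged), 25 out-of-bag bootstrap
    evaluations (averaged), and the 0.632+ bootstrap blend of training and
    out-of-bag metrics with an overfitting-adaptive weight.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if scheme in ("cv10", "loocv"):
        if scheme == "cv10":
            n_splits = min(10, min(np.bincount(pd.factorize(y)[0])))
            folds = list(
                StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed).split(X, y)
            )
        else:
            folds = [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
        y_pred = np.empty_like(y)
        score = np.full(len(y), np.nan)
        seen = np.zeros(len(y), dtype=bool)
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                warnings.warn("fold with a single class skipped", stacklevel=2)
                continue
            pred, sc = _fit_predict(clf, X[tr], y[tr], X[te])
            y_pred[te] = pred
            seen[te] = True
            if sc is not None:
                score[te] = sc
        if not seen.any():
            raise ValueError("all folds skipped: cannot evaluate")
        sc = score[seen] if np.isfinite(score[seen]).all() else None
        return _metrics(y[seen], y_pred[seen], sc)
    if scheme == "holdout":
        tr, te = _stratified_indices(y, 1 / 3, rng)
        pred, sc = _fit_predict(clf, X[tr], y[tr], X[te])
        return _metrics(y[te], pred, sc)
    if scheme == "repeated_holdout":
        accum: list[dict[str, float]] = []
        for _ in range(n_repeats):
            tr, te = _stratified_indices(y, 1 / 3, rng)
            pred, sc = _fit_predict(clf, X[tr], y[tr], X[te])
            accum.append(_metrics(y[te], pred, sc))
        return {k: float(np.mean([m[k] for m in accum])) for k in accum[0]}
    if scheme in ("bootstrap", "bootstrap_632plus"):
        oob_metrics: list[dict[str, float]] = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(y), size=len(y))
            oob = np.setdiff1d(np.arange(len(y)), idx)
            if oob.size == 0 or len(np.unique(y[idx])) < 2:
                warnings.warn("degenerate bootstrap sample skipped", stacklevel=2)
                continue
            pred, sc = _fit_predict(clf, X[idx], y[idx], X[oob])
            oob_metrics.append(_metrics(y[oob], pred, sc))
        if not oob_metrics:
            raise ValueError("all bootstrap samples degenerate")
        oob_avg = {k: float(np.mean([m[k] for m in oob_metrics])) for k in oob_metrics[0]}
        if scheme == "bootstrap":
            return oob_avg
        # training (resubstitution) metrics
        pred_tr, sc_tr = _fit_predict(clf, X, y, X)
        train = _metrics(y, pred_tr, sc_tr)
        # no-information error rate from marginal label / prediction frequencies
        gamma = 0.0
        for c in np.unique(y):
            p_c = float(np.mean(y == c))
            q_c = float(np.mean(pred_tr == c))
            gamma += p_c * (1.0 - q_c)
        w = bootstrap_632plus_weight(1.0 - train["accuracy"], 1.0 - oob_avg["accuracy"], gamma)
        return {k: float((1.0 - w) * train[k] + w * oob_avg[k]) for k in train}
    raise ValueError(f"unknown evaluation scheme {scheme!r}")


# ---------------------------------------------------------------------------
# model search and selection

@dataclass
class ModelReport:
    classifier_name: str
    optimization_metric: str
    selected_gene_ids: list[str]
    scheme_metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    search_strategy: str = "top_k"
    sd_filter_failed: bool = False

    @property
    def avg_mcc(self) -> float:
        return float(np.mean([m["MCC"] for m in self.scheme_metrics.values()]))

    @property
    def mcc_sd(self) -> float:
        vals = [m["MCC"] for m in self.scheme_metrics.values()]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "classifier_name": self.classifier_name,
            "optimization_metric": self.optimization_metric,
            "search_strategy": self.search_strategy,
            "selected_gene_ids": list(self.selected_gene_ids),
            "scheme_metrics": self.scheme_metrics,
            "avg_mcc": self.avg_mcc,
            "mcc_sd": self.mcc_sd,
            "sd_filter_failed": self.sd_filter_failed,
        }


def _opt_score(clf, X, y, metric: str, seed: int) -> float:
    m = evaluate(clf, X, y, "cv10", seed=seed)
    return -m[metric] if metric in _MINIMIZED else m[metric]


def search_models(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    train_ids: list[str],
    ranked: list[RankedFeature],
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    metrics: tuple[str, ...] = OPTIMIZATION_METRICS,
    k_grid: range | tuple[int, ...] = range(1, 26),
    stepwise: bool = True,
    stepwise_patience: int = 3,
    seed: int = 0,
) -> list[ModelReport]:
    """Sweep classifier x optimization-metric x feature-subset strategy.

    For each (classifier, metric) the feature subset is chosen either as the
    best top-k prefix of the information-gain ranking (k over ``k_grid``) or
    by greedy forward selection along the ranking (stopping after
    ``stepwise_patience`` consecutive non-improvements); subsets are scored
    by stratified 10-fold CV on the training samples. The winning subset is
    then evaluated under all six schemes to produce a ModelReport.
    """
    genes = [rf.gene_id for rf in ranked]
    Xfull = norm.loc[genes, train_ids].to_numpy(dtype=float).T  # samples x genes
    y = samples.set_index("sample").loc[train_ids, "class"].to_numpy()
    reports: list[ModelReport] = []
    for ci, cname in enumerate(classifiers):
        for mi, metric in enumerate(metrics):
            clf_seed = seed + 1000 * ci + mi
            clf = make_classifier(cname, seed=clf_seed)
            candidates: list[tuple[str, list[int]]] = []
            # top-k prefixes of the IG ranking
            best_k, best_score = None, -np.inf
            for k in k_grid:
                if k > len(genes):
                    break
                s = _opt_score(clf, Xfull[:, :k], y, metric, clf_seed)
                if s > best_score:
                    best_k, best_score = k, s
            if best_k is not None:
                candidates.append(("top_k", list(range(best_k))))
            if stepwise:
                chosen: list[int] = []
                best_s, stall = -np.inf, 0
                for j in range(len(genes)):
                    trial = chosen + [j]
                    s = _opt_score(clf, Xfull[:, trial], y, metric, clf_seed)
                    if s > best_s:
                        chosen, best_s, stall = trial, s, 0
                    else:
                        stall += 1
                        if stall >= stepwise_patience:
                            break
                if chosen:
                    candidates.append(("stepwise", chosen))
            for strategy, idx in candidates:
                scheme_metrics = {
                    scheme: evaluate(clf, Xfull[:, idx], y, scheme, seed=clf_seed)
                    for scheme in EVAL_SCHEMES
                }
                reports.append(
                    ModelReport(
                        classifier_name=cname,
                        optimization_metric=metric,
                        selected_gene_ids=[genes[j] for j in idx],
                        scheme_metrics=scheme_metrics,
                        search_strategy=strategy,
                    )
                )
    return reports


def select_best_models(
    reports: list[ModelReport], top_n: int = 5, sd_max: float = 0.1
) -> list[ModelReport]:
    """Top models by AVG_MCC among those with MCC standard deviation < sd_max.

    Ties broken by fewer selected genes, then classifier name. If the
    stability filter removes everything, the single best-AVG_MCC model is
    returned flagged with ``sd_filter_failed``.
    """
    if not reports:
        raise ValueError("no model reports to select from")
    key = lambda r: (-r.avg_mcc, len(r.selected_gene_ids), r.classifier_name)
    stable = sorted((r for r in reports if r.mcc_sd < sd_max), key=key)
    if not stable:
        warnings.warn(
            "no model met the MCC stability criterion; returning best AVG_MCC model",
            stacklevel=2,
        )
        best = min(reports, key=key)
        best.sd_filter_failed = True
        return [best]
    return stable[:top_n]


def extract_biomarkers(selected: list[ModelReport]) -> list[str]:
    """Union of selected gene ids across models, in first-appearance order."""
    if not selected:
        raise ValueError("no selected models")
    seen: list[str] = []
    for r in selected:
        for g in r.selected_gene_ids:
            if g not in seen:
                seen.append(g)
    return seen


def discover_biomarkers(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    ig_threshold: float = 0.01,
    train_fraction: float = 2 / 3,
    top_n: int = 5,
    sd_max: float = 0.1,
    seed: int = 0,
    **search_kwargs,
) -> dict:
    """End-to-end ML tier: split, rank, search, select, extract.

    Returns a dict with the split, ranked features, all reports, the selected
    top models, and the biomarker union/intersection.
    """
    train_ids, test_ids = split_train_test(samples, SplitSpec(train_fraction, seed))
    ranked = rank_features(norm[train_ids], samples, ig_threshold)
    reports = search_models(norm, samples, train_ids, ranked, seed=seed, **search_kwargs)
    selected = select_best_models(reports, top_n=top_n, sd_max=sd_max)
    union = extract_biomarkers(selected)
    inter = set(selected[0].selected_gene_ids)
    for r in selected[1:]:
        inter &= set(r.selected_gene_ids)
    return {
        "train_ids": train_ids,
        "test_ids": test_ids,
        "ranked": ranked,
        "reports": reports,
        "selected": selected,
        "biomarkers": union,
        "biomarkers_intersection": sorted(inter),
    }
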