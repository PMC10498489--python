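"""Binary QSAR classifiers, Mondrian conformal wrappers and ensembles.

The zoo covers the classical algorithm families used for structure–
activity classification: random forest, balanced random forest (class-
balanced per-tree bootstraps), RBF support-vector machine, naive Bayes,
k-nearest-neighbour (k in {1,3}) on Tanimoto/Jaccard distance, partial
least squares, logistic regression, gradient-boosted trees, a single
decision tree, and a randomized-descriptor baseline (descriptor rows
permuted relative to the labels before fitting, so any apparent skill is
spurious).

Conformal layer
---------------
An inductive Mondrian (label-conditional) conformal wrapper splits the
training data into a proper training part and a calibration part, scores
calibration items with the nonconformity 1 - P(class), and converts a
test item's nonconformity into a per-class p-value

    p_c = (#{calibration alpha_i of class c >= alpha} + 1) / (n_c + 1).

The prediction set at significance eps contains every class with p > eps;
singleton sets define the applicability domain (AD). Under exchangeability
the per-class error rate of the prediction sets is at most eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "REPRESENTATIONS",
    "ModelConfig",
    "FittedClassifier",
    "fit_classifier",
    "MondrianConformalClassifier",
    "conformal_pvalue",
    "PredictionSet",
    "prediction_set",
    "majority_vote",
    "probability_ensemble",
    "simple_majority",
    "default_registry",
]

ALGORITHMS = (
    "random-forest",
    "balanced-random-forest",
    "support-vector",
    "naive-bayes",
    "knn-1",
    "knn-3",
    "pls",
    "logistic",
    "gradient-boosted-trees",
    "decision-tree",
    "randomized-baseline",
)

REPRESENTATIONS = ("fingerprint", "physchem", "both", "randomized")


# ---------------------------------------------------------------------------
# base estimators
# ---------------------------------------------------------------------------

class BalancedRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest whose per-tree bootstraps are drawn class-balanced.

    Each tree sees a bootstrap of size 2 * minority-count drawn equally
    from both classes, which rebalances the class distribution inside
    every tree without reweighting.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need two classes")
        rng = np.random.default_rng(self.random_state)
        idx_by_class = [np.flatnonzero(y_enc == c) for c in range(len(self.classes_))]
        n_min = min(len(ix) for ix in idx_by_class)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            boot = np.concatenate(
                [rng.choice(ix, size=n_min, replace=True) for ix in idx_by_class]
            )
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[boot], y_enc[boot])
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        proba = np.zeros((len(X), len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            cols = tree.classes_.astype(int)
            proba[:, cols] += p
        proba /= len(self.estimators_)
        return proba

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares regression on 0/1 labels, thresholded at 0.5.

    The continuous PLS response, clipped to [0,1], doubles as the positive
    class probability.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        ncomp = min(self.n_components, X.shape[1], len(X) - 1)
        self.pls_ = PLSRegression(n_components=max(1, ncomp), scale=False)
        self.pls_.fit(X, y_enc.astype(float))
        return self

    def predict_proba(self, X):
        raw = np.clip(self.pls_.predict(np.asarray(X, dtype=float)).ravel(), 0.0, 1.0)
        return np.column_stack([1.0 - raw, raw])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _base_estimator(algorithm: str, representation: str, seed: int):
    binary_features = representation == "fingerprint"
    if algorithm in ("random-forest", "randomized-baseline"):
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if algorithm == "balanced-random-forest":
        return BalancedRandomForest(n_estimators=500, random_state=seed)
    if algorithm == "support-vector":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "naive-bayes":
        return BernoulliNB() if binary_features else GaussianNB()
    if algorithm in ("knn-1", "knn-3"):
        k = 1 if algorithm == "knn-1" else 3
        metric = "jaccard" if binary_features else "euclidean"
        return KNeighborsClassifier(n_neighbors=k, metric=metric)
    if algorithm == "pls":
        return PLSClassifier()
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "gradient-boosted-trees":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm == "decision-tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# fitted classifier facade
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    name: str
    algorithm: str
    representation: str = "fingerprint"
    conformal: bool = False
    significance: float = 0.25


@dataclass
class FittedClassifier:
    """A fitted base classifier plus its metadata.

    ``predict_proba(X)`` returns the probability of the positive (active)
    class; ``predict(X)`` returns boolean labels.
    """

    algorithm: str
    representation: str
    seed: int
    estimator: object = field(repr=False)
    classes_: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X))
        pos = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, pos]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5


def fit_classifier(
    X: np.ndarray, y: "np.ndarray | list", algorithm: str, representation: str = "fingerprint", seed: int = 0
) -> FittedClassifier:
    """Fit one classifier of the zoo; deterministic under a fixed seed.

    The ``randomized-baseline`` algorithm permutes the descriptor rows
    relative to the labels before fitting, severing any structure–activity
    link while preserving both marginals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    if algorithm == "randomized-baseline" or representation == "randomized":
        rng = np.random.default_rng(seed)
        X = X[rng.permutation(len(X))]

    est = _base_estimator(algorithm, representation, seed)
    est.fit(X, y)
    return FittedClassifier(
        algorithm=algorithm,
        representation=representation,
        seed=seed,
        estimator=est,
        classes_=np.asarray(est.classes_).astype(int),
    )


# ---------------------------------------------------------------------------
# Mondrian conformal prediction
# ---------------------------------------------------------------------------

def conformal_pvalue(alpha: float, calibration_scores: "np.ndarray | list") -> float:
    """Unsmoothed conformal p-value of a nonconformity against a calibration set."""
    cal = np.asarray(calibration_scores, dtype=float)
    if cal.size == 0:
        raise ValueError("empty calibration set")
    return float((np.sum(cal >= alpha) + 1) / (cal.size + 1))


@dataclass(frozen=True)
class PredictionSet:
    p_active: float
    p_inactive: float
    labels: frozenset
    in_ad: bool


def prediction_set(p_active: float, p_inactive: float, eps: float) -> PredictionSet:
    """Conformal prediction set at significance ``eps``; singleton = in-AD."""
    labels = frozenset(
        name for name, p in (("active", p_active), ("inactive", p_inactive)) if p > eps
    )
    return PredictionSet(p_active, p_inactive, labels, in_ad=len(labels) == 1)


class MondrianConformalClassifier:
    """Inductive label-conditional conformal classifier.

    Splits (X, y) into proper-training and calibration parts (class-
    stratified), fits the base algorithm on the former and retains
    per-class nonconformity scores 1 - P(true class) on the latter.
    """

    def __init__(
        self,
        algorithm: str = "random-forest",
        representation: str = "fingerprint",
        significance: float = 0.25,
        calibration_fraction: float = 0.30,
        seed: int = 0,
    ):
        if not 0.0 < significance < 1.0:
            raise ValueError("significance must be in (0,1)")
        self.algorithm = algorithm
        self.representation = representation
        self.significance = significance
        self.calibration_fraction = calibration_fraction
        self.seed = seed

    def fit(self, X, y) -> "MondrianConformalClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        X_tr, X_cal, y_tr, y_cal = train_test_split(
            X, y, test_size=self.calibration_fraction, stratify=y, random_state=self.seed
        )
        self.base_ = fit_classifier(X_tr, y_tr, self.algorithm, self.representation, self.seed)
        p_active = self.base_.predict_proba(X_cal)
        p_true = np.where(y_cal == 1, p_active, 1.0 - p_active)
        alpha = 1.0 - p_true
        self.calibration_ = {1: np.sort(alpha[y_cal == 1]), 0: np.sort(alpha[y_cal == 0])}
        if min(len(v) for v in self.calibration_.values()) == 0:
            raise ValueError("a class is missing from the calibration split")
        return self

    def pvalues(self, X) -> np.ndarray:
        """Per-item (p_inactive, p_active) conformal p-values, shape (n, 2)."""
        p_active = self.base_.predict_proba(np.asarray(X))
        out = np.empty((len(p_active), 2))
        for i, pa in enumerate(p_active):
            out[i, 1] = conformal_pvalue(1.0 - pa, self.calibration_[1])
            out[i, 0] = conformal_pvalue(pa, self.calibration_[0])
        return out

    def predict_sets(self, X, eps: "float | None" = None) -> list[PredictionSet]:
        eps = self.significance if eps is None else eps
        return [prediction_set(pa, pi, eps) for pi, pa in self.pvalues(X)]

    def predict_table(self, X, eps: "float | None" = None) -> tuple[np.ndarray, np.ndarray]:
        """Compact (label, in_ad) arrays: label True = active (higher p-value)."""
        eps = self.significance if eps is None else eps
        pv = self.pvalues(X)
        label = pv[:, 1] >= pv[:, 0]
        in_ad = ((pv > eps).sum(axis=1)) == 1
        return label, in_ad

    def predict_proba(self, X) -> np.ndarray:
        return self.base_.predict_proba(X)


# ---------------------------------------------------------------------------
# consensus / ensembles
# ---------------------------------------------------------------------------

def majority_vote(labels: "list[str]", quorum: int) -> str:
    """Quorum consensus: the label reached by >= quorum members, else 'suspicious'.

    Out-of-AD members abstain and must be excluded by the caller before
    voting; the quorum refers to the submitted votes.
    """
    if not labels:
        raise ValueError("no votes")
    if quorum > len(labels):
        raise ValueError(f"quorum {quorum} exceeds member count {len(labels)}")
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    for lab, n in counts.items():
        if n >= quorum:
            return lab
    return "suspicious"


def probability_ensemble(probas: "list[float] | np.ndarray", statistic: str = "mean") -> float:
    """Mean or median of member probabilities (label via the 0.5 threshold)."""
    p = np.asarray(probas, dtype=float)
    if p.size == 0:
        raise ValueError("no member probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    if statistic == "mean":
        return float(p.mean())
    if statistic == "median":
        return float(np.median(p))
    raise ValueError(f"unknown statistic {statistic!r}")


def simple_majority(labels: "list[str]") -> str:
    """Strict majority of binary labels; ties resolve to 'active'.

    The hazard-averse tie-break reflects the screening context: missing a
    genuinely active (oxidative-stress-inducing) compound is costlier than
    a false alarm.
    """
    if not labels:
        raise ValueError("no votes")
    n_active = sum(1 for lab in labels if lab == "active")
    return "active" if n_active >= len(labels) / 2 else "inactive"


# ---------------------------------------------------------------------------
# suite orchestration
# ---------------------------------------------------------------------------

@dataclass
class SuiteMember:
    """One fitted roster entry; resolves its representation from a dict of matrices."""

    config: ModelConfig
    model: object = field(repr=False)

    def _X(self, representations: dict) -> np.ndarray:
        rep = self.config.representation
        if rep in ("both", "randomized"):
            return np.hstack([representations["fingerprint"], representations["physchem"]])
        return representations[rep]

    def predict(self, representations: dict) -> tuple[np.ndarray, np.ndarray]:
        """(active labels, in-AD flags); plain models are always in-AD."""
        X = self._X(representations)
        if isinstance(self.model, MondrianConformalClassifier):
            return self.model.predict_table(X)
        labels = self.model.predict(X)
        return np.asarray(labels, dtype=bool), np.ones(len(X), dtype=bool)

    def predict_proba(self, representations: dict) -> np.ndarray:
        return self.model.predict_proba(self._X(representations))


def fit_suite(
    representations: dict,
    y: "np.ndarray | list",
    registry: "list[ModelConfig] | None" = None,
    seed: int = 0,
) -> dict[str, SuiteMember]:
    """Fit every roster model on its representation; returns name -> member.

    ``representations`` must provide "fingerprint" and "physchem" matrices
    with aligned rows; "both"/"randomized" models see their concatenation.
    """
    registry = default_registry() if registry is None else registry
    suite = {}
    for cfg in registry:
        X = (
            np.hstack([representations["fingerprint"], representations["physchem"]])
            if cfg.representation in ("both", "randomized")
            else representations[cfg.representation]
        )
        if cfg.conformal:
            model = MondrianConformalClassifier(
                cfg.algorithm, cfg.representation, cfg.significance, seed=seed
            ).fit(X, y)
        else:
            model = fit_classifier(X, np.asarray(y), cfg.algorithm, cfg.representation, seed)
        suite[cfg.name] = SuiteMember(cfg, model)
    return suite


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def default_registry(significance: float = 0.25) -> list[ModelConfig]:
    """The default model roster: one entry per algorithm family.

    Conformal wrappers are attached to the forest and SVM fingerprint
    models; the randomized baseline closes the list.
    """
    return [
        ModelConfig("cp_rf_fp", "random-forest", "fingerprint", True, significance),
        ModelConfig("cp_svm_fp", "support-vector", "fingerprint", True, significance),
        ModelConfig("cp_rf_physchem", "random-forest", "physchem", True, significance),
        ModelConfig("rf_both", "random-forest", "both", False, significance),
        ModelConfig("brf_physchem", "balanced-random-forest", "physchem", False, significance),
        ModelConfig("nb_fp", "naive-bayes", "fingerprint", False, significance),
        ModelConfig("knn1_fp", "knn-1", "fingerprint", False, significance),
        ModelConfig("knn3_fp", "knn-3", "fingerprint", False, significance),
        ModelConfig("pls_both", "pls", "both", False, significance),
        ModelConfig("logistic_both", "logistic", "both", False, significance),
        ModelConfig("gbt_physchem", "gradient-boosted-trees", "physchem", False, significance),
        ModelConfig("dt_physchem", "decision-tree", "physchem", False, significance),
        ModelConfig("random_baseline", "randomized-baseline", "randomized", False, significance),
    ]
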