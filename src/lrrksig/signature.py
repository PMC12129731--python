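"""Classifier selection and minimal-signature search.

Pipeline: grid-searched model selection under stratified 5-fold
cross-validation with SMOTE applied *inside* each training fold (never to test
folds), scored by balanced accuracy (mean per-class recall); ANOVA
pre-selection and backwards recursive feature elimination; then a Monte-Carlo
tree search (UCB1) over add-feature / STOP actions that grows a subset one
feature per round, with lookahead depth fixed to five and a per-round budget
of ``trees_factor x n_candidates`` simulations.  Subsets whose cross-validated
balanced accuracy exceeds 0.90 are collected, the most frequently represented
features seed a refinement search, and the best subset after refinement is the
signature.  Signature quality is reported as one-vs-rest ROC AUC per class
from held-out decision scores plus a 2-component PCA projection.

Rewards are memoized by frozen subset key — essential for the
10-per-candidate simulation budget to be tractable — which also makes the
whole search deterministic given (data, config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import MCTSConfig
from .errors import ConfigError, DesignError

log = logging.getLogger("lrrksig")

STOP = "<STOP>"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Mean per-class recall.  Predictions outside the true label set simply
    count as errors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ConfigError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ConfigError("label vectors differ in length")
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(X: np.ndarray, y: Sequence, k: int = 5, seed: int = 0
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling to the majority-class count.

    Each synthetic point is ``x + u * (neighbor - x)`` with ``u ~ U(0, 1)``
    and the neighbor drawn among the k nearest same-class points.  Original
    rows come first and unchanged; the returned provenance array holds the
    original row index for real rows and -1 for synthetic rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 1:
        raise ConfigError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ConfigError(
            f"classes {small} have a single sample; SMOTE needs >= 2 per class "
            f"(merge classes or drop them — silent duplication is not done)")
    rng = np.random.default_rng(seed)
    n_major = counts.max()
    X_new, y_new = [X], [y]
    prov = [np.arange(len(y))]
    for cls, cnt in zip(classes, counts):
        need = int(n_major - cnt)
        if need == 0:
            continue
        pts = X[y == cls]
        k_eff = min(k, len(pts) - 1)
        # k nearest same-class neighbors by squared Euclidean distance;
        # column 0 of idx is the point itself (distance 0)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k_eff + 1]
        base = rng.integers(0, len(pts), size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.random(need)[:, None]
        neigh = pts[idx[base, pick]]
        synth = pts[base] + u * (neigh - pts[base])
        X_new.append(synth)
        y_new.append(np.full(need, cls, dtype=y.dtype))
        prov.append(np.full(need, -1))
    return (np.vstack(X_new), np.concatenate(y_new),
            np.concatenate(prov).astype(int))


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A model family plus fixed hyperparameters; hashable for caching."""
    model: str  # "svm" | "random_forest" | "gradient_boosting"
    params: tuple = ()  # sorted (key, value) pairs

    @classmethod
    def make(cls, model: str, **params) -> "ClassifierSpec":
        return cls(model=model, params=tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    params = spec.param_dict
    if spec.model == "svm":
        # cap libsvm iterations: rare degenerate oversampled subsets
        # otherwise stall the solver far past any useful optimization
        params.setdefault("max_iter", 100_000)
        return SVC(random_state=seed, decision_function_shape="ovr", **params)
    if spec.model == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.model == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ConfigError(f"unknown model {spec.model!r}")


#: default grid: maximum-margin classifier over linear / RBF kernels
DEFAULT_CANDIDATES = [
    ("svm", {"kernel": ["linear"], "C": [0.1, 1, 10]}),
    ("svm", {"kernel": ["rbf"], "C": [0.1, 1, 10], "gamma": ["scale", 0.01, 0.1]}),
]
DEFAULT_SPEC = ClassifierSpec.make("svm", kernel="linear", C=1)


# ---------------------------------------------------------------------------
# cross-validated evaluation with SMOTE inside folds
# ---------------------------------------------------------------------------

class SubsetEvaluator:
    """Cached cross-validated balanced accuracy of feature subsets.

    Folds are stratified and fixed per (seed) so subset scores are paired;
    SMOTE runs on the training portion of each fold only.  The cache key is
    the frozen subset (classifier spec and seed are fixed per evaluator).
    """

    def __init__(self, X: pd.DataFrame, y: Sequence, spec: ClassifierSpec,
                 n_folds: int = 5, seed: int = 0, smote_k: int = 5,
                 cv_repeats: int = 3):
        if n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        self.X = X
        self.y = np.asarray(y)
        self.spec = spec
        self.seed = int(seed)
        self.smote_k = smote_k
        # repeated stratified partitions cut the evaluation variance so that
        # small between-subset differences are real signal, not fold noise;
        # all partitions are fixed per seed, so scores stay paired
        self.folds = []
        for r in range(max(1, cv_repeats)):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed + 1000 * r)
            self.folds.extend(skf.split(np.zeros(len(self.y)), self.y))
        self.cache: Dict[frozenset, float] = {}
        self.cache_hits = 0
        self.n_evaluations = 0

    def score(self, subset: Sequence[str]) -> float:
        if not subset:
            raise ConfigError("empty feature subset")
        key = frozenset(subset)
        if key in self.cache:
            self.cache_hits += 1
            return self.cache[key]
        missing = [f for f in subset if f not in self.X.columns]
        if missing:
            raise ConfigError(f"unknown features: {missing[:5]}")
        cols = [c for c in self.X.columns if c in key]  # stable column order
        Xs = self.X[cols].to_numpy(dtype=float)
        scores = []
        for i, (tr, te) in enumerate(self.folds):
            Xo, yo, _ = smote_oversample(Xs[tr], self.y[tr], k=self.smote_k,
                                         seed=self.seed + i)
            clf = make_classifier(self.spec, seed=self.seed)
            clf.fit(Xo, yo)
            scores.append(balanced_accuracy(self.y[te], clf.predict(Xs[te])))
        val = float(np.mean(scores))
        self.cache[key] = val
        self.n_evaluations += 1
        return val


def cv_evaluate(X: pd.DataFrame, y: Sequence, feature_subset: Sequence[str],
                classifier_spec: ClassifierSpec, n_folds: int = 5,
                seed: int = 0, smote_k: int = 5,
                return_fold_info: bool = False):
    """One-shot cross-validated balanced accuracy of a feature subset.

    With ``return_fold_info`` the per-fold bookkeeping is returned too:
    (test_indices, train_provenance) pairs, where provenance -1 marks
    SMOTE-synthetic rows — the leakage guard asserts that test folds contain
    only real rows.
    """
    ev = SubsetEvaluator(X, y, classifier_spec, n_folds, seed, smote_k,
                         cv_repeats=1)
    score = ev.score(list(feature_subset))
    if not return_fold_info:
        return score
    info = []
    cols = [c for c in X.columns if c in set(feature_subset)]
    Xs = X[cols].to_numpy(dtype=float)
    yarr = np.asarray(y)
    for i, (tr, te) in enumerate(ev.folds):
        _, _, prov = smote_oversample(Xs[tr], yarr[tr], k=smote_k, seed=seed + i)
        info.append({"test_indices": te, "train_provenance": prov})
    return score, info


def grid_search_model(X: pd.DataFrame, y: Sequence,
                      candidates: Optional[list] = None,
                      n_folds: int = 5, seed: int = 0) -> ClassifierSpec:
    """Best (model, hyperparameters) by cross-validated balanced accuracy over
    the full feature set; ties break by declaration order."""
    candidates = DEFAULT_CANDIDATES if candidates is None else candidates
    if not candidates or all(not grid for _, grid in candidates):
        raise ConfigError("grid search needs at least one non-empty grid")
    best_spec, best_score = None, -np.inf
    for model, grid in candidates:
        if not grid:
            raise ConfigError(f"empty grid for model {model!r}")
        for params in ParameterGrid(grid):
            spec = ClassifierSpec.make(model, **params)
            score = cv_evaluate(X, y, list(X.columns), spec, n_folds, seed)
            if score > best_score:
                best_spec, best_score = spec, score
    log.info("grid search best: %s (balanced accuracy %.3f)", best_spec, best_score)
    return best_spec


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

def _importances(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                 seed: int) -> np.ndarray:
    clf = make_classifier(spec, seed=seed)
    clf.fit(X, y)
    if hasattr(clf, "coef_"):
        return np.abs(clf.coef_).mean(axis=0)
    if hasattr(clf, "feature_importances_"):
        return np.asarray(clf.feature_importances_, dtype=float)
    res = permutation_importance(clf, X, y, n_repeats=3, random_state=seed)
    return res.importances_mean


def rfecv_select(X: pd.DataFrame, y: Sequence, classifier_spec: ClassifierSpec,
                 n_folds: int = 5, seed: int = 0, step: float = 0.10,
                 screen_p: Optional[pd.Series] = None,
                 p_cutoff: float = 0.05, smote_k: int = 5) -> List[str]:
    """Backwards recursive feature elimination with cross-validated scoring.

    If per-feature screening p-values are given, only features with
    ``p < p_cutoff`` enter.  Each iteration drops the lowest-importance 10% of
    remaining features (importance = mean |coefficient| for linear models,
    impurity or permutation importance otherwise, ties broken
    lexicographically) and the best-scoring set ever seen is returned.
    """
    features = list(X.columns)
    if screen_p is not None:
        features = [f for f in features if screen_p.get(f, 1.0) < p_cutoff]
        if not features:
            raise DesignError("no feature passed the screening p cutoff")
    ev = SubsetEvaluator(X, y, classifier_spec, n_folds, seed, smote_k)
    yarr = np.asarray(y)
    current = list(features)
    best_set, best_score = None, -np.inf
    while current:
        score = ev.score(current)
        if score > best_score:
            best_set, best_score = list(current), score
        if len(current) == 1:
            break
        Xo, yo, _ = smote_oversample(X[current].to_numpy(dtype=float), yarr,
                                     k=smote_k, seed=seed)
        imp = _importances(classifier_spec, Xo, yo, seed)
        n_drop = max(1, int(math.floor(step * len(current))))
        ranked = sorted(zip(imp, current), key=lambda t: (t[0], t[1]))
        drop = {f for _, f in ranked[:n_drop]}
        current = [f for f in current if f not in drop]
    log.info("RFE-CV kept %d features (balanced accuracy %.3f)",
             len(best_set), best_score)
    return best_set


# ---------------------------------------------------------------------------
# MCTS over feature subsets
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    """Selected subset, its cross-validated score, and the search evidence."""
    features: List[str]
    balanced_accuracy: float
    per_class_auc: Dict = field(default_factory=dict)
    qualifying_subsets: List[Tuple[Tuple[str, ...], float]] = field(default_factory=list)
    search_trace: List[Tuple[int, str, float]] = field(default_factory=list)
    pca_coordinates: Optional[pd.DataFrame] = None
    #: the search's own cross-validated score of the subset (optimistic:
    #: it was maximized over); the headline balanced_accuracy is held-out
    search_score: Optional[float] = None


class _Node:
    __slots__ = ("action", "children", "visits", "total", "best", "untried")

    def __init__(self, action: Optional[str], untried: List[str]):
        self.action = action
        self.children: Dict[str, _Node] = {}
        self.visits = 0
        self.total = 0.0
        self.best = -np.inf  # best reward seen in this subtree (max-backup)
        self.untried = list(untried)


def _ucb_pick(node: _Node, c: float, rng: np.random.Generator) -> "_Node":
    log_n = math.log(node.visits)
    best, best_val = None, -np.inf
    for child in node.children.values():
        val = child.total / child.visits + c * math.sqrt(log_n / child.visits)
        if val > best_val:
            best, best_val = child, val
    return best


def _grow_subset(initial: List[str], candidates: List[str],
                 reward_fn: Callable[[frozenset], float], cfg: MCTSConfig,
                 rng: np.random.Generator, evaluated: Dict[frozenset, float],
                 trace: List[tuple], iteration_offset: int = 0) -> List[str]:
    """Grow ``initial`` one feature per round until STOP wins.

    Each round spends ``trees_factor * len(candidates)`` simulations of a
    depth-bounded UCB1 tree whose actions are add-a-feature or STOP.  The
    tree policy uses mean-value UCB1; the round's decision uses max-backup:
    the feature appended is the root child whose subtree achieved the best
    reward.  STOP wins when no explored extension within the lookahead depth
    improves on the current subset by at least ``improvement_epsilon``.
    """

    def reward(subset: frozenset) -> float:
        if subset in evaluated:
            return evaluated[subset]
        val = reward_fn(subset)
        evaluated[subset] = val
        return val

    S = list(initial)
    budget = cfg.trees_factor * len(candidates)
    if budget == 0:
        raise ConfigError("MCTS budget is zero")
    it = iteration_offset
    max_rounds = len(candidates)
    for _ in range(max_rounds):
        remaining = [f for f in candidates if f not in S]
        if not remaining:
            break
        root = _Node(None, untried=remaining + [STOP])
        base = frozenset(S)
        current_score = reward(base)
        for _sim in range(budget):
            node, path = root, []
            # selection
            while not node.untried and node.children:
                node = _ucb_pick(node, cfg.ucb_c, rng)
                path.append(node)
                if node.action == STOP or len(path) >= cfg.depth:
                    break
            # expansion
            if node.untried and node.action != STOP and len(path) < cfg.depth:
                i = int(rng.integers(len(node.untried)))
                action = node.untried.pop(i)
                added = {p.action for p in path if p.action != STOP}
                nxt = [f for f in remaining if f not in added and f != action] \
                    if action != STOP else []
                child = _Node(action, untried=nxt + [STOP] if nxt else [])
                node.children[action] = child
                node = child
                path.append(node)
            # rollout to depth / STOP
            added = [p.action for p in path if p.action != STOP]
            stopped = any(p.action == STOP for p in path)
            while not stopped and len(added) < cfg.depth:
                pool = [f for f in remaining if f not in added] + [STOP]
                pick = pool[int(rng.integers(len(pool)))]
                if pick == STOP:
                    break
                added.append(pick)
            r = reward(base | set(added))
            # backprop (mean for the tree policy, max for the decision)
            root.visits += 1
            root.total += r
            root.best = max(root.best, r)
            for p in path:
                p.visits += 1
                p.total += r
                p.best = max(p.best, r)
        if not root.children:
            break
        it += 1
        best_action, best_node = max(
            root.children.items(),
            key=lambda kv: (kv[1].best, kv[1].visits, kv[0]))
        if best_action == STOP or \
                best_node.best < current_score + cfg.improvement_epsilon:
            trace.append((it, STOP, current_score))
            break
        # append only when the single-step addition itself improves: the
        # lookahead locates promising features, the one-step gate keeps the
        # subset minimal when the apparent improvement is noise further out
        step_score = reward(base | {best_action})
        if step_score - current_score < cfg.improvement_epsilon:
            trace.append((it, STOP, current_score))
            break
        S.append(best_action)
        base = frozenset(S)
        trace.append((it, best_action, step_score))
    return S


def _best_recorded(evaluated: Dict[frozenset, float]) -> Tuple[List[str], float]:
    """Best evaluated subset: max score, then smallest, then lexicographic."""
    best_key = max(evaluated,
                   key=lambda k: (evaluated[k], -len(k), tuple(sorted(k))[::-1]))
    # resolve exact ties deterministically
    best_score = evaluated[best_key]
    tied = [k for k, v in evaluated.items() if v == best_score]
    tied.sort(key=lambda k: (len(k), tuple(sorted(k))))
    return sorted(tied[0]), best_score


def mcts_feature_search(X: Optional[pd.DataFrame], y: Optional[Sequence],
                        candidate_features: Sequence[str],
                        classifier_spec: Optional[ClassifierSpec] = None,
                        cfg: Optional[MCTSConfig] = None, n_folds: int = 5,
                        smote_k: int = 5,
                        reward_fn: Optional[Callable] = None
                        ) -> SignatureResult:
    """Screen every candidate as a first feature and grow subsets by MCTS.

    ``reward_fn`` (frozen subset -> score) replaces the default cached
    cross-validated balanced accuracy; tests use deterministic reward tables
    through it.  Returns the best subset found, every qualifying subset
    (score > ``accept_threshold``) and the growth trace.
    """
    cfg = cfg or MCTSConfig()
    cfg.validate()
    candidates = list(dict.fromkeys(candidate_features))
    if not candidates:
        raise ConfigError("empty candidate set")
    if reward_fn is None:
        if X is None or y is None:
            raise ConfigError("X and y are required without a custom reward_fn")
        ev = SubsetEvaluator(X, y, classifier_spec or DEFAULT_SPEC, n_folds,
                             cfg.seed, smote_k)
        reward_fn = lambda subset: ev.score(sorted(subset))  # noqa: E731
    rng = np.random.default_rng(cfg.seed)
    evaluated: Dict[frozenset, float] = {}
    terminals: Dict[frozenset, float] = {}
    trace: List[tuple] = []
    for first in candidates:
        final = _grow_subset([first], candidates, reward_fn, cfg, rng,
                             evaluated, trace, iteration_offset=len(trace))
        fs = frozenset(final)
        if fs not in evaluated:
            evaluated[fs] = reward_fn(fs)
        terminals[fs] = evaluated[fs]
    best, best_score = _best_recorded(terminals)
    qualifying = sorted(
        ((tuple(sorted(k)), v) for k, v in terminals.items()
         if v > cfg.accept_threshold),
        key=lambda t: (-t[1], len(t[0]), t[0]))
    return SignatureResult(features=best, balanced_accuracy=best_score,
                           qualifying_subsets=qualifying, search_trace=trace)


def refine_signature(qualifying_subsets: List[Tuple[Tuple[str, ...], float]],
                     X: Optional[pd.DataFrame], y: Optional[Sequence],
                     classifier_spec: Optional[ClassifierSpec] = None,
                     cfg: Optional[MCTSConfig] = None, n_folds: int = 5,
                     smote_k: int = 5,
                     candidate_features: Optional[Sequence[str]] = None,
                     reward_fn: Optional[Callable] = None,
                     fallback: Optional[SignatureResult] = None
                     ) -> SignatureResult:
    """Second MCTS seeded by the most frequent features across qualifying
    subsets (top ``refine_init_size``, default = depth); the result never
    scores below the initial set itself.  With no qualifying subsets, fall
    back to the best subset from the first search."""
    cfg = cfg or MCTSConfig()
    cfg.validate()
    if not qualifying_subsets:
        if fallback is None:
            raise ConfigError("no qualifying subsets and no fallback result")
        log.info("refinement: no qualifying subsets, keeping best-trace subset")
        return fallback
    freq: Dict[str, int] = {}
    for subset, _ in qualifying_subsets:
        for f in subset:
            freq[f] = freq.get(f, 0) + 1
    m = cfg.refine_init_size or cfg.depth
    candidates = list(dict.fromkeys(
        candidate_features if candidate_features is not None
        else [f for subset, _ in qualifying_subsets for f in subset]))
    if reward_fn is None:
        ev = SubsetEvaluator(X, y, classifier_spec or DEFAULT_SPEC, n_folds,
                             cfg.seed, smote_k)
        reward_fn = lambda subset: ev.score(sorted(subset))  # noqa: E731
    # frequency ties are broken by each feature's own single-feature score,
    # then lexicographically, so the initial set is deterministic
    ranked = sorted(freq, key=lambda f: (-freq[f],
                                         -reward_fn(frozenset([f])), f))
    initial = ranked[:m]
    evaluated: Dict[frozenset, float] = {}
    terminals: Dict[frozenset, float] = {}
    trace: List[tuple] = []
    rng = np.random.default_rng(cfg.seed + 1)
    init_key = frozenset(initial)
    evaluated[init_key] = reward_fn(init_key)
    terminals[init_key] = evaluated[init_key]
    final = _grow_subset(initial, candidates, reward_fn, cfg, rng, evaluated,
                         trace)
    fs = frozenset(final)
    terminals[fs] = evaluated.get(fs, reward_fn(fs))
    # the signature is the refinement's own best subset (growth can only add
    # with positive lookahead gain, so this is >= the initial set's score)
    best, best_score = _best_recorded(terminals)
    return SignatureResult(features=best, balanced_accuracy=best_score,
                           qualifying_subsets=list(qualifying_subsets),
                           search_trace=trace)


# ---------------------------------------------------------------------------
# signature evaluation
# ---------------------------------------------------------------------------

def evaluate_signature(X: pd.DataFrame, y: Sequence, features: Sequence[str],
                       classifier_spec: Optional[ClassifierSpec] = None,
                       n_folds: int = 5, seed: int = 0, smote_k: int = 5
                       ) -> SignatureResult:
    """Held-out one-vs-rest ROC AUC per class, overall balanced accuracy and a
    2-component PCA projection of the standardized signature features."""
    spec = classifier_spec or DEFAULT_SPEC
    features = list(features)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ConfigError(f"features absent from X: {missing[:5]}")
    yarr = np.asarray(y)
    classes = np.unique(yarr)
    Xs = X[features].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof_scores = np.zeros((len(yarr), len(classes)))
    oof_pred = np.empty(len(yarr), dtype=yarr.dtype)
    for i, (tr, te) in enumerate(skf.split(Xs, yarr)):
        if len(np.unique(yarr[te])) < len(classes):
            raise DesignError("a class is absent from a CV fold; reduce n_folds")
        Xo, yo, _ = smote_oversample(Xs[tr], yarr[tr], k=smote_k, seed=seed + i)
        clf = make_classifier(spec, seed=seed)
        clf.fit(Xo, yo)
        oof_pred[te] = clf.predict(Xs[te])
        if hasattr(clf, "decision_function"):
            df = clf.decision_function(Xs[te])
        else:
            df = clf.predict_proba(Xs[te])
        if df.ndim == 1:  # binary: one score column
            df = np.column_stack([-df, df])
        cls_order = list(clf.classes_)
        for ci, cls in enumerate(classes):
            oof_scores[te, ci] = df[:, cls_order.index(cls)]

    per_class_auc = {}
    for ci, cls in enumerate(classes):
        truth = (yarr == cls).astype(int)
        per_class_auc[cls] = _roc_auc(truth, oof_scores[:, ci])
    ba = balanced_accuracy(yarr, oof_pred)

    coords = PCA(n_components=min(2, len(features), len(yarr)),
                 random_state=seed).fit_transform(
        StandardScaler().fit_transform(Xs))
    pca_df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in
                                           range(coords.shape[1])])
    pca_df.insert(0, "sample_id", list(X.index))
    pca_df["label"] = yarr
    return SignatureResult(features=features, balanced_accuracy=ba,
                           per_class_auc=per_class_auc, pca_coordinates=pca_df)


def _roc_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), tie-aware."""
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DesignError("AUC undefined: a class side is empty")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# end-to-end search driver
# ---------------------------------------------------------------------------

def anova_feature_p(X: pd.DataFrame, y: Sequence) -> pd.Series:
    """One-way ANOVA p per feature column across the classes of ``y``."""
    yarr = np.asarray(y)
    groups = [X[yarr == cls].to_numpy(dtype=float) for cls in np.unique(yarr)]
    F, p = stats.f_oneway(*groups, axis=0)
    return pd.Series(np.where(np.isnan(p), 1.0, p), index=X.columns)


def find_signature(X: pd.DataFrame, y: Sequence,
                   classifier_spec: Optional[ClassifierSpec] = None,
                   cfg: Optional[MCTSConfig] = None, n_folds: int = 5,
                   anova_p_cutoff: float = 0.05, smote_k: int = 5,
                   min_candidates: int = 2, max_candidates: Optional[int] = 15
                   ) -> SignatureResult:
    """ANOVA screen -> RFE-CV -> MCTS -> frequency refinement -> evaluation.

    If fewer than ``min_candidates`` features pass the ANOVA screen, the
    top-p features are taken so the search is always defined;
    ``max_candidates`` optionally truncates to the smallest screening p.
    """
    cfg = cfg or MCTSConfig()
    spec = classifier_spec or DEFAULT_SPEC
    p = anova_feature_p(X, y)
    passing = p.index[p < anova_p_cutoff].tolist()
    if len(passing) < min_candidates:
        passing = p.nsmallest(min_candidates).index.tolist()
        log.info("ANOVA screen kept < %d features; falling back to top-p",
                 min_candidates)
    if max_candidates is not None and len(passing) > max_candidates:
        passing = p.loc[passing].nsmallest(max_candidates).index.tolist()
    selected = rfecv_select(X[passing], y, spec, n_folds, cfg.seed,
                            smote_k=smote_k)
    ev = SubsetEvaluator(X, y, spec, n_folds, cfg.seed, smote_k)
    reward = lambda subset: ev.score(sorted(subset))  # noqa: E731
    first = mcts_feature_search(X, y, selected, spec, cfg, n_folds, smote_k,
                                reward_fn=reward)
    refined = refine_signature(first.qualifying_subsets, X, y, spec, cfg,
                               n_folds, smote_k, candidate_features=selected,
                               reward_fn=reward, fallback=first)
    final = evaluate_signature(X, y, refined.features, spec, n_folds, cfg.seed,
                               smote_k)
    final.qualifying_subsets = refined.qualifying_subsets
    final.search_trace = first.search_trace + refined.search_trace
    # the headline score is the held-out evaluation of the chosen subset;
    # the search's own (maximized, hence optimistic) CV score stays in the
    # trace and qualifying-subset records
    final.search_score = refined.balanced_accuracy
    return final
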