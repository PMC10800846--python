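"""Stage-1 machine learning: minimal OTU signature predicting host line.

The search mirrors a WEKA-style workflow:

1. every OTU is scored by information gain (entropy reduction after
   supervised MDL discretization of its counts) and by its differential-
   abundance p-value; the two rankings are combined by their mean rank;
2. a three-classifier ensemble (linear-kernel SVM, single-hidden-layer
   perceptron, CART decision tree) is evaluated under two validation schemes
   (one stratified 66/34 percent split and a stratified K-fold hold-out whose
   cell is the mean of its K runs); performance is always the mean of the six
   classifier x validation cells;
3. the worst-ranked fraction of OTUs is dropped and the ensemble re-run,
   iterating until a floor; the best-performing (smallest on ties) set is the
   candidate signature;
4. each candidate OTU is evaluated as the sole attribute, and OTUs below the
   individual-accuracy threshold or present in only one line are removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from microsig._seeds import child_seed
from microsig.containers import ConfigError, InputError, OtuTable

CLASSIFIERS = ("svm", "neural_net", "decision_tree")
VALIDATIONS = ("percent_split", "kfold_holdout")


# ---------------------------------------------------------------------------
# information gain with supervised MDL discretization
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray):
    """Best binary cut by information gain over class-boundary midpoints."""
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], labels[order]
    n = len(v)
    base = _entropy(y)
    best = (None, 0.0, None, None)
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        cut = (v[i] + v[i - 1]) / 2.0
        left, right = y[:i], y[i:]
        cond = (i * _entropy(left) + (n - i) * _entropy(right)) / n
        gain = base - cond
        if best[0] is None or gain > best[1] + 1e-12:
            best = (cut, gain, left, right)
    return best


def _mdl_accepts(gain: float, y: np.ndarray, left: np.ndarray, right: np.ndarray) -> bool:
    n = len(y)
    k = len(np.unique(y))
    k1, k2 = len(np.unique(left)), len(np.unique(right))
    delta = math.log2(3**k - 2) - (k * _entropy(y) - k1 * _entropy(left) - k2 * _entropy(right))
    return gain > (math.log2(n - 1) + delta) / n


def mdl_cut_points(values, labels) -> list[float]:
    """Fayyad-Irani recursive MDL partitioning; returns sorted cut points."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)

    def recurse(v, y, out):
        if len(v) < 2 or len(np.unique(y)) < 2:
            return
        cut, gain, left, right = _best_cut(v, y)
        if cut is None or not _mdl_accepts(gain, y, left, right):
            return
        out.append(cut)
        mask = v <= cut
        recurse(v[mask], y[mask], out)
        recurse(v[~mask], y[~mask], out)

    cuts: list[float] = []
    recurse(values, labels, cuts)
    return sorted(cuts)


def info_gain(values, labels, cuts=None) -> float:
    """Information gain (bits) of a feature about class labels.

    The continuous feature is discretized by supervised MDL binning (or by
    explicit ``cuts``), and the gain is ``H(labels) - H(labels | bin)``.
    A single resulting bin, or constant labels, gives 0 bits.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise InputError("feature and labels differ in length")
    if len(np.unique(labels)) < 2:
        warnings.warn("constant labels: information gain is 0")
        return 0.0
    if cuts is None:
        cuts = mdl_cut_points(values, labels)
    if len(cuts) == 0:
        return 0.0
    bins = np.searchsorted(np.asarray(cuts, dtype=float), values, side="left")
    base = _entropy(labels)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _entropy(labels[mask])
    return max(base - cond, 0.0)


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

def rank_features(info_gains: pd.Series, p_values: pd.Series) -> pd.DataFrame:
    """Combine the information-gain and p-value orderings by mean rank.

    Rank 1 is best on either criterion (highest gain, lowest p); ties get the
    average rank. Features with a missing p-value receive the worst p-rank.
    The result is sorted best-first by combined rank, ties broken by id.
    """
    ig = pd.Series(info_gains, dtype=float)
    pv = pd.Series(p_values, dtype=float).reindex(ig.index)
    if pv.isna().any():
        missing = sorted(pv.index[pv.isna()])
        warnings.warn(f"features without p-value assigned worst p-rank: {missing[:5]}...")
        pv = pv.fillna(np.inf)
    ig_rank = ig.rank(ascending=False, method="average")
    p_rank = pv.rank(ascending=True, method="average")
    out = pd.DataFrame(
        {"info_gain": ig, "p_value": pv.replace(np.inf, np.nan), "combined_rank": (ig_rank + p_rank) / 2.0}
    )
    # order ids first, then a stable sort on combined rank: ties break by id
    out = out.loc[sorted(out.index)]
    return out.sort_values("combined_rank", kind="mergesort")


# ---------------------------------------------------------------------------
# ensemble evaluation
# ---------------------------------------------------------------------------

@dataclass
class MLConfig:
    """Settings of the classifier ensemble and the signature search."""

    split_fraction: float = 0.66  # training share of the percent split
    k_folds: int = 6
    removal_fraction: float = 0.2
    floor: int = 5
    accuracy_threshold: float = 0.75
    hidden_cap: int = 64  # upper bound on perceptron hidden units
    max_epochs: int = 500

    def validate(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0,1)")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if not 0 < self.removal_fraction < 1:
            raise ConfigError("removal_fraction must be in (0,1)")
        if self.floor < 1:
            raise ConfigError("floor must be >= 1")


@dataclass
class EnsembleResult:
    """Accuracies of each classifier x validation cell and their mean."""

    cells: dict  # (classifier, validation) -> accuracy
    average_accuracy: float

    @classmethod
    def from_cells(cls, cells: dict) -> "EnsembleResult":
        vals = [cells[(c, v)] for c in CLASSIFIERS for v in VALIDATIONS]
        return cls(cells=dict(cells), average_accuracy=float(np.mean(vals)))


def _make_estimator(name: str, n_features: int, n_classes: int, seed: int, config: MLConfig):
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if name == "neural_net":
        hidden = min(math.ceil((n_features + n_classes) / 2), config.hidden_cap)
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(hidden,),
                solver="lbfgs",
                max_iter=config.max_epochs,
                random_state=seed,
            ),
        )
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ConfigError(f"unknown classifier {name!r}")


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """One stratified split; the test side is rounded down per class."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(np.floor((1 - train_fraction) * len(idx))))
        if n_test >= len(idx):
            raise InputError(f"class {cls!r} too small for the percent split")
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def evaluate_ensemble(X, y, config: MLConfig | None = None, seed: int = 0, strat=None) -> EnsembleResult:
    """Run the three-classifier / two-validation ensemble.

    The percent split and the fold assignment are built once per call (from
    ``seed``) and shared by all three classifiers, so the cells are directly
    comparable; the K-fold cell is the mean of its K hold-out runs. ``strat``
    optionally supplies coarser labels used only to build the stratified
    split/folds (for targets with classes too rare to stratify); the
    classifiers always see ``y``.
    """
    config = config or MLConfig()
    config.validate()
    Xv = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    yv = np.asarray(y)
    classes = np.unique(yv)
    if len(classes) < 2:
        raise InputError("ensemble needs at least 2 classes")
    sv = yv if strat is None else np.asarray(strat)
    _, strat_counts = np.unique(sv, return_counts=True)
    if strat_counts.min() < 2:
        raise InputError("every (stratification) class needs at least 2 samples")

    rng = np.random.default_rng(seed)
    tr, te = _stratified_split(sv, config.split_fraction, rng)
    if len(np.unique(sv)) < 2:  # merging collapsed stratification entirely
        k = min(config.k_folds, len(yv) // 2)
        folds = list(KFold(n_splits=k, shuffle=True, random_state=child_seed(seed, "kfold")).split(Xv))
    else:
        k = min(config.k_folds, int(strat_counts.min()))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=child_seed(seed, "kfold"))
        folds = list(skf.split(Xv, sv))

    cells = {}
    for name in CLASSIFIERS:
        est_seed = child_seed(seed, name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = _make_estimator(name, Xv.shape[1], len(classes), est_seed, config)
            est.fit(Xv[tr], yv[tr])
            cells[(name, "percent_split")] = float(np.mean(est.predict(Xv[te]) == yv[te]))
            accs = []
            for f_tr, f_te in folds:
                est = _make_estimator(name, Xv.shape[1], len(classes), est_seed, config)
                est.fit(Xv[f_tr], yv[f_tr])
                accs.append(float(np.mean(est.predict(Xv[f_te]) == yv[f_te])))
            cells[(name, "kfold_holdout")] = float(np.mean(accs))
    return EnsembleResult.from_cells(cells)


# ---------------------------------------------------------------------------
# iterative reduction and filters
# ---------------------------------------------------------------------------

@dataclass
class SignatureResult:
    iterations: list = field(default_factory=list)  # (feature tuple, EnsembleResult)
    best_set: list = field(default_factory=list)
    per_otu: dict = field(default_factory=dict)
    final_signature: list = field(default_factory=list)

    @property
    def best_accuracy(self) -> float:
        sizes = {len(f): r.average_accuracy for f, r in self.iterations}
        return sizes[len(self.best_set)]


def reduce_dimensionality(X: pd.DataFrame, y, ranked: pd.DataFrame, config: MLConfig | None = None, seed: int = 0) -> SignatureResult:
    """Iteratively shrink the feature set along the combined ranking.

    Starting from all ranked features, the ensemble is evaluated, the
    worst-ranked ``removal_fraction`` (at least one feature) is dropped, and
    the process repeats down to ``floor`` features. ``best_set`` is the
    evaluated set with the highest average accuracy, the smallest on ties.
    """
    config = config or MLConfig()
    order = [f for f in ranked.index if f in set(X.columns)]
    if not order:
        raise InputError("ranking covers none of the table's features")
    current = list(order)
    iterations = []
    while True:
        res = evaluate_ensemble(X[current], y, config, seed)
        iterations.append((tuple(current), res))
        if len(current) <= config.floor:
            break
        n_next = len(current) - max(1, int(len(current) * config.removal_fraction))
        current = current[: max(n_next, config.floor)]
    best = max(iterations, key=lambda it: (it[1].average_accuracy, -len(it[0])))
    return SignatureResult(iterations=iterations, best_set=list(best[0]))


def per_feature_performance(X: pd.DataFrame, y, otus, config: MLConfig | None = None, seed: int = 0) -> dict[str, float]:
    """Average ensemble accuracy of each OTU used as the sole attribute.

    The same seed (hence the same split and folds) is reused for every OTU so
    the individual accuracies are comparable.
    """
    missing = sorted(set(otus) - set(X.columns))
    if missing:
        raise InputError(f"OTUs not in table: {missing}")
    return {o: evaluate_ensemble(X[[o]], y, config, seed).average_accuracy for o in otus}


def filter_signature(per_otu: dict, table: OtuTable, threshold: float = 0.75) -> list[str]:
    """Keep OTUs with individual accuracy >= threshold and present in both lines."""
    if not per_otu:
        raise InputError("empty per-OTU accuracy map")
    lines = table.lines
    final = []
    for otu in sorted(per_otu):
        if per_otu[otu] < threshold:
            continue
        in_all = all((table.counts.loc[table.meta["line"] == line, otu] > 0).any() for line in lines)
        if in_all:
            final.append(otu)
    if not final:
        warnings.warn("no OTU survived the signature filters")
    return final


def find_signature(table: OtuTable, p_values: pd.Series, config: MLConfig | None = None, seed: int = 0) -> SignatureResult:
    """Full stage-1 search on an OTU table: rank, reduce, evaluate, filter."""
    config = config or MLConfig()
    y = table.line_labels().to_numpy()
    gains = pd.Series({o: info_gain(table.counts[o].to_numpy(), y) for o in table.otu_ids})
    ranked = rank_features(gains, p_values)
    result = reduce_dimensionality(table.counts, y, ranked, config, seed)
    result.per_otu = per_feature_performance(table.counts, y, result.best_set, config, seed)
    result.final_signature = filter_signature(result.per_otu, table, config.accuracy_threshold)
    return result
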