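"""Exhaustive biomarker signature search with repeated stratified CV.

Workflow for estimating the prognostic power of peptide/protein panels on
a small two-class cohort (N0 = no lymph-node metastasis, N+ = metastasis):

1. stratified 80/20 split into a training and an untouched test set;
2. univariate Mann-Whitney filter (P < 0.10) on the training set only;
3. exhaustive enumeration of every non-empty subset of the retained
   features (2^N - 1 candidate signatures);
4. for each signature, repeated stratified k-fold cross-validation
   (default 100 repetitions of 10 folds), optionally balancing each
   training fold with SMOTE — synthetic samples never enter an
   evaluation fold;
5. ranking by mean accuracy/AUC and final validation of the chosen
   signature on the held-out test set.

The positive class is N+ throughout; classifier scores are its predicted
probability. Every stochastic step (split, fold shuffles, SMOTE draws,
classifier seeds) is derived from ``CVConfig.base_seed`` by fixed offsets
so a full run is replayable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConfigurationError,
    ParameterError,
    SchemaError,
    SmoteError,
    StratificationError,
    UndefinedAUCError,
)
from .srm import mann_whitney

POSITIVE_LABEL = "N+"
NEGATIVE_LABEL = "N0"

METRICS = ("accuracy", "roc_auc", "f1", "sensitivity", "specificity", "precision")

# fixed multipliers deriving per-step seeds from base_seed (all mod 2^31)
_SMOTE_STRIDE = 100_003
_CLF_STRIDE = 7_919
_FOLD_STRIDE = 1_009
_SEED_MOD = 2**31


def _binarize(labels) -> np.ndarray:
    """Map labels to {0, 1} with N+ (or 1/True) as the positive class."""
    arr = np.asarray(labels)
    uniq = set(np.unique(arr).tolist())
    if uniq <= {0, 1, True, False}:
        return arr.astype(int)
    if uniq <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
        return (arr == POSITIVE_LABEL).astype(int)
    raise ParameterError(f"labels must be binary 0/1 or N0/N+, got {sorted(map(str, uniq))}")


# --------------------------------------------------------------------------
# Configuration and classifier contracts
# --------------------------------------------------------------------------


@dataclass
class CVConfig:
    """Cross-validation schedule and balancing options."""

    repetitions: int = 100
    folds: int = 10
    test_fraction: float = 0.2
    filter_alpha: float = 0.10
    balance: str = "none"  # "none" | "smote"
    smote_k: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.balance not in ("none", "smote"):
            raise ConfigurationError(f"balance must be 'none' or 'smote', got {self.balance!r}")


@dataclass
class ClassifierSpec:
    """A named classifier contract: ``factory(seed)`` builds a fresh estimator.

    The estimator must implement sklearn's fit API; scores are taken from
    ``predict_proba`` when available, otherwise the decision function is
    squashed through a logistic so scores always lie in [0, 1].
    """

    name: str
    factory: object  # Callable[[int], estimator]

    def fit_score(self, X_train, y_train, X_eval, seed: int) -> np.ndarray:
        est = self.factory(int(seed) % _SEED_MOD)
        est.fit(X_train, y_train)
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X_eval)
            pos_col = list(est.classes_).index(1)
            return proba[:, pos_col]
        return expit(est.decision_function(X_eval))


def make_classifiers() -> dict[str, ClassifierSpec]:
    """The seven-algorithm sweep set, seed-controlled.

    Random Forest (the default evaluation classifier) uses 500 trees with
    sqrt(p) features per split.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, Perceptron
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "linear_svm": ClassifierSpec("linear_svm", lambda s: SVC(kernel="linear", random_state=s)),
        "rbf_svm": ClassifierSpec("rbf_svm", lambda s: SVC(kernel="rbf", random_state=s)),
        "decision_tree": ClassifierSpec(
            "decision_tree", lambda s: DecisionTreeClassifier(random_state=s)
        ),
        "logistic_regression": ClassifierSpec(
            "logistic_regression",
            lambda s: LogisticRegression(max_iter=2000, random_state=s),
        ),
        "random_forest": ClassifierSpec(
            "random_forest",
            lambda s: RandomForestClassifier(
                n_estimators=500, max_features="sqrt", random_state=s, n_jobs=1
            ),
        ),
        "perceptron": ClassifierSpec("perceptron", lambda s: Perceptron(random_state=s)),
        "naive_bayes": ClassifierSpec("naive_bayes", lambda s: GaussianNB()),
    }


# --------------------------------------------------------------------------
# Split, filter, enumeration, SMOTE
# --------------------------------------------------------------------------


def stratified_holdout(labels, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split by per-class rounding.

    Each class contributes ``round(test_fraction * n_class)`` members to
    the test set (e.g. 14 N0 / 26 N+ at 0.2 gives a 3 + 5 test set), so
    test proportions stay within one patient of the cohort's.
    """
    y = _binarize(labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise StratificationError(f"class {cls} has {members.size} member(s); need >= 2")
        n_test = int(np.round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)  # both sides keep the class
        test_idx.extend(rng.permutation(members)[:n_test].tolist())
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def mw_filter(X: pd.DataFrame, labels, alpha: float = 0.10) -> list[str]:
    """Univariate Mann-Whitney feature filter (training data only).

    Retains features whose two-sided U-test p-value between classes is
    strictly below ``alpha``. Run this on the training split only — the
    test set must never influence feature selection.
    """
    y = _binarize(labels)
    if y.min() == y.max():
        raise ParameterError("both classes must be present for filtering")
    kept = []
    for feat in X.columns:
        v = X[feat].to_numpy(dtype=float)
        _u, p = mann_whitney(v[y == 1], v[y == 0])
        if p < alpha:
            kept.append(feat)
    return kept


def enumerate_signatures(features) -> list[tuple]:
    """All 2^N - 1 non-empty feature subsets, by size then lexicographic."""
    feats = list(features)
    if not 1 <= len(feats) <= 20:
        raise ParameterError(
            f"{len(feats)} features would enumerate 2^{len(feats)}-1 signatures; "
            "pre-filter to at most 20"
        )
    out: list[tuple] = []
    for size in range(1, len(feats) + 1):
        out.extend(itertools.combinations(sorted(feats), size))
    return out


def smote(
    X, labels, k: int = 5, seed: int = 0, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling: balance classes by interpolation.

    Each synthetic sample is ``x + u * (neighbor - x)`` for a uniformly
    drawn minority sample ``x``, one of its ``k`` nearest minority
    neighbours (Euclidean, computed on features standardized by the
    minority mean/sd when ``standardize``), and ``u ~ Uniform(0, 1)``.
    Returns ``(X_augmented, y_augmented, synthetic_mask)``; originals are
    untouched and come first. A ``k`` exceeding the minority size minus
    one is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = _binarize(labels)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        mask = np.zeros(y.size, dtype=bool)
        return X.copy(), y.copy(), mask
    minority = int(np.argmin(counts))
    n_needed = int(counts.max() - counts.min())
    idx_min = np.flatnonzero(y == minority)
    if idx_min.size < 2:
        raise SmoteError("minority class must have at least 2 members")
    if k > idx_min.size - 1:
        warnings.warn(f"smote k={k} reduced to {idx_min.size - 1} (minority size limit)")
        k = idx_min.size - 1

    Xm = X[idx_min]
    if standardize:
        mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xm - mu) / sd
    else:
        Z = Xm
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    neighbors = np.argsort(d2, axis=1)[:, :k]  # within-minority indices

    rng = np.random.default_rng(seed)
    synth = np.empty((n_needed, X.shape[1]))
    for s in range(n_needed):
        i = int(rng.integers(idx_min.size))
        j = int(neighbors[i, rng.integers(k)])
        u = rng.random()
        synth[s] = Xm[i] + u * (Xm[j] - Xm[i])
    X_aug = np.vstack([X, synth])
    y_aug = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    mask = np.concatenate([np.zeros(y.size, dtype=bool), np.ones(n_needed, dtype=bool)])
    return X_aug, y_aug, mask


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def roc_auc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Computed from midranks; identical to the Mann-Whitney statistic
    U / (n_pos * n_neg).
    """
    y = _binarize(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined with a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def binary_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a probability threshold (positive = N+).

    F1 is the harmonic mean of precision and sensitivity; precision with
    no predicted positives is reported as 0 with ``precision_defined``
    False.
    """
    y = _binarize(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    precision_defined = (tp + fp) > 0
    prec = tp / (tp + fp) if precision_defined else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": (tp + tn) / y.size,
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "precision_defined": precision_defined,
    }


# --------------------------------------------------------------------------
# Repeated cross-validation
# --------------------------------------------------------------------------


@dataclass
class SignatureResult:
    """Per-signature CV outcome: one row of metrics per repetition."""

    signature: tuple
    metrics: pd.DataFrame  # repetitions x METRICS
    classifier: str
    config: CVConfig
    audit: list = field(default_factory=list, repr=False)

    @property
    def means(self) -> dict[str, float]:
        return self.metrics.mean().to_dict()


def _effective_folds(y: np.ndarray, folds: int) -> int:
    min_class = int(np.bincount(y, minlength=2).min())
    if min_class < 2:
        raise StratificationError("each class needs >= 2 members for cross-validation")
    if folds > min_class:
        warnings.warn(f"folds reduced from {folds} to {min_class} (smallest class size)")
        return min_class
    return folds


def repeated_cv(
    X: pd.DataFrame,
    labels,
    signature,
    clf: ClassifierSpec,
    cfg: CVConfig,
    collect_audit: bool = False,
) -> SignatureResult:
    """Repeated stratified k-fold CV of one signature.

    Per repetition ``r`` a fresh stratified fold assignment is drawn with
    seed ``base_seed + r``; each training fold is optionally balanced with
    SMOTE (synthetic points are used for fitting only), the held-out fold
    is scored, and the repetition's metrics are computed on the pooled
    out-of-fold scores. The result stores the full per-repetition metric
    distributions.
    """
    signature = tuple(signature)
    missing = [f for f in signature if f not in X.columns]
    if missing:
        raise SchemaError(f"signature features absent from table: {missing}")
    Xs = X.loc[:, list(signature)].to_numpy(dtype=float)
    y = _binarize(labels)
    folds = _effective_folds(y, cfg.folds)

    rows = []
    audit: list[dict] = []
    for rep in range(cfg.repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(cfg.base_seed + rep) % _SEED_MOD)
        oof = np.full(y.size, np.nan)
        for fold, (tr, ev) in enumerate(skf.split(Xs, y)):
            X_tr, y_tr = Xs[tr], y[tr]
            n_synth = 0
            if cfg.balance == "smote":
                sm_seed = (cfg.base_seed + _SMOTE_STRIDE * rep + _FOLD_STRIDE * fold) % _SEED_MOD
                X_tr, y_tr, synth_mask = smote(X_tr, y_tr, k=cfg.smote_k, seed=sm_seed)
                n_synth = int(synth_mask.sum())
            clf_seed = (cfg.base_seed + _CLF_STRIDE * rep + _FOLD_STRIDE * fold) % _SEED_MOD
            oof[ev] = clf.fit_score(X_tr, y_tr, Xs[ev], clf_seed)
            if collect_audit:
                audit.append(
                    {
                        "repetition": rep,
                        "fold": fold,
                        "train_rows": tr.copy(),
                        "eval_rows": ev.copy(),
                        "n_synthetic_in_fit": n_synth,
                        "n_eval": int(ev.size),
                    }
                )
        assert not np.isnan(oof).any(), "folds must partition the training set"
        row = binary_metrics(y, oof)
        row.pop("precision_defined")
        row["roc_auc"] = roc_auc(y, oof)
        rows.append(row)
    metrics = pd.DataFrame(rows)[list(METRICS)]
    return SignatureResult(
        signature=signature, metrics=metrics, classifier=clf.name, config=cfg, audit=audit
    )


def classifier_sweep(
    X: pd.DataFrame, labels, signatures, classifiers, cfg: CVConfig
) -> pd.DataFrame:
    """Rank classifiers by mean CV accuracy (then AUC) over reference signatures."""
    specs = list(classifiers)
    if not specs:
        raise ParameterError("need at least one classifier")
    rows = []
    for spec in specs:
        means = pd.DataFrame(
            [repeated_cv(X, labels, s, spec, cfg).means for s in signatures]
        ).mean()
        rows.append({"classifier": spec.name, **means.to_dict()})
    report = pd.DataFrame(rows).sort_values(
        ["accuracy", "roc_auc"], ascending=False, kind="stable"
    )
    report.insert(0, "rank", range(1, len(report) + 1))
    return report.reset_index(drop=True)


def rank_signatures(results, accuracy_floor: float = 0.0) -> list[SignatureResult]:
    """Order signatures for selection.

    Signatures below the mean-accuracy floor are dropped; the rest sort by
    mean AUC descending, ties broken toward the smaller signature, then
    lexicographically.
    """
    results = list(results)
    if not results:
        raise ParameterError("no signature results to rank")
    kept = [r for r in results if r.means["accuracy"] >= accuracy_floor]
    return sorted(
        kept, key=lambda r: (-r.means["roc_auc"], len(r.signature), r.signature)
    )


def holdout_validate(
    X_train: pd.DataFrame,
    labels_train,
    X_test: pd.DataFrame,
    labels_test,
    signature,
    clf: ClassifierSpec,
    cfg: CVConfig,
) -> dict:
    """Fit once on the full training set and score the untouched test set."""
    overlap = set(X_train.index) & set(X_test.index)
    if overlap:
        raise ParameterError(f"test patients overlap training set: {sorted(overlap)[:5]}")
    signature = tuple(signature)
    for f in signature:
        if f not in X_test.columns:
            raise SchemaError(f"feature {f!r} missing from test table")
    Xtr = X_train.loc[:, list(signature)].to_numpy(dtype=float)
    ytr = _binarize(labels_train)
    if cfg.balance == "smote":
        Xtr, ytr, _mask = smote(Xtr, ytr, k=cfg.smote_k, seed=cfg.base_seed % _SEED_MOD)
    scores = clf.fit_score(
        Xtr, ytr, X_test.loc[:, list(signature)].to_numpy(dtype=float), cfg.base_seed
    )
    yte = _binarize(labels_test)
    out = binary_metrics(yte, scores)
    if yte.min() != yte.max():
        out["roc_auc"] = roc_auc(yte, scores)
    return out


# --------------------------------------------------------------------------
# End-to-end search
# --------------------------------------------------------------------------


@dataclass
class SearchReport:
    train_index: np.ndarray
    test_index: np.ndarray
    retained_features: list
    results: list  # SignatureResult, enumeration order
    ranked: list  # SignatureResult, selection order
    best: SignatureResult
    holdout: dict


def signature_search(
    X: pd.DataFrame,
    labels,
    cfg: CVConfig,
    clf: ClassifierSpec | None = None,
    holdout_clf: ClassifierSpec | None = None,
    accuracy_floor: float = 0.0,
) -> SearchReport:
    """Full pipeline: split, filter, enumerate, CV every signature, validate.

    The univariate filter and all cross-validation run strictly on the
    training split; the held-out fraction is touched exactly once, by the
    final validation of the top-ranked signature.
    """
    if X.isna().any().any():
        raise SchemaError("feature table contains missing values at model entry")
    clf = clf or make_classifiers()["random_forest"]
    y = _binarize(labels)
    train, test = stratified_holdout(y, cfg.test_fraction, cfg.base_seed)
    X_tr, y_tr = X.iloc[train], y[train]
    retained = mw_filter(X_tr, y_tr, cfg.filter_alpha)
    if not retained:
        raise ParameterError("no feature passed the univariate filter")
    sigs = enumerate_signatures(retained)
    results = [repeated_cv(X_tr, y_tr, s, clf, cfg) for s in sigs]
    ranked = rank_signatures(results, accuracy_floor)
    if not ranked:
        ranked = rank_signatures(results, 0.0)
    best = ranked[0]
    holdout = holdout_validate(
        X_tr, y_tr, X.iloc[test], y[test], best.signature, holdout_clf or clf, cfg
    )
    return SearchReport(
        train_index=train,
        test_index=test,
        retained_features=retained,
        results=results,
        ranked=ranked,
        best=best,
        holdout=holdout,
    )
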