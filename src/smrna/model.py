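"""Multi-class random-forest modelling of small-RNA locus features.

Covers forest training, backwards-elimination feature selection with the
out-of-bag (OOB) permutation importance and a one-standard-error rule,
selection-stability reports over repeated runs, stratified
cross-validation (optionally with selection nested inside folds),
permuted-label baselines, classical MDS of the forest proximity matrix,
and train-on-one / test-on-another dataset validation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES, FeatureMatrix

log = logging.getLogger(__name__)

try:  # per-tree bootstrap bookkeeping; no public API exposes OOB indices
    import inspect

    from sklearn.ensemble._forest import _generate_unsampled_indices

    _UNSAMPLED_TAKES_WEIGHT = (
        "sample_weight" in inspect.signature(_generate_unsampled_indices).parameters
    )

    def _oob_indices(tree_state: int, n_samples: int) -> np.ndarray:
        if _UNSAMPLED_TAKES_WEIGHT:
            return _generate_unsampled_indices(tree_state, n_samples, n_samples, None)
        return _generate_unsampled_indices(tree_state, n_samples, n_samples)

except ImportError:  # pragma: no cover - replicate sklearn's bootstrap draw

    def _oob_indices(tree_state: int, n_samples: int) -> np.ndarray:
        from sklearn.utils import check_random_state

        sampled = check_random_state(tree_state).randint(
            0, n_samples, n_samples, dtype=np.int32
        )
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        return np.flatnonzero(mask)


def _default_mtry(n_features: int, mtry_factor: float | None = None) -> int:
    base = math.sqrt(n_features)
    m = int(base) if mtry_factor is None else int(mtry_factor * base)
    return max(1, min(n_features, m))


def _as_xy(fm: FeatureMatrix | pd.DataFrame, y=None) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(fm, FeatureMatrix):
        return fm.data, (fm.y if y is None else np.asarray(y))
    if y is None:
        raise ValueError("labels required")
    return fm, np.asarray(y)


@dataclass
class ForestModel:
    """A trained multi-class random forest over a selected feature subset."""

    estimator: RandomForestClassifier
    selected_features: list[str]
    classes: list[str]
    ntree: int
    mtry: int
    seed: int
    oob_error: float

    def predict(self, fm: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        data = fm.data if isinstance(fm, FeatureMatrix) else fm
        return self.estimator.predict(data[self.selected_features].to_numpy(float))

    def save(self, path: str | Path) -> None:
        """Save as a directory archive: manifest.json + model.joblib."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "selected_features": self.selected_features,
            "classes": self.classes,
            "ntree": self.ntree,
            "mtry": self.mtry,
            "seed": self.seed,
            "oob_error": self.oob_error,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        joblib.dump(self.estimator, path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        est = joblib.load(path / "model.joblib")
        return cls(
            estimator=est,
            selected_features=manifest["selected_features"],
            classes=manifest["classes"],
            ntree=manifest["ntree"],
            mtry=manifest["mtry"],
            seed=manifest["seed"],
            oob_error=manifest["oob_error"],
        )


def train_forest(
    fm: FeatureMatrix | pd.DataFrame,
    y=None,
    ntree: int = 1000,
    mtry: int | None = None,
    mtry_factor: float | None = None,
    seed: int = 0,
    features: list[str] | None = None,
    oob: bool = True,
) -> ForestModel:
    """Train a random forest; fully reproducible given ``seed``."""
    data, yv = _as_xy(fm, y)
    if features is not None:
        data = data[features]
    classes = sorted(np.unique(yv))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    p = data.shape[1]
    m = mtry if mtry is not None else _default_mtry(p, mtry_factor)
    est = RandomForestClassifier(
        n_estimators=ntree,
        max_features=m,
        bootstrap=True,
        oob_score=oob,
        random_state=int(seed),
        n_jobs=1,
    )
    est.fit(data.to_numpy(float), yv)
    oob_error = float(1.0 - est.oob_score_) if oob else float("nan")
    return ForestModel(
        estimator=est,
        selected_features=list(data.columns),
        classes=[str(c) for c in classes],
        ntree=ntree,
        mtry=m,
        seed=int(seed),
        oob_error=oob_error,
    )


def oob_permutation_importance(
    model: ForestModel, data: pd.DataFrame, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Mean decrease in OOB accuracy when each feature is permuted (per tree)."""
    X = data[model.selected_features].to_numpy(float)
    yv = np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    n_trees = 0
    for tree in model.estimator.estimators_:
        oob_idx = _oob_indices(tree.random_state, n)
        if len(oob_idx) == 0:
            continue
        n_trees += 1
        Xo = X[oob_idx]
        yo = yv[oob_idx]
        classes = model.estimator.classes_
        base_pred = classes.take(np.argmax(tree.predict_proba(Xo), axis=1))
        base_acc = float(np.mean(base_pred == yo))
        perm = rng.permutation(len(oob_idx))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            pred = classes.take(np.argmax(tree.predict_proba(Xp), axis=1))
            drops[j] += base_acc - float(np.mean(pred == yo))
    return drops / max(n_trees, 1)


@dataclass
class SelectionResult:
    selected: list[str]
    trace: list[tuple[tuple[str, ...], float]]  # (feature set, OOB error), shrinking
    threshold: float


def select_features(
    fm: FeatureMatrix | pd.DataFrame,
    y=None,
    drop_frac: float = 0.35,
    ntree: int = 1000,
    se_rule: float = 1.0,
    seed: int = 0,
    importance: str = "permutation",
    mtry_factor: float | None = None,
) -> SelectionResult:
    """Backwards variable elimination on random-forest importance.

    Iteratively fits a forest, ranks features by OOB permutation
    importance (or Gini), drops the ``drop_frac`` fraction least
    important (at least one), and refits down to two features. Returns
    the smallest feature set whose OOB error is within ``se_rule``
    standard errors of the minimum, plus the full elimination trace.
    """
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    data, yv = _as_xy(fm, y)
    if data.shape[1] < 2:
        raise ValueError("feature selection requires at least two features")
    n = len(data)
    rng = np.random.default_rng(seed)
    current = list(data.columns)
    trace: list[tuple[tuple[str, ...], float]] = []
    while True:
        sub_seed = int(rng.integers(2**31))
        mdl = train_forest(
            data[current], yv, ntree=ntree, mtry_factor=mtry_factor, seed=sub_seed
        )
        trace.append((tuple(current), mdl.oob_error))
        if len(current) <= 2:
            break
        if importance == "gini":
            imp = mdl.estimator.feature_importances_
        elif importance == "permutation":
            imp = oob_permutation_importance(mdl, data[current], yv, seed=sub_seed)
        else:
            raise ValueError(f"unknown importance measure {importance!r}")
        n_drop = max(1, int(drop_frac * len(current)))
        n_keep = max(2, len(current) - n_drop)
        order = np.argsort(imp, kind="stable")[::-1]  # most important first
        current = [current[i] for i in sorted(order[:n_keep])]
    errors = np.array([e for _, e in trace])
    min_err = float(errors.min())
    se = math.sqrt(min_err * (1.0 - min_err) / n)
    threshold = min_err + se_rule * se
    eligible = [fs for fs, e in trace if e <= threshold]
    selected = min(eligible, key=len)
    return SelectionResult(selected=list(selected), trace=trace, threshold=threshold)


@dataclass
class SelectionReport:
    """Per-class, per-feature selection counts over R one-vs-rest runs."""

    counts: pd.DataFrame  # features x classes, int selection counts
    signs: pd.DataFrame  # features x classes, {-1, 0, +1} from difference of means
    R: int


def feature_signs(fm: FeatureMatrix, classes: list[str], tol: float = 1e-12) -> pd.DataFrame:
    """Sign of (class mean - rest mean) for every feature and class."""
    signs = pd.DataFrame(0, index=fm.data.columns, columns=classes, dtype=int)
    y = fm.y
    for cls in classes:
        in_cls = fm.data[y == cls].mean(axis=0)
        rest = fm.data[y != cls].mean(axis=0)
        diff = in_cls - rest
        signs[cls] = np.where(np.abs(diff) <= tol, 0, np.sign(diff)).astype(int)
    return signs


def stability_selection(
    fm: FeatureMatrix,
    R: int = 100,
    seed: int = 0,
    classes: list[str] | None = None,
    **select_kwargs,
) -> SelectionReport:
    """Repeat one-vs-rest feature selection R times per class and count selections."""
    if R < 2:
        raise ValueError("stability selection requires R >= 2 runs")
    y = fm.y
    if classes is None:
        classes = sorted(np.unique(y))
    counts = pd.DataFrame(0, index=fm.data.columns, columns=classes, dtype=int)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(2**31, size=(len(classes), R))
    for ci, cls in enumerate(classes):
        y_bin = np.where(y == cls, cls, "rest")
        for r in range(R):
            res = select_features(fm.data, y_bin, seed=int(run_seeds[ci, r]), **select_kwargs)
            counts.loc[res.selected, cls] += 1
    return SelectionReport(counts=counts, signs=feature_signs(fm, classes), R=R)


@dataclass
class EvaluationReport:
    """Pooled confusion matrix with per-class recall/PPV/accuracy."""

    classes: list[str]
    confusion: np.ndarray  # rows = true, cols = predicted
    baseline: list[float] | None = None
    excluded_classes: list[str] = field(default_factory=list)

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None, **kw) -> "EvaluationReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        conf = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            conf[index[t], index[p]] += 1
        return cls(classes=list(classes), confusion=conf, **kw)

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.confusion).astype(float)

    @property
    def recall(self) -> np.ndarray:
        """REC_k = TP_k / (TP_k + FN_k)."""
        denom = self.confusion.sum(axis=1).astype(float)
        return np.divide(self.tp, denom, out=np.zeros_like(self.tp), where=denom > 0)

    @property
    def ppv(self) -> np.ndarray:
        """PPV_k = TP_k / (TP_k + FP_k)."""
        denom = self.confusion.sum(axis=0).astype(float)
        return np.divide(self.tp, denom, out=np.zeros_like(self.tp), where=denom > 0)

    @property
    def acc_k(self) -> np.ndarray:
        """ACC_k = (TP_k + TN_k) / (TP_k + TN_k + FP_k + FN_k)."""
        fp = self.confusion.sum(axis=0) - self.tp
        fn = self.confusion.sum(axis=1) - self.tp
        tn = self.total - self.tp - fp - fn
        return (self.tp + tn) / self.total

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.total)

    def per_class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.confusion.sum(axis=1),
                "recall": self.recall,
                "ppv": self.ppv,
                "acc": self.acc_k,
            },
            index=pd.Index(self.classes, name="class"),
        )

    def summary(self) -> str:
        lines = [self.per_class_table().to_string(float_format=lambda v: f"{v:.4f}")]
        lines.append(f"overall accuracy: {self.overall_accuracy:.4f} (n={self.total})")
        if self.baseline:
            lines.append(
                f"permuted-label baseline: mean accuracy "
                f"{float(np.mean(self.baseline)):.4f} over {len(self.baseline)} permutations"
            )
        if self.excluded_classes:
            lines.append(f"excluded classes: {', '.join(self.excluded_classes)}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        conf = pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)
        with open(path, "w") as fh:
            fh.write("# confusion matrix (rows = true, cols = predicted)\n")
            conf.to_csv(fh, sep="\t", index_label="class")
            fh.write("# per-class metrics\n")
            self.per_class_table().to_csv(fh, sep="\t")
            fh.write(f"# overall_accuracy\t{self.overall_accuracy!r}\n")
            if self.baseline:
                fh.write(f"# baseline_mean_accuracy\t{float(np.mean(self.baseline))!r}\n")


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[str]]:
    """Round-robin stratified fold assignment; single-member classes excluded."""
    folds: list[list[int]] = [[] for _ in range(k)]
    excluded = []
    for cls in sorted(np.unique(y)):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            log.warning("class %s has a single member; excluded from cross-validation", cls)
            excluded.append(str(cls))
            continue
        if len(idx) < k:
            log.warning(
                "class %s has %d members (< %d folds); effectively leave-one-out", cls, len(idx), k
            )
        idx = rng.permutation(idx)
        offset = int(rng.integers(k))
        for i, ix in enumerate(idx):
            folds[(i + offset) % k].append(int(ix))
    return [np.array(sorted(f), dtype=int) for f in folds], excluded


def cross_validate(
    fm: FeatureMatrix,
    y=None,
    k_folds: int = 10,
    nested: bool = True,
    seed: int = 0,
    ntree: int = 1000,
    mtry_factor: float | None = None,
    selection_kwargs: dict | None = None,
    features: list[str] | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with one pooled confusion matrix.

    With ``nested``, feature selection is re-run inside every training
    split (avoiding selection bias); otherwise all columns (or the
    ``features`` subset, e.g. from a pooled pre-selection) are used.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    data, yv = _as_xy(fm, y)
    if features is not None:
        data = data[features]
    rng = np.random.default_rng(seed)
    folds, excluded = _stratified_folds(yv, k_folds, rng)
    keep = np.concatenate(folds) if folds else np.array([], dtype=int)
    classes = sorted(np.unique(yv[keep]))
    sel_kw = dict(selection_kwargs or {})
    sel_kw.setdefault("ntree", ntree)
    y_true_all, y_pred_all = [], []
    for fold in folds:
        test_mask = np.zeros(len(data), dtype=bool)
        test_mask[fold] = True
        train_mask = ~test_mask
        train_mask[np.setdiff1d(np.arange(len(data)), keep)] = False
        train_X, train_y = data[train_mask], yv[train_mask]
        fold_seed = int(rng.integers(2**31))
        cols = list(data.columns)
        if nested:
            cols = select_features(train_X, train_y, seed=fold_seed, **sel_kw).selected
        mdl = train_forest(
            train_X[cols], train_y, ntree=ntree, mtry_factor=mtry_factor,
            seed=fold_seed, oob=False,
        )
        pred = mdl.estimator.predict(data.loc[test_mask, cols].to_numpy(float))
        y_true_all.extend(yv[test_mask])
        y_pred_all.extend(pred)
    return EvaluationReport.from_predictions(
        y_true_all, y_pred_all, classes=classes, excluded_classes=excluded
    )


def permutation_baseline(
    fm: FeatureMatrix,
    y=None,
    n_perms: int = 100,
    seed: int = 0,
    k_folds: int = 10,
    ntree: int = 1000,
    mtry_factor: float | None = None,
) -> list[float]:
    """Cross-validated accuracies after label permutation (class sizes kept).

    Selection is disabled in the baseline runs to keep cost bounded; the
    mean of the returned list is the chance-level reference.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    data, yv = _as_xy(fm, y)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_perms):
        y_perm = rng.permutation(yv)
        rep = cross_validate(
            data, y_perm, k_folds=k_folds, nested=False,
            seed=int(rng.integers(2**31)), ntree=ntree, mtry_factor=mtry_factor,
        )
        accs.append(rep.overall_accuracy)
    return accs


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # n x d
    eigenvalues: np.ndarray
    stress: float
    source: str = "random-forest proximity"


def forest_proximity(model: ForestModel, fm: FeatureMatrix | pd.DataFrame) -> np.ndarray:
    """P_ij = fraction of trees in which samples i and j share a terminal node."""
    data = fm.data if isinstance(fm, FeatureMatrix) else fm
    leaves = model.estimator.apply(data[model.selected_features].to_numpy(float))
    n, t = leaves.shape
    prox = np.zeros((n, n))
    for k in range(t):
        col = leaves[:, k]
        prox += col[:, None] == col[None, :]
    return prox / t


def proximity_mds(
    model: ForestModel, fm: FeatureMatrix | pd.DataFrame, dims: int = 2
) -> MdsEmbedding:
    """Classical (Torgerson) MDS of the forest proximity matrix.

    Distances are d_ij = sqrt(1 - P_ij); coordinates come from the top
    positive eigenpairs of the double-centred squared-distance matrix.
    """
    prox = forest_proximity(model, fm)
    n = prox.shape[0]
    if not 1 <= dims <= min(5, n - 1):
        raise ValueError("dims must be between 1 and min(5, n - 1)")
    D = np.sqrt(np.clip(1.0 - prox, 0.0, None))
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    coords = np.zeros((n, dims))
    for d in range(dims):
        if w[d] > 1e-12:
            coords[:, d] = V[:, d] * math.sqrt(w[d])
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    denom = float((D**2).sum())
    stress = math.sqrt(float(((emb_d - D) ** 2).sum()) / denom) if denom > 0 else 0.0
    return MdsEmbedding(coordinates=coords, eigenvalues=w[:dims], stress=stress)


def cross_dataset_validate(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    nested: bool = True,
    seed: int = 0,
    ntree: int = 1000,
    mtry_factor: float | None = None,
    selection_kwargs: dict | None = None,
) -> EvaluationReport:
    """Train (with optional feature selection) on one dataset, evaluate on another."""
    if list(train_fm.data.columns) != list(test_fm.data.columns):
        raise ValueError("train and test feature columns differ")
    train_y = train_fm.y
    test_y = test_fm.y
    train_classes = set(np.unique(train_y))
    extra = sorted(set(np.unique(test_y)) - train_classes)
    if extra:
        n_drop = int(np.isin(test_y, extra).sum())
        log.warning(
            "dropping %d test loci from classes absent in training: %s", n_drop, ", ".join(extra)
        )
        test_fm = FeatureMatrix(
            test_fm.data[~test_fm.labels.isin(extra)], test_fm.labels[~test_fm.labels.isin(extra)]
        )
        test_y = test_fm.y
    rng = np.random.default_rng(seed)
    cols = list(train_fm.data.columns)
    sel_kw = dict(selection_kwargs or {})
    sel_kw.setdefault("ntree", ntree)
    if nested:
        cols = select_features(
            train_fm.data, train_y, seed=int(rng.integers(2**31)), **sel_kw
        ).selected
    mdl = train_forest(
        train_fm.data[cols], train_y, ntree=ntree, mtry_factor=mtry_factor,
        seed=int(rng.integers(2**31)), oob=False,
    )
    pred = mdl.estimator.predict(test_fm.data[cols].to_numpy(float))
    return EvaluationReport.from_predictions(
        test_y, pred, classes=sorted(train_classes | set(np.unique(test_y))),
        excluded_classes=extra,
    )
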