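"""Classifier training: feature assembly, 50/50 split, 5-fold CV tuned by
AUC, held-out evaluation, and F1-optimal decision-threshold calibration.

Five algorithm families are supported, each tuning a single hyperparameter:

======  ===============================================  ==================
id      concrete model                                   tuned parameter
======  ===============================================  ==================
glm     elastic-net logistic regression (saga)           l1 mixing "alpha"
knn     k-nearest neighbours                             k
svm     RBF support vector machine                       log2(C)
ann     single-hidden-layer perceptron                   weight decay
rf      random forest, 500 trees                         mtry (max_features)
======  ===============================================  ==================

Features are standardized (train-set mean/SD) for glm/knn/svm/ann and used
raw for rf.  Grid-AUC ties break toward the smaller hyperparameter; F1 ties
break toward the lowest threshold.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import sklearn
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from smireg import __version__
from smireg.chem_features import fingerprint_columns
from smireg.pair_data import RegulationDataset
from smireg.rna_features import build_descriptor, descriptor_columns

N_FEATURES = 443

ALGORITHMS = ("glm", "knn", "svm", "ann", "rf")

DEFAULT_GRIDS: dict[str, list] = {
    "glm": [0.0, 0.25, 0.5, 0.75, 1.0],
    "knn": list(range(3, 23, 2)),
    "svm": list(range(-2, 7)),  # log2(C)
    "ann": [round(0.1 * i, 1) for i in range(1, 10)],
    "rf": [21, 100, 149],
}

SCALED_ALGORITHMS = frozenset({"glm", "knn", "svm", "ann"})


def feature_names() -> list[str]:
    return descriptor_columns() + fingerprint_columns()


def assemble_features(ds: RegulationDataset) -> tuple[pd.DataFrame, np.ndarray, list[tuple[str, str]]]:
    """One 443-feature row per pair: miRNA descriptor (277) ++ fingerprint (166).

    Returns (X, y, keys) where keys[i] = (sm_id, mirna_id) of row i.
    """
    desc_cache = {mid: build_descriptor(rec) for mid, rec in ds.mirnas.items()}
    missing = [p.sm_id for p in ds.pairs if p.sm_id not in ds.fingerprints]
    if missing:
        raise ValueError(f"unfeaturizable molecule(s): {sorted(set(missing))}")
    rows, labels, keys = [], [], []
    for p in ds.pairs:
        rows.append(np.concatenate([desc_cache[p.mirna_id], ds.fingerprints[p.sm_id]]))
        labels.append(p.label)
        keys.append((p.sm_id, p.mirna_id))
    X = pd.DataFrame(np.vstack(rows), columns=feature_names())
    assert X.shape[1] == N_FEATURES
    return X, np.asarray(labels, dtype=int), keys


def split_train_test(
    X: pd.DataFrame, y: np.ndarray, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified split into (1-fraction) train / fraction test, deterministic under seed."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 2:
        raise ValueError("need >= 2 rows per class to split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=fraction, stratify=y, random_state=seed
    )
    return X_tr, X_te, y_tr, y_te


def make_estimator(algorithm: str, param, seed: int = 0):
    """Concrete scikit-learn estimator for an (algorithm, hyperparameter) pair."""
    if algorithm == "glm":
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=float(param), C=1.0, max_iter=5000
        )
    elif algorithm == "knn":
        clf = KNeighborsClassifier(n_neighbors=int(param))
    elif algorithm == "svm":
        clf = SVC(kernel="rbf", C=2.0 ** float(param), probability=True, random_state=seed)
    elif algorithm == "ann":
        clf = MLPClassifier(
            hidden_layer_sizes=(5,), alpha=float(param), max_iter=2000, random_state=seed
        )
    elif algorithm == "rf":
        clf = RandomForestClassifier(
            n_estimators=500, max_features=int(param), random_state=seed, n_jobs=1
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if algorithm in SCALED_ALGORITHMS:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation with midrank tie handling."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks for ties
    return (float(np.sum(ranks[y_true == 1])) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def sens_spec(y_true: np.ndarray, scores: np.ndarray, cutoff: float = 0.5) -> tuple[float, float]:
    pred = np.asarray(scores) >= cutoff
    y_true = np.asarray(y_true).astype(bool)
    sens = float(np.mean(pred[y_true])) if y_true.any() else float("nan")
    spec = float(np.mean(~pred[~y_true])) if (~y_true).any() else float("nan")
    return sens, spec


@dataclass
class CVResult:
    """Per-grid-value 5-fold CV metrics for one algorithm, plus the winner."""

    algorithm: str
    table: pd.DataFrame  # param, ROC, Sens, Spec, ROCSD, SensSD, SpecSD
    best_param: object
    best_auc: float


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    algorithm: str,
    grid: Sequence | None = None,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Tune one hyperparameter by mean CV AUC; Sens/Spec reported at cutoff 0.5.

    AUC ties between grid values break toward the smaller value (grid order).
    """
    grid = list(DEFAULT_GRIDS[algorithm] if grid is None else grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    grid = sorted(grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for _, val_idx in splits:
        if len(np.unique(y[val_idx])) < 2:
            raise ValueError("degenerate CV fold: a validation fold contains a single class")

    records = []
    for param in grid:
        aucs, senss, specs = [], [], []
        for tr_idx, val_idx in splits:
            est = make_estimator(algorithm, param, seed=seed)
            est.fit(X.iloc[tr_idx], y[tr_idx])
            proba = est.predict_proba(X.iloc[val_idx])[:, 1]
            aucs.append(auc_score(y[val_idx], proba))
            se, sp = sens_spec(y[val_idx], proba)
            senss.append(se)
            specs.append(sp)
        records.append(
            {
                "param": param,
                "ROC": float(np.mean(aucs)),
                "Sens": float(np.mean(senss)),
                "Spec": float(np.mean(specs)),
                "ROCSD": float(np.std(aucs, ddof=1)),
                "SensSD": float(np.std(senss, ddof=1)),
                "SpecSD": float(np.std(specs, ddof=1)),
            }
        )
    table = pd.DataFrame(records)
    best_idx = int(table["ROC"].idxmax())  # idxmax keeps the first (smallest param) on ties
    return CVResult(
        algorithm=algorithm,
        table=table,
        best_param=table.loc[best_idx, "param"],
        best_auc=float(table.loc[best_idx, "ROC"]),
    )


def evaluate_test(model, X_test: pd.DataFrame, y_test: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Held-out AUC plus ROC curve points (FPR, TPR, threshold)."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(X_test)[:, 1]
    auc = auc_score(y_test, proba)  # raises on single-class input
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y_test, proba)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def f1_score_at(y_true: np.ndarray, proba: np.ndarray, threshold: float) -> float:
    """F1 of predicted-positive = (proba >= threshold); 0 when no positives predicted."""
    pred = np.asarray(proba) >= threshold
    y_true = np.asarray(y_true).astype(bool)
    tp = int(np.sum(pred & y_true))
    fp = int(np.sum(pred & ~y_true))
    fn = int(np.sum(~pred & y_true))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def select_threshold(
    model, X: pd.DataFrame, y: np.ndarray, grid: Sequence[float] | None = None
) -> tuple[float, float]:
    """Scan the threshold grid (default 0.00..1.00 step 0.01) for maximum F1.

    Returns (threshold, max_f1); ties resolve to the lowest threshold.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold calibration needs both classes")
    proba = model.predict_proba(X)[:, 1]
    if not np.any(proba >= min(grid)):
        raise ValueError("no grid threshold yields any predicted positive")
    best_t, best_f1 = None, -1.0
    for t in grid:
        f1 = f1_score_at(y, proba, float(t))
        if f1 > best_f1:  # strict: keeps the lowest threshold on ties
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


@dataclass
class TrainedModelBundle:
    """A fitted, calibrated direction-specific model plus its provenance."""

    direction: str
    algorithm: str
    model: object
    best_param: object
    feature_columns: list[str]
    threshold: float  # "suggestion rate"
    max_f1: float
    test_auc: float
    cv_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, out / "model.joblib")
        self.cv_table.to_csv(out / "cv_report.tsv", sep="\t", index=False)
        meta = {
            "direction": self.direction,
            "algorithm": self.algorithm,
            "best_param": self.best_param,
            "feature_columns": self.feature_columns,
            "threshold": self.threshold,
            "max_f1": self.max_f1,
            "test_auc": self.test_auc,
            "versions": {
                "smireg": __version__,
                "sklearn": sklearn.__version__,
                "python": platform.python_version(),
            },
            **self.metadata,
        }
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return out

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "TrainedModelBundle":
        d = Path(bundle_dir)
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
        known = {"direction", "algorithm", "best_param", "feature_columns", "threshold", "max_f1", "test_auc"}
        return cls(
            direction=meta["direction"],
            algorithm=meta["algorithm"],
            model=joblib.load(d / "model.joblib"),
            best_param=meta["best_param"],
            feature_columns=meta["feature_columns"],
            threshold=meta["threshold"],
            max_f1=meta["max_f1"],
            test_auc=meta["test_auc"],
            cv_table=pd.read_csv(d / "cv_report.tsv", sep="\t"),
            metadata={k: v for k, v in meta.items() if k not in known},
        )


def train_direction(
    ds: RegulationDataset,
    algorithms: Sequence[str] = ALGORITHMS,
    grids: dict[str, Sequence] | None = None,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> tuple[TrainedModelBundle, pd.DataFrame]:
    """Full training protocol for one direction.

    50/50 stratified split; per-algorithm 5-fold CV on the training half to
    tune the hyperparameter by mean AUC; refit at the tuned value on the full
    training half; evaluate on the held-out half; keep the algorithm with the
    highest test AUC and calibrate its F1-optimal threshold on the held-out
    half.  Returns (bundle, CV report table mirroring the per-algorithm
    Model/ROC/Sens/Spec/SD layout).
    """
    X, y, _keys = assemble_features(ds)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, fraction=test_fraction, seed=seed)

    report_rows = []
    fitted: dict[str, tuple[object, CVResult, float]] = {}
    for algo in algorithms:
        grid = None if grids is None else grids.get(algo)
        cv = cross_validate(X_tr, y_tr, algo, grid=grid, seed=seed)
        model = make_estimator(algo, cv.best_param, seed=seed)
        model.fit(X_tr, y_tr)
        test_auc, _curve = evaluate_test(model, X_te, y_te)
        fitted[algo] = (model, cv, test_auc)
        best = cv.table.loc[cv.table["param"] == cv.best_param].iloc[0]
        report_rows.append(
            {
                "Model": algo.upper(),
                "param": cv.best_param,
                "ROC": best["ROC"],
                "Sens": best["Sens"],
                "Spec": best["Spec"],
                "ROCSD": best["ROCSD"],
                "SensSD": best["SensSD"],
                "SpecSD": best["SpecSD"],
                "test_AUC": test_auc,
            }
        )
    report = pd.DataFrame(report_rows)

    best_algo = max(fitted, key=lambda a: fitted[a][2])
    model, cv, test_auc = fitted[best_algo]
    threshold, max_f1 = select_threshold(model, X_te, y_te)
    bundle = TrainedModelBundle(
        direction=ds.direction,
        algorithm=best_algo,
        model=model,
        best_param=cv.best_param,
        feature_columns=feature_names(),
        threshold=threshold,
        max_f1=max_f1,
        test_auc=test_auc,
        cv_table=cv.table,
        metadata={"seed": seed, "test_fraction": test_fraction, "n_pairs": len(ds.pairs)},
    )
    return bundle, report
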