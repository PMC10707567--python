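"""Cross-validation harness, evaluation metrics, and the ablation suite.

Per fold, every fitted component — standardiser, per-view SDA, recursive
feature elimination, and the attention + CNN head — sees training-fold rows
only; the held-out fold enters the pipeline solely through frozen transforms.
The :mod:`maacnn.leakage` guard instruments every fit call so a run can prove
this.  ASD is the positive class throughout.

Ten-fold scores are fold-averaged (mean of per-fold ACC/SEN/SPEC/AUC);
leave-one-out pools the confusion counts over all folds, since per-singleton
sensitivity/specificity are undefined.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .atlas import AtlasSpec, feature_count
from .attention import AttentionConfig
from .config import ModelConfig
from .leakage import guard
from .model import train_head
from .sda import Standardizer, default_sda_config, pretrain_sda, sda_transform

__all__ = [
    "ConfusionCounts", "EvalReport", "stratified_kfold", "metrics", "auc",
    "train_maacnn", "loocv", "rfe_baseline", "ablation_suite", "ABLATION_ARMS",
]

ABLATION_ARMS = ("cnn", "cnn+sda", "cnn+attention", "full")


class UndefinedMetricWarning(UserWarning):
    pass


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN with ASD (label 1) as the positive class."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, SEN, SPEC as fractions; undefined ratios become None + warning."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    out: dict[str, float | None] = {"ACC": (c.TP + c.TN) / c.total}
    if c.TP + c.FN > 0:
        out["SEN"] = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("no positive subjects: sensitivity undefined",
                      UndefinedMetricWarning, stacklevel=2)
        out["SEN"] = None
    if c.TN + c.FP > 0:
        out["SPEC"] = c.TN / (c.TN + c.FP)
    else:
        warnings.warn("no negative subjects: specificity undefined",
                      UndefinedMetricWarning, stacklevel=2)
        out["SPEC"] = None
    return out


def auc(labels, scores) -> float | None:
    """Area under the ROC curve of the positive-class scores (ties count 1/2)."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class input: AUC undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return None
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def stratified_kfold(labels, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint stratified test folds covering all subjects."""
    labels = np.asarray(labels, int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < k={k}; use a smaller k")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(labels), labels)]


def rfe_baseline(x: np.ndarray, y: np.ndarray, target_dim: int,
                 seed: int = 0, row_ids=None) -> np.ndarray:
    """Recursive feature elimination to ``target_dim`` features.

    Each round fits an L2-regularised logistic regression on the surviving
    features and drops the 10% (of those remaining) with the smallest
    coefficient magnitudes, never overshooting the target.  Returns the
    sorted selected column indices.
    """
    guard.check_fit(row_ids, what="rfe_baseline")
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    m = x.shape[1]
    if target_dim >= m:
        raise ValueError(f"target_dim {target_dim} must be < feature count {m}")
    if target_dim < 1:
        raise ValueError("target_dim must be >= 1")
    remaining = np.arange(m)
    while len(remaining) > target_dim:
        # default penalty is the L2 ridge; C=1.0
        est = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
        est.fit(x[:, remaining], y)
        importance = np.abs(est.coef_).ravel()
        n_drop = min(max(1, int(0.1 * len(remaining))), len(remaining) - target_dim)
        drop = np.argsort(importance, kind="stable")[:n_drop]
        remaining = np.delete(remaining, drop)
    return np.sort(remaining)


@dataclass
class EvalReport:
    """Per-fold and aggregate scores of one cross-validated run."""

    protocol: str
    seed: int
    config_digest: str
    aggregation: str  # "fold-mean" | "pooled"
    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)  # ACC/SEN/SPEC in percent, AUC fraction
    pooled: dict | None = None
    attention_weights: dict | None = None  # view -> mean weight over folds
    leakage: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=float, **kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def table(self) -> str:
        lines = [f"protocol: {self.protocol}   seed: {self.seed}   "
                 f"config: {self.config_digest}"]
        header = f"{'fold':>4} {'ACC%':>7} {'SEN%':>7} {'SPEC%':>7} {'AUC':>6}"
        lines.append(header)
        fmt = lambda v: "   n/a" if v is None else f"{v:6.2f}"
        for k, f in enumerate(self.folds):
            lines.append(f"{k:>4} {fmt(f['ACC'])} {fmt(f['SEN'])} "
                         f"{fmt(f['SPEC'])} {fmt(f['AUC'])}")
        m = self.mean
        lines.append(f"mean {fmt(m.get('ACC'))} {fmt(m.get('SEN'))} "
                     f"{fmt(m.get('SPEC'))} {fmt(m.get('AUC'))}")
        return "\n".join(lines)


def _as_array_views(views: dict) -> dict[str, np.ndarray]:
    out = {}
    index = None
    for name, v in views.items():
        if hasattr(v, "to_numpy"):
            if index is not None and not v.index.equals(index):
                bad = sorted(set(v.index).symmetric_difference(index))
                raise ValueError(f"subject misalignment across views: {bad[:10]}")
            index = v.index
            v = v.to_numpy()
        out[name] = np.asarray(v, float)
    sizes = {name: v.shape[0] for name, v in out.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"views disagree on subject count: {sizes}")
    return out


def _infer_atlas(name: str, n_features: int) -> AtlasSpec:
    """Recover the ROI count of a view from S = n(n-1)/2."""
    n = int(round((1 + np.sqrt(1 + 8 * n_features)) / 2))
    if feature_count(max(n, 2)) != n_features:
        raise ValueError(
            f"view {name!r} has {n_features} features, which is not n(n-1)/2 "
            "for any ROI count; FC feature tables are expected")
    return AtlasSpec(name, n)


def _encode_views_for_fold(views: dict[str, np.ndarray], y: np.ndarray,
                           train_idx: np.ndarray, cfg: ModelConfig,
                           rng: np.random.Generator, use_sda: bool,
                           rfe_seed: int) -> np.ndarray:
    """Fit per-view reducers on the training rows only; encode all subjects.

    Returns (n_views, N, F).  ``use_sda=False`` selects F features per view by
    RFE on the (train-standardised) raw features instead.
    """
    f_dim = cfg.sda.code_dim
    encoded = []
    for name, x in views.items():
        if use_sda:
            atlas = _infer_atlas(name, x.shape[1])
            configs = default_sda_config(
                atlas, code_dim=f_dim, learning_rate=cfg.sda.learning_rate,
                momentum=cfg.sda.momentum, epochs=cfg.sda.epochs,
                batch_size=cfg.sda.batch_size)
            model = pretrain_sda(x[train_idx], atlas, rng, configs=configs,
                                 row_ids=train_idx)
            encoded.append(sda_transform(model, x))
        else:
            scaler = Standardizer().fit(x[train_idx], row_ids=train_idx)
            xs = scaler.transform(x)
            sel = rfe_baseline(xs[train_idx], y[train_idx], f_dim,
                               seed=rfe_seed, row_ids=train_idx)
            encoded.append(xs[:, sel])
    return np.stack(encoded, axis=0)


def _run_protocol(views: dict[str, np.ndarray], y: np.ndarray, cfg: ModelConfig,
                  seed: int, test_folds: list[np.ndarray], protocol: str,
                  aggregation: str, use_sda: bool = True) -> EvalReport:
    view_names = list(views.keys())
    att_cfg = AttentionConfig(
        n_views=len(view_names), hidden_width=cfg.attention.hidden_width,
        global_weights=cfg.attention.global_weights,
        normalize=cfg.attention.normalize)
    guard.reset()
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(len(test_folds))
    report = EvalReport(protocol=protocol, seed=seed,
                        config_digest=cfg.digest(), aggregation=aggregation)
    pooled_counts = ConfusionCounts()
    pooled_scores, pooled_labels = [], []
    weight_sums = np.zeros(len(view_names))
    n_all = len(y)
    for fold_k, (test_idx, fseed) in enumerate(zip(test_folds, fold_seeds)):
        test_idx = np.asarray(test_idx)
        train_idx = np.setdiff1d(np.arange(n_all), test_idx)
        rng = np.random.default_rng(fseed)
        rfe_seed = int(fseed.generate_state(1)[0] % (2 ** 31))
        with guard.protect(test_idx):
            xp = _encode_views_for_fold(views, y, train_idx, cfg, rng,
                                        use_sda, rfe_seed)
            head = train_head(xp[:, train_idx], y[train_idx], att_cfg, cfg.cnn,
                              rng, row_ids=train_idx)
        proba = head.predict_proba(xp[:, test_idx])[:, 1]
        pred = (proba > cfg.threshold).astype(int)
        counts = ConfusionCounts.from_predictions(y[test_idx], pred)
        pooled_counts = pooled_counts + counts
        pooled_scores.append(proba)
        pooled_labels.append(y[test_idx])
        weight_sums += head.mean_view_weights(xp[:, test_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMetricWarning)
            m = metrics(counts)
            fold_auc = auc(y[test_idx], proba)
        report.folds.append({
            "test_indices": test_idx.tolist(),
            "counts": asdict(counts),
            "ACC": 100.0 * m["ACC"],
            "SEN": None if m["SEN"] is None else 100.0 * m["SEN"],
            "SPEC": None if m["SPEC"] is None else 100.0 * m["SPEC"],
            "AUC": fold_auc,
        })
    if aggregation == "fold-mean":
        for key in ("ACC", "SEN", "SPEC", "AUC"):
            vals = [f[key] for f in report.folds if f[key] is not None]
            report.mean[key] = float(np.mean(vals)) if vals else None
    else:  # pooled (LOOCV)
        m = metrics(pooled_counts)
        report.pooled = {"counts": asdict(pooled_counts)}
        report.mean = {
            "ACC": 100.0 * m["ACC"],
            "SEN": None if m["SEN"] is None else 100.0 * m["SEN"],
            "SPEC": None if m["SPEC"] is None else 100.0 * m["SPEC"],
            "AUC": auc(np.concatenate(pooled_labels), np.concatenate(pooled_scores)),
        }
    report.attention_weights = dict(
        zip(view_names, (weight_sums / len(test_folds)).tolist()))
    report.leakage = {"n_checks": guard.n_checks, "n_violations": guard.n_violations}
    return report


def train_maacnn(views: dict, labels, config: ModelConfig | None = None,
                 seed: int = 0, use_sda: bool = True) -> EvalReport:
    """Stratified k-fold cross-validated training and evaluation.

    ``views`` maps view names to subject x feature tables (DataFrames with a
    shared subject index, or aligned arrays).  Every fitted stage sees
    training-fold rows only.
    """
    cfg = config or ModelConfig()
    arr_views = _as_array_views(views)
    y = np.asarray(labels, int)
    split_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    test_folds = stratified_kfold(y, cfg.folds, split_seed)
    return _run_protocol(arr_views, y, cfg, seed, test_folds,
                         protocol=f"{cfg.folds}-fold stratified CV",
                         aggregation="fold-mean", use_sda=use_sda)


def loocv(views: dict, labels, config: ModelConfig | None = None,
          seed: int = 0, use_sda: bool = True) -> EvalReport:
    """Leave-one-out CV; metrics from confusion counts pooled over all folds."""
    cfg = config or ModelConfig()
    arr_views = _as_array_views(views)
    y = np.asarray(labels, int)
    if len(y) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    test_folds = [np.array([k]) for k in range(len(y))]
    return _run_protocol(arr_views, y, cfg, seed, test_folds,
                         protocol="LOOCV", aggregation="pooled", use_sda=use_sda)


def ablation_suite(views: dict, labels, config: ModelConfig | None = None,
                   seed: int = 0) -> list[dict]:
    """Four arms under identical folds and seeds:

    1. ``cnn`` — first view only, RFE-selected features, CNN alone;
    2. ``cnn+sda`` — first view only, SDA codes, CNN;
    3. ``cnn+attention`` — all views, RFE-selected features, attention fusion;
    4. ``full`` — all views, SDA codes, attention fusion.

    Returns one row per arm with mean ACC (percent), mean AUC and the shared
    fold digest.
    """
    cfg = config or ModelConfig()
    arr_views = _as_array_views(views)
    if len(arr_views) < 2:
        raise ValueError("ablation needs >= 2 views for the attention arms")
    y = np.asarray(labels, int)
    split_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    test_folds = stratified_kfold(y, cfg.folds, split_seed)
    fold_digest = hashlib.sha256(
        json.dumps([f.tolist() for f in test_folds]).encode()).hexdigest()[:16]
    first = {next(iter(arr_views)): arr_views[next(iter(arr_views))]}
    arms = {
        "cnn": (first, False),
        "cnn+sda": (first, True),
        "cnn+attention": (arr_views, False),
        "full": (arr_views, True),
    }
    rows = []
    for arm, (arm_views, use_sda) in arms.items():
        rep = _run_protocol(arm_views, y, cfg, seed, test_folds,
                            protocol=f"{cfg.folds}-fold stratified CV",
                            aggregation="fold-mean", use_sda=use_sda)
        rows.append({"arm": arm, "ACC": rep.mean["ACC"], "AUC": rep.mean["AUC"],
                     "fold_digest": fold_digest,
                     "leakage_violations": rep.leakage["n_violations"]})
    return rows
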