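"""Training loop, evaluation protocols, hyperparameter sweep and ablations.

Two evaluation protocols are provided: leave-one-subject-out (LOSO)
cross-validation, which measures cross-subject generalization by holding
out every subject once, and within-subject k-fold cross-validation (three
folds by default: two train, one test).  Performance is reported as
accuracy and macro-averaged F1 (both in percent); aggregate mean +/- SD
over LOSO folds excludes any subjects reserved for hyperparameter
validation.  Run comparisons use paired or Welch two-sample t-tests on
per-fold macro-F1.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy
import sklearn
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from . import __version__, nn
from .data import (LABELS, SignatureDataset, StratificationError,
                   split_by_subject, split_within_subject)
from .geometry import CuffLayout, ElectrodeGraph, GraphConfig, build_graph
from .model import (GraphCache, ModelConfig, calibrate_init, forward,
                    init_params, loss, predict)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "EvalReport",
    "TrainedModel",
    "ComparisonResult",
    "DegenerateComparisonError",
    "train_model",
    "evaluate",
    "run_loso",
    "run_within_subject",
    "sweep_graph_hparams",
    "run_ablations",
    "ablation_table",
    "compare_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults mirror the reference training setup (learning rate 1e-3,
    batch size 1024 capped at the training-set size, Gaussian-noise
    augmentation); early stopping monitors loss on a 10% stratified slice
    of the training data.  ``validation_subjects`` are excluded from LOSO
    aggregate means (they are still evaluated and reported per fold).
    """

    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 60
    patience: int = 8
    augment_fraction: float = 0.05
    seed: int = 0
    validation_subjects: tuple[str, ...] = ()

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.augment_fraction < 0:
            raise ValueError("augment_fraction must be non-negative")


@dataclass
class FoldResult:
    """Metrics for one held-out fold (all scores in percent)."""

    held_out: str
    accuracy: float
    macro_f1: float
    per_class: dict
    confusion: list
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalReport:
    """Per-fold results plus aggregate mean +/- SD over included folds."""

    folds: list
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float
    validation_subjects: tuple = ()
    protocol: str = "loso"
    provenance: dict = field(default_factory=dict)

    def fold_f1(self, include_validation: bool = False) -> dict[str, float]:
        return {f.held_out: f.macro_f1 for f in self.folds
                if include_validation or f.held_out not in self.validation_subjects}

    def to_json(self, path) -> None:
        payload = {
            "protocol": self.protocol,
            "folds": [f.to_dict() for f in self.folds],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_macro_f1": self.mean_macro_f1,
            "sd_macro_f1": self.sd_macro_f1,
            "validation_subjects": list(self.validation_subjects),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(folds=[FoldResult(**f) for f in d["folds"]],
                   mean_accuracy=d["mean_accuracy"], sd_accuracy=d["sd_accuracy"],
                   mean_macro_f1=d["mean_macro_f1"], sd_macro_f1=d["sd_macro_f1"],
                   validation_subjects=tuple(d.get("validation_subjects", ())),
                   protocol=d.get("protocol", "loso"),
                   provenance=d.get("provenance", {}))

    def to_table(self) -> pd.DataFrame:
        """One row per fold, accuracy/macro-F1 columns, mean +/- SD footer."""
        rows = [{"subject": f.held_out, "accuracy": f.accuracy,
                 "macro_f1": f.macro_f1} for f in self.folds]
        rows.append({"subject": "mean±sd",
                     "accuracy": f"{self.mean_accuracy:.2f} ± {self.sd_accuracy:.2f}",
                     "macro_f1": f"{self.mean_macro_f1:.2f} ± {self.sd_macro_f1:.2f}"})
        return pd.DataFrame(rows)


@dataclass
class TrainedModel:
    """Trained parameters with everything needed to evaluate them."""

    params: dict
    model_config: ModelConfig
    graph: ElectrodeGraph
    cache: GraphCache
    channel_mean: np.ndarray
    channel_std: np.ndarray
    history: list

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.channel_mean[None, :, None])
                / self.channel_std[None, :, None]).astype(np.float32)


class DegenerateComparisonError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


def _provenance(seed: int, **configs) -> dict:
    cfg = {k: asdict(v) if hasattr(v, "__dataclass_fields__") else v
           for k, v in configs.items()}
    blob = json.dumps(cfg, sort_keys=True, default=list)
    return {
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {"cuffgraph": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "sklearn": sklearn.__version__},
    }


def _stratified_holdout(labels: np.ndarray, subjects: np.ndarray,
                        fraction: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split indices for early stopping, stratifying on (subject, label)
    where possible, falling back to label-only or plain random."""
    idx = np.arange(len(labels))
    seed = int(rng.integers(2 ** 31))
    combo = np.char.add(subjects.astype(str), labels.astype(str))
    for strat in (combo, labels, None):
        try:
            tr, va = train_test_split(idx, test_size=fraction, random_state=seed,
                                      stratify=strat)
            return tr, va
        except ValueError:
            continue
    raise AssertionError("unreachable")


def train_model(train: SignatureDataset, mcfg: ModelConfig, gcfg: GraphConfig,
                tcfg: TrainConfig, graph: ElectrodeGraph | None = None
                ) -> TrainedModel:
    """Train the classifier on one training set.

    Minimizes cross-entropy plus the L2 penalty with Adam; Gaussian-noise
    augmentation is applied to training batches only; early stopping
    monitors loss on a 10% stratified slice of the training data and the
    best checkpoint is restored.  Channel-wise z-scoring statistics are
    computed on the training portion only.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    labels = train.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if graph is None:
        graph = build_graph(train.layout, gcfg)
    cache = GraphCache(graph)

    ss = np.random.SeedSequence(tcfg.seed)
    rng_init, rng_split, rng_batch, rng_aug, rng_drop = \
        (np.random.default_rng(s) for s in ss.spawn(5))

    x_all = train.values.astype(np.float32)
    mean = x_all.mean(axis=(0, 2))
    std = np.maximum(x_all.std(axis=(0, 2)), 1e-8)
    x_all = (x_all - mean[None, :, None]) / std[None, :, None]

    tr_idx, va_idx = _stratified_holdout(labels, train.subjects, 0.1, rng_split)
    x_tr, y_tr = x_all[tr_idx], labels[tr_idx]
    x_va, y_va = x_all[va_idx], labels[va_idx]

    params = init_params(mcfg, rng_init)
    calibrate_init(params, mcfg, cache, x_tr[:min(len(x_tr), 256)])
    opt = nn.Adam(params, lr=tcfg.learning_rate)
    batch = min(tcfg.batch_size, len(x_tr))

    best_loss = np.inf
    best_params = {k: p.data.copy() for k, p in params.items()}
    wait = 0
    history: list[dict] = []
    for epoch in range(tcfg.max_epochs):
        order = rng_batch.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), batch):
            sel = order[start:start + batch]
            xb = x_tr[sel]
            if tcfg.augment_fraction > 0:
                rms = np.sqrt(np.mean(xb.astype(np.float64) ** 2,
                                      axis=(1, 2), keepdims=True))
                xb = xb + (tcfg.augment_fraction * rms
                           * rng_aug.standard_normal(xb.shape)).astype(xb.dtype)
            opt.zero_grad()
            logits = forward(params, xb, cache, mcfg, rng=rng_drop, training=True)
            obj = loss(logits, y_tr[sel], mcfg, params)
            obj.backward()
            opt.step()
            epoch_loss += float(obj.data) * len(sel)
        epoch_loss /= len(x_tr)

        va_logits = forward(params, x_va, cache, mcfg, training=False)
        va_loss = float(nn.softmax_cross_entropy(va_logits, y_va).data)
        va_acc = float((va_logits.data.argmax(axis=1) == y_va).mean())
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_loss": va_loss, "val_accuracy": va_acc})
        logger.info("epoch %d train_loss=%.4f val_loss=%.4f val_acc=%.3f",
                    epoch, epoch_loss, va_loss, va_acc)
        if va_loss < best_loss - 1e-6:
            best_loss = va_loss
            best_params = {k: p.data.copy() for k, p in params.items()}
            wait = 0
        else:
            wait += 1
            if wait > tcfg.patience:
                break
    for k, p in params.items():
        p.data = best_params[k]
    return TrainedModel(params=params, model_config=mcfg, graph=graph,
                        cache=cache, channel_mean=mean, channel_std=std,
                        history=history)


def evaluate(model: TrainedModel, test: SignatureDataset,
             held_out: str = "") -> FoldResult:
    """Confusion matrix, accuracy and macro-F1 on a test set.

    Macro-F1 is the unweighted mean of per-class F1; a class absent from
    both truth and prediction contributes F1 = 0.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    x = model.normalize(test.values)
    y_true = test.labels
    y_pred = predict(model.params, x, model.cache, model.model_config)
    return _fold_result(y_true, y_pred, held_out or ",".join(test.subject_ids))


def _fold_result(y_true: np.ndarray, y_pred: np.ndarray, held_out: str) -> FoldResult:
    classes = list(range(len(LABELS)))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = 100.0 * np.trace(cm) / cm.sum()
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    per_class = {LABELS[c]: {"precision": float(prec[c]), "recall": float(rec[c]),
                             "f1": float(f1[c])} for c in classes}
    return FoldResult(held_out=held_out, accuracy=float(acc),
                      macro_f1=float(100.0 * f1.mean()), per_class=per_class,
                      confusion=cm.tolist(), n_test=int(cm.sum()))


def _aggregate(folds: list[FoldResult], excluded: tuple[str, ...],
               protocol: str, provenance: dict) -> EvalReport:
    included = [f for f in folds if f.held_out not in excluded]
    if not included:
        raise ValueError("no folds left after excluding validation subjects")
    acc = np.array([f.accuracy for f in included])
    f1 = np.array([f.macro_f1 for f in included])
    return EvalReport(folds=folds,
                      mean_accuracy=float(acc.mean()),
                      sd_accuracy=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
                      mean_macro_f1=float(f1.mean()),
                      sd_macro_f1=float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
                      validation_subjects=tuple(excluded), protocol=protocol,
                      provenance=provenance)


def run_loso(ds: SignatureDataset, mcfg: ModelConfig, gcfg: GraphConfig,
             tcfg: TrainConfig) -> EvalReport:
    """Leave-one-subject-out cross-validation: one fold per subject."""
    subjects = ds.subject_ids
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    graph = build_graph(ds.layout, gcfg)
    folds = []
    for held in subjects:
        train_ds, test_ds = split_by_subject(ds, held)
        model = train_model(train_ds, mcfg, gcfg, tcfg, graph=graph)
        folds.append(evaluate(model, test_ds, held_out=held))
        logger.info("LOSO fold %s: acc=%.2f%% macroF1=%.2f%%",
                    held, folds[-1].accuracy, folds[-1].macro_f1)
    return _aggregate(folds, tcfg.validation_subjects, "loso",
                      _provenance(tcfg.seed, model=mcfg, graph=gcfg, train=tcfg))


def run_within_subject(ds: SignatureDataset, mcfg: ModelConfig,
                       gcfg: GraphConfig, tcfg: TrainConfig,
                       n_folds: int = 3) -> EvalReport:
    """Within-subject cross-validation (train on n_folds-1 folds, test on 1).

    Per-subject metrics are the unweighted mean over folds; the aggregate
    includes every subject.  Subjects whose class counts cannot be
    stratified into ``n_folds`` folds are skipped with a warning.
    """
    graph = build_graph(ds.layout, gcfg)
    subject_folds = []
    for subject in ds.subject_ids:
        try:
            results = []
            for fold in range(n_folds):
                tr, te = split_within_subject(ds, subject, n_folds, fold, tcfg.seed)
                model = train_model(tr, mcfg, gcfg, tcfg, graph=graph)
                results.append(evaluate(model, te, held_out=f"{subject}/fold{fold}"))
        except StratificationError as err:
            logger.warning("skipping subject %s: %s", subject, err)
            continue
        cm = np.sum([np.asarray(r.confusion) for r in results], axis=0)
        subject_folds.append(FoldResult(
            held_out=subject,
            accuracy=float(np.mean([r.accuracy for r in results])),
            macro_f1=float(np.mean([r.macro_f1 for r in results])),
            per_class={}, confusion=cm.tolist(), n_test=int(cm.sum())))
    return _aggregate(subject_folds, (), "within_subject",
                      _provenance(tcfg.seed, model=mcfg, graph=gcfg, train=tcfg,
                                  n_folds=n_folds))


def sweep_graph_hparams(ds: SignatureDataset, mcfg: ModelConfig,
                        tcfg: TrainConfig, k_grid, sigma_grid,
                        metric: str = "geodesic"
                        ) -> tuple[pd.DataFrame, tuple[int, float]]:
    """LOSO mean macro-F1 over a (k, sigma) grid.

    Returns (grid, argmax) where the grid DataFrame has sigma rows and k
    columns, and argmax is the best (k, sigma) cell.
    """
    if not len(list(k_grid)) or not len(list(sigma_grid)):
        raise ValueError("grids must be non-empty")
    table = pd.DataFrame(index=[float(s) for s in sigma_grid],
                         columns=[int(k) for k in k_grid], dtype=float)
    table.index.name = "sigma"
    table.columns.name = "k"
    best = (None, -np.inf)
    for sigma in sigma_grid:
        for k in k_grid:
            gcfg = GraphConfig(metric=metric, k=int(k), sigma=float(sigma))
            report = run_loso(ds, mcfg, gcfg, tcfg)
            table.loc[float(sigma), int(k)] = report.mean_macro_f1
            if report.mean_macro_f1 > best[1]:
                best = ((int(k), float(sigma)), report.mean_macro_f1)
            logger.info("sweep k=%d sigma=%g -> macroF1=%.2f%%",
                        k, sigma, report.mean_macro_f1)
    return table, best[0]


ABLATION_VARIANTS = ("geodesic", "cnn1d", "euclidean", "random")


def run_ablations(ds: SignatureDataset, mcfg: ModelConfig, gcfg: GraphConfig,
                  tcfg: TrainConfig,
                  variants: tuple[str, ...] = ABLATION_VARIANTS
                  ) -> dict[str, EvalReport]:
    """Matched LOSO runs differing in exactly one factor each.

    "geodesic" is the reference; "cnn1d" swaps the temporal encoder;
    "euclidean" and "random" swap the graph topology.  All runs share the
    same training seed and settings.
    """
    from dataclasses import replace
    reports = {}
    for variant in variants:
        if variant == "cnn1d":
            m, g = replace(mcfg, encoder="cnn1d"), gcfg
        elif variant in ("euclidean", "random"):
            m, g = mcfg, replace(gcfg, metric=variant)
        elif variant == "geodesic":
            m, g = mcfg, replace(gcfg, metric="geodesic")
        else:
            raise ValueError(f"unknown ablation variant {variant!r}")
        reports[variant] = run_loso(ds, m, g, tcfg)
    return reports


def ablation_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Comparison table: one row per variant, one column per subject plus
    the aggregate mean +/- SD of macro-F1."""
    rows = []
    for name, rep in reports.items():
        row = {"variant": name}
        for f in rep.folds:
            row[f.held_out] = f.macro_f1
        row["mean_macro_f1"] = rep.mean_macro_f1
        row["sd_macro_f1"] = rep.sd_macro_f1
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    test_type: str
    statistic: float
    pvalue: float
    df: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def __str__(self) -> str:
        return (f"{self.test_type}: t={self.statistic:.4f}, df={self.df:g}, "
                f"p={self.pvalue:.4g} (two-sided; significance threshold "
                f"alpha={self.alpha})")


def compare_runs(a: EvalReport, b: EvalReport, paired: bool = True
                 ) -> ComparisonResult:
    """Compare two runs on per-fold macro-F1.

    Paired: Student's paired t-test on per-subject differences (folds are
    aligned by held-out id).  Unpaired: Welch's two-sample t-test.  Folds
    of validation subjects are excluded, matching the aggregate means.
    """
    fa, fb = a.fold_f1(), b.fold_f1()
    if paired:
        common = sorted(set(fa) & set(fb))
        if len(common) < 2:
            raise ValueError("paired comparison needs >= 2 aligned folds")
        xs = np.array([fa[s] for s in common])
        ys = np.array([fb[s] for s in common])
        if np.allclose(xs - ys, (xs - ys)[0]) and np.std(xs - ys) == 0:
            raise DegenerateComparisonError(
                "paired differences have zero variance; t statistic undefined")
        t, p = stats.ttest_rel(xs, ys)
        return ComparisonResult("paired t-test", float(t), float(p),
                                df=float(len(common) - 1))
    xs = np.array(list(fa.values()))
    ys = np.array(list(fb.values()))
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("unpaired comparison needs >= 2 folds per run")
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return ComparisonResult("Welch t-test", float(res.statistic),
                            float(res.pvalue), df=float(res.df))
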