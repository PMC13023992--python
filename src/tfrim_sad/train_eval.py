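"""Training and evaluation: leakage-safe z-scoring, multi-label BCE, k-fold
cross-validation, and the clinical metric suite with voting-based fusion.

Normalisation statistics are computed per input channel on the training
portion of each fold only and frozen before they touch held-out subjects.
Training minimises the mean binary cross-entropy between the three sigmoid
outputs and the soft labels, with Adam at 1e-4, cosine-annealed, and early
stopping on a validation split carved out of the training portion (held-out
test folds are never used for stopping).  Main-task metrics compare the
majority vote of the three binarised heads against the subject-level hard
label; subtask metrics use per-index hard abnormality (v_k < v_th).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import labels as _labels
from .labels import LabelConfig
from .network import DualStreamNet, NetworkConfig
from .nn import Adam, CosineAnnealingLR, Tensor, no_grad
from .simulate import IOSRecording, SubjectRecord
from .tfrim import TFRIMConfig, build_tfrim

__all__ = [
    "NormalizationStats", "FoldSplit", "TrainConfig", "MetricsReport",
    "zscore_fit", "zscore_apply", "bce_loss", "kfold_split", "train_fold",
    "evaluate", "run_cv", "cohort_to_arrays", "binary_metrics",
    "DualStreamSADClassifier",
]

SIGMA_FLOOR = 1e-8
EPS_CLIP = 1e-7
INPUT_KEYS = ("tfrim", "wave", "demo")


# --------------------------------------------------------------------------
# data packing

def cohort_to_arrays(records: list[SubjectRecord], recordings: list[IOSRecording],
                     tfrim_config: TFRIMConfig = TFRIMConfig(),
                     label_config: LabelConfig = LabelConfig()) -> dict:
    """Assemble the model-ready arrays for a cohort.

    Returns a dict with inputs ``tfrim`` (n,2,H,W), ``wave`` (n,2,9120),
    ``demo`` (n,4: age, sex, height, weight), targets ``y_soft`` (n,3),
    ``y_hard`` (n,), ``v`` (n,3) and ``subject_ids``.
    """
    tfrims, waves, demo, y_soft, y_hard, v = [], [], [], [], [], []
    for rec, wave in zip(records, recordings):
        tfrims.append(build_tfrim(wave, tfrim_config).values)
        waves.append(np.stack([wave.pressure[: tfrim_config.crop_samples],
                               wave.flow[: tfrim_config.crop_samples]]))
        demo.append([rec.age, float(rec.sex), rec.height, rec.weight])
        y_soft.append(_labels.soft_labels(rec.v1, rec.v2, rec.v3, label_config))
        y_hard.append(_labels.hard_label(rec.v1, rec.v2, rec.v3, label_config))
        v.append([rec.v1, rec.v2, rec.v3])
    return {
        "tfrim": np.stack(tfrims), "wave": np.stack(waves),
        "demo": np.asarray(demo, dtype=float),
        "y_soft": np.stack(y_soft), "y_hard": np.asarray(y_hard, dtype=int),
        "v": np.asarray(v, dtype=float),
        "subject_ids": [r.subject_id for r in records],
    }


def _subset(data: dict, idx: np.ndarray) -> dict:
    out = {}
    for k, val in data.items():
        if k == "subject_ids":
            out[k] = [val[i] for i in idx]
        else:
            out[k] = val[idx]
    return out


# --------------------------------------------------------------------------
# normalisation

@dataclass
class NormalizationStats:
    """Frozen per-channel mean/sd, fitted on training subjects only."""

    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]


def _channel_axes(key: str, arr: np.ndarray) -> tuple[int, ...]:
    # stats per channel: tfrim (n,2,H,W) -> axes (0,2,3); wave (n,2,L) ->
    # (0,2); demo (n,4) -> (0,)
    return tuple(i for i in range(arr.ndim) if i != 1) if arr.ndim > 2 else (0,)


def zscore_fit(train_data: dict, keys: tuple[str, ...] = INPUT_KEYS) -> NormalizationStats:
    mu, sigma = {}, {}
    for key in keys:
        arr = np.asarray(train_data[key], dtype=float)
        if arr.shape[0] == 0:
            raise ValueError("cannot fit normalisation on an empty training portion")
        axes = _channel_axes(key, arr)
        mu[key] = arr.mean(axis=axes)
        sd = arr.std(axis=axes)
        if np.any(sd < SIGMA_FLOOR):
            warnings.warn(f"constant channel in {key!r}; sigma floored at {SIGMA_FLOOR}")
            sd = np.maximum(sd, SIGMA_FLOOR)
        sigma[key] = sd
    return NormalizationStats(mu=mu, sigma=sigma)


def zscore_apply(stats: NormalizationStats, data: dict) -> dict:
    out = dict(data)
    for key, mu in stats.mu.items():
        arr = np.asarray(data[key], dtype=float)
        shape = [1] * arr.ndim
        shape[1 if arr.ndim > 2 else arr.ndim - 1] = -1
        out[key] = (arr - mu.reshape(shape)) / stats.sigma[key].reshape(shape)
    return out


# --------------------------------------------------------------------------
# loss

def bce_loss(y_pred: Tensor | np.ndarray, y_soft: np.ndarray) -> Tensor:
    """Mean over the three sub-labels and the batch of the binary
    cross-entropy against soft targets; predictions clipped to
    [1e-7, 1-1e-7]."""
    if not isinstance(y_pred, Tensor):
        y_pred = Tensor(np.asarray(y_pred, dtype=float))
    y_soft = np.asarray(y_soft, dtype=float)
    if y_pred.shape != y_soft.shape:
        raise ValueError(f"prediction shape {y_pred.shape} != target {y_soft.shape}")
    p = y_pred.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    t = Tensor(y_soft)
    ll = t * p.log() + (1.0 - t) * (1.0 - p).log()
    return -ll.mean()


# --------------------------------------------------------------------------
# folds

@dataclass
class FoldSplit:
    assignments: np.ndarray  # fold index 0..k-1 per subject
    k: int
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments != fold)[0]


def kfold_split(n_subjects: int, k: int = 5, seed: int = 0,
                stratify_by: np.ndarray | None = None) -> FoldSplit:
    """Random (optionally stratified) mutually exclusive folds; sizes differ
    by at most one per stratum.  Falls back to unstratified with a warning
    when a stratum has fewer members than folds."""
    if n_subjects < k:
        raise ValueError(f"need at least k={k} subjects, got {n_subjects}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n_subjects, dtype=int)
    stratified = stratify_by is not None
    if stratified:
        stratify_by = np.asarray(stratify_by)
        _, counts = np.unique(stratify_by, return_counts=True)
        if counts.min() < k:
            warnings.warn("stratum smaller than k; falling back to unstratified split")
            stratified = False
    if stratified:
        for value in np.unique(stratify_by):
            idx = np.nonzero(stratify_by == value)[0]
            idx = rng.permutation(idx)
            assignments[idx] = np.arange(idx.size) % k
    else:
        idx = rng.permutation(n_subjects)
        assignments[idx] = np.arange(n_subjects) % k
    return FoldSplit(assignments=assignments, k=k, seed=seed, stratified=stratified)


# --------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0


def _forward_batch(model: DualStreamNet, data: dict, idx: np.ndarray) -> Tensor:
    cfg = model.cfg
    return model(
        tfrim=data["tfrim"][idx] if cfg.use_tfrim else None,
        wave=data["wave"][idx] if cfg.use_time else None,
        demo=data["demo"][idx] if cfg.use_demo else None,
    )


def predict_probabilities(model: DualStreamNet, data: dict,
                          batch_size: int = 64) -> np.ndarray:
    model.eval()
    n = next(np.asarray(data[k]).shape[0] for k in INPUT_KEYS if k in data)
    out = []
    with no_grad():
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            out.append(_forward_batch(model, data, idx).data)
    return np.concatenate(out, axis=0)


def train_fold(net_config: NetworkConfig, train_data: dict, val_data: dict,
               train_config: TrainConfig = TrainConfig()) -> tuple[dict, list[dict]]:
    """Train one model with Adam + cosine annealing and early stopping on the
    validation loss; returns (checkpoint, history).

    The checkpoint holds the best-validation weights, the configs and nothing
    else; normalisation stats are managed by the caller so they can be frozen
    on the right subjects.
    """
    n_train = train_data["y_soft"].shape[0]
    batch = train_config.batch_size
    if batch > n_train:
        warnings.warn(f"batch size reduced from {batch} to cohort size {n_train}")
        batch = n_train
    model = DualStreamNet(net_config, seed=train_config.seed)
    opt = Adam(model.parameters(), lr=train_config.lr)
    sched = CosineAnnealingLR(opt, t_max=train_config.max_epochs)
    rng = np.random.default_rng(np.random.SeedSequence((train_config.seed, 77)))

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    history: list[dict] = []
    since_best = 0
    for epoch in range(train_config.max_epochs):
        model.train()
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, batch):
            idx = order[start: start + batch]
            model.zero_grad()
            probs = _forward_batch(model, train_data, idx)
            loss = bce_loss(probs, train_data["y_soft"][idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss {loss.data}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_probs = predict_probabilities(model, val_data)
        val_loss = float(bce_loss(val_probs, val_data["y_soft"]).data)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "lr": opt.lr})
        sched.step()
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break
    model.load_state_dict(best_state)
    checkpoint = {"state": best_state, "net_config": net_config,
                  "train_config": train_config, "best_epoch": best_epoch,
                  "best_val_loss": best_val}
    return checkpoint, history


# --------------------------------------------------------------------------
# metrics

def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Confusion-matrix metrics with positive class = 1; metrics whose
    denominator is empty come back as NaN rather than failing."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    def ratio(num, den):
        return num / den if den > 0 else float("nan")
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    return {"accuracy": ratio(tp + tn, tp + tn + fp + fn), "sensitivity": sens,
            "specificity": spec, "precision": prec, "f1": f1,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


@dataclass
class MetricsReport:
    main: dict
    subtasks: list[dict] = field(default_factory=list)


def evaluate(probabilities: np.ndarray, data: dict,
             cfg: LabelConfig = LabelConfig()) -> MetricsReport:
    """Voted main-task metrics against the hard SAD label plus per-subtask
    metrics against per-index hard abnormality (v_k < v_th)."""
    probs = np.asarray(probabilities, dtype=float)
    y_hard = np.asarray(data["y_hard"], dtype=int)
    if probs.shape[0] != y_hard.shape[0] or probs.shape[1] != 3:
        raise ValueError("probabilities and labels misaligned")
    votes = (probs >= cfg.tau).astype(int)
    decision = (votes.sum(axis=1) >= 2).astype(int)
    subtask_truth = (np.asarray(data["v"], dtype=float) < cfg.vth).astype(int)
    subtasks = [binary_metrics(subtask_truth[:, k], votes[:, k]) for k in range(3)]
    return MetricsReport(main=binary_metrics(y_hard, decision), subtasks=subtasks)


def _average_reports(reports: list[MetricsReport]) -> MetricsReport:
    def avg(dicts: list[dict]) -> dict:
        keys = ("accuracy", "sensitivity", "specificity", "precision", "f1")
        return {k: float(np.nanmean([d[k] for d in dicts])) for k in keys}
    return MetricsReport(
        main=avg([r.main for r in reports]),
        subtasks=[avg([r.subtasks[k] for r in reports]) for k in range(3)],
    )


def run_cv(data: dict, net_config: NetworkConfig = NetworkConfig(),
           train_config: TrainConfig = TrainConfig(), k: int = 5,
           seed: int = 0, label_config: LabelConfig = LabelConfig()
           ) -> tuple[MetricsReport, list[MetricsReport], list[dict]]:
    """Stratified k-fold cross-validation with fold-local normalisation.

    Returns (averaged report, per-fold reports, per-fold checkpoints).
    """
    n = data["y_hard"].shape[0]
    split = kfold_split(n, k=k, seed=seed, stratify_by=data["y_hard"])
    fold_reports: list[MetricsReport] = []
    checkpoints: list[dict] = []
    for fold in range(k):
        tr_idx = split.train_indices(fold)
        te_idx = split.test_indices(fold)
        stats = zscore_fit(_subset(data, tr_idx))
        train_all = zscore_apply(stats, _subset(data, tr_idx))
        test = zscore_apply(stats, _subset(data, te_idx))
        # validation split for early stopping, carved out of the training
        # portion (test folds never steer stopping)
        k_inner = min(max(int(round(1.0 / train_config.val_fraction)), 2),
                      tr_idx.size)
        inner = kfold_split(tr_idx.size, k=k_inner, seed=seed + 1000 + fold,
                            stratify_by=train_all["y_hard"])
        val_idx = inner.test_indices(0)
        fit_idx = inner.train_indices(0)
        ckpt, history = train_fold(net_config, _subset(train_all, fit_idx),
                                   _subset(train_all, val_idx), train_config)
        model = DualStreamNet(net_config, seed=train_config.seed)
        model.load_state_dict(ckpt["state"])
        probs = predict_probabilities(model, test)
        report = evaluate(probs, test, label_config)
        ckpt["stats"] = stats
        ckpt["fold"] = fold
        ckpt["history"] = history
        fold_reports.append(report)
        checkpoints.append(ckpt)
    return _average_reports(fold_reports), fold_reports, checkpoints


# --------------------------------------------------------------------------
# sklearn-style estimator

class DualStreamSADClassifier:
    """scikit-learn style interface over the dual-stream network.

    ``X`` is a dict with keys ``tfrim`` (n,2,H,W), ``wave`` (n,2,L) and
    ``demo`` (n,4) (only the branches enabled by ``network`` are required);
    ``y`` is the (n,3) soft-label matrix.  ``predict`` returns the voted SAD
    decision; ``predict_proba`` the three subtask probabilities.
    """

    def __init__(self, network: NetworkConfig = NetworkConfig(),
                 lr: float = 1e-4, batch_size: int = 256, max_epochs: int = 200,
                 patience: int = 10, val_fraction: float = 0.1,
                 random_state: int = 0, label_config: LabelConfig = LabelConfig()):
        self.network = network
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.label_config = label_config

    _param_names = ("network", "lr", "batch_size", "max_epochs", "patience",
                    "val_fraction", "random_state", "label_config")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           val_fraction=self.val_fraction, seed=self.random_state)

    def fit(self, X: dict, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        data = {k: np.asarray(v) for k, v in X.items() if k in INPUT_KEYS}
        data["y_soft"] = y
        data["y_hard"] = (np.sum(y >= 0.5, axis=1) >= 2).astype(int)
        keys = tuple(k for k in INPUT_KEYS if k in data)
        self.norm_stats_ = zscore_fit(data, keys=keys)
        normed = zscore_apply(self.norm_stats_, data)
        n = y.shape[0]
        k_inner = min(max(int(round(1.0 / self.val_fraction)), 2), n)
        inner = kfold_split(n, k=k_inner, seed=self.random_state,
                            stratify_by=data["y_hard"])
        val_idx = inner.test_indices(0)
        fit_idx = inner.train_indices(0)
        ckpt, history = train_fold(self.network, _subset(normed, fit_idx),
                                   _subset(normed, val_idx), self._train_config())
        self.model_ = DualStreamNet(self.network, seed=self.random_state)
        self.model_.load_state_dict(ckpt["state"])
        self.history_ = history
        self.n_features_in_ = n
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted; call fit first")

    def predict_proba(self, X: dict) -> np.ndarray:
        self._check_fitted()
        data = {k: np.asarray(v) for k, v in X.items() if k in INPUT_KEYS}
        normed = zscore_apply(self.norm_stats_, data)
        return predict_probabilities(self.model_, normed)

    def predict(self, X: dict) -> np.ndarray:
        probs = self.predict_proba(X)
        votes = (probs >= self.label_config.tau).astype(int)
        return (votes.sum(axis=1) >= 2).astype(int)

    def score(self, X: dict, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        y_hard = (np.sum(y >= 0.5, axis=1) >= 2).astype(int)
        return float(np.mean(self.predict(X) == y_hard))
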