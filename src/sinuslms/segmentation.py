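"""Training and applying the 2D U-Net sinus segmenter.

:class:`UNetSegmenter` is a scikit-learn style estimator: ``fit`` trains
on a stack of coronal slices with paired label maps, ``predict`` returns
per-pixel label maps.  Training minimizes a combined soft-Dice +
cross-entropy loss with Adam (learning rate 0.01, betas 0.9/0.999),
batch size 16, up to 100 epochs with early stopping on validation loss.
No augmentation is applied.  All randomness (weight init, shuffling,
dropout) flows from a single seed, so runs are reproducible on one
device.

Subject-level fivefold cross-validation lives in :func:`crossvalidate`:
folds partition subjects (never slices), so no subject leaks between
training and validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .errors import ConfigurationError, ShapeMismatchError
from .imaging import ImageVolume, LabelVolume
from .metrics import dice, dice_table
from .nn import Adam, UNet2D, dice_ce_loss
from .nn.unet import NetConfig, default_net_config, small_canvas_net_config
from .regions import Region

__all__ = [
    "NetConfig",
    "TrainConfig",
    "SliceDataset",
    "UNetSegmenter",
    "default_net_config",
    "small_canvas_net_config",
    "make_folds",
    "crossvalidate",
    "segment_volume",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for the segmenter."""

    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 100
    early_stopping_patience: int = 10
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    n_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class SliceDataset:
    """Coronal slices with labels and the subject each slice came from."""

    images: np.ndarray  # (n, rows, cols) float
    labels: np.ndarray  # (n, rows, cols) int
    subjects: np.ndarray  # (n,) subject identifiers

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.images.shape != self.labels.shape:
            raise ShapeMismatchError("images and labels differ in shape")
        if len(self.subjects) != len(self.images):
            raise ShapeMismatchError("one subject id per slice required")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray) -> "SliceDataset":
        return SliceDataset(self.images[mask], self.labels[mask], self.subjects[mask])

    @classmethod
    def from_phantoms(cls, volumes, normalize: bool = True) -> "SliceDataset":
        """Stack phantom volumes slice-wise; z-scores each volume by default."""
        imgs, labs, subj = [], [], []
        for pv in volumes:
            data = pv.image.data
            if normalize:
                data = (data - data.mean()) / data.std()
            imgs.append(data)
            labs.append(pv.labels.data)
            subj += [pv.name] * data.shape[0]
        return cls(np.concatenate(imgs), np.concatenate(labs), np.array(subj))


class UNetSegmenter(BaseEstimator):
    """2D U-Net multi-class sinus segmenter with an sklearn estimator API.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`; pass a
    ``net_config`` to override the architecture wholesale (e.g. the
    small-canvas configuration for CPU runs).

    Fitted attributes
    -----------------
    net_ : the trained :class:`~sinuslms.nn.UNet2D`
    loss_history_ : per-epoch mean training loss
    val_loss_history_ : per-epoch validation loss (empty without val data)
    epochs_run_ : number of epochs actually executed
    """

    def __init__(
        self,
        net_config: NetConfig | None = None,
        learning_rate: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        batch_size: int = 16,
        max_epochs: int = 100,
        early_stopping_patience: int = 10,
        dice_weight: float = 1.0,
        ce_weight: float = 1.0,
        seed: int = 0,
    ):
        self.net_config = net_config
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.dice_weight = dice_weight
        self.ce_weight = ce_weight
        self.seed = seed

    # ------------------------------------------------------------------
    def _resolved_config(self, X: np.ndarray) -> NetConfig:
        if self.net_config is not None:
            return self.net_config
        return NetConfig(in_rows=X.shape[-2], in_cols=X.shape[-1])

    def _epoch_loss(self, net, X, y, train, opt=None, rng=None):
        order = np.arange(len(X))
        if train:
            rng.shuffle(order)
        losses = []
        for start in range(0, len(order), self.batch_size):
            idx = order[start : start + self.batch_size]
            xb = X[idx][:, None]
            yb = y[idx]
            logits = net.forward(xb, train=train)
            loss, dlogits = dice_ce_loss(
                logits, yb, dice_weight=self.dice_weight, ce_weight=self.ce_weight
            )
            losses.append(loss * len(idx))
            if train:
                opt.zero_grad()
                net.backward(dlogits)
                opt.step()
        return float(np.sum(losses) / len(order))

    def fit(self, X, y, validation_data=None):
        """Train on slices ``X`` (n, rows, cols) with labels ``y``.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair driving
        early stopping; without it training runs the full epoch budget.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or X.shape != y.shape:
            raise ShapeMismatchError(
                f"expected matching (n, rows, cols) arrays, got {X.shape} and {y.shape}"
            )
        if len(X) == 0:
            raise ValueError("empty training set")
        if y.max() == 0:
            raise ValueError("training labels contain no foreground class")
        cfg = self._resolved_config(X)
        cfg.validate()
        TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
        ).validate()

        net = UNet2D(cfg, seed=self.seed)
        opt = Adam(
            net.params, lr=self.learning_rate, beta1=self.beta1, beta2=self.beta2
        )
        rng = np.random.default_rng(self.seed + 1)

        self.loss_history_: list[float] = []
        self.val_loss_history_: list[float] = []
        best_val = np.inf
        best_weights = None
        patience_left = self.early_stopping_patience

        for epoch in range(self.max_epochs):
            tr_loss = self._epoch_loss(net, X, y, train=True, opt=opt, rng=rng)
            self.loss_history_.append(tr_loss)
            if validation_data is not None:
                Xv, yv = validation_data
                val_loss = self._epoch_loss(
                    net, np.asarray(Xv, dtype=np.float32), np.asarray(yv, dtype=np.int64),
                    train=False,
                )
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = net.get_weights()
                    patience_left = self.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_weights is not None:
            net.set_weights(best_weights)
        self.epochs_run_ = len(self.loss_history_)
        self.net_ = net
        return self

    def predict(self, X) -> np.ndarray:
        """Per-pixel argmax labels for slices ``X`` (ties -> lowest code)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape, dtype=np.int16)
        for start in range(0, len(X), self.batch_size):
            out[start : start + self.batch_size] = self.net_.predict_labels(
                X[start : start + self.batch_size][:, None]
            )
        return out

    def predict_proba(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        return self.net_.predict_proba(X[:, None])

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Checkpoint weights (npz) with embedded JSON provenance."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        path = Path(path)
        meta = {
            "net_config": asdict(self.net_.cfg),
            "train_params": {
                k: v for k, v in self.get_params().items() if k != "net_config"
            },
            "epochs_run": self.epochs_run_,
            "loss_history": self.loss_history_,
            "val_loss_history": self.val_loss_history_,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.net_.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        ncfg = meta["net_config"]
        ncfg["channels"] = tuple(ncfg["channels"])
        ncfg["factors"] = tuple(map(tuple, ncfg["factors"]))
        ncfg["kernel"] = tuple(ncfg["kernel"])
        cfg = NetConfig(**ncfg)
        est = cls(net_config=cfg, **meta["train_params"])
        est.net_ = UNet2D(cfg, seed=est.seed)
        est.net_.set_weights(weights)
        est.loss_history_ = meta["loss_history"]
        est.val_loss_history_ = meta["val_loss_history"]
        est.epochs_run_ = meta["epochs_run"]
        return est


def segment_volume(model: UNetSegmenter, vol: ImageVolume) -> LabelVolume:
    """Segment a preprocessed volume slice by slice into a label map."""
    labels = model.predict(vol.data)
    return LabelVolume(labels.astype(np.int16), vol.spacing)


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(subjects, n_folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled subject-level folds: disjoint, exhaustive, sizes equal
    within one (77 subjects over 5 folds -> {16, 16, 15, 15, 15})."""
    subjects = np.asarray(sorted(set(np.asarray(subjects).tolist())))
    if len(subjects) < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects for {n_folds}-fold CV, got {len(subjects)}"
        )
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [subjects[val_idx] for _, val_idx in kf.split(subjects)]


def _per_subject_region_dice(
    pred: np.ndarray, truth: np.ndarray, subjects: np.ndarray
) -> pd.DataFrame:
    """Pool left/right per sinus type, one Dice value per subject+type."""
    rows = []
    for subj in pd.unique(subjects):
        m = subjects == subj
        p, t = pred[m], truth[m]
        for region in Region:
            rows.append(
                {
                    "subject": subj,
                    "side": region.side.value,
                    "region": region.sinus.value,
                    "dsc": dice(p == int(region), t == int(region)),
                }
            )
    df = pd.DataFrame(rows)
    # pooled left+right per sinus type (union masks would differ; Table-style
    # reporting averages the two sides' Dice values)
    pooled = (
        df.groupby(["subject", "region"], sort=False)["dsc"].mean().reset_index()
    )
    return pooled


def crossvalidate(
    dataset: SliceDataset,
    net_cfg: NetConfig,
    train_cfg: TrainConfig,
    n_boot: int = 1000,
) -> dict:
    """Subject-level k-fold cross-validation of the segmenter.

    Returns a dict with the fold assignment, per-subject per-region Dice
    values, a mean + 95% CI summary table, and the fitted fold models.
    """
    train_cfg.validate()
    folds = make_folds(dataset.subjects, train_cfg.n_folds, seed=train_cfg.seed)
    per_subject = []
    models = []
    for fold_id, val_subjects in enumerate(folds):
        val_mask = np.isin(dataset.subjects, val_subjects)
        train_ds = dataset.subset(~val_mask)
        val_ds = dataset.subset(val_mask)
        est = UNetSegmenter(
            net_config=net_cfg,
            learning_rate=train_cfg.learning_rate,
            beta1=train_cfg.beta1,
            beta2=train_cfg.beta2,
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            early_stopping_patience=train_cfg.early_stopping_patience,
            dice_weight=train_cfg.dice_weight,
            ce_weight=train_cfg.ce_weight,
            seed=train_cfg.seed + fold_id,
        )
        est.fit(
            train_ds.images, train_ds.labels,
            validation_data=(val_ds.images, val_ds.labels),
        )
        pred = est.predict(val_ds.images)
        df = _per_subject_region_dice(pred, val_ds.labels, val_ds.subjects)
        df["fold"] = fold_id
        per_subject.append(df)
        models.append(est)
    per_subject = pd.concat(per_subject, ignore_index=True)
    summary = dice_table(per_subject, n_boot=n_boot, seed=train_cfg.seed)
    return {
        "folds": folds,
        "per_subject_dice": per_subject,
        "summary": summary,
        "models": models,
    }
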