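"""Dataset generation, thermal-status labels, and the CNN classifiers.

The monitoring task is cast as per-ROI image classification.  Each
simulated treatment snapshot yields a two-channel real image (Re/Im of the
TSVD-reconstructed differential contrast) per ROI, labelled from the
imposed temperature rise dT:

    tumor (3 classes):      0 unheated   dT < 3 degC
                            1 therapeutic 3 <= dT < 7 degC
                            2 hot        dT >= 7 degC
    spinal cord (2 classes): 0 unheated  dT < 2 degC
                             1 hot       dT >= 2 degC

Two independent compact CNNs — one per ROI — are trained with Adam under a
K-fold cross-validation protocol (default 10 folds, lr 1e-4, batch 16, at
most 300 epochs, early stopping after 10 epochs without validation-loss
improvement, best-validation weights restored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import AntennaLayout, FrequencySet, MomForwardSolver, add_awgn
from .imaging import build_roi_operator, differential_data, tsvd_invert
from .nn import Adam, SmallCnn, categorical_cross_entropy, softmax
from .phantom import (
    Phantom,
    PhantomConfig,
    build_neck_phantom,
    randomize_tissues,
    set_roi_temperatures,
)

logger = logging.getLogger(__name__)

__all__ = [
    "assign_tumor_label",
    "assign_cord_label",
    "LabeledSample",
    "SimulationSetup",
    "generate_dataset",
    "as_arrays",
    "SmallCnnClassifier",
    "build_cnn",
    "cross_entropy",
    "TrainConfig",
    "FoldResult",
    "kfold_train",
]

TUMOR_CLASSES = ("unheated", "therapeutic", "hot")
CORD_CLASSES = ("unheated", "hot")


def assign_tumor_label(delta_T: float) -> int:
    """Tumor thermal-status class from the temperature rise dT [degC]."""
    if delta_T < 0:
        raise ValueError(f"temperature rise must be non-negative, got {delta_T}")
    if delta_T < 3.0:
        return 0
    if delta_T < 7.0:
        return 1
    return 2


def assign_cord_label(delta_T: float) -> int:
    """Spinal-cord thermal-status class from the temperature rise dT [degC]."""
    if delta_T < 0:
        raise ValueError(f"temperature rise must be non-negative, got {delta_T}")
    return 0 if delta_T < 2.0 else 1


@dataclass(frozen=True)
class LabeledSample:
    """One ROI image with its ground truth."""

    image: np.ndarray  # (size, size, 2) real
    label: int
    delta_T: float
    sample_id: int


@dataclass(frozen=True)
class SimulationSetup:
    """Everything the data generator needs besides sizes and the seed."""

    phantom_config: PhantomConfig = field(default_factory=PhantomConfig)
    layout: AntennaLayout = field(default_factory=AntennaLayout.default_ring)
    frequencies: FrequencySet = field(default_factory=FrequencySet.evenly_spaced)
    snr_db: float = 30.0
    p_cut: int = 1
    #: When True, the DWBA operator is built from the nominal (unrandomized)
    #: phantom instead of the sample's own, to study model mismatch.
    nominal_baseline: bool = False
    tumor_temperatures: tuple[float, ...] = tuple(float(t) for t in range(37, 47))
    cord_temperatures: tuple[float, ...] = tuple(float(t) for t in range(37, 41))


def generate_dataset(
    setup: SimulationSetup,
    n_tumor: int,
    n_cord: int,
    seed: int,
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Simulate labelled ROI images for both classifiers.

    Each simulation randomizes all tissue permittivities, draws one tumor
    and one cord temperature uniformly from their discrete 1-degC grids,
    solves the unheated and heated scattering problems at every frequency,
    corrupts both measurement sessions with AWGN, forms the differential
    data, and inverts both ROIs by TSVD — so a single simulation feeds both
    datasets.  Reproducible under ``seed``.  A simulation whose solve fails
    is skipped (logged); more than 1% skips aborts the run.
    """
    base = build_neck_phantom(setup.phantom_config)
    solver = MomForwardSolver(base, setup.layout, setup.frequencies)
    nominal_records = solver.solve(base) if setup.nominal_baseline else None

    n_total = max(n_tumor, n_cord)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_total)
    tumor_samples: list[LabeledSample] = []
    cord_samples: list[LabeledSample] = []
    skipped = 0
    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        try:
            sample = _simulate_one(setup, base, solver, nominal_records, rng)
        except Exception:  # noqa: BLE001 - any stage failure skips the sample
            logger.exception("simulation %d failed; skipping", i)
            skipped += 1
            if skipped > max(1, n_total // 100):
                raise RuntimeError(f"too many failed simulations ({skipped}/{i + 1})")
            continue
        img_t, img_c, dT_t, dT_c = sample
        if len(tumor_samples) < n_tumor:
            tumor_samples.append(
                LabeledSample(image=img_t, label=assign_tumor_label(dT_t), delta_T=dT_t, sample_id=i)
            )
        if len(cord_samples) < n_cord:
            cord_samples.append(
                LabeledSample(image=img_c, label=assign_cord_label(dT_c), delta_T=dT_c, sample_id=i)
            )
    return tumor_samples, cord_samples


def _simulate_one(
    setup: SimulationSetup,
    base: Phantom,
    solver: MomForwardSolver,
    nominal_records,
    rng: np.random.Generator,
):
    phant = randomize_tissues(base, rng)
    T_t = float(rng.choice(setup.tumor_temperatures))
    T_c = float(rng.choice(setup.cord_temperatures))
    baseline = solver.solve(phant)  # unheated state at 37/37
    heated = solver.solve(set_roi_temperatures(phant, T_t, T_c))
    es0 = np.stack([r.es for r in baseline])
    es_s = np.stack([r.es for r in heated])
    # independent noise draws on the two measurement sessions
    es0_n = add_awgn(es0, setup.snr_db, rng)
    es_s_n = add_awgn(es_s, setup.snr_db, rng)
    delta = differential_data(es_s_n, es0_n)
    op_records = nominal_records if nominal_records is not None else baseline
    op_t = build_roi_operator(op_records, base.tumor_roi)
    op_c = build_roi_operator(op_records, base.cord_roi)
    img_t = tsvd_invert(op_t, delta, setup.p_cut).channels()
    img_c = tsvd_invert(op_c, delta, setup.p_cut).channels()
    return img_t, img_c, T_t - 37.0, T_c - 37.0


def as_arrays(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a sample list into (X, y, delta_T) arrays."""
    X = np.stack([s.image for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    dT = np.array([s.delta_T for s in samples])
    return X, y, dT


def cross_entropy(
    predictions: np.ndarray, truths: np.ndarray, per_class_normalized: bool = True
) -> float:
    """Categorical cross-entropy between probability vectors and one-hot truths."""
    p = np.atleast_2d(np.asarray(predictions, float))
    t = np.atleast_2d(np.asarray(truths, float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return categorical_cross_entropy(p, t, per_class_normalized)


class SmallCnnClassifier:
    """Compact CNN classifier for small two-channel ROI images.

    scikit-learn estimator interface: ``fit(X, y)``, ``predict``,
    ``predict_proba``, ``score``, ``get_params``/``set_params``.  ``X`` has
    shape (N, H, W, 2).  A validation set may be passed explicitly to
    ``fit`` (used by the cross-validation driver); otherwise
    ``validation_fraction`` is split off internally for early stopping.

    Architecture: conv(3x3, 16) -> ReLU -> conv(3x3, 32) -> ReLU ->
    dense(64) -> ReLU -> dense(n_classes) + softmax.  The layer sizes are
    configurable; the defaults keep the parameter count well below the
    dataset sizes in use.
    """

    def __init__(
        self,
        conv_channels: tuple[int, int] = (16, 32),
        dense_units: int = 64,
        learning_rate: float = 1e-4,
        batch_size: int = 16,
        max_epochs: int = 300,
        patience: int = 10,
        validation_fraction: float = 0.1,
        per_class_normalized_loss: bool = True,
        standardize: bool = False,
        seed: int = 0,
    ):
        self.conv_channels = conv_channels
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.per_class_normalized_loss = per_class_normalized_loss
        self.standardize = standardize
        self.seed = seed

    # -- sklearn plumbing -------------------------------------------------
    _param_names = (
        "conv_channels",
        "dense_units",
        "learning_rate",
        "batch_size",
        "max_epochs",
        "patience",
        "validation_fraction",
        "per_class_normalized_loss",
        "standardize",
        "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SmallCnnClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "SmallCnnClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError(f"X must be (N, H, W, C), got shape {X.shape}")
        self.classes_ = np.unique(y)
        n_classes = max(int(self.classes_.size), 2)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[c] for c in y], dtype=np.int64)

        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            X_val, yv = X[val_idx], yi[val_idx]
            X_tr, y_tr = X[train_idx], yi[train_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float64)
            yv = np.array([class_index[c] for c in np.asarray(y_val)], dtype=np.int64)
            X_tr, y_tr = X, yi

        if self.standardize:
            self.mean_ = X_tr.mean(axis=(0, 1, 2))
            self.scale_ = X_tr.std(axis=(0, 1, 2)) + 1e-12
        else:
            self.mean_, self.scale_ = 0.0, 1.0
        X_tr = (X_tr - self.mean_) / self.scale_
        X_val = (X_val - self.mean_) / self.scale_

        net = SmallCnn(
            input_shape=X.shape[1:],
            n_classes=n_classes,
            conv_channels=tuple(self.conv_channels),
            dense_units=self.dense_units,
            rng=rng,
        )
        self.n_params_ = net.n_params
        opt = Adam(net.params, lr=self.learning_rate)
        eye = np.eye(n_classes)
        loss_scale_cls = n_classes if self.per_class_normalized_loss else 1

        best_val = np.inf
        best_params = net.copy_params()
        best_epoch = 0
        train_hist: list[float] = []
        val_hist: list[float] = []
        since_best = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X_tr))
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X_tr[idx], y_tr[idx]
                logits, cache = net.forward(xb, want_cache=True)
                probs = softmax(logits)
                onehot = eye[yb]
                loss = categorical_cross_entropy(probs, onehot, self.per_class_normalized_loss)
                epoch_loss += loss * len(idx)
                d_logits = (probs - onehot) / (len(idx) * loss_scale_cls)
                grads = net.backward(cache, d_logits)
                opt.step(net.params, grads)
            train_hist.append(epoch_loss / len(X_tr))
            val_probs = softmax(net.forward(X_val))
            val_loss = categorical_cross_entropy(val_probs, eye[yv], self.per_class_normalized_loss)
            val_hist.append(val_loss)
            if val_loss < best_val:
                best_val, best_epoch, since_best = val_loss, epoch, 0
                best_params = net.copy_params()
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        net.load_params(best_params)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.loss_history_ = {"train": np.array(train_hist), "val": np.array(val_hist)}
        return self

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        X = (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_
        return softmax(self.net_.forward(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def build_cnn(
    input_shape: tuple[int, int, int], n_classes: int, seed: int = 0, **kwargs
) -> SmallCnn:
    """Construct the raw (untrained) network; reports its parameter count."""
    if n_classes not in (2, 3):
        raise ValueError("monitoring classifiers use 2 or 3 classes")
    net = SmallCnn(
        input_shape=input_shape, n_classes=n_classes, rng=np.random.default_rng(seed), **kwargs
    )
    logger.info("built CNN %s -> %d classes, %d parameters", input_shape, n_classes, net.n_params)
    return net


@dataclass(frozen=True)
class TrainConfig:
    """Cross-validation training protocol parameters."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 10
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least two folds")
        for name in ("learning_rate", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FoldResult:
    """Validation outcome of one cross-validation fold."""

    fold: int
    val_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    train_history: np.ndarray
    val_history: np.ndarray
    best_epoch: int
    classifier: SmallCnnClassifier


def kfold_train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    classifier_kwargs: dict | None = None,
) -> list[FoldResult]:
    """K-fold cross-validation: each sample is validated exactly once.

    The dataset size must divide evenly into ``cfg.n_folds`` folds.  Fold
    assignment is a seeded permutation split into contiguous chunks; each
    fold trains a freshly initialized classifier (fold-indexed seed) on the
    other folds and evaluates on the held-out one.
    """
    n = len(X)
    if n % cfg.n_folds != 0:
        divisors = [k for k in range(2, min(n, 25)) if n % k == 0]
        raise ValueError(f"{n} samples not divisible into {cfg.n_folds} folds; valid: {divisors}")
    n_val = n // cfg.n_folds
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    results = []
    for k in range(cfg.n_folds):
        val_idx = perm[k * n_val : (k + 1) * n_val]
        train_idx = np.concatenate([perm[: k * n_val], perm[(k + 1) * n_val :]])
        clf = SmallCnnClassifier(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=cfg.seed + 1000 * (k + 1),
            **(classifier_kwargs or {}),
        )
        clf.fit(X[train_idx], y[train_idx], X_val=X[val_idx], y_val=y[val_idx])
        results.append(
            FoldResult(
                fold=k,
                val_indices=val_idx,
                y_true=np.asarray(y)[val_idx],
                y_pred=clf.predict(X[val_idx]),
                train_history=clf.loss_history_["train"],
                val_history=clf.loss_history_["val"],
                best_epoch=clf.best_epoch_,
                classifier=clf,
            )
        )
    return results
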