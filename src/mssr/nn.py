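"""Feed-forward network harness: splitting, fitting with early stopping,
hyperparameter grid search, and test-set R².

The networks are fully connected multilayer perceptrons with ReLU hidden
layers and a single linear output, trained by minibatch Adam on
mean-squared error.  Training runs epoch by epoch against an explicit
validation set: when the validation MSE has not improved for ``patience``
epochs training halts and the weights of the best epoch are restored.
The canonical search grid crosses 3 shapes x 3 learning rates x 3
patience values x 3 batch sizes = 81 combinations; the combination with
the lowest validation MSE wins, ties going to the earlier combination in
canonical order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dgp import SimulatedDataset

CANONICAL_SHAPES: tuple[tuple[int, ...], ...] = ((10,), (10, 10), (10, 10, 10))
CANONICAL_LEARNING_RATES: tuple[float, ...] = (0.0001, 0.001, 0.01)
CANONICAL_PATIENCE: tuple[int, ...] = (5, 10, 15)
CANONICAL_BATCH_SIZES: tuple[int, ...] = (32, 64, 128)

#: fractions of the published protocol: 20% of all rows held out for
#: testing, then 20% of the remaining training rows for validation
TEST_FRACTION = 0.2
VALIDATION_FRACTION = 0.2

DEFAULT_MAX_EPOCHS = 200


class FitFailure(RuntimeError):
    """Raised when a fit (or a whole grid search) produces no finite loss."""


@dataclass(frozen=True)
class HyperParameters:
    """One point of the search grid."""

    shape: tuple[int, ...] = (10,)
    learning_rate: float = 0.001
    patience: int = 10
    batch_size: int = 32

    def canonical_key(self) -> tuple:
        return (len(self.shape), self.shape, self.learning_rate, self.patience, self.batch_size)


def canonical_grid() -> list[HyperParameters]:
    """The full 81-combination grid in canonical order."""
    return [
        HyperParameters(shape=s, learning_rate=lr, patience=p, batch_size=b)
        for s, lr, p, b in itertools.product(
            CANONICAL_SHAPES, CANONICAL_LEARNING_RATES, CANONICAL_PATIENCE, CANONICAL_BATCH_SIZES
        )
    ]


def fast_grid() -> list[HyperParameters]:
    """A reduced 8-combination grid for desk-scale runs: 2 shapes x 2
    learning rates x 1 patience x 2 batch sizes."""
    return [
        HyperParameters(shape=s, learning_rate=lr, patience=5, batch_size=b)
        for s, lr, b in itertools.product(
            ((10,), (10, 10)), (0.001, 0.01), (32, 64)
        )
    ]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """Disjoint train/validation/test partitions of one dataset."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def split_dataset(dataset: SimulatedDataset, seed: int) -> Split:
    """Randomly partition into 64% train / 16% validation / 20% test."""
    n = dataset.n
    if n < 10:
        raise ValueError("dataset must have at least 10 rows to split")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    perm = rng.permutation(n)
    n_test = round(TEST_FRACTION * n)
    n_val = round(VALIDATION_FRACTION * (n - n_test))
    test_idx = np.sort(perm[:n_test])
    val_idx = np.sort(perm[n_test : n_test + n_val])
    train_idx = np.sort(perm[n_test + n_val :])
    X = dataset.X.astype(np.float64)
    y = dataset.Y
    return Split(
        X_train=X[train_idx], y_train=y[train_idx],
        X_val=X[val_idx], y_val=y[val_idx],
        X_test=X[test_idx], y_test=y[test_idx],
        train_idx=train_idx, val_idx=val_idx, test_idx=test_idx,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one early-stopped fit."""

    model: MLPRegressor
    hp: HyperParameters
    val_loss: float
    epochs_run: int
    best_epoch: int
    seed: int
    failed: bool = False
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.scaler is not None:
            mean, scale = self.scaler
            X = (X - mean) / scale
        return self.model.predict(X)


def fit_nn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hp: HyperParameters,
    seed: int = 0,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    standardize: bool = False,
) -> FitResult:
    """Train one network with early stopping on the validation MSE.

    Weights of the best validation epoch are restored on exit.  Inputs
    are the raw Likert codes unless ``standardize`` is set (train-set
    mean/sd scaling, applied consistently at prediction time).  A fit
    whose validation loss never becomes finite is returned flagged as
    failed rather than raised, so replication loops can count failures.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    scaler = None
    if standardize:
        mean = X_train.mean(axis=0)
        scale = X_train.std(axis=0)
        scale[scale == 0] = 1.0
        scaler = (mean, scale)
        X_train = (X_train - mean) / scale
        X_val = (X_val - mean) / scale

    model = MLPRegressor(
        hidden_layer_sizes=hp.shape,
        activation="relu",
        solver="adam",
        learning_rate_init=hp.learning_rate,
        batch_size=min(hp.batch_size, X_train.shape[0]),
        shuffle=True,
        random_state=int(seed) % (2**32),
        max_iter=1,  # the loop below drives the epochs via partial_fit
    )

    best_loss = np.inf
    best_weights: tuple[list, list] | None = None
    best_epoch = 0
    wait = 0
    epoch = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for epoch in range(1, max_epochs + 1):
            model.partial_fit(X_train, y_train)
            pred = model.predict(X_val)
            val_loss = float(np.mean((pred - y_val) ** 2))
            if np.isfinite(val_loss) and val_loss < best_loss:
                best_loss = val_loss
                best_weights = (
                    [w.copy() for w in model.coefs_],
                    [b.copy() for b in model.intercepts_],
                )
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= hp.patience:
                    break

    if best_weights is None:
        return FitResult(model=model, hp=hp, val_loss=np.inf, epochs_run=epoch,
                         best_epoch=0, seed=seed, failed=True, scaler=scaler)
    model.coefs_, model.intercepts_ = best_weights
    return FitResult(model=model, hp=hp, val_loss=best_loss, epochs_run=epoch,
                     best_epoch=best_epoch, seed=seed, scaler=scaler)


def grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid: Sequence[HyperParameters] | None = None,
    seed: int = 0,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    standardize: bool = False,
    repeats: int = 1,
) -> FitResult:
    """Fit every grid combination and return the best fit by validation MSE.

    Ties are broken in favour of the earlier combination in canonical
    order (shape, then learning rate, then patience, then batch size).
    ``repeats`` fits each combination several times with distinct
    sub-seeds and keeps its best run.  Raises :class:`FitFailure` if no
    combination achieves a finite validation loss.
    """
    grid = list(canonical_grid() if grid is None else grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    grid.sort(key=HyperParameters.canonical_key)
    root = np.random.SeedSequence(entropy=int(seed))
    fit_seeds = root.generate_state(len(grid) * repeats)

    best: FitResult | None = None
    for i, hp in enumerate(grid):
        for r in range(repeats):
            result = fit_nn(
                X_train, y_train, X_val, y_val, hp,
                seed=int(fit_seeds[i * repeats + r]),
                max_epochs=max_epochs, standardize=standardize,
            )
            if result.failed:
                continue
            if best is None or result.val_loss < best.val_loss:
                best = result
    if best is None:
        raise FitFailure("every grid combination produced a non-finite validation loss")
    return best


def evaluate_r2(fit: FitResult, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Test-set R² = 1 - SSE/SST, with SST about the test-set mean.

    May be negative when the network predicts worse than the test mean.
    A zero-variance test outcome leaves R² undefined and raises.
    """
    y_test = np.asarray(y_test, dtype=np.float64)
    if y_test.size == 0:
        raise ValueError("test partition is empty")
    sst = float(np.sum((y_test - y_test.mean()) ** 2))
    if sst == 0.0:
        raise FitFailure("test outcome has zero variance; R² undefined")
    pred = fit.predict(X_test)
    sse = float(np.sum((pred - y_test) ** 2))
    return 1.0 - sse / sst
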