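"""Feed-forward knot classifiers, losses and binarisation rules.

The classifier is a 4-hidden-layer feed-forward network with rectifier
activations and a softmax output trained under sparse categorical
cross-entropy with early stopping (scikit-learn's multilayer perceptron
provides exactly this combination).  Hidden widths are sized to a
trainable-parameter budget: ~4x10^5 parameters for per-bead features
(StA, XYZ) and ~3.6x10^6 for the N x N StS maps, matching a fixed
layer-width ratio of 2:4:3:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = ["ClassifierSpec", "TrainConfig", "bce_loss", "binarise",
           "binary_accuracy", "hidden_widths", "train_classifier", "predict"]

#: budgets: per-bead features vs full StS maps
PARAM_BUDGET_LOCAL = 400_000
PARAM_BUDGET_STS = 3_600_000


def hidden_widths(input_dim: int, n_classes: int,
                  budget: int = PARAM_BUDGET_LOCAL,
                  ratios=(2, 4, 3, 1)) -> tuple[int, ...]:
    """Four hidden-layer widths meeting the parameter budget (+-25%).

    Widths follow the fixed ratio; the scale is chosen so the total
    trainable-parameter count (weights + biases) is as close to the
    budget as possible.
    """
    def count(widths):
        dims = [input_dim, *widths, n_classes]
        return sum(dims[i] * dims[i + 1] + dims[i + 1]
                   for i in range(len(dims) - 1))

    best, best_err = None, np.inf
    for scale in range(2, 2000):
        widths = tuple(max(int(r * scale), 1) for r in ratios)
        err = abs(count(widths) - budget)
        if err < best_err:
            best, best_err = widths, err
    total = count(best)
    if not 0.75 * budget <= total <= 1.25 * budget:
        raise ValueError(
            f"no width assignment within 25% of {budget} parameters "
            f"(best {total})")
    return best


@dataclass
class ClassifierSpec:
    """Feed-forward architecture bound to a parameter budget."""

    input_dim: int
    n_classes: int
    param_budget: int = PARAM_BUDGET_LOCAL
    activation: str = "relu"
    widths: tuple = field(default=None)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.widths is None:
            self.widths = hidden_widths(self.input_dim, self.n_classes,
                                        self.param_budget)

    @property
    def n_parameters(self) -> int:
        dims = [self.input_dim, *self.widths, self.n_classes]
        return sum(dims[i] * dims[i + 1] + dims[i + 1]
                   for i in range(len(dims) - 1))


@dataclass
class TrainConfig:
    loss: str = "sparse_categorical_crossentropy"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.loss not in ("sparse_categorical_crossentropy",
                             "binary_crossentropy"):
            raise ValueError(f"unsupported loss {self.loss!r}")


# ---------------------------------------------------------------------------
# losses and binarisation
# ---------------------------------------------------------------------------

def bce_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = 1e-7) -> float:
    """Binary cross-entropy, mean over output neurons.

    ``-(1/N) sum_i [y_i log(yhat_i) + (1 - y_i) log(1 - yhat_i)]`` with
    predictions clipped ``eps`` away from 0 and 1.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    p = np.clip(y_hat, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def binarise(y_prob: np.ndarray) -> np.ndarray:
    """Heaviside step at 0.5: ``y_pred = theta(y_prob - 0.5)``, theta(0) = 1."""
    return (np.asarray(y_prob) >= 0.5).astype(np.int8)


def binary_accuracy(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Fraction of matching bits: correct / total."""
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError("shape mismatch")
    return float((y_pred == y_true).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class DivergenceError(RuntimeError):
    pass


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     spec: ClassifierSpec, config: TrainConfig | None = None):
    """Train the feed-forward softmax classifier; returns (model, history).

    ``features`` is (n_samples, input_dim); integer labels.  Early
    stopping monitors a held-out validation fraction of the training
    data (sparse categorical cross-entropy).
    """
    config = config or TrainConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != spec {spec.input_dim}")
    model = MLPClassifier(
        hidden_layer_sizes=spec.widths,
        activation=spec.activation,
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(X)),
        max_iter=config.max_epochs,
        early_stopping=True,
        n_iter_no_change=config.patience,
        validation_fraction=config.validation_fraction,
        random_state=config.seed,
        tol=1e-5,
    )
    import warnings
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    history = {
        "train_loss": list(map(float, model.loss_curve_)),
        "val_score": list(map(float, getattr(model, "validation_scores_", []))),
        "n_epochs": int(model.n_iter_),
    }
    if not np.isfinite(model.loss_):
        raise DivergenceError(f"non-finite loss; config={config}")
    return model, history


def predict(model, features: np.ndarray) -> np.ndarray:
    """Class probabilities (softmax outputs), one row per conformation."""
    return model.predict_proba(np.asarray(features, dtype=np.float64))
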