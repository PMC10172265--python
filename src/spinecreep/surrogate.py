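"""LSTM surrogate for per-cycle hysteresis-parameter prediction.

The surrogate maps the normalized second-cycle loop parameters of a loading
block plus the environmental feature τ_t to the ten loop parameters of every
following cycle.  By default the 11-vector input is repeated at every
timestep j (the network's internal state unrolls the creep trajectory) and
the output at step j is the parameter vector of cycle j+2; a teacher-forcing
layout (input at step j is cycle j+1, autoregressive at prediction time) is
available behind ``input_layout="teacher"``.

Training minimizes the masked mean squared error with Adam, stopping when the
training loss reaches the target, when the moving average of the validation
loss stops improving over the patience window, or at the epoch cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .hysteresis import HysteresisParams, eval_boltzmann, r_squared
from .nn import Adam, DenseLayer, LSTMLayer, masked_mse, masked_mse_grad
from .scaling import INPUT_FEATURES, OUTPUT_FEATURES, SequenceScaler
from .sequences import CycleSequence

__all__ = [
    "SurrogateConfig",
    "TrainingLog",
    "LSTMSurrogate",
    "sequences_to_arrays",
    "evaluate_mean_r2",
]

N_INPUT = len(INPUT_FEATURES)   # 11
N_OUTPUT = len(OUTPUT_FEATURES)  # 10


@dataclass(frozen=True)
class SurrogateConfig:
    """Hyperparameters of the surrogate network.

    ``reference()`` returns the full-scale configuration of the original
    study (6 stacked LSTM layers, 44 753-epoch cap, full-batch updates);
    ``desk()`` is a small configuration sized for a single CPU.
    """

    hidden_units: tuple[int, ...] = (32, 64)
    dropout: float = 0.0
    learning_rate: float = 3e-3
    lr_decay: float = 0.9995
    batch_size: int = 16
    max_epochs: int = 3000
    target_loss: float = 5e-4
    patience: int = 50
    clip_norm: float | None = 1.0
    input_layout: str = "repeat"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_units) < 1 or any(u < 1 for u in self.hidden_units):
            raise ValueError("hidden_units must be a nonempty tuple of positive ints")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.target_loss, self.patience) <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.input_layout not in ("repeat", "teacher"):
            raise ValueError("input_layout must be 'repeat' or 'teacher'")

    @classmethod
    def reference(cls, **overrides) -> "SurrogateConfig":
        kw = dict(
            hidden_units=(64, 64, 128, 128, 256, 256),
            dropout=0.15,
            learning_rate=1e-3,
            lr_decay=1.0,
            batch_size=324,  # exceeds the training set: full-batch updates
            max_epochs=44753,
            target_loss=5e-4,
            patience=50,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def desk(cls, **overrides) -> "SurrogateConfig":
        return cls(**overrides)

    def to_estimator(self) -> "LSTMSurrogate":
        return LSTMSurrogate(**asdict(self))


@dataclass
class TrainingLog:
    """Per-epoch loss trace and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    stop_reason: str = ""
    final_loss: float = float("nan")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        val = self.validation_loss or [float("nan")] * len(self.train_loss)
        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss, "validation_loss": val}
        )


def sequences_to_arrays(sequences: list[CycleSequence], layout: str = "repeat"):
    """Assemble padded (X, Y, mask) batches from cycle sequences.

    The first retained cycle (cycle 2, after dropping preconditioning) is the
    input anchor; outputs are the remaining cycles.  Padding is zero and the
    boolean mask marks real steps.
    """
    if not sequences:
        raise ValueError("no sequences given")
    feats = []
    for seq in sequences:
        mat = seq.params_matrix()
        if mat.shape[0] < 2:
            raise ValueError(f"sequence {seq.sequence_id} has fewer than 2 cycles")
        feats.append((seq.tau_t, mat))
    P = max(mat.shape[0] - 1 for _, mat in feats)
    N = len(feats)
    X = np.zeros((N, P, N_INPUT))
    Y = np.zeros((N, P, N_OUTPUT))
    mask = np.zeros((N, P), dtype=bool)
    for i, (tau_t, mat) in enumerate(feats):
        p = mat.shape[0] - 1
        if layout == "repeat":
            X[i, :p, 0] = tau_t
            X[i, :p, 1:] = mat[0]
        elif layout == "teacher":
            X[i, :p, 0] = tau_t
            X[i, :p, 1:] = mat[:-1]
        else:
            raise ValueError("layout must be 'repeat' or 'teacher'")
        Y[i, :p] = mat[1:]
        mask[i, :p] = True
    return X, Y, mask


class LSTMSurrogate(BaseEstimator, RegressorMixin):
    """Stacked-LSTM sequence surrogate with a linear dense head.

    scikit-learn style estimator: hyperparameters in ``__init__``, fitted
    state in trailing-underscore attributes (``layers_``, ``scaler_``,
    ``log_``, ``n_epochs_``, ``stop_reason_``).
    """

    def __init__(
        self,
        hidden_units: tuple[int, ...] = (32, 64),
        dropout: float = 0.0,
        learning_rate: float = 3e-3,
        lr_decay: float = 0.9995,
        batch_size: int = 16,
        max_epochs: int = 3000,
        target_loss: float = 5e-4,
        patience: int = 50,
        clip_norm: float | None = 1.0,
        input_layout: str = "repeat",
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.target_loss = target_loss
        self.patience = patience
        self.clip_norm = clip_norm
        self.input_layout = input_layout
        self.seed = seed

    # -- model construction -------------------------------------------------

    def build_model(self):
        """Seeded random initialization of the stacked layers and dense head."""
        SurrogateConfig(**self.get_params())  # validates hyperparameters
        rng = np.random.default_rng(self.seed)
        layers = []
        n_in = N_INPUT
        for n_units in self.hidden_units:
            layers.append(LSTMLayer(n_in, int(n_units), rng))
            n_in = int(n_units)
        head = DenseLayer(n_in, N_OUTPUT, rng)
        return layers, head, rng

    def n_parameters(self) -> int:
        layers, head, _ = (self.layers_, self.head_, None) if hasattr(self, "layers_") \
            else self.build_model()
        return sum(l.n_parameters() for l in layers) + head.n_parameters()

    # -- forward ------------------------------------------------------------

    def _forward(self, X, rng=None, collect_cache=False):
        caches = []
        H = X
        drop_masks = []
        for layer in self.layers_:
            H, cache = layer.forward(H)
            if rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                dmask = (rng.random(H.shape) < keep) / keep
                H = H * dmask
                drop_masks.append(dmask)
            else:
                drop_masks.append(None)
            caches.append(cache)
        Y, head_cache = self.head_.forward(H)
        if collect_cache:
            return Y, caches, drop_masks, head_cache
        return Y

    def _backward(self, dY, caches, drop_masks, head_cache):
        grads: list[np.ndarray] = []
        dH, head_grads = self.head_.backward(dY, head_cache)
        grads = head_grads
        for layer, cache, dmask in zip(self.layers_[::-1], caches[::-1], drop_masks[::-1]):
            if dmask is not None:
                dH = dH * dmask
            dH, layer_grads = layer.backward(dH, cache)
            grads = layer_grads + grads
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, sequences: list[CycleSequence], validation: list[CycleSequence] | None = None,
            scaler: SequenceScaler | None = None):
        """Train on cycle sequences; the scaler is fitted on this training
        split only unless a pre-fitted one is supplied."""
        self.layers_, self.head_, init_rng = self.build_model()
        self._train_rng = np.random.default_rng(init_rng.integers(2**31))

        if scaler is None:
            scaler = SequenceScaler(INPUT_FEATURES)
            rows = np.vstack([
                np.column_stack([np.full(len(s), s.tau_t), s.params_matrix()])
                for s in sequences
            ])
            scaler.fit(rows)
        self.scaler_ = scaler
        self.output_scaler_ = scaler.subset(OUTPUT_FEATURES)

        X, Y, mask = self._scaled_arrays(sequences)
        val_arrays = self._scaled_arrays(validation) if validation else None

        params = [p for l in self.layers_ for p in l.params] + self.head_.params
        opt = Adam(params, learning_rate=self.learning_rate, clip_norm=self.clip_norm)
        log = TrainingLog()
        N = X.shape[0]
        # the dual rule watches the moving averages of BOTH losses: training
        # stalls only when neither average improved within the patience window
        best_val_ma = np.inf
        best_val_epoch = 0
        best_train_ma = np.inf
        best_train_epoch = 0
        ma_window = self.patience  # smooth over the patience horizon

        for epoch in range(1, self.max_epochs + 1):
            opt.lr = self.learning_rate * self.lr_decay ** (epoch - 1)
            order = self._train_rng.permutation(N)
            epoch_loss = 0.0
            drop_rng = self._train_rng if self.dropout > 0 else None
            for start in range(0, N, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb, mb = X[idx], Y[idx], mask[idx]
                pred, caches, dmasks, hcache = self._forward(xb, rng=drop_rng, collect_cache=True)
                loss = masked_mse(pred, yb, mb)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged at epoch {epoch}")
                grads = self._backward(masked_mse_grad(pred, yb, mb), caches, dmasks, hcache)
                opt.step(grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= N
            log.train_loss.append(epoch_loss)

            train_ma = float(np.mean(log.train_loss[-ma_window:]))
            if train_ma < best_train_ma * (1.0 - 1e-6):
                best_train_ma = train_ma
                best_train_epoch = epoch
            if val_arrays is not None:
                xv, yv, mv = val_arrays
                val_loss = masked_mse(self._forward(xv), yv, mv)
                log.validation_loss.append(val_loss)
                val_ma = float(np.mean(log.validation_loss[-ma_window:]))
                if val_ma < best_val_ma * (1.0 - 1e-6):
                    best_val_ma = val_ma
                    best_val_epoch = epoch
                if epoch - max(best_val_epoch, best_train_epoch) >= self.patience:
                    log.stop_reason = "patience"

            if epoch_loss <= self.target_loss:
                log.stop_reason = "target_loss"
            if log.stop_reason:
                break
        if not log.stop_reason:
            log.stop_reason = "max_epochs"
        log.final_loss = log.train_loss[-1]
        self.log_ = log
        self.n_epochs_ = log.n_epochs
        self.stop_reason_ = log.stop_reason
        return self

    def _scaled_arrays(self, sequences):
        X, Y, mask = sequences_to_arrays(sequences, layout=self.input_layout)
        Xs = np.where(mask[:, :, None],
                      self.scaler_.transform(X, warn_extrapolation=False), 0.0)
        Ys = np.where(mask[:, :, None],
                      self.output_scaler_.transform(Y, warn_extrapolation=False), 0.0)
        return Xs, Ys, mask

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "layers_"):
            raise ValueError("LSTMSurrogate is not fitted")

    def predict_array(self, second_cycle_params, tau_t: float, n_steps: int) -> np.ndarray:
        """Predict (n_steps, 10) raw parameter vectors for cycles 3, 4, …

        Runs the forward pass without masking or dropout; in the teacher
        layout predictions are fed back autoregressively.
        """
        self._check_fitted()
        if n_steps == 0:
            return np.zeros((0, N_OUTPUT))
        if n_steps < 0:
            raise ValueError("n_steps must be ≥ 0")
        p2 = second_cycle_params.to_vector() if isinstance(second_cycle_params, HysteresisParams) \
            else np.asarray(second_cycle_params, dtype=float)
        x0 = self.scaler_.transform(np.concatenate([[tau_t], p2]), warn_extrapolation=False)
        if self.input_layout == "repeat":
            X = np.tile(x0, (1, n_steps, 1))
            out = self._forward(X)[0]
        else:
            out = np.empty((n_steps, N_OUTPUT))
            x_prev = x0
            X = np.empty((1, n_steps, N_INPUT))
            for j in range(n_steps):
                X[0, j] = x_prev
                pred = self._forward(X[:, :j + 1])[0, j]
                out[j] = pred
                x_prev = np.concatenate([[x0[0]], pred])
        return self.output_scaler_.inverse_transform(out)

    def predict_sequence(self, second_cycle_params, tau_t: float, n_steps: int) -> list[HysteresisParams]:
        """Like :meth:`predict_array` but as loop-parameter objects.

        Predicted loops with an inverted envelope (A > B, expected for well
        under 1 % of predictions) are repaired by swapping A and B; the count
        is recorded in ``n_envelope_violations_``.
        """
        raw = self.predict_array(second_cycle_params, tau_t, n_steps)
        violations = int(np.sum(raw[:, 0] > raw[:, 1]))
        self.n_envelope_violations_ = getattr(self, "n_envelope_violations_", 0) + violations
        out = []
        for vec in raw:
            if vec[0] > vec[1]:
                vec = vec.copy()
                vec[0], vec[1] = vec[1], vec[0]
            out.append(HysteresisParams.from_vector(vec))
        return out

    def predict(self, sequences: list[CycleSequence]) -> list[np.ndarray]:
        """Per-sequence predicted parameter matrices for cycles 3..K."""
        self._check_fitted()
        return [
            self.predict_array(seq.cycles[0], seq.tau_t, len(seq) - 1)
            for seq in sequences
        ]

    def score(self, sequences: list[CycleSequence], y=None) -> float:
        """Mean curve R² between predicted and true cycles (higher is better)."""
        preds = self.predict(sequences)
        truths = [seq.params_matrix()[1:] for seq in sequences]
        return evaluate_mean_r2(preds, truths)


def evaluate_mean_r2(predicted, true, grid=None) -> float:
    """Mean pooled-branch curve R² between predicted and true cycles.

    ``predicted`` and ``true`` are matched lists of (n_cycles, 10) parameter
    matrices; each cycle's curves are reconstructed on the moment grid and
    compared by the coefficient of determination, pooling both branches.
    """
    if grid is None:
        grid = np.linspace(-7.5, 7.5, 101)
    if len(predicted) != len(true):
        raise ValueError("predicted and true lists must align")
    scores = []
    for pred_mat, true_mat in zip(predicted, true):
        pred_mat = np.atleast_2d(pred_mat)
        true_mat = np.atleast_2d(true_mat)
        if pred_mat.shape != true_mat.shape:
            raise ValueError("cycle counts differ between prediction and truth")
        for pv, tv in zip(pred_mat, true_mat):
            curves = []
            for vec in (tv, pv):
                A, B = vec[0], vec[1]
                upper = eval_boltzmann(A, B, *vec[2:6], grid)
                lower = eval_boltzmann(A, B, *vec[6:10], grid)
                curves.append(np.concatenate([upper, lower]))
            scores.append(r_squared(curves[0], curves[1]))
    return float(np.mean(scores))
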