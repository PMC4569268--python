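"""Feed-forward neural network surrogate for fermentation responses.

Architecture: k inputs -> H hidden units with the hyperbolic-tangent
sigmoid ("tansig", identical to tanh) -> one linear ("purelin") output:

    y = LW . tanh(IW x + b) + a

Inputs and the response are min-max scaled to [-1, 1] before training;
tanh saturates on raw concentration scales.  Three trainers are
provided: plain gradient descent (``gd``), gradient descent with an
adaptive learning rate (``gda``), and Levenberg-Marquardt (``lm``), a
damped Gauss-Newton method whose accepted steps never increase the
training error.  Epoch-wise SSE is tracked on the normalized scale so
that training is invariant to affine rescaling of the response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .doe import DesignTable

__all__ = [
    "NeuralModel",
    "TrainingConfig",
    "TrainingReport",
    "NotFittedError",
    "DivergenceError",
    "init_network",
    "forward",
    "train",
    "predict_table",
]


class NotFittedError(RuntimeError):
    """The network has no normalization constants yet."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def tansig(z: np.ndarray) -> np.ndarray:
    """Hyperbolic tangent sigmoid, 2/(1+exp(-2z)) - 1 == tanh(z)."""
    return np.tanh(z)


@dataclass
class NeuralModel:
    """Weights, biases and normalization constants of a k-H-1 network."""

    IW: np.ndarray  # (H, k) input-to-hidden weights
    b: np.ndarray  # (H,) hidden biases
    LW: np.ndarray  # (H,) hidden-to-output weights
    a: float  # output bias
    norm_in: np.ndarray | None = None  # (2, k) per-factor min / max
    norm_out: np.ndarray | None = None  # (2,) response min / max
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.IW.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.IW.shape[1]

    @property
    def n_params(self) -> int:
        return self.IW.size + self.b.size + self.LW.size + 1

    # -- parameter vector helpers (used by the trainers) ----------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.IW.ravel(), self.b, self.LW, [self.a]])

    def set_params(self, w: np.ndarray) -> None:
        H, k = self.IW.shape
        self.IW = w[: H * k].reshape(H, k).copy()
        self.b = w[H * k : H * k + H].copy()
        self.LW = w[H * k + H : H * k + 2 * H].copy()
        self.a = float(w[-1])

    # -- scaling --------------------------------------------------------
    def scale_in(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.norm_in
        rng = np.where(hi > lo, hi - lo, 1.0)
        return 2.0 * (X - lo) / rng - 1.0

    def scale_out(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.norm_out
        rng = hi - lo if hi > lo else 1.0
        return 2.0 * (y - lo) / rng - 1.0

    def unscale_out(self, yn: np.ndarray) -> np.ndarray:
        lo, hi = self.norm_out
        rng = hi - lo if hi > lo else 1.0
        return (yn + 1.0) / 2.0 * rng + lo

    def forward(self, composition: np.ndarray | Sequence[float]) -> np.ndarray | float:
        """Predicted activity at one composition or an (n, k) matrix."""
        if self.norm_in is None or self.norm_out is None:
            raise NotFittedError("network has no normalization constants; train first")
        X = np.asarray(composition, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"composition has length {X.shape[1]}, expected {self.n_inputs}"
            )
        Z = self.scale_in(X)
        h = tansig(Z @ self.IW.T + self.b)
        yn = h @ self.LW + self.a
        y = self.unscale_out(yn)
        return float(y[0]) if single else y

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "n_hidden": self.n_hidden,
            "IW": self.IW.tolist(),
            "b": self.b.tolist(),
            "LW": self.LW.tolist(),
            "a": self.a,
            "norm_in": None if self.norm_in is None else self.norm_in.tolist(),
            "norm_out": None if self.norm_out is None else self.norm_out.tolist(),
            "seed": self.seed,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NeuralModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        o = json.loads(text)
        return cls(
            IW=np.array(o["IW"], dtype=float),
            b=np.array(o["b"], dtype=float),
            LW=np.array(o["LW"], dtype=float),
            a=float(o["a"]),
            norm_in=None if o["norm_in"] is None else np.array(o["norm_in"]),
            norm_out=None if o["norm_out"] is None else np.array(o["norm_out"]),
            seed=o.get("seed"),
        )


@dataclass
class TrainingConfig:
    algorithm: Literal["gd", "gda", "lm"] = "lm"
    max_epochs: int = 1000
    goal_sse: float = 1e-5  # on the normalized response scale
    learning_rate: float = 0.01
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    seed: int = 0
    early_stop_patience: int = 6
    #: split labels whose rows enter the SSE being minimized.  The study
    #: fit its network to the union of its training and test rows (its
    #: test-row predictions interpolate the observations exactly), with
    #: only the validation rows held out; set to ("train",) to fit on
    #: the training rows alone.
    train_splits: tuple[str, ...] = ("train", "test")

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_inc, self.lr_dec, self.mu0, self.mu_inc, self.mu_dec) <= 0:
            raise ValueError("all rates must be positive")
        if not (self.mu_dec < 1.0 < self.mu_inc):
            raise ValueError("require mu_dec < 1 < mu_inc")


@dataclass
class TrainingReport:
    sse_trace: list[float]  # accepted SSE per epoch (normalized scale)
    step_trace: list[tuple[int, float, float, bool]]  # (epoch, sse, mu_or_lr, accepted)
    r_train: float
    r_test: float
    r_validation: float
    stop_reason: str
    epochs: int

    def trace_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.step_trace, columns=["epoch", "sse", "mu_or_lr", "accepted"]
        ).to_csv(path, index=False)


def init_network(n_hidden: int, seed: int, n_inputs: int = 5) -> NeuralModel:
    """Seeded random network with weights uniform in [-0.5, 0.5]."""
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    rng = np.random.default_rng(seed)
    return NeuralModel(
        IW=rng.uniform(-0.5, 0.5, size=(n_hidden, n_inputs)),
        b=rng.uniform(-0.5, 0.5, size=n_hidden),
        LW=rng.uniform(-0.5, 0.5, size=n_hidden),
        a=float(rng.uniform(-0.5, 0.5)),
        seed=seed,
    )


def forward(model: NeuralModel, composition) -> np.ndarray | float:
    """Functional alias for :meth:`NeuralModel.forward`."""
    return model.forward(composition)


def _net_out_and_jac(w: np.ndarray, Z: np.ndarray, H: int, k: int):
    """Network output and Jacobian d out / d w on normalized inputs."""
    IW = w[: H * k].reshape(H, k)
    b = w[H * k : H * k + H]
    LW = w[H * k + H : H * k + 2 * H]
    a = w[-1]
    act = np.tanh(Z @ IW.T + b)  # (n, H)
    out = act @ LW + a
    dact = 1.0 - act**2  # (n, H)
    # d out/d IW_{jm} = LW_j * dact_j * z_m
    J_iw = (LW * dact)[:, :, None] * Z[:, None, :]  # (n, H, k)
    J = np.concatenate(
        [J_iw.reshape(len(Z), H * k), LW * dact, act, np.ones((len(Z), 1))], axis=1
    )
    return out, J


def _net_out(w: np.ndarray, Z: np.ndarray, H: int, k: int) -> np.ndarray:
    IW = w[: H * k].reshape(H, k)
    return np.tanh(Z @ IW.T + w[H * k : H * k + H]) @ w[H * k + H : H * k + 2 * H] + w[-1]


def _split_corr(model: NeuralModel, design: DesignTable, split: str) -> float:
    sub = design.subset(split)
    if len(sub) < 2:
        return float("nan")
    pred = model.forward(sub.uncoded)
    obs = sub.observed
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


def train(
    model: NeuralModel, design: DesignTable, config: TrainingConfig
) -> tuple[NeuralModel, TrainingReport]:
    """Fit the network by SSE minimization over the configured splits.

    The rows entering the objective are those whose split label is in
    ``config.train_splits`` (default: training and test rows, with the
    validation rows held out).  Normalization constants are set from the
    whole design.  ``gd`` takes
    fixed-rate gradient steps; ``gda`` accepts a step only if it does not
    worsen the SSE, growing the rate by ``lr_inc`` after improvement and
    shrinking it by ``lr_dec`` after a rejection; ``lm`` solves the
    damped normal equations (J'J + mu I) d = J'r, rejecting steps that
    increase the SSE and adapting mu.  When validation rows exist, the
    validation SSE is monitored and the weights with the lowest
    validation SSE within ``early_stop_patience`` epochs of the best are
    returned.
    """
    in_fit = design.df["split"].isin(config.train_splits).to_numpy()
    if not in_fit.any():
        raise ValueError(f"design has no rows with split in {config.train_splits}")
    y_all = design.observed
    X_all = design.uncoded

    model = NeuralModel(
        IW=model.IW.copy(),
        b=model.b.copy(),
        LW=model.LW.copy(),
        a=model.a,
        norm_in=np.vstack([X_all.min(axis=0), X_all.max(axis=0)]),
        norm_out=np.array([np.nanmin(y_all), np.nanmax(y_all)]),
        seed=model.seed,
    )
    H, k = model.IW.shape
    Z = model.scale_in(X_all[in_fit])
    t = model.scale_out(y_all[in_fit])

    val_set = design.subset("validation")
    use_val = (
        len(val_set) >= 2
        and config.early_stop_patience > 0
        and "validation" not in config.train_splits
    )
    if use_val:
        Zv = model.scale_in(val_set.uncoded)
        tv = model.scale_out(val_set.observed)

    w = model.get_params()
    out, J = _net_out_and_jac(w, Z, H, k)
    r = t - out
    sse = float(r @ r)

    sse_trace: list[float] = []
    step_trace: list[tuple[int, float, float, bool]] = []
    stop_reason = "max_epochs"
    mu = config.mu0
    lr = config.learning_rate
    best_val = np.inf
    best_w = w.copy()
    best_epoch = 0

    if sse <= config.goal_sse:
        stop_reason = "goal_reached"
        epochs_run = 0
    else:
        epochs_run = 0
        for epoch in range(1, config.max_epochs + 1):
            if config.algorithm == "lm":
                accepted = False
                JtJ = J.T @ J
                Jtr = J.T @ r
                while mu <= config.mu_max:
                    try:
                        step = np.linalg.solve(
                            JtJ + mu * np.eye(len(w)), Jtr
                        )
                    except np.linalg.LinAlgError:
                        mu *= config.mu_inc
                        continue
                    w_new = w + step
                    out_new = _net_out(w_new, Z, H, k)
                    r_new = t - out_new
                    sse_new = float(r_new @ r_new)
                    if not np.isfinite(sse_new):
                        raise DivergenceError(f"non-finite loss at epoch {epoch}")
                    if sse_new < sse:
                        w, sse = w_new, sse_new
                        mu = max(mu * config.mu_dec, 1e-20)
                        accepted = True
                        break
                    mu *= config.mu_inc
                    step_trace.append((epoch, sse_new, mu, False))
                if not accepted:
                    stop_reason = "mu_max_exceeded"
                    epochs_run = epoch
                    break
                out, J = _net_out_and_jac(w, Z, H, k)
                r = t - out
                step_trace.append((epoch, sse, mu, True))
            elif config.algorithm in ("gd", "gda"):
                grad = J.T @ r  # -(1/2) dSSE/dw
                w_new = w + lr * grad
                out_new = _net_out(w_new, Z, H, k)
                r_new = t - out_new
                sse_new = float(r_new @ r_new)
                if not np.isfinite(sse_new):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                if config.algorithm == "gd":
                    w, sse = w_new, sse_new
                    step_trace.append((epoch, sse, lr, True))
                else:
                    if sse_new <= sse:
                        w, sse = w_new, sse_new
                        lr *= config.lr_inc
                        step_trace.append((epoch, sse, lr, True))
                    else:
                        lr *= config.lr_dec
                        step_trace.append((epoch, sse_new, lr, False))
                out, J = _net_out_and_jac(w, Z, H, k)
                r = t - out
            else:
                raise ValueError(f"unknown algorithm {config.algorithm!r}")

            sse_trace.append(sse)
            epochs_run = epoch

            if use_val:
                rv = tv - _net_out(w, Zv, H, k)
                val_sse = float(rv @ rv)
                if val_sse < best_val:
                    best_val = val_sse
                    best_w = w.copy()
                    best_epoch = epoch
                elif epoch - best_epoch >= config.early_stop_patience:
                    stop_reason = "early_stopping"
                    break

            if sse <= config.goal_sse:
                stop_reason = "goal_reached"
                break

    if use_val and np.isfinite(best_val):
        model.set_params(best_w)
    else:
        model.set_params(w)

    report = TrainingReport(
        sse_trace=sse_trace,
        step_trace=step_trace,
        r_train=_split_corr(model, design, "train"),
        r_test=_split_corr(model, design, "test"),
        r_validation=_split_corr(model, design, "validation"),
        stop_reason=stop_reason,
        epochs=epochs_run,
    )
    return model, report


def predict_table(model: NeuralModel, design: DesignTable) -> np.ndarray:
    """Row-wise forward pass over a design, order preserving."""
    return np.asarray(model.forward(design.uncoded), dtype=float)
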