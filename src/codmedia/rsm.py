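"""Second-order response-surface regression.

Fits the full quadratic polynomial

    Y(x) = a0 + Σ a_i x_i + Σ_{i<j} a_ij x_i x_j + Σ a_ii x_i²

to a designed experiment by ordinary least squares, in either coded or
uncoded factor units, and provides predictions, per-term ANOVA
diagnostics, basis conversion, and response-surface slices.  For k
factors the model has 1 + k + k(k-1)/2 + k coefficients (21 for k=5).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .doe import DesignTable, FactorSpec, code_values

__all__ = [
    "QuadraticModel",
    "FitDiagnostics",
    "SingularDesignError",
    "factor_pairs",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "anova_table",
    "surface_slice",
    "convert_basis",
]


class SingularDesignError(ValueError):
    """The quadratic model matrix is rank deficient."""


def factor_pairs(k: int) -> list[tuple[int, int]]:
    """Index pairs (i, j), i<j, in the canonical interaction order."""
    return list(itertools.combinations(range(k), 2))


@dataclass
class QuadraticModel:
    """Coefficients of a full second-order polynomial in k factors.

    ``interactions`` follows :func:`factor_pairs` order.  ``basis``
    records which unit system the coefficients apply to; predictions are
    invariant under :func:`convert_basis`.
    """

    intercept: float
    linear: np.ndarray
    interactions: np.ndarray
    quadratic: np.ndarray
    basis: Literal["coded", "uncoded"] = "uncoded"
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        k = self.k
        if self.quadratic.shape != (k,) or self.interactions.shape != (k * (k - 1) // 2,):
            raise ValueError("inconsistent coefficient vector lengths")
        if not self.factor_names:
            self.factor_names = [f"x{i + 1}" for i in range(k)]

    @property
    def k(self) -> int:
        return len(self.linear)

    @property
    def n_terms(self) -> int:
        return 1 + 2 * self.k + self.k * (self.k - 1) // 2

    def coefficient_vector(self) -> np.ndarray:
        """All coefficients in model-matrix column order."""
        return np.concatenate(
            [[self.intercept], self.linear, self.interactions, self.quadratic]
        )

    def predict(self, x: np.ndarray | Sequence[float]) -> np.ndarray | float:
        """Evaluate the polynomial at one composition or an (n, k) matrix.

        Compositions must be expressed in the model's own basis.
        """
        arr = np.asarray(x, dtype=float)
        single = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if arr.shape[1] != self.k:
            raise ValueError(
                f"composition has length {arr.shape[1]}, expected {self.k}"
            )
        y = model_matrix(arr) @ self.coefficient_vector()
        return float(y[0]) if single else y

    def term_names(self) -> list[str]:
        names = self.factor_names
        out = ["intercept"] + list(names)
        out += [f"{names[i]}:{names[j]}" for i, j in factor_pairs(self.k)]
        out += [f"{n}^2" for n in names]
        return out

    def to_json(self, path: str | Path | None = None, diagnostics: "FitDiagnostics | None" = None) -> str:
        names = self.factor_names
        obj = {
            "basis": self.basis,
            "intercept": self.intercept,
            "linear": {n: float(v) for n, v in zip(names, self.linear)},
            "interactions": {
                f"{names[i]}:{names[j]}": float(v)
                for (i, j), v in zip(factor_pairs(self.k), self.interactions)
            },
            "quadratic": {n: float(v) for n, v in zip(names, self.quadratic)},
        }
        if diagnostics is not None:
            obj["diagnostics"] = {
                "r2": diagnostics.r_squared,
                "r": diagnostics.r,
                "f": diagnostics.f_overall,
                "p": diagnostics.p_overall,
            }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QuadraticModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        obj = json.loads(text)
        names = list(obj["linear"])
        k = len(names)
        inter = np.array(
            [obj["interactions"][f"{names[i]}:{names[j]}"] for i, j in factor_pairs(k)]
        )
        return cls(
            intercept=float(obj["intercept"]),
            linear=np.array([obj["linear"][n] for n in names]),
            interactions=inter,
            quadratic=np.array([obj["quadratic"][n] for n in names]),
            basis=obj.get("basis", "uncoded"),
            factor_names=names,
        )


@dataclass
class FitDiagnostics:
    """Goodness-of-fit summary of an OLS quadratic fit."""

    r_squared: float
    r: float
    f_overall: float
    p_overall: float
    residuals: np.ndarray
    dof_model: int
    dof_error: int


def model_matrix(X: np.ndarray) -> np.ndarray:
    """Expand an (n, k) factor matrix into the (n, 21) quadratic basis.

    Column order: intercept, k linear, k(k-1)/2 interactions
    (:func:`factor_pairs` order), k squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, i] for i in range(k))
    cols.extend(X[:, i] * X[:, j] for i, j in factor_pairs(k))
    cols.extend(X[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


def _check_rank(M: np.ndarray, term_names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the dependent columns via pivoted QR
        _, _, piv = linalg.qr(M, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        raise SingularDesignError(
            "model matrix is rank deficient; collinear terms: "
            + ", ".join(term_names[i] for i in bad)
        )


def fit_quadratic(
    design: DesignTable, basis: Literal["coded", "uncoded"] = "uncoded"
) -> tuple[QuadraticModel, FitDiagnostics]:
    """OLS fit of the full quadratic surface to a design's observed column."""
    y = design.observed
    if np.isnan(y).any():
        raise ValueError("design has missing observed responses")
    X = design.coded if basis == "coded" else design.uncoded
    n, k = X.shape
    p = 1 + 2 * k + k * (k - 1) // 2
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} terms, have {n}")
    M = model_matrix(X)

    names = ["intercept"] + design.factor_names
    names += [
        f"{design.factor_names[i]}:{design.factor_names[j]}"
        for i, j in factor_pairs(k)
    ]
    names += [f"{nm}^2" for nm in design.factor_names]
    _check_rank(M, names)

    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    dof_model = p - 1
    dof_error = n - p
    ssr = sst - sse
    f_overall = (ssr / dof_model) / (sse / dof_error) if dof_error > 0 else np.inf
    p_overall = float(stats.f.sf(f_overall, dof_model, dof_error))

    n_int = k * (k - 1) // 2
    model = QuadraticModel(
        intercept=float(beta[0]),
        linear=beta[1 : 1 + k],
        interactions=beta[1 + k : 1 + k + n_int],
        quadratic=beta[1 + k + n_int :],
        basis=basis,
        factor_names=design.factor_names,
    )
    diag = FitDiagnostics(
        r_squared=r2,
        r=float(np.sqrt(r2)),
        f_overall=float(f_overall),
        p_overall=p_overall,
        residuals=resid,
        dof_model=dof_model,
        dof_error=dof_error,
    )
    return model, diag


def predict(model: QuadraticModel, composition: np.ndarray | Sequence[float]):
    """Functional alias for :meth:`QuadraticModel.predict`."""
    return model.predict(composition)


def _anova_term_order(names: Sequence[str], k: int) -> list[str]:
    """Intercept, then each factor's linear and square term, then the
    interactions ordered by the higher factor index (1·2, 1·3, 2·3, ...)."""
    out = ["intercept"]
    for i in range(k):
        out.append(names[i])
        out.append(f"{names[i]}^2")
    for j in range(1, k):
        for i in range(j):
            out.append(f"{names[i]}:{names[j]}")
    return out


def anova_table(model: QuadraticModel, design: DesignTable) -> pd.DataFrame:
    """Per-term type-III ANOVA of the quadratic fit.

    Each term's sum of squares is the increase in residual SS when that
    single column is dropped from the full model; F = SS / MS_error with
    (1, dof_error) degrees of freedom.  Returns a DataFrame with columns
    term, sum_of_squares, standard_error, mean_square, f_value, p_value.
    """
    y = design.observed
    X = design.coded if model.basis == "coded" else design.uncoded
    M = model_matrix(X)
    n, p = M.shape
    dof_error = n - p
    if dof_error < 1:
        raise ValueError("no residual degrees of freedom; ANOVA unavailable")

    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    sse_full = float(resid @ resid)
    mse = sse_full / dof_error

    # coefficient standard errors from (M'M)^-1
    xtx_inv = np.linalg.inv(M.T @ M)
    se = np.sqrt(mse * np.diag(xtx_inv))

    rows = {}
    all_names = model.term_names()
    for idx, term in enumerate(all_names):
        M_red = np.delete(M, idx, axis=1)
        b_red, _, _, _ = np.linalg.lstsq(M_red, y, rcond=None)
        r_red = y - M_red @ b_red
        ss = float(r_red @ r_red) - sse_full
        ss = max(ss, 0.0)
        f_val = ss / mse
        rows[term] = {
            "term": term,
            "sum_of_squares": ss,
            "standard_error": float(se[idx]),
            "mean_square": ss,  # 1 df per term
            "f_value": f_val,
            "p_value": float(stats.f.sf(f_val, 1, dof_error)),
        }
    order = _anova_term_order(model.factor_names, model.k)
    return pd.DataFrame([rows[t] for t in order]).set_index("term")


def surface_slice(
    model: QuadraticModel,
    var_i: int,
    var_j: int,
    factors: Sequence[FactorSpec],
    fixed: np.ndarray | Sequence[float] | None = None,
    grid_n: int = 21,
) -> pd.DataFrame:
    """Predicted response over a 2-D lattice in factors i and j.

    The grid spans each factor's design box [low star, high star] with
    ``grid_n`` points per axis; the remaining factors are held at
    ``fixed`` (default: their centers).  Returns a long-format DataFrame
    with the two factor columns and ``predicted``.
    """
    if var_i == var_j:
        raise ValueError("var_i and var_j must differ")
    factors = list(factors)
    k = len(factors)
    base = np.array([f.center for f in factors]) if fixed is None else np.asarray(
        fixed, dtype=float
    )
    if base.shape != (k,):
        raise ValueError(f"fixed vector must have length {k}")
    gi = np.linspace(*factors[var_i].bounds, grid_n)
    gj = np.linspace(*factors[var_j].bounds, grid_n)
    II, JJ = np.meshgrid(gi, gj, indexing="ij")
    pts = np.tile(base, (grid_n * grid_n, 1))
    pts[:, var_i] = II.ravel()
    pts[:, var_j] = JJ.ravel()
    if model.basis == "coded":
        pts_eval = code_values(pts, factors)
    else:
        pts_eval = pts
    z = model.predict(pts_eval)
    return pd.DataFrame(
        {
            factors[var_i].name: pts[:, var_i],
            factors[var_j].name: pts[:, var_j],
            "predicted": z,
        }
    )


def convert_basis(
    model: QuadraticModel,
    factors: Sequence[FactorSpec],
    to: Literal["coded", "uncoded"],
) -> QuadraticModel:
    """Re-express the polynomial's coefficients in the other unit system.

    Uses the affine substitution x = c + h·z (or its inverse) on the
    quadratic form; predictions are unchanged to machine precision.
    """
    if model.basis == to:
        return model
    k = model.k
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])

    # express as y = a0 + a'v + v'Av with symmetric A
    A = np.diag(model.quadratic.astype(float))
    for (i, j), val in zip(factor_pairs(k), model.interactions):
        A[i, j] += val / 2.0
        A[j, i] += val / 2.0
    a = model.linear.astype(float)
    a0 = float(model.intercept)

    if model.basis == "coded" and to == "uncoded":
        # v = (x - c) / h  ->  substitute
        D = np.diag(1.0 / halves)
        B = D @ A @ D
        b = D @ a - 2.0 * B @ centers
        b0 = a0 - a @ (centers / halves) + centers @ B @ centers
    else:
        # v = c + h z ... wait: uncoded -> coded, x = c + h*z
        H = np.diag(halves)
        B = H @ A @ H
        b = H @ a + 2.0 * H @ A @ centers
        b0 = a0 + a @ centers + centers @ A @ centers

    inter = np.array([2.0 * B[i, j] for i, j in factor_pairs(k)])
    return QuadraticModel(
        intercept=float(b0),
        linear=b,
        interactions=inter,
        quadratic=np.diag(B).copy(),
        basis=to,
        factor_names=model.factor_names,
    )
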