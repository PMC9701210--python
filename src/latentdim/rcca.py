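"""Regularised canonical correlation analysis (RCCA).

Two row-aligned views ``X`` (n participants x p features, e.g. parcel-wise
brain structure) and ``Y`` (n x q, e.g. behavioural scores) are linked by a
pair of weight vectors ``(u, v)`` maximising the cross-view covariance
``u' Cxy v`` subject to regularised unit-variance constraints

    u' [(1 - c_x) Cxx + c_x I] u = 1,
    v' [(1 - c_y) Cyy + c_y I] v = 1,

where ``Cxx, Cyy, Cxy`` are (co)variance matrices with an ``n - 1`` divisor
and ``c_x, c_y`` in [0, 1] interpolate between classical CCA (c = 0) and a
PLS-like solution (c = 1).  The reported canonical correlation is always the
plain Pearson correlation between the score vectors ``Xu`` and ``Yv``.

The solver works in the participant-space basis: each view is reduced by an
economy SVD, so the cost is governed by ``n`` even when the number of
features far exceeds the number of participants.  Weights always lie in the
row space of the training data, which is where the optimum lives for any
c > 0 and is the canonical minimum-norm choice at c = 0.

Successive dimensions are obtained by projection deflation: the rank-one
component of each view along its own score vector is removed, which makes
successive scores orthogonal on the deflating set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RccaModel",
    "ScorePair",
    "LoadingSet",
    "Deflator",
    "fit_rcca",
    "project",
    "compute_loadings",
    "deflate",
    "make_deflator",
]

#: relative threshold below which singular values are treated as zero
SINGULAR_VALUE_TOL = 1e-10


class DegenerateDataError(ValueError):
    """Raised when a view carries no usable variance or n is too small."""


@dataclass
class RccaModel:
    """A fitted weight pair for one latent dimension.

    ``train_corr`` is the Pearson correlation of the training scores.  The
    sign convention is fixed so that the behavioural loading of largest
    magnitude on the training set is positive; ``(u, v)`` and ``(-u, -v)``
    describe the same model.
    """

    u: np.ndarray
    v: np.ndarray
    c_x: float
    c_y: float
    train_corr: float
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_train: int

    def to_dict(self) -> dict:
        return {
            "c_x": self.c_x,
            "c_y": self.c_y,
            "train_corr": self.train_corr,
            "n_train": self.n_train,
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RccaModel":
        return cls(
            u=np.asarray(d["u"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            c_x=float(d["c_x"]),
            c_y=float(d["c_y"]),
            train_corr=float(d["train_corr"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            n_train=int(d["n_train"]),
        )


@dataclass
class ScorePair:
    """Per-participant projections of the two views onto the weights."""

    brain: np.ndarray  # Xu
    behaviour: np.ndarray  # Yv

    def corr(self) -> float:
        """Pearson correlation between the two score vectors."""
        sb = self.brain - self.brain.mean()
        sv = self.behaviour - self.behaviour.mean()
        nb, nv = np.linalg.norm(sb), np.linalg.norm(sv)
        if nb <= 0 or nv <= 0:
            raise DegenerateDataError(
                "constant score vector: canonical correlation is undefined"
            )
        return float(sb @ sv / (nb * nv))


@dataclass
class LoadingSet:
    """Pearson correlations of the original variables with the scores.

    Zero-variance variables get NaN (an explicit undefined marker), never a
    silent zero.
    """

    brain: pd.Series
    behaviour: pd.Series


def _check_views(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D matrices")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"views are not row-aligned: {X.shape[0]} vs {Y.shape[0]} rows"
        )
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not allowed")
    return X, Y


def fit_rcca(X: np.ndarray, Y: np.ndarray, c_x: float, c_y: float) -> RccaModel:
    """Fit the leading regularised canonical weight pair.

    Parameters
    ----------
    X, Y
        Row-aligned data matrices.  Centering is performed internally on the
        rows passed in (the fitting set); pre-centered input is unaffected.
    c_x, c_y
        Regularisation parameters in [0, 1].
    """
    X, Y = _check_views(X, Y)
    n = X.shape[0]
    if n < 3:
        raise DegenerateDataError(f"need at least 3 samples to fit, got {n}")
    if not (0.0 <= c_x <= 1.0 and 0.0 <= c_y <= 1.0):
        raise ValueError("regularisation parameters must lie in [0, 1]")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    Ux, sx, Vxt = np.linalg.svd(Xc, full_matrices=False)
    Uy, sy, Vyt = np.linalg.svd(Yc, full_matrices=False)
    kx = sx > SINGULAR_VALUE_TOL * (sx[0] if sx.size else 0.0)
    ky = sy > SINGULAR_VALUE_TOL * (sy[0] if sy.size else 0.0)
    if not kx.any():
        raise DegenerateDataError("view X has zero variance")
    if not ky.any():
        raise DegenerateDataError("view Y has zero variance")
    Ux, sx, Vxt = Ux[:, kx], sx[kx], Vxt[kx]
    Uy, sy, Vyt = Uy[:, ky], sy[ky], Vyt[ky]

    # regularised variances along each principal direction
    dx = (1.0 - c_x) * sx**2 / (n - 1) + c_x
    dy = (1.0 - c_y) * sy**2 / (n - 1) + c_y

    # whitened cross-covariance in the participant-space basis
    K = (sx[:, None] * (Ux.T @ Uy) * sy[None, :]) / (n - 1)
    K /= np.sqrt(dx)[:, None]
    K /= np.sqrt(dy)[None, :]

    A, sig, Bt = np.linalg.svd(K)
    a = A[:, 0] / np.sqrt(dx)
    b = Bt[0] / np.sqrt(dy)
    u = Vxt.T @ a
    v = Vyt.T @ b

    scores = ScorePair(Xc @ u, Yc @ v)
    train_corr = scores.corr()

    # sign convention: largest-magnitude behavioural loading is positive
    y_sd = Yc.std(axis=0, ddof=1)
    s_beh = scores.behaviour - scores.behaviour.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        load = (Yc.T @ s_beh) / ((n - 1) * y_sd * s_beh.std(ddof=1))
    load = np.where(np.isfinite(load), load, 0.0)
    j = int(np.argmax(np.abs(load)))
    if load[j] < 0:
        # flipping both weights flips both scores; their correlation is
        # unchanged, so train_corr needs no update
        u, v = -u, -v

    return RccaModel(
        u=u, v=v, c_x=float(c_x), c_y=float(c_y),
        train_corr=train_corr, x_mean=x_mean, y_mean=y_mean, n_train=n,
    )


def project(model: RccaModel, X: np.ndarray, Y: np.ndarray) -> ScorePair:
    """Project data onto a fitted weight pair (training means subtracted)."""
    X, Y = _check_views(X, Y)
    if X.shape[1] != model.u.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but model expects {model.u.shape[0]}"
        )
    if Y.shape[1] != model.v.shape[0]:
        raise ValueError(
            f"Y has {Y.shape[1]} columns but model expects {model.v.shape[0]}"
        )
    return ScorePair((X - model.x_mean) @ model.u, (Y - model.y_mean) @ model.v)


def _column_corrs(M: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with a score vector."""
    Mc = M - M.mean(axis=0)
    s = score - score.mean()
    s_norm = np.linalg.norm(s)
    col_norm = np.linalg.norm(Mc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc.T @ s) / (col_norm * s_norm)
    r[col_norm <= 0] = np.nan
    return r


def compute_loadings(
    X_orig: np.ndarray,
    Y_orig: np.ndarray,
    scores: ScorePair,
    brain_names=None,
    behaviour_names=None,
) -> LoadingSet:
    """Correlate each original variable with its view's score vector."""
    X_orig, Y_orig = _check_views(X_orig, Y_orig)
    if X_orig.shape[0] != scores.brain.shape[0]:
        raise ValueError("scores are not row-aligned with the data")
    bl = _column_corrs(X_orig, scores.brain)
    yl = _column_corrs(Y_orig, scores.behaviour)
    if brain_names is None:
        brain_names = [f"x{i}" for i in range(X_orig.shape[1])]
    if behaviour_names is None:
        behaviour_names = [f"y{i}" for i in range(Y_orig.shape[1])]
    return LoadingSet(
        brain=pd.Series(bl, index=list(brain_names)),
        behaviour=pd.Series(yl, index=list(behaviour_names)),
    )


@dataclass
class Deflator:
    """Out-of-sample projection deflation operator for one fitted dimension.

    Built from the set the model was fitted on; applying it to new rows
    removes the same rank-one component, so deflation of optimisation and
    holdout data stays leakage-free.
    """

    model: RccaModel
    qx: np.ndarray = field(repr=False)
    qy: np.ndarray = field(repr=False)

    def apply(self, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scores = project(self.model, X, Y)
        Xd = (X - self.model.x_mean) - np.outer(scores.brain, self.qx)
        Yd = (Y - self.model.y_mean) - np.outer(scores.behaviour, self.qy)
        return Xd, Yd


def make_deflator(X: np.ndarray, Y: np.ndarray, model: RccaModel) -> Deflator:
    """Build a deflator from the deflating set (typically the fitting set)."""
    X, Y = _check_views(X, Y)
    scores = project(model, X, Y)
    sx, sy = scores.brain, scores.behaviour
    nx, ny = sx @ sx, sy @ sy
    if nx <= 0 or ny <= 0:
        raise DegenerateDataError("zero-norm score: cannot deflate")
    Xc = X - model.x_mean
    Yc = Y - model.y_mean
    return Deflator(model=model, qx=(Xc.T @ sx) / nx, qy=(Yc.T @ sy) / ny)


def deflate(X: np.ndarray, Y: np.ndarray, model: RccaModel) -> tuple[np.ndarray, np.ndarray]:
    """Projection-deflate both views on the given rows.

    The returned matrices are centered with the model's training means; on
    the deflating set ``X_deflated @ u`` is zero to numerical precision.
    """
    return make_deflator(X, Y, model).apply(X, Y)
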