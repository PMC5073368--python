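"""Reference firmness and PLSR firmness prediction from mean spectra.

Firmness is the slope (N/mm) of the force/deformation curve of a berry
compressed between parallel plates, fitted by least squares over the
0.5--2.5 mm displacement window where the curve is close to linear.

For non-destructive prediction, partial least squares regression (PLSR)
relates each berry's mean reflectance spectrum (141 collinear bands) to
its measured firmness.  Components are latent directions of maximal
predictor-response covariance extracted iteratively (NIPALS); their
number is chosen by 10-fold cross-validation minimizing RMSEP unless
given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.linalg import matrix_rank
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .cube import HyperCube
from .segment import LabelMap

__all__ = [
    "FirmnessCurve",
    "PLSRModel",
    "firmness_slope",
    "mean_spectrum",
    "plsr_fit",
    "plsr_predict",
    "rmsep",
    "SLOPE_WINDOW_MM",
]

SLOPE_WINDOW_MM = (0.5, 2.5)
"""Displacement window (mm) over which the firmness slope is fitted."""


@dataclass
class FirmnessCurve:
    """Force/deformation record of one compression test."""

    deformation: np.ndarray  # mm, strictly increasing
    force: np.ndarray  # N

    def __post_init__(self) -> None:
        self.deformation = np.asarray(self.deformation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.deformation.shape != self.force.shape or self.deformation.ndim != 1:
            raise ValueError("deformation and force must be equal-length 1-D arrays")
        if np.any(np.diff(self.deformation) <= 0):
            raise ValueError("deformation samples must be strictly increasing")
        if self.deformation[0] < 0:
            raise ValueError("deformation must start at >= 0 mm")


def firmness_slope(
    curve: FirmnessCurve, window_mm: tuple[float, float] = SLOPE_WINDOW_MM
) -> float:
    """Least-squares slope (N/mm) of force vs deformation inside the window."""
    lo, hi = window_mm
    sel = (curve.deformation >= lo) & (curve.deformation <= hi)
    if sel.sum() < 2:
        raise ValueError(
            f"need >= 2 samples inside [{lo}, {hi}] mm, found {int(sel.sum())}"
        )
    slope, _ = np.polyfit(curve.deformation[sel], curve.force[sel], 1)
    return float(slope)


def mean_spectrum(cube: HyperCube, labelmap: LabelMap, berry_id: int) -> np.ndarray:
    """Per-band mean reflectance over one berry's pixels.

    All berry pixels contribute, including the calyx disc: the exclusion
    rule applies to tissue classification, not to whole-fruit spectra.
    """
    mask = labelmap.berry_mask(berry_id)
    if not mask.any():
        raise ValueError(f"berry {berry_id} has no pixels")
    return cube.data[mask].mean(axis=0)


@dataclass
class PLSRModel:
    """Fitted PLSR with centering vectors and training diagnostics."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # regression vector on centered predictors
    training_rmse: float
    cv_rmsep: float | None = None  # set when n_components was chosen by CV

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"predictors have {X.shape[1]} bands, model expects {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean


def _fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    return pls


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    max_components: int = 20,
    cv_folds: int = 10,
    seed: int = 0,
) -> PLSRModel:
    """Fit PLSR of a response on spectra.

    With ``n_components=None`` the count is selected by k-fold
    cross-validation minimizing RMSEP over 1..min(max_components, rank).
    Deterministic for fixed inputs and seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to regress")
    rank = matrix_rank(X - X.mean(axis=0))
    cv_rmsep = None
    if n_components is None:
        kmax = int(min(max_components, rank))
        folds = min(cv_folds, X.shape[0])
        errors = []
        for k in range(1, kmax + 1):
            preds = np.empty_like(y)
            for tr, te in KFold(folds, shuffle=True, random_state=seed).split(X):
                pls = _fit_pls(X[tr], y[tr], min(k, matrix_rank(X[tr] - X[tr].mean(0))))
                preds[te] = pls.predict(X[te]).ravel()
            errors.append(rmsep(preds, y))
        n_components = int(np.argmin(errors)) + 1
        cv_rmsep = float(min(errors))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds predictor rank {rank}")
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    pls = _fit_pls(X, y, n_components)
    coef = pls.coef_.reshape(-1)
    model = PLSRModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        coef=coef,
        training_rmse=0.0,
        cv_rmsep=cv_rmsep,
    )
    model.training_rmse = rmsep(model.predict(X), y)
    return model


def plsr_predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predicted firmness for each spectrum row."""
    return model.predict(X)


def rmsep(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean squared error of prediction."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.size != observed.size:
        raise ValueError("predicted and observed lengths differ")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))
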