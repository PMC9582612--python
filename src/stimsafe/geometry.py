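"""Geometric correction factor from resistivity–resistance calibration.

For a 4-contact measurement in a solution of resistivity rho, the measured
bulk resistance is R = rho * G / (4*pi): G captures how the contact
diameter and inter-contact separation confine the current-spreading volume.
G/(4*pi) is the slope of the rho–R line, fit through the origin because the
relation has no offset term; an optional intercept diagnoses electrode
polarization leaking into the 4-contact measurement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import GeometricFactor

__all__ = [
    "fit_geometric_factor",
    "conductivity_to_resistivity",
    "GeometricFactorEstimator",
]


def conductivity_to_resistivity(sigma: float) -> float:
    """Resistivity (ohm*m) from measured conductivity (S/m)."""
    if sigma <= 0:
        raise ValueError("conductivity must be > 0")
    return 1.0 / sigma


class GeometricFactorEstimator(BaseEstimator, RegressorMixin):
    """Least-squares line R = rho * G/(4*pi), through the origin by default.

    Attributes
    ----------
    g_ : float
        Geometric correction factor (1/m).
    slope_se_ : float
        Standard error of the regression slope.
    intercept_ : float
        0 when ``with_intercept`` is False; otherwise the fitted offset
        (ohm), a diagnostic for interface leakage into the 4-contact
        measurement.
    """

    def __init__(self, with_intercept: bool = False):
        self.with_intercept = with_intercept

    def fit(self, X, y):
        rho = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=float).ravel()
        if rho.size != r.size or rho.size < 3:
            raise ValueError("need >= 3 (rho, R) points with matching lengths")
        if np.any(rho <= 0) or np.any(r <= 0):
            raise ValueError("resistivities and resistances must be > 0")
        n = rho.size
        if self.with_intercept:
            a_mat = np.column_stack([rho, np.ones(n)])
        else:
            a_mat = rho[:, None]
        coef, *_ = np.linalg.lstsq(a_mat, r, rcond=None)
        slope = float(coef[0])
        self.intercept_ = float(coef[1]) if self.with_intercept else 0.0
        if slope <= 0:
            raise ValueError("non-positive fitted slope; check the calibration series")
        resid = r - a_mat @ coef
        dof = n - a_mat.shape[1]
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(a_mat.T @ a_mat)
            self.slope_se_ = float(np.sqrt(cov[0, 0]))
        else:
            self.slope_se_ = 0.0
        self.g_ = 4 * np.pi * slope
        self.n_points_ = n
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "g_")
        return np.asarray(X, dtype=float).ravel() * self.g_ / (4 * np.pi) + self.intercept_

    @property
    def params_(self) -> GeometricFactor:
        check_is_fitted(self, "g_")
        return GeometricFactor(
            g=self.g_, slope_se=4 * np.pi * self.slope_se_, n_points=self.n_points_
        )


def fit_geometric_factor(
    rho: Sequence[float], r: Sequence[float], with_intercept: bool = False
) -> GeometricFactor:
    """Fit G = 4*pi*R/rho from a calibration series; see
    :class:`GeometricFactorEstimator`."""
    return GeometricFactorEstimator(with_intercept=with_intercept).fit(rho, r).params_
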