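"""Predictive cathodal-excitation model and safe-current limits.

The central quantity is the cathodal excitation V_elec: the slow polarization
built up at the electrode interface during the cathodal charge-injection
phase, after discarding the instantaneous access drop.  Its dependence on
injected current I, pulse width t_pw and interface reactance |Z_imag| is
captured by the saturating-log law

    V_elec = a * ln(b * |I|**k2 * t_pw**k4 * |Z_imag|**k6 + 1)

fit on magnitudes (cathodal potentials are negative; the sign is restored at
reporting).  Because the units of b depend on the fitted exponents, fitting
is performed on scaled inputs (microamps, microseconds, kiloohms by default)
and the convention is recorded with the parameters.

Inverting the law at the cathodal electrolysis threshold E_mc gives the safe
current limit; substituting the impedance–diameter power law |Z_imag| =
alpha * D**d1 expresses the limit as a function of contact diameter, which
is compared against the empirical Shannon charge-density boundary
log10(D) = k − log10(Q).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .types import (
    SafetyParams,
    ScalingParams,
    ShannonResult,
    SingleFactorParams,
    UnitConvention,
)

__all__ = [
    "predict_velec",
    "fit_single_factor",
    "fit_full_model",
    "invert_ilimit",
    "ilimit_vs_diameter",
    "shannon_limit",
    "holdout_transfer",
    "adjusted_r2",
    "electric_field",
    "double_layer_field_ratio",
    "CathodalExcitationModel",
    "SingleFactorModel",
]

_EXP_BOUNDS = (1e-6, 3.0)
_B_DECADES = np.logspace(-6, 2, 9)


# --------------------------------------------------------------------------
# forward law, inverse, auxiliary arithmetic
# --------------------------------------------------------------------------


def predict_velec(p: SafetyParams, i_inj, t_pw, z_imag) -> np.ndarray | float:
    """Cathodal excitation magnitude (V) for SI inputs (A, s, ohm).

    Returns 0 whenever any of the three factors is 0 (ln 1 = 0).
    """
    i_inj = np.asarray(i_inj, dtype=float)
    t_pw = np.asarray(t_pw, dtype=float)
    z_imag = np.asarray(z_imag, dtype=float)
    if np.any(i_inj < 0) or np.any(t_pw < 0) or np.any(z_imag < 0):
        raise ValueError("i_inj, t_pw and z_imag must be >= 0 (magnitudes)")
    u = p.unit_convention
    x = (
        p.b
        * (i_inj / u.current_scale_a) ** p.k2
        * (t_pw / u.time_scale_s) ** p.k4
        * (z_imag / u.impedance_scale_ohm) ** p.k6
    )
    v = p.a * np.log1p(x)
    return v if v.ndim else float(v)


def invert_ilimit(p: SafetyParams, e_mc: float, t_pw: float, z_imag: float) -> float:
    """Closed-form safe-current limit: the current at which V_elec = |E_mc|.

    ``e_mc`` is the cathodal electrolysis threshold magnitude (V).
    """
    if e_mc < 0:
        raise ValueError("e_mc must be a magnitude (>= 0)")
    if t_pw <= 0 or z_imag <= 0:
        raise ValueError("t_pw and z_imag must be > 0")
    u = p.unit_convention
    ts = t_pw / u.time_scale_s
    zs = z_imag / u.impedance_scale_ohm
    i_scaled = (np.expm1(e_mc / p.a) / (p.b * ts**p.k4 * zs**p.k6)) ** (1.0 / p.k2)
    return float(i_scaled * u.current_scale_a)


def ilimit_vs_diameter(
    p: SafetyParams,
    s: ScalingParams,
    e_mc: float,
    t_pw: float,
    diameter: float,
) -> float:
    """Safe-current limit vs contact diameter.

    Literal substitution of the impedance–diameter power law into the
    current-limit inverse, guaranteeing mutual consistency of the two forms.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return invert_ilimit(p, e_mc, t_pw, float(s.reactance(diameter)))


def shannon_limit(diameter: float, t_pw: float, k: float = 1.8) -> ShannonResult:
    """Charge-per-phase limit from the log-linear damage boundary.

    Solving log10(Q/A) = k − log10(Q) gives Q = sqrt(A * 10**k) with A the
    contact area in cm^2 and Q in uC/phase; the current limit is Q / t_pw.
    """
    if diameter <= 0 or t_pw <= 0:
        raise ValueError("diameter and t_pw must be > 0")
    area_cm2 = np.pi * (diameter * 100.0 / 2.0) ** 2
    q_uc = float(np.sqrt(area_cm2 * 10.0**k))
    return ShannonResult(
        k=k,
        q_per_phase_uc=q_uc,
        charge_density_uc_cm2=q_uc / area_cm2,
        area_cm2=area_cm2,
        i_limit_a=q_uc * 1e-6 / t_pw,
        t_pw_s=t_pw,
    )


def adjusted_r2(obs, pred, n_params: int) -> float:
    """Adjusted coefficient of determination, 1 − (1−R²)(N−1)/(N−p−1)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D arrays of equal length")
    n = obs.size
    if n <= n_params + 1:
        raise ValueError(f"need N > n_params + 1 (got N={n}, p={n_params})")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def electric_field(voltage: float, thickness_m: float) -> float:
    """Mean electric field (V/cm) across a layer of the given thickness."""
    if thickness_m <= 0:
        raise ValueError("thickness must be > 0")
    return voltage / (thickness_m * 100.0)


def double_layer_field_ratio(
    v_dl: float = 1.0,
    d_dl_m: float = 1e-9,
    v_spread: float = 10.0,
    d_spread_m: float = 10e-6,
) -> float:
    """Ratio of the double-layer field to the current-crowding-region field.

    With the defaults (1 V across 1 nm vs 10 V across 10 um) the double-layer
    field is 10 MV/cm, the spreading-region field 10 kV/cm, ratio 1000 —
    the scale separation that justifies discarding instantaneous ohmic drops
    when reading the interface polarization.
    """
    return electric_field(v_dl, d_dl_m) / electric_field(v_spread, d_spread_m)


# --------------------------------------------------------------------------
# single-factor law
# --------------------------------------------------------------------------


class SingleFactorModel(BaseEstimator, RegressorMixin):
    """One-factor excitation law |V| = ln(k_scale * x**k_exp + 1).

    ``x`` is one of injected current, pulse width or reactance, already
    expressed in the fitting scale; the other factors are absorbed into
    k_scale.  Used mainly to initialise the full-surface fit.

    Attributes
    ----------
    k_scale_, k_exp_ : float
        Fitted scale and exponent.
    adj_r2_ : float
    degenerate_ : bool
        True when the response carries no signal (all-zero v).
    at_bound_ : bool
        True when k_exp_ is pinned at an optimisation bound.
    """

    def __init__(self, factor: str = "current", exp_bounds: tuple = _EXP_BOUNDS):
        self.factor = factor
        self.exp_bounds = exp_bounds

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if x.size != v.size or x.size < 5:
            raise ValueError("need >= 5 points with matching lengths")
        if np.any(x <= 0):
            raise ValueError("factor values must be > 0")
        if np.any(v < 0):
            raise ValueError("excitations are magnitudes, must be >= 0")
        if self.factor not in ("current", "pulse_width", "impedance"):
            raise ValueError(f"unknown factor {self.factor!r}")

        if np.all(v == 0):
            self.k_scale_, self.k_exp_ = 0.0, 1.0
            self.degenerate_, self.at_bound_ = True, False
            self.adj_r2_ = float("nan")
            self.n_features_in_ = 1
            return self

        # log-linearisation: ln(exp(v) - 1) = ln k_scale + k_exp * ln x
        mask = v > 1e-12
        lx, lv = np.log(x[mask]), np.log(np.expm1(v[mask]))
        slope, intercept = np.polyfit(lx, lv, 1)
        k_exp0 = float(np.clip(slope, *self.exp_bounds))
        k_scale0 = float(np.exp(intercept))

        def resid(theta):
            return np.log1p(np.exp(theta[0]) * x ** theta[1]) - v

        sol = optimize.least_squares(
            resid,
            x0=[np.log(max(k_scale0, 1e-300)), k_exp0],
            bounds=([-np.inf, self.exp_bounds[0]], [np.inf, self.exp_bounds[1]]),
        )
        if not sol.success:
            raise RuntimeError(
                f"single-factor fit did not converge; residual norm {sol.cost:.3e}"
            )
        self.k_scale_ = float(np.exp(sol.x[0]))
        self.k_exp_ = float(sol.x[1])
        self.degenerate_ = False
        self.at_bound_ = bool(
            np.isclose(self.k_exp_, self.exp_bounds[0])
            or np.isclose(self.k_exp_, self.exp_bounds[1])
        )
        self.adj_r2_ = adjusted_r2(v, np.log1p(self.k_scale_ * x**self.k_exp_), 2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "k_scale_")
        x = np.asarray(X, dtype=float).ravel()
        return np.log1p(self.k_scale_ * x**self.k_exp_)

    @property
    def params_(self) -> SingleFactorParams:
        check_is_fitted(self, "k_scale_")
        return SingleFactorParams(
            factor=self.factor,
            k_scale=self.k_scale_ if not self.degenerate_ else 0.0,
            k_exp=self.k_exp_,
            adj_r2=self.adj_r2_,
            degenerate=self.degenerate_,
        )


def fit_single_factor(factor: str, x: Sequence[float], v: Sequence[float]) -> SingleFactorParams:
    """Fit the one-factor law; see :class:`SingleFactorModel`."""
    return SingleFactorModel(factor=factor).fit(x, v).params_


# --------------------------------------------------------------------------
# full-surface model
# --------------------------------------------------------------------------


class CathodalExcitationModel(BaseEstimator, RegressorMixin):
    """Full cathodal-excitation surface V = a*ln(b*I^k2*t^k4*Z^k6 + 1).

    Parameters
    ----------
    fix_k2, fix_k4, fix_k6 : float or None
        Freeze an exponent instead of fitting it.  Freezing k6 is the
        standard move when the dataset holds the reactance constant (its
        contribution is then absorbed into b).
    units : UnitConvention
        Scales applied to (I, t_pw, Z) before fitting; b is reported under
        this convention.
    b_grid : sequence of float
        Multi-start grid of initial b values (the ln(1+x) law has a flat
        region that a single start can stall in).
    exp_bounds : (float, float)
        Box bounds for the fitted exponents.
    residual : {"relative", "absolute"}
        "relative" (default) minimises log-excitation misfit — the
        maximum-likelihood choice under multiplicative measurement noise,
        and the one that lets the small-excitation records anchor b.
        "absolute" minimises plain volt misfit; required when any observed
        excitation is zero.

    The design matrix X has three columns in SI units: injected current (A),
    pulse width (s), reactance magnitude (ohm); y holds excitation
    magnitudes (V).
    """

    def __init__(
        self,
        fix_k2: Optional[float] = None,
        fix_k4: Optional[float] = None,
        fix_k6: Optional[float] = None,
        units: UnitConvention = UnitConvention(),
        b_grid: Sequence[float] = tuple(_B_DECADES),
        exp_bounds: tuple = _EXP_BOUNDS,
        residual: str = "relative",
    ):
        self.fix_k2 = fix_k2
        self.fix_k4 = fix_k4
        self.fix_k6 = fix_k6
        self.units = units
        self.b_grid = b_grid
        self.exp_bounds = exp_bounds
        self.residual = residual

    # -- helpers -----------------------------------------------------------

    def _scaled(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3): current A, pulse width s, reactance ohm")
        u = self.units
        return X / np.array([u.current_scale_a, u.time_scale_s, u.impedance_scale_ohm])

    @staticmethod
    def _check_variation(Xs, fixed) -> None:
        names = ("current", "pulse_width", "impedance")
        for j, name in enumerate(names):
            if fixed[j] is None and len(np.unique(Xs[:, j])) < 2:
                raise ValueError(
                    f"rank-deficient design: factor {name!r} is constant; "
                    f"fix its exponent (fix_k{2 * (j + 1)}) or vary it"
                )

    def _init_exponents(self, Xs, y, fixed) -> list[float]:
        """Exponent initialisation from single-factor fits.

        For each free factor, take the largest subset of records in which the
        other two factors are constant and fit the one-factor law; fall back
        to 1.0 when no informative subset exists.
        """
        inits = []
        for j in range(3):
            if fixed[j] is not None:
                inits.append(fixed[j])
                continue
            others = [k for k in range(3) if k != j]
            uniq, counts = np.unique(Xs[:, others], axis=0, return_counts=True)
            best = uniq[np.argmax(counts)]
            mask = np.all(np.isclose(Xs[:, others], best), axis=1)
            k_exp = 1.0
            if mask.sum() >= 5 and np.any(y[mask] > 0):
                try:
                    k_exp = SingleFactorModel().fit(Xs[mask, j], y[mask]).k_exp_
                except (ValueError, RuntimeError):
                    pass
            inits.append(float(np.clip(k_exp, *self.exp_bounds)))
        return inits

    # -- sklearn interface -------------------------------------------------

    def fit(self, X, y):
        Xs = self._scaled(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != Xs.shape[0]:
            raise ValueError("X and y length mismatch")
        if y.size < 10:
            raise ValueError("need >= 10 records")
        if np.any(Xs <= 0):
            raise ValueError("all factors must be > 0")
        if np.any(y < 0):
            raise ValueError("excitations are magnitudes, must be >= 0")
        if self.residual not in ("relative", "absolute"):
            raise ValueError("residual must be 'relative' or 'absolute'")
        if self.residual == "relative" and np.any(y == 0):
            raise ValueError(
                "zero excitations are incompatible with relative residuals; "
                "use residual='absolute'"
            )
        fixed = [self.fix_k2, self.fix_k4, self.fix_k6]
        self._check_variation(Xs, fixed)

        k_init = self._init_exponents(Xs, y, fixed)
        free = [j for j in range(3) if fixed[j] is None]
        a0 = max(np.max(y) / np.log(10.0), 1e-3)
        lx = np.log(Xs)

        def unpack(theta):
            a = np.exp(theta[0])
            b = np.exp(theta[1])
            ks = list(fixed)
            for i, j in enumerate(free):
                ks[j] = theta[2 + i]
            return a, b, ks

        log_y = np.log(y) if self.residual == "relative" else None

        def resid(theta):
            a, b, ks = unpack(theta)
            pred = a * np.log1p(b * np.exp(lx @ np.asarray(ks)))
            if log_y is not None:
                return np.log(np.maximum(pred, 1e-300)) - log_y
            return pred - y

        lo = [np.log(1e-5), np.log(1e-14)] + [self.exp_bounds[0]] * len(free)
        hi = [np.log(1e3), np.log(1e10)] + [self.exp_bounds[1]] * len(free)

        best = None
        for b0 in self.b_grid:
            theta0 = np.array(
                [np.log(a0), np.log(b0)] + [k_init[j] for j in free]
            )
            sol = optimize.least_squares(resid, theta0, bounds=(lo, hi))
            if sol.success and (
                best is None
                or sol.cost < best.cost * (1 - 1e-12)
                or (
                    np.isclose(sol.cost, best.cost, rtol=1e-9)
                    and np.linalg.norm(sol.x) < np.linalg.norm(best.x)
                )
            ):
                best = sol
        if best is None:
            raise RuntimeError("excitation-surface fit did not converge from any start")

        a, b, ks = unpack(best.x)
        self.a_, self.b_ = float(a), float(b)
        self.k2_, self.k4_, self.k6_ = (float(k) for k in ks)
        n_free = 2 + len(free)
        self.n_params_ = n_free
        self.adj_r2_ = adjusted_r2(y, self.a_ * np.log1p(b * np.exp(lx @ np.asarray(ks))), n_free)
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        Xs = self._scaled(X)
        arg = self.b_ * np.prod(Xs ** np.array([self.k2_, self.k4_, self.k6_]), axis=1)
        return self.a_ * np.log1p(arg)

    @property
    def params_(self) -> SafetyParams:
        check_is_fitted(self, "a_")
        return SafetyParams(
            a=self.a_,
            b=self.b_,
            k2=self.k2_,
            k4=self.k4_,
            k6=self.k6_,
            unit_convention=self.units,
            adj_r2=self.adj_r2_,
        )


def fit_full_model(records, fix_k6: Optional[float] = None) -> SafetyParams:
    """Fit the full excitation surface to (i_inj, t_pw, z_imag, v_elec) rows.

    SI units throughout; returns the fitted constants under the default
    (uA, us, kOhm) convention.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("records must be rows of (i_inj, t_pw, z_imag, v_elec)")
    model = CathodalExcitationModel(fix_k6=fix_k6)
    model.fit(arr[:, :3], arr[:, 3])
    return model.params_


def holdout_transfer(p_bench: SafetyParams, invivo_records) -> tuple[float, float, float]:
    """Benchtop-to-in-vivo transfer: refit only the impedance exponent.

    a, b, k2, k4 are intrinsic to the electrode and carried over; k6 is refit
    by 1-D least squares on the held-out records.  Returns (k6_refit, R²,
    paired-t-test p-value between observed and predicted excitations).
    """
    arr = np.asarray(invivo_records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("records must be rows of (i_inj, t_pw, z_imag, v_elec)")
    if arr.shape[0] < 8:
        raise ValueError("need >= 8 held-out records")
    if len(np.unique(arr[:, 2])) < 2:
        raise ValueError("rank-deficient design: factor 'impedance' is constant")
    u = p_bench.unit_convention
    i_s = arr[:, 0] / u.current_scale_a
    t_s = arr[:, 1] / u.time_scale_s
    z_s = arr[:, 2] / u.impedance_scale_ohm
    v = arr[:, 3]

    relative = bool(np.all(v > 0))  # log misfit under multiplicative noise

    def sse(k6):
        pred = p_bench.a * np.log1p(
            p_bench.b * i_s**p_bench.k2 * t_s**p_bench.k4 * z_s**k6
        )
        if relative:
            return float(np.sum((np.log(np.maximum(pred, 1e-300)) - np.log(v)) ** 2))
        return float(np.sum((pred - v) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=_EXP_BOUNDS, method="bounded", options={"xatol": 1e-12}
    )
    k6_refit = float(res.x)
    pred = p_bench.a * np.log1p(
        p_bench.b * i_s**p_bench.k2 * t_s**p_bench.k4 * z_s**k6_refit
    )
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum((v - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    diffs = v - pred
    # differences at numerical-precision scale carry no evidence against the
    # null; a t-test on them is meaningless
    if np.max(np.abs(diffs)) <= 1e-7 * max(np.max(np.abs(v)), 1e-30):
        p_val = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_val = float(stats.ttest_rel(v, pred).pvalue)
        if np.isnan(p_val):
            p_val = 1.0
    return k6_refit, r2, p_val
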