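"""EIS analysis: interface delineation, reactance extraction, scaling fits.

The multi-configuration protocol: a 4-contact measurement sees only the
medium; subtracting it from the 3-contact measurement delineates the
electrode–electrolyte interface of the working contact.  The interface
reactance at the principal frequency of the stimulus (10 kHz for a 100 us
pulse) feeds the excitation model; its power-law decay with contact
diameter, |Z_imag| = alpha * D**d1, couples the safety limit to geometry.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .circuit import interface_impedance, medium_impedance
from .types import (
    CircuitParams,
    Config,
    EISSpectrum,
    InterfaceParams,
    MediumParams,
    ScalingParams,
)

__all__ = [
    "delineate_interface",
    "reactance_at",
    "fit_impedance_scaling",
    "corner_frequency",
    "fit_circuit",
    "ImpedanceScaling",
    "CircuitFitter",
]


def delineate_interface(z3: EISSpectrum, z4: EISSpectrum) -> EISSpectrum:
    """Interface spectrum of the working contact: 3-contact minus 4-contact.

    Identical grids subtract pointwise; overlapping grids are resampled onto
    the intersection (linear in log-frequency, real and imaginary parts
    separately).  Disjoint frequency ranges are an error.
    """
    f3, f4 = z3.freqs, z4.freqs
    if f3.shape == f4.shape and np.allclose(f3, f4, rtol=1e-12):
        return EISSpectrum(freqs=f3, z=z3.z - z4.z, config="three_contact", meta=z3.meta)
    lo = max(f3[0], f4[0])
    hi = min(f3[-1], f4[-1])
    if lo >= hi:
        raise ValueError("frequency ranges do not overlap; cannot delineate")
    f_common = np.unique(np.concatenate([f3[(f3 >= lo) & (f3 <= hi)], f4[(f4 >= lo) & (f4 <= hi)]]))

    def resample(spec: EISSpectrum) -> np.ndarray:
        lf = np.log10(spec.freqs)
        lt = np.log10(f_common)
        return np.interp(lt, lf, spec.z.real) + 1j * np.interp(lt, lf, spec.z.imag)

    return EISSpectrum(
        freqs=f_common, z=resample(z3) - resample(z4), config="three_contact", meta=z3.meta
    )


def reactance_at(s: EISSpectrum, f: float) -> float:
    """|Im Z| (ohm) at frequency f, interpolated in log-frequency.

    Impedance spectra are near power-law, so the reactance is interpolated
    log–log (exact for a pure power law and at grid points); spectra with a
    vanishing imaginary part anywhere fall back to linear-in-|Im Z|.
    No extrapolation: f outside the measured range is an error.
    """
    if not s.freqs[0] <= f <= s.freqs[-1]:
        raise ValueError(
            f"frequency {f:g} Hz outside measured range "
            f"[{s.freqs[0]:g}, {s.freqs[-1]:g}] Hz"
        )
    im = np.abs(s.z.imag)
    lf = np.log10(s.freqs)
    if np.all(im > 0):
        return float(10.0 ** np.interp(np.log10(f), lf, np.log10(im)))
    return float(np.interp(np.log10(f), lf, im))


def corner_frequency(s: EISSpectrum) -> Optional[float]:
    """Lowest frequency at which the phase rises through -45 degrees.

    Log-interpolated between grid points.  Returns None when the phase never
    crosses -45 degrees within the grid (e.g. a purely resistive spectrum).
    """
    ph = s.phase_deg
    for i in range(len(ph) - 1):
        if ph[i] <= -45.0 <= ph[i + 1]:
            if ph[i + 1] == ph[i]:
                return float(s.freqs[i])
            frac = (-45.0 - ph[i]) / (ph[i + 1] - ph[i])
            lf = np.log10(s.freqs[i]) + frac * (np.log10(s.freqs[i + 1]) - np.log10(s.freqs[i]))
            return float(10.0**lf)
    return None


class ImpedanceScaling(BaseEstimator, RegressorMixin):
    """Power-law impedance–diameter scaling |Z_imag| = alpha * D**d1.

    Fit as a least-squares line in log–log space; ``alpha_`` is the scale
    (ohm * m^-d1, an intrinsic material property), ``d1_`` the decay
    exponent (negative for every real electrode family).
    """

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).ravel()
        z = np.asarray(y, dtype=float).ravel()
        if d.size != z.size:
            raise ValueError("diameters and reactances must have equal length")
        if len(np.unique(d)) < 3:
            raise ValueError("need >= 3 distinct diameters")
        if np.any(d <= 0) or np.any(z <= 0):
            raise ValueError("diameters and reactances must be > 0")
        slope, intercept = np.polyfit(np.log(d), np.log(z), 1)
        self.d1_ = float(slope)
        self.alpha_ = float(np.exp(intercept))
        pred = intercept + slope * np.log(d)
        ss_tot = float(np.sum((np.log(z) - np.mean(np.log(z))) ** 2))
        ss_res = float(np.sum((np.log(z) - pred) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        return self.alpha_ * np.asarray(X, dtype=float).ravel() ** self.d1_

    @property
    def params_(self) -> ScalingParams:
        check_is_fitted(self, "alpha_")
        return ScalingParams(alpha=self.alpha_, d1=self.d1_, r2=self.r2_)


def fit_impedance_scaling(pairs: Sequence[tuple[float, float]]) -> ScalingParams:
    """Fit |Z_imag| = alpha * D**d1 to (diameter m, reactance ohm) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be rows of (diameter_m, reactance_ohm)")
    return ImpedanceScaling().fit(arr[:, 0], arr[:, 1]).params_


# --------------------------------------------------------------------------
# equivalent-circuit fitting
# --------------------------------------------------------------------------


class CircuitFitter(BaseEstimator):
    """Complex nonlinear least-squares fit of the equivalent circuit.

    Residuals are the stacked real/imaginary misfits weighted by 1/|Z|
    (relative errors, so decades of impedance contribute evenly).

    Parameters
    ----------
    config : which sub-circuit the spectrum represents.
        four_contact fits the medium only; three_contact adds the working
        interface; two_contact assumes symmetric contacts (interface counted
        twice).
    intracellular : bool
        Fit the bulk intracellular branch (r_ex parallel r_in + c_in).  When
        False — the right choice for saline, which has no cell membranes —
        the medium reduces to a single series resistance and only that
        combination is identifiable.  When True the branch is fit in the
        canonical form r_in = r_ex: the bulk one-pole response has only
        three identifiable degrees of freedom, so the four raw elements
        cannot all be resolved from a spectrum.

    Attributes
    ----------
    medium_ : MediumParams
    interface_ : InterfaceParams or None (four_contact)
    at_bounds_ : list of parameter names pinned at an optimisation bound.
    insensitive_ : list of parameter names the spectrum carries (almost) no
        information about — pinned at a bound or with a vanishing Jacobian
        column, e.g. the capacitive elements of a purely resistive spectrum.
    residual_norm_ : float
    """

    _EXP_CAP = 30.0  # bound for log-scale parameters

    def __init__(self, config: Config = "three_contact", intracellular: bool = False):
        self.config = config
        self.intracellular = intracellular

    def _names(self) -> list[str]:
        names = []
        if self.config in ("three_contact", "two_contact"):
            names += ["q_dl", "n_dl", "r_ct"]
        names += ["r_series"]
        if self.intracellular:
            names += ["r_ex", "c_in"]  # canonical r_in = r_ex
        return names

    def _model(self, theta: np.ndarray, f: np.ndarray) -> np.ndarray:
        names = self._names()
        p = dict(zip(names, theta))
        if self.intracellular:
            r_ex = np.exp(p["r_ex"])
            med = MediumParams(
                r_spread=np.exp(p["r_series"]),
                r_ex=r_ex,
                r_in=r_ex,
                c_in=np.exp(p["c_in"]),
            )
        else:
            med = MediumParams(r_spread=np.exp(p["r_series"]), r_ex=0.0)
        z = np.asarray(medium_impedance(med, f), dtype=complex)
        if self.config != "four_contact":
            iface = InterfaceParams(
                q_dl=np.exp(p["q_dl"]), n_dl=p["n_dl"], r_ct=np.exp(p["r_ct"])
            )
            mult = 2.0 if self.config == "two_contact" else 1.0
            z = z + mult * np.asarray(interface_impedance(iface, f), dtype=complex)
        return z

    def _init(self, s: EISSpectrum) -> np.ndarray:
        f, z = s.freqs, s.z
        r_hi = max(float(z.real[-1]), 1e-3)
        theta = []
        if self.config != "four_contact":
            # CPE slope/level from the low-frequency reactance
            im = np.abs(z.imag)
            mask = im > 0
            if mask.sum() >= 2:
                sl, ic = np.polyfit(np.log(2 * np.pi * f[mask]), np.log(im[mask]), 1)
                n0 = float(np.clip(-sl, 0.05, 0.999))
                q0 = np.sin(n0 * np.pi / 2) / np.exp(ic)
            else:
                n0, q0 = 0.9, 1e-6
            mult = 2.0 if self.config == "two_contact" else 1.0
            q0 = max(q0 * mult, 1e-12)
            r_ct0 = 10.0 * float(np.max(np.abs(z)))
            theta += [np.log(q0), n0, np.log(r_ct0)]
        theta += [np.log(r_hi)]
        if self.intracellular:
            r_lo = max(float(z.real[0]), 1e-3)
            r_ex0 = max(r_lo - r_hi, 0.1 * r_hi)
            k = int(np.argmax(np.abs(z.imag[: len(f)])))
            c0 = 1.0 / (2 * np.pi * f[k] * r_ex0)
            theta += [np.log(r_ex0), np.log(c0)]
            # series resistance init: high-f plateau holds r_s + r_ex||r_in
            theta[-3] = np.log(max(r_hi / 2, 1e-3))
        return np.asarray(theta, dtype=float)

    def fit(self, X, y=None):
        s = X
        if not isinstance(s, EISSpectrum):
            raise TypeError("CircuitFitter.fit expects an EISSpectrum")
        f, z = s.freqs, s.z
        if len(f) < 10 or np.log10(f[-1] / f[0]) < 3:
            raise ValueError("need >= 10 frequencies spanning >= 3 decades")
        w = 1.0 / np.abs(z)

        def resid(theta):
            d = (self._model(theta, f) - z) * w
            return np.concatenate([d.real, d.imag])

        names = self._names()
        lo = [-self._EXP_CAP] * len(names)
        hi = [self._EXP_CAP] * len(names)
        if "n_dl" in names:
            j = names.index("n_dl")
            lo[j], hi[j] = 1e-3, 1.0

        theta0 = np.clip(self._init(s), lo, hi)
        sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        if not sol.success:
            raise RuntimeError(
                f"circuit fit did not converge; residual norm {np.sqrt(2 * sol.cost):.3e}"
            )
        p = dict(zip(names, sol.x))
        if self.intracellular:
            r_ex = float(np.exp(p["r_ex"]))
            self.medium_ = MediumParams(
                r_spread=float(np.exp(p["r_series"])),
                r_ex=r_ex,
                r_in=r_ex,
                c_in=float(np.exp(p["c_in"])),
            )
        else:
            self.medium_ = MediumParams(r_spread=float(np.exp(p["r_series"])), r_ex=0.0)
        if self.config != "four_contact":
            self.interface_ = InterfaceParams(
                q_dl=float(np.exp(p["q_dl"])),
                n_dl=float(p["n_dl"]),
                r_ct=float(np.exp(p["r_ct"])),
            )
        else:
            self.interface_ = None
        self.at_bounds_ = [
            nm
            for nm, v, l, h in zip(names, sol.x, lo, hi)
            if np.isclose(v, l, atol=1e-6) or np.isclose(v, h, atol=1e-6)
        ]
        # a Jacobian column the residual barely feels marks an element the
        # spectrum carries no information about (e.g. capacitances of a
        # purely resistive spectrum)
        col_norms = np.linalg.norm(np.asarray(sol.jac), axis=0)
        scale = max(float(np.max(col_norms)), 1e-300)
        weak = {nm for nm, c in zip(names, col_norms) if c < 1e-6 * scale}
        self.insensitive_ = sorted(weak | set(self.at_bounds_))
        self.residual_norm_ = float(np.sqrt(2 * sol.cost))
        return self

    @property
    def circuit_params_(self) -> CircuitParams:
        """Fitted elements as a full circuit.

        For four_contact fits the interfaces are blocking placeholders (the
        measurement carries no interface information).
        """
        check_is_fitted(self, "medium_")
        iface = self.interface_ or InterfaceParams(q_dl=1e-15, n_dl=1.0, r_ct=1e15)
        return CircuitParams(working=iface, counter=iface, medium=self.medium_)


def fit_circuit(
    s: EISSpectrum, config: Optional[Config] = None, intracellular: bool = False
) -> CircuitParams:
    """Fit the equivalent circuit to a spectrum; see :class:`CircuitFitter`."""
    return CircuitFitter(
        config=config or s.config, intracellular=intracellular
    ).fit(s).circuit_params_
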