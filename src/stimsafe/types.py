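"""Domain containers for electrode–electrolyte measurements and model parameters.

Sign conventions used throughout:

* impedance phase in degrees, capacitive behaviour negative;
* measured potentials are signed, the cathodal phase of a transient is
  negative; model fitting is done on magnitudes (see :mod:`stimsafe.safety`);
* the electrolysis window is stored signed, ``e_mc < 0 < e_ma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "Config",
    "ElectrodeSpec",
    "InterfaceParams",
    "MediumParams",
    "CircuitParams",
    "StimPulse",
    "EISSpectrum",
    "VoltageTransient",
    "CVSweep",
    "ElectrolysisWindow",
    "TransientFeatures",
    "ScalingParams",
    "GeometricFactor",
    "SafetyParams",
    "SingleFactorParams",
    "ShannonResult",
    "UnitConvention",
]

Config = Literal["two_contact", "three_contact", "four_contact"]

MATERIALS = ("PtNR", "planar_Pt", "PEDOT", "clinical_depth", "sEEG", "strip")


@dataclass(frozen=True)
class ElectrodeSpec:
    """Identity and geometry of a bipolar contact pair.

    ``separation_factor`` is the edge-to-edge separation S expressed as a
    multiple of the contact diameter D (the design ladder uses 1.5–5).
    """

    material: str
    diameter_m: float
    separation_factor: float = 1.5
    medium: Literal["benchtop_saline", "in_vivo"] = "benchtop_saline"

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(
                f"unknown material {self.material!r}; expected one of {MATERIALS}"
            )
        if self.diameter_m <= 0:
            raise ValueError("diameter_m must be > 0")
        if self.separation_factor < 1:
            raise ValueError("separation_factor must be >= 1")
        if self.medium not in ("benchtop_saline", "in_vivo"):
            raise ValueError(f"unknown medium {self.medium!r}")


@dataclass(frozen=True)
class InterfaceParams:
    """Electrode–electrolyte interface elements.

    A constant-phase double layer (q_dl, n_dl) in parallel with a Faradaic
    branch: charge-transfer resistance r_ct in series with a Faradaic
    pseudo-capacitance CPE (q_f, n_f).  ``faradaic_nonlinearity`` is an
    optional exponential coefficient (1/V) making the charge-transfer
    conductance grow with the interface bias magnitude.
    """

    q_dl: float  # S*s^n
    n_dl: float
    r_ct: float  # ohm
    q_f: float = 0.0
    n_f: float = 0.9
    faradaic_nonlinearity: float = 0.0  # 1/V

    def __post_init__(self) -> None:
        if self.q_dl <= 0:
            raise ValueError("q_dl must be > 0")
        if not 0 < self.n_dl <= 1:
            raise ValueError("n_dl must be in (0, 1]")
        if self.r_ct <= 0:
            raise ValueError("r_ct must be > 0")
        if self.q_f < 0:
            raise ValueError("q_f must be >= 0")
        if not 0 < self.n_f <= 1:
            raise ValueError("n_f must be in (0, 1]")


@dataclass(frozen=True)
class MediumParams:
    """Series (spreading + lead) and bulk tissue/saline elements.

    The bulk is an extracellular resistance in parallel with an intracellular
    branch (resistance in series with a capacitance); ``c_in = 0`` opens the
    intracellular branch.
    """

    r_spread: float
    r_ex: float
    r_in: float = 0.0
    c_in: float = 0.0
    r_lead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_spread", "r_ex", "r_in", "r_lead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c_in < 0:
            raise ValueError("c_in must be >= 0")


@dataclass(frozen=True)
class CircuitParams:
    """Full bipolar circuit: working interface, counter interface, medium."""

    working: InterfaceParams
    counter: InterfaceParams
    medium: MediumParams

    def replace(self, **kw) -> "CircuitParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class StimPulse:
    """Biphasic symmetric square current pulse, cathodal phase first.

    ``i_inj`` is the amplitude magnitude (A); ``t_pw`` the per-phase width (s).
    """

    i_inj: float
    t_pw: float
    interphase_gap: float = 0.0
    shape: str = "biphasic_symmetric_square"

    def __post_init__(self) -> None:
        if self.i_inj <= 0:
            raise ValueError("i_inj must be > 0")
        if self.t_pw <= 0:
            raise ValueError("t_pw must be > 0")
        if self.interphase_gap < 0:
            raise ValueError("interphase_gap must be >= 0")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class EISSpectrum:
    """Complex impedance vs frequency for one wiring configuration."""

    freqs: np.ndarray  # Hz, strictly ascending
    z: np.ndarray  # complex ohm
    config: Config
    meta: Optional[ElectrodeSpec] = None

    def __post_init__(self) -> None:
        self.freqs = _as_float_array(self.freqs)
        self.z = np.asarray(self.z, dtype=complex)
        if self.freqs.ndim != 1 or self.freqs.size == 0:
            raise ValueError("freqs must be a non-empty 1-D array")
        if np.any(self.freqs <= 0):
            raise ValueError("freqs must be > 0")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if self.z.shape != self.freqs.shape:
            raise ValueError("z and freqs must have equal length")
        if self.config not in ("two_contact", "three_contact", "four_contact"):
            raise ValueError(f"unknown config {self.config!r}")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in degrees; capacitive spectra are negative."""
        return np.degrees(np.angle(self.z))


@dataclass
class VoltageTransient:
    """Measured total potential during a current pulse on a uniform grid."""

    t: np.ndarray  # s, uniform from 0
    v: np.ndarray  # V, signed (cathodal negative)
    pulse: StimPulse
    meta: Optional[ElectrodeSpec] = None

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t)
        self.v = _as_float_array(self.v)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("t must be a 1-D array with >= 2 samples")
        if self.t[0] != 0:
            raise ValueError("t must start at 0")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("t must be a uniform, increasing grid")
        if self.v.shape != self.t.shape:
            raise ValueError("v and t must have equal length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class CVSweep:
    """Cyclic voltammetry sweep: applied potential and resulting current."""

    v: np.ndarray  # V
    i: np.ndarray  # A
    scan_rate: float  # V/s
    config: Literal["two_contact", "three_contact"] = "two_contact"
    meta: Optional[ElectrodeSpec] = None

    def __post_init__(self) -> None:
        self.v = _as_float_array(self.v)
        self.i = _as_float_array(self.i)
        if self.v.shape != self.i.shape:
            raise ValueError("v and i must have equal length")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be > 0")


#: Sentinel threshold meaning "no electrolysis onset inside the scan range".
OPEN_WINDOW = float("nan")


@dataclass(frozen=True)
class ElectrolysisWindow:
    """Cathodal/anodal electrolysis onset potentials, signed (e_mc < 0 < e_ma).

    NaN on either side is the open-window sentinel: the scan did not reach
    that onset.
    """

    e_mc: float
    e_ma: float
    method_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.e_mc) and self.e_mc >= 0:
            raise ValueError("e_mc must be negative (signed convention)")
        if not np.isnan(self.e_ma) and self.e_ma <= 0:
            raise ValueError("e_ma must be positive (signed convention)")

    @property
    def cathodal_magnitude(self) -> float:
        return abs(self.e_mc)

    @property
    def width(self) -> float:
        return self.e_ma - self.e_mc

    @property
    def is_open(self) -> bool:
        return bool(np.isnan(self.e_mc) or np.isnan(self.e_ma))


@dataclass(frozen=True)
class TransientFeatures:
    """Access step and cathodal excitation extracted from one transient."""

    v_access: float  # V, magnitude
    v_elec: float  # V, magnitude at end of cathodal phase
    pulse: StimPulse
    clamped: bool = False  # a negative raw estimate was clamped to 0

    def __post_init__(self) -> None:
        if self.v_access < 0 or self.v_elec < 0:
            raise ValueError("v_access and v_elec are magnitudes, must be >= 0")


@dataclass(frozen=True)
class ScalingParams:
    """Power-law impedance–diameter scaling |Z_imag| = alpha * D**d1."""

    alpha: float  # ohm * m^-d1
    d1: float
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def reactance(self, diameter_m) -> np.ndarray:
        return self.alpha * np.asarray(diameter_m, dtype=float) ** self.d1


@dataclass(frozen=True)
class GeometricFactor:
    """Geometric correction factor G = 4*pi*R/rho from a rho–R calibration."""

    g: float  # 1/m
    slope_se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be > 0")


@dataclass(frozen=True)
class UnitConvention:
    """Scales applied to (current, pulse width, reactance) before fitting.

    The rate constant b of the excitation model has units that depend on the
    exponents, so the convention under which it was fit must travel with it.
    Defaults: microamps, microseconds, kiloohms.
    """

    current_scale_a: float = 1e-6
    time_scale_s: float = 1e-6
    impedance_scale_ohm: float = 1e3


@dataclass(frozen=True)
class SafetyParams:
    """Fitted constants of the cathodal-excitation model.

    V_elec = a * ln(b * I^k2 * t_pw^k4 * |Z_imag|^k6 + 1), magnitudes, with
    I, t_pw, |Z_imag| expressed in ``unit_convention`` scales.
    """

    a: float  # V
    b: float
    k2: float
    k4: float
    k6: float
    unit_convention: UnitConvention = UnitConvention()
    adj_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if min(self.k2, self.k4, self.k6) <= 0:
            raise ValueError("exponents k2, k4, k6 must be > 0")


@dataclass(frozen=True)
class SingleFactorParams:
    """One-factor excitation law |V| = ln(k_scale * x^k_exp + 1)."""

    factor: Literal["current", "pulse_width", "impedance"]
    k_scale: float
    k_exp: float
    adj_r2: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.k_scale <= 0 or self.k_exp <= 0):
            raise ValueError("k_scale and k_exp must be > 0")


@dataclass(frozen=True)
class ShannonResult:
    """Charge-per-phase safety limit from the empirical log-linear boundary.

    log10(charge density) = k - log10(charge), k dimensionless (default 1.8).
    """

    k: float
    q_per_phase_uc: float
    charge_density_uc_cm2: float
    area_cm2: float
    i_limit_a: float
    t_pw_s: float
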