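"""Forward model of the bipolar electrode–tissue circuit.

Frequency domain: complex impedance of the interface (constant-phase double
layer in parallel with a Faradaic branch), the medium (series spreading/lead
resistance plus bulk tissue), and their combinations in the 2-, 3- and
4-contact wiring configurations.

Time domain: response to a biphasic symmetric square current pulse.  Each
constant-phase element is realised as a log-spaced ladder of parallel-RC
rungs whose resistances are solved by non-negative least squares against the
analytic CPE over the band [1/(10*t_pw), 10/dt]; the resulting linear circuit
is stepped exactly with matrix exponentials.  An optional bias-dependent
Faradaic conductance g(V) = exp(gamma*|V|)/r_ct makes the system nonlinear,
in which case a stiff ODE integrator is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import nnls

from .types import (
    CircuitParams,
    Config,
    EISSpectrum,
    InterfaceParams,
    MediumParams,
    StimPulse,
    VoltageTransient,
)

__all__ = [
    "cpe_impedance",
    "interface_impedance",
    "medium_impedance",
    "configuration_spectrum",
    "simulate_transient",
    "CPELadder",
    "build_cpe_ladder",
]

# n this close to the ideal limits is realised as an ideal capacitor/resistor:
# a band-limited RC ladder cannot reproduce a true integrator or a pure
# resistor outside its band.
_N_CAP_LIMIT = 0.9995
_N_RES_LIMIT = 1e-6


def cpe_impedance(q: float, n: float, f) -> np.ndarray | complex:
    """Impedance of a constant-phase element, Z = 1/(q*(j*2*pi*f)**n).

    Phase is -n*90 degrees at every frequency; n = 1 is an ideal capacitor of
    capacitance q, n = 0 a resistor of 1/q.
    """
    f = np.asarray(f, dtype=float)
    if q <= 0:
        raise ValueError("CPE coefficient q must be > 0")
    if not 0 <= n <= 1:
        raise ValueError("CPE exponent n must be in [0, 1]")
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    z = 1.0 / (q * (1j * 2 * np.pi * f) ** n)
    return z if z.ndim else complex(z)


def interface_impedance(p: InterfaceParams, f) -> np.ndarray | complex:
    """Small-signal interface impedance: Z_DL || (R_CT + Z_CF).

    With q_f = 0 the Faradaic branch reduces to the charge-transfer
    resistance alone.
    """
    z_dl = cpe_impedance(p.q_dl, p.n_dl, f)
    if p.q_f > 0:
        z_far = p.r_ct + cpe_impedance(p.q_f, p.n_f, f)
    else:
        z_far = p.r_ct
    return z_dl * z_far / (z_dl + z_far)


def medium_impedance(p: MediumParams, f) -> np.ndarray | complex:
    """Medium impedance: r_lead + r_spread + (r_ex || (r_in + 1/(jwC_in)))."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    series = p.r_lead + p.r_spread
    if p.c_in > 0:
        z_in = p.r_in + 1.0 / (1j * 2 * np.pi * f * p.c_in)
        z_bulk = p.r_ex * z_in / (p.r_ex + z_in)
    else:
        # intracellular branch open
        z_bulk = np.full_like(f, p.r_ex, dtype=complex) if f.ndim else complex(p.r_ex)
    z = series + z_bulk
    return z if np.ndim(z) else complex(z)


def configuration_spectrum(p: CircuitParams, config: Config, freqs) -> EISSpectrum:
    """Impedance spectrum seen in a 2-, 3- or 4-contact measurement.

    four_contact sees only the medium; three_contact adds the working
    interface; two_contact adds both working and counter interfaces.
    """
    freqs = np.asarray(freqs, dtype=float)
    z = np.asarray(medium_impedance(p.medium, freqs), dtype=complex)
    if config == "four_contact":
        pass
    elif config == "three_contact":
        z = z + interface_impedance(p.working, freqs)
    elif config == "two_contact":
        z = z + interface_impedance(p.working, freqs) + interface_impedance(p.counter, freqs)
    else:
        raise ValueError(f"unknown configuration {config!r}")
    return EISSpectrum(freqs=freqs, z=z, config=config)


# --------------------------------------------------------------------------
# CPE time-domain realisation
# --------------------------------------------------------------------------


@dataclass
class CPELadder:
    """Series chain of parallel-RC rungs approximating a CPE in a band.

    ``Z(w) = r0 + sum_k rs[k] / (1 + j*w*taus[k])`` plus, when ``c_ideal`` is
    set, a true series capacitor (used for n -> 1).
    """

    rs: np.ndarray  # ohm, per rung
    taus: np.ndarray  # s, per rung
    r0: float = 0.0  # series resistor (n -> 0 limit)
    c_ideal: Optional[float] = None  # F (n -> 1 limit)

    @property
    def n_states(self) -> int:
        return len(self.rs) + (1 if self.c_ideal is not None else 0)

    def impedance(self, f) -> np.ndarray:
        w = 2 * np.pi * np.asarray(f, dtype=float)
        z = np.full(w.shape, self.r0, dtype=complex)
        for r, tau in zip(self.rs, self.taus):
            z += r / (1 + 1j * w * tau)
        if self.c_ideal is not None:
            z += 1.0 / (1j * w * self.c_ideal)
        return z


def build_cpe_ladder(
    q: float,
    n: float,
    f_lo: float,
    f_hi: float,
    rungs_per_decade: int = 8,
) -> CPELadder:
    """Fit a parallel-RC ladder to a CPE over [f_lo, f_hi].

    Rung pole frequencies are log-spaced across the band (slightly extended);
    rung resistances are solved by non-negative least squares on the stacked
    real/imaginary parts, weighted by 1/|Z| so the fit is relative.
    """
    if q <= 0 or f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("need q > 0 and 0 < f_lo < f_hi")
    if rungs_per_decade < 1:
        raise ValueError("rungs_per_decade must be >= 1")
    if n >= _N_CAP_LIMIT:
        return CPELadder(rs=np.empty(0), taus=np.empty(0), c_ideal=q)
    if n <= _N_RES_LIMIT:
        return CPELadder(rs=np.empty(0), taus=np.empty(0), r0=1.0 / q)

    # poles extend a decade below and half above the band: the CPE keeps
    # growing below f_lo, and without low-side rungs the ladder saturates
    # early and the band-edge magnitude sags
    ext_lo, ext_hi = 1.0, 0.5
    decades = np.log10(f_hi / f_lo)
    n_rungs = max(3, int(np.ceil((decades + ext_lo + ext_hi) * rungs_per_decade)))
    f_poles = np.logspace(np.log10(f_lo) - ext_lo, np.log10(f_hi) + ext_hi, n_rungs)
    taus = 1.0 / (2 * np.pi * f_poles)

    f_fit = np.logspace(
        np.log10(f_lo) - ext_lo / 2, np.log10(f_hi) + ext_hi / 2, max(4 * n_rungs, 60)
    )
    z_target = cpe_impedance(q, n, f_fit)
    w = 2 * np.pi * f_fit
    # columns: rung responses; rows: weighted Re then Im (relative fit)
    resp = 1.0 / (1.0 + 1j * np.outer(w, taus))
    weight = 1.0 / np.abs(z_target)
    a_mat = np.vstack([resp.real * weight[:, None], resp.imag * weight[:, None]])
    b_vec = np.concatenate([z_target.real * weight, z_target.imag * weight])
    rs, _ = nnls(a_mat, b_vec, maxiter=30 * n_rungs)
    keep = rs > 0
    return CPELadder(rs=rs[keep], taus=taus[keep])


# --------------------------------------------------------------------------
# Transient simulation
# --------------------------------------------------------------------------


class _InterfaceBlock:
    """State bookkeeping for one interface: DL ladder + Faradaic branch."""

    def __init__(self, p: InterfaceParams, f_lo: float, f_hi: float, rungs: int):
        self.p = p
        self.dl = build_cpe_ladder(p.q_dl, p.n_dl, f_lo, f_hi, rungs)
        self.far = (
            build_cpe_ladder(p.q_f, p.n_f, f_lo, f_hi, rungs) if p.q_f > 0 else None
        )
        self.n_states = self.dl.n_states + (self.far.n_states if self.far else 0)

    @staticmethod
    def _branch_voltage(ladder: CPELadder, x: np.ndarray, i_branch: float) -> float:
        return ladder.r0 * i_branch + float(np.sum(x))

    def currents(self, x: np.ndarray, i_total: float) -> tuple[float, float, float]:
        """Split the interface current; returns (i_dl, i_far, v_interface)."""
        nd = self.dl.n_states
        s_dl = float(np.sum(x[:nd]))
        s_f = float(np.sum(x[nd:])) if self.far else 0.0
        # bias-dependent charge transfer: estimate |V| from the DL states
        r_ct = self.p.r_ct
        if self.p.faradaic_nonlinearity > 0:
            r_ct = r_ct * np.exp(-self.p.faradaic_nonlinearity * abs(s_dl))
        r_far = r_ct + (self.far.r0 if self.far else 0.0)
        i_dl = (i_total * r_far + s_f - s_dl) / (self.dl.r0 + r_far)
        i_far = i_total - i_dl
        v_if = self.dl.r0 * i_dl + s_dl
        return i_dl, i_far, v_if

    @staticmethod
    def _ladder_deriv(ladder: CPELadder, x: np.ndarray, i_branch: float) -> np.ndarray:
        dx = np.empty(ladder.n_states)
        nr = len(ladder.rs)
        if nr:
            caps = ladder.taus / ladder.rs  # C_k = tau_k / R_k
            dx[:nr] = i_branch / caps - x[:nr] / ladder.taus
        if ladder.c_ideal is not None:
            dx[nr] = i_branch / ladder.c_ideal
        return dx

    def deriv(self, x: np.ndarray, i_total: float) -> np.ndarray:
        i_dl, i_far, _ = self.currents(x, i_total)
        nd = self.dl.n_states
        dx = np.empty(self.n_states)
        dx[:nd] = self._ladder_deriv(self.dl, x[:nd], i_dl)
        if self.far:
            dx[nd:] = self._ladder_deriv(self.far, x[nd:], i_far)
        return dx


class _Circuit:
    """Assembled state-space circuit for one wiring configuration."""

    def __init__(self, p: CircuitParams, config: Config, f_lo, f_hi, rungs):
        self.p = p
        self.blocks: list[_InterfaceBlock] = []
        if config in ("two_contact", "three_contact"):
            self.blocks.append(_InterfaceBlock(p.working, f_lo, f_hi, rungs))
        if config == "two_contact":
            self.blocks.append(_InterfaceBlock(p.counter, f_lo, f_hi, rungs))
        m = p.medium
        self.tissue_state = m.c_in > 0
        self.n_states = sum(b.n_states for b in self.blocks) + (
            1 if self.tissue_state else 0
        )
        self.nonlinear = any(
            b.p.faradaic_nonlinearity > 0 and b.p.q_dl > 0 for b in self.blocks
        )

    def _tissue(self, v_c: float, i_total: float) -> tuple[float, float]:
        """Bulk tissue voltage and capacitor-current derivative input."""
        m = self.p.medium
        if not self.tissue_state:
            return m.r_ex * i_total, 0.0
        if m.r_in > 0:
            g = 1.0 / m.r_ex + 1.0 / m.r_in
            v_t = (i_total + v_c / m.r_in) / g
            i_in = (v_t - v_c) / m.r_in
        else:
            v_t = v_c
            i_in = i_total - v_c / m.r_ex
        return v_t, i_in / m.c_in

    def deriv(self, x: np.ndarray, i_total: float) -> np.ndarray:
        dx = np.empty(self.n_states)
        k = 0
        for b in self.blocks:
            dx[k : k + b.n_states] = b.deriv(x[k : k + b.n_states], i_total)
            k += b.n_states
        if self.tissue_state:
            _, dvc = self._tissue(x[k], i_total)
            dx[k] = dvc
        return dx

    def voltage(self, x: np.ndarray, i_total: float) -> float:
        m = self.p.medium
        v = i_total * (m.r_lead + m.r_spread)
        k = 0
        for b in self.blocks:
            _, _, v_if = b.currents(x[k : k + b.n_states], i_total)
            v += v_if
            k += b.n_states
        v_t, _ = self._tissue(x[k] if self.tissue_state else 0.0, i_total)
        return v + v_t

    def linearize(self) -> tuple[np.ndarray, np.ndarray]:
        """Extract A, B of dx/dt = A x + B u by probing the derivative."""
        n = self.n_states
        a = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            a[:, j] = self.deriv(e, 0.0)
        b = self.deriv(np.zeros(n), 1.0)
        return a, b


def _segments(pulse: StimPulse, tail: float) -> list[tuple[float, float]]:
    """(end_time, signed current) segments: cathodal, gap, anodal, tail."""
    segs = [(pulse.t_pw, -pulse.i_inj)]
    t = pulse.t_pw
    if pulse.interphase_gap > 0:
        t += pulse.interphase_gap
        segs.append((t, 0.0))
    t += pulse.t_pw
    segs.append((t, +pulse.i_inj))
    if tail > 0:
        segs.append((t + tail, 0.0))
    return segs


def simulate_transient(
    p: CircuitParams,
    pulse: StimPulse,
    dt: float,
    rc_ladder_rungs: int = 8,
    config: Config = "two_contact",
    tail_fraction: float = 0.0,
) -> VoltageTransient:
    """Voltage transient for a biphasic symmetric square current pulse.

    ``rc_ladder_rungs`` is the CPE ladder density in rungs per decade over
    the band [1/(10*t_pw), 10/dt].  The cathodal (first) phase produces a
    negative measured potential.  With every ``faradaic_nonlinearity`` zero
    the circuit is linear and is stepped exactly via matrix exponentials;
    otherwise a stiff implicit integrator is used.
    """
    if dt <= 0 or dt > pulse.t_pw / 100:
        raise ValueError(
            f"dt too coarse: need dt <= t_pw/100 = {pulse.t_pw / 100:.3e} s"
        )
    if rc_ladder_rungs < 3:
        raise ValueError("rc_ladder_rungs must be >= 3 per decade")

    f_lo = 1.0 / (10.0 * pulse.t_pw)
    f_hi = 10.0 / dt
    circ = _Circuit(p, config, f_lo, f_hi, rc_ladder_rungs)
    segs = _segments(pulse, tail_fraction * pulse.t_pw)
    t_end = segs[-1][0]
    t_grid = np.arange(0.0, t_end + dt / 2, dt)

    if circ.n_states == 0:
        v = np.array([circ.voltage(np.empty(0), _current_at(segs, t)) for t in t_grid])
        return VoltageTransient(t=t_grid, v=v, pulse=pulse)

    if not circ.nonlinear:
        v = _step_linear(circ, segs, t_grid, dt)
    else:
        v = _step_stiff(circ, segs, t_grid)
    return VoltageTransient(t=t_grid, v=v, pulse=pulse)


def _assign_segments(segs, t_grid, eps) -> np.ndarray:
    """Left-continuous segment index per sample: t = t_pw reads the cathodal
    end-of-phase voltage, t = 0 the pulse onset."""
    ends = np.array([e for e, _ in segs])
    idx = np.searchsorted(ends, t_grid - eps, side="left")
    return np.minimum(idx, len(segs) - 1)


def _current_at(segs: list[tuple[float, float]], t: float) -> float:
    eps = 1e-9 * segs[0][0]
    return segs[int(_assign_segments(segs, np.array([t]), eps)[0])][1]


def _step_linear(circ, segs, t_grid, dt) -> np.ndarray:
    a_mat, b_vec = circ.linearize()
    n = circ.n_states
    ends = np.array([e for e, _ in segs])
    us = np.array([u for _, u in segs])
    eps = dt * 1e-6
    assign = _assign_segments(segs, t_grid, eps)
    cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}

    def propagator(h: float, u: float):
        key = (float(np.round(h / dt, 9)), u)
        if key not in cache:
            m = np.zeros((n + 1, n + 1))
            m[:n, :n] = a_mat * h
            m[:n, n] = b_vec * u * h
            e = expm(m)
            cache[key] = (e[:n, :n], e[:n, n])
        return cache[key]

    x = np.zeros(n)
    v = np.empty(len(t_grid))
    for k, t in enumerate(t_grid):
        v[k] = circ.voltage(x, us[assign[k]])
        if k == len(t_grid) - 1:
            break
        t_next = t_grid[k + 1]
        inner = ends[(ends > t + eps) & (ends < t_next - eps)]
        pts = [t, *inner, t_next]
        for t0, t1 in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (t0 + t1)
            u = us[min(np.searchsorted(ends, mid, side="left"), len(segs) - 1)]
            phi, gam = propagator(t1 - t0, u)
            x = phi @ x + gam
    return v


def _step_stiff(circ, segs, t_grid) -> np.ndarray:
    from scipy.integrate import solve_ivp

    eps = (t_grid[1] - t_grid[0]) * 1e-6
    assign = _assign_segments(segs, t_grid, eps)
    x = np.zeros(circ.n_states)
    v = np.empty(len(t_grid))
    t_prev = 0.0
    for j, (t_end, u) in enumerate(segs):
        mask = assign == j
        t_eval = np.clip(t_grid[mask], t_prev, t_end)
        sol = solve_ivp(
            lambda t, y: circ.deriv(y, u),
            (t_prev, t_end),
            x,
            method="BDF",
            t_eval=np.unique(np.concatenate([t_eval, [t_end]])),
            rtol=1e-7,
            atol=1e-12,
        )
        y_at = {float(tt): sol.y[:, i] for i, tt in enumerate(sol.t)}
        v[mask] = [circ.voltage(y_at[float(tt)], u) for tt in t_eval]
        x = sol.y[:, -1]
        t_prev = t_end
    return v
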