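"""Voltage-transient analysis: cathodal excitation and the safe current.

The measured pulse potential is the sum of an instantaneous access step
(series spreading/lead/bulk resistance — three orders of magnitude weaker
field than the double layer's) and the slow interface polarization that
actually drives electrolysis.  The access step is estimated by a line fit
over the first tenth of the cathodal phase extrapolated to t = 0+, which is
robust to one-sample onset smearing; the cathodal excitation is the
end-of-phase magnitude minus that step.

``find_imax`` inverts any monotone excitation provider (measured library,
circuit simulator, or the fitted excitation law) against the cathodal
electrolysis threshold by bisection.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .types import ElectrolysisWindow, StimPulse, TransientFeatures, VoltageTransient

__all__ = ["extract_cathodal_excitation", "find_imax"]


def extract_cathodal_excitation(vt: VoltageTransient) -> TransientFeatures:
    """Split a transient into access step and cathodal excitation magnitudes.

    Requires the cathodal phase to be resolved by at least 20 samples.
    Negative raw estimates (possible under noise) are clamped to zero and
    flagged.
    """
    t_pw = vt.pulse.t_pw
    eps = vt.dt * 1e-6
    in_phase = vt.t <= t_pw + eps
    if in_phase.sum() < 20:
        raise ValueError("need >= 20 samples in the cathodal phase")
    if vt.t[-1] < t_pw - eps:
        raise ValueError("record ends before the cathodal phase boundary")

    # back-extrapolate |v| over (0, t_pw/10] to t = 0+
    early = (vt.t > eps) & (vt.t <= t_pw / 10 + eps)
    if early.sum() < 2:
        raise ValueError("sampling does not resolve the pulse onset")
    slope, intercept = np.polyfit(vt.t[early], np.abs(vt.v[early]), 1)

    v_access = float(intercept)
    v_end = float(np.abs(vt.v[in_phase][-1]))
    v_elec = v_end - v_access

    clamped = False
    if v_access < 0:
        v_access, clamped = 0.0, True
    if v_elec < 0:
        v_elec, clamped = 0.0, True
    return TransientFeatures(
        v_access=v_access, v_elec=v_elec, pulse=vt.pulse, clamped=clamped
    )


def find_imax(
    provider: Callable[[float], float],
    window: ElectrolysisWindow,
    t_pw: float,
    bracket: tuple[float, float],
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Largest safe injected current: the I at which the cathodal excitation
    reaches the cathodal electrolysis threshold |E_mc|.

    ``provider(i_inj)`` must return the cathodal excitation magnitude (V)
    for a current magnitude (A) at the given pulse width; it is bisected
    until the excitation is within ``tol`` volts of |E_mc|.  Monotonicity is
    verified on the bracket endpoints.
    """
    if np.isnan(window.e_mc):
        raise ValueError("window has no cathodal threshold (open window)")
    target = abs(window.e_mc)
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    v_lo, v_hi = provider(lo), provider(hi)
    if v_lo >= v_hi:
        raise ValueError(
            f"excitation not increasing on bracket: v({lo:g} A) = {v_lo:.4g} V, "
            f"v({hi:g} A) = {v_hi:.4g} V"
        )
    if not v_lo <= target <= v_hi:
        raise ValueError(
            f"bracket does not straddle |E_mc| = {target:.4g} V: "
            f"excitations [{v_lo:.4g}, {v_hi:.4g}] V"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v_mid = provider(mid)
        if abs(v_mid - target) < tol:
            return mid
        if v_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
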