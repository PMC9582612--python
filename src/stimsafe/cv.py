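"""Electrolysis (water) window extraction from cyclic voltammetry.

Below the window the sweep current is capacitive (proportional to scan
rate) plus reversible redox contributions; past either onset, irreversible
electrolysis makes the current grow without bound.  The detector looks for
that signature: current exceeding a multiple of the capacitive baseline
envelope and growing monotonically for the remainder of the sweep arm.
A derivative-only criterion is deliberately avoided — it fires on noise.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .types import CVSweep, ElectrolysisWindow

__all__ = ["detect_electrolysis_window", "ElectrolysisWindowDetector"]


def _fold_arms(v: np.ndarray, i: np.ndarray, n_bins: int = 400):
    """Average forward and reverse sweep arms onto a common potential grid.

    Direction alignment: samples are binned by potential regardless of sweep
    direction and bin-averaged, which cancels the capacitive hysteresis sign.
    """
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=np.abs(i), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mask = counts > 0
    return centers[mask], sums[mask] / counts[mask]


class ElectrolysisWindowDetector(BaseEstimator):
    """Ratio-over-baseline electrolysis onset detector.

    Parameters
    ----------
    baseline_band : float
        Fraction of the potential range, centred, used to estimate the
        capacitive baseline envelope (default: middle 40%).
    onset_ratio : float
        A sweep arm is in electrolysis once |i| exceeds this multiple of the
        baseline envelope *and* |i| keeps growing for the rest of the arm.

    The detector is invariant to uniform current scaling.  Attributes
    ``window_`` (ElectrolysisWindow) and ``e_mc_`` / ``e_ma_`` are set by
    :meth:`fit`; an arm with no onset inside the scan range gets the NaN
    open-window sentinel.
    """

    def __init__(self, baseline_band: float = 0.4, onset_ratio: float = 3.0):
        self.baseline_band = baseline_band
        self.onset_ratio = onset_ratio

    def fit(self, X: CVSweep, y=None):
        cv = X
        if not isinstance(cv, CVSweep):
            raise TypeError("expected a CVSweep")
        if len(cv.v) < 100:
            raise ValueError("need >= 100 samples")
        if cv.v.min() >= 0 or cv.v.max() <= 0:
            raise ValueError("sweep must span both polarities")
        if not 0 < self.baseline_band < 1:
            raise ValueError("baseline_band must be in (0, 1)")
        if self.onset_ratio <= 1:
            raise ValueError("onset_ratio must be > 1")

        v_grid, i_mag = _fold_arms(cv.v, cv.i)
        v_span = cv.v.max() - cv.v.min()
        v_mid = 0.5 * (cv.v.max() + cv.v.min())
        half = 0.5 * self.baseline_band * v_span
        in_band = np.abs(v_grid - v_mid) <= half
        baseline = float(np.max(i_mag[in_band])) if np.any(in_band) else float(np.median(i_mag))
        threshold = self.onset_ratio * max(baseline, 1e-300)

        self.e_ma_ = self._arm_onset(v_grid, i_mag, threshold, anodal=True)
        self.e_mc_ = self._arm_onset(v_grid, i_mag, threshold, anodal=False)
        self.window_ = ElectrolysisWindow(
            e_mc=self.e_mc_,
            e_ma=self.e_ma_,
            method_meta={
                "baseline_band": self.baseline_band,
                "onset_ratio": self.onset_ratio,
                "baseline_current_a": baseline,
                "config": cv.config,
            },
        )
        return self

    @staticmethod
    def _arm_onset(v_grid, i_mag, threshold, anodal: bool) -> float:
        """Lowest-|V| grid potential past which |i| exceeds threshold and
        keeps growing to the end of the arm; NaN when no onset is found."""
        if anodal:
            v_arm, i_arm = v_grid[v_grid > 0], i_mag[v_grid > 0]
        else:
            v_arm, i_arm = -v_grid[v_grid < 0][::-1], i_mag[v_grid < 0][::-1]
        above = i_arm > threshold
        growing = np.r_[np.diff(i_arm) > 0, True]
        # sustained growth: all later increments positive
        sustained = np.cumprod(growing[::-1])[::-1].astype(bool)
        ok = above & sustained
        if not np.any(ok):
            return float("nan")
        v_on = float(v_arm[np.argmax(ok)])
        return v_on if anodal else -v_on


def detect_electrolysis_window(
    cv: CVSweep, baseline_band: float = 0.4, onset_ratio: float = 3.0
) -> ElectrolysisWindow:
    """Extract the electrolysis window; see :class:`ElectrolysisWindowDetector`."""
    det = ElectrolysisWindowDetector(baseline_band=baseline_band, onset_ratio=onset_ratio)
    return det.fit(cv).window_
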