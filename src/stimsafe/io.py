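"""CSV/JSON readers and writers for the measurement record types.

Layouts
-------
EIS:        ``freq_hz, z_real_ohm, z_imag_ohm`` (one file per configuration)
CV:         ``potential_v, current_a``
Transient:  ``time_s, voltage_v``
rho–R:      ``resistivity_ohm_m, resistance_ohm``
Features:   ``i_inj_a, t_pw_s, v_access_v, v_elec_v``

Each measurement CSV has a JSON sidecar (same stem, ``.json``) carrying the
electrode spec and acquisition settings.  Model parameters serialise to
JSON with their unit convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CVSweep,
    EISSpectrum,
    ElectrodeSpec,
    ElectrolysisWindow,
    SafetyParams,
    ScalingParams,
    StimPulse,
    TransientFeatures,
    UnitConvention,
    VoltageTransient,
)

__all__ = [
    "write_eis", "read_eis",
    "write_cv", "read_cv",
    "write_transient", "read_transient",
    "write_features_table", "read_features_table",
    "write_params", "read_safety_params", "read_scaling_params", "read_window",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _spec_to_dict(spec: Optional[ElectrodeSpec]) -> Optional[dict]:
    return dataclasses.asdict(spec) if spec is not None else None


def _spec_from_dict(d: Optional[dict]) -> Optional[ElectrodeSpec]:
    return ElectrodeSpec(**d) if d else None


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# -- EIS -------------------------------------------------------------------


def write_eis(s: EISSpectrum, path: str | Path) -> Path:
    path = Path(path).with_suffix(".csv")
    pd.DataFrame(
        {"freq_hz": s.freqs, "z_real_ohm": s.z.real, "z_imag_ohm": s.z.imag}
    ).to_csv(path, index=False)
    _write_json(_sidecar(path), {"config": s.config, "electrode": _spec_to_dict(s.meta)})
    return path


def read_eis(path: str | Path) -> EISSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(_sidecar(path).read_text())
    return EISSpectrum(
        freqs=df["freq_hz"].to_numpy(),
        z=df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy(),
        config=side["config"],
        meta=_spec_from_dict(side.get("electrode")),
    )


# -- CV --------------------------------------------------------------------


def write_cv(cv: CVSweep, path: str | Path) -> Path:
    path = Path(path).with_suffix(".csv")
    pd.DataFrame({"potential_v": cv.v, "current_a": cv.i}).to_csv(path, index=False)
    _write_json(
        _sidecar(path),
        {
            "scan_rate_v_per_s": cv.scan_rate,
            "config": cv.config,
            "electrode": _spec_to_dict(cv.meta),
        },
    )
    return path


def read_cv(path: str | Path) -> CVSweep:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(_sidecar(path).read_text())
    return CVSweep(
        v=df["potential_v"].to_numpy(),
        i=df["current_a"].to_numpy(),
        scan_rate=side["scan_rate_v_per_s"],
        config=side["config"],
        meta=_spec_from_dict(side.get("electrode")),
    )


# -- transients ------------------------------------------------------------


def write_transient(vt: VoltageTransient, path: str | Path) -> Path:
    path = Path(path).with_suffix(".csv")
    pd.DataFrame({"time_s": vt.t, "voltage_v": vt.v}).to_csv(path, index=False)
    _write_json(
        _sidecar(path),
        {
            "i_inj_a": vt.pulse.i_inj,
            "t_pw_s": vt.pulse.t_pw,
            "interphase_gap_s": vt.pulse.interphase_gap,
            "electrode": _spec_to_dict(vt.meta),
        },
    )
    return path


def read_transient(path: str | Path) -> VoltageTransient:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(_sidecar(path).read_text())
    pulse = StimPulse(
        i_inj=side["i_inj_a"],
        t_pw=side["t_pw_s"],
        interphase_gap=side.get("interphase_gap_s", 0.0),
    )
    return VoltageTransient(
        t=df["time_s"].to_numpy(),
        v=df["voltage_v"].to_numpy(),
        pulse=pulse,
        meta=_spec_from_dict(side.get("electrode")),
    )


# -- feature tables --------------------------------------------------------


def write_features_table(features: Sequence[TransientFeatures], path: str | Path) -> Path:
    path = Path(path).with_suffix(".csv")
    pd.DataFrame(
        {
            "i_inj_a": [f.pulse.i_inj for f in features],
            "t_pw_s": [f.pulse.t_pw for f in features],
            "v_access_v": [f.v_access for f in features],
            "v_elec_v": [f.v_elec for f in features],
        }
    ).to_csv(path, index=False)
    return path


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- parameter JSON --------------------------------------------------------


def write_params(obj, path: str | Path, provenance: Optional[dict] = None) -> Path:
    """Serialise SafetyParams / ScalingParams / ElectrolysisWindow to JSON."""
    path = Path(path).with_suffix(".json")
    if isinstance(obj, SafetyParams):
        d = {
            "kind": "safety_params",
            "a_v": obj.a, "b": obj.b, "k2": obj.k2, "k4": obj.k4, "k6": obj.k6,
            "adj_r2": None if np.isnan(obj.adj_r2) else obj.adj_r2,
            "unit_convention": dataclasses.asdict(obj.unit_convention),
        }
    elif isinstance(obj, ScalingParams):
        d = {
            "kind": "scaling_params",
            "alpha": obj.alpha, "d1": obj.d1,
            "r2": None if np.isnan(obj.r2) else obj.r2,
        }
    elif isinstance(obj, ElectrolysisWindow):
        d = {
            "kind": "electrolysis_window",
            "e_mc_v": None if np.isnan(obj.e_mc) else obj.e_mc,
            "e_ma_v": None if np.isnan(obj.e_ma) else obj.e_ma,
            "method_meta": obj.method_meta,
        }
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    if provenance:
        d["provenance"] = provenance
    _write_json(path, d)
    return path


def read_safety_params(path: str | Path) -> SafetyParams:
    d = json.loads(Path(path).read_text())
    return SafetyParams(
        a=d["a_v"], b=d["b"], k2=d["k2"], k4=d["k4"], k6=d["k6"],
        unit_convention=UnitConvention(**d["unit_convention"]),
        adj_r2=float("nan") if d.get("adj_r2") is None else d["adj_r2"],
    )


def read_scaling_params(path: str | Path) -> ScalingParams:
    d = json.loads(Path(path).read_text())
    return ScalingParams(
        alpha=d["alpha"], d1=d["d1"],
        r2=float("nan") if d.get("r2") is None else d["r2"],
    )


def read_window(path: str | Path) -> ElectrolysisWindow:
    d = json.loads(Path(path).read_text())
    nan = float("nan")
    return ElectrolysisWindow(
        e_mc=nan if d.get("e_mc_v") is None else d["e_mc_v"],
        e_ma=nan if d.get("e_ma_v") is None else d["e_ma_v"],
        method_meta=d.get("method_meta", {}),
    )
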