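"""End-to-end orchestration: generate/load -> EIS -> CV -> transients -> model.

A run is described by a :class:`RunConfig` (JSON on disk) naming either a
synthetic-study generator spec or a set of measured input files.  The
pipeline executes the full analysis chain and writes every artifact plus a
manifest listing the seed, package versions, generator truth (when
synthetic) and a SHA-256 hash per output file, so a run can be reproduced
and checked byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as sio
from .cv import detect_electrolysis_window
from .eis import delineate_interface, fit_impedance_scaling, reactance_at
from .safety import fit_full_model, ilimit_vs_diameter, shannon_limit
from .synthetic import (
    DIAMETERS_M,
    PRESETS,
    NoiseSpec,
    electrode_truth,
    generate_cv,
    generate_eis_dataset,
    generate_transient_dataset,
)
from .transients import extract_cathodal_excitation
from .types import ElectrodeSpec

__all__ = ["RunConfig", "GeneratorSpec", "InputPaths", "DetectorSettings",
           "parse_config", "run_pipeline"]


class GeneratorSpec(BaseModel):
    """Synthetic-study description: one material swept over a diameter ladder."""

    model_config = ConfigDict(extra="forbid")

    material: str = "PtNR"
    diameters_um: list[float] = [30.0, 50.0, 100.0, 200.0, 400.0]
    separation_factor: float = 1.5
    medium: Literal["benchtop_saline", "in_vivo"] = "benchtop_saline"
    currents_ua: list[float] = [20.0, 50.0, 100.0, 200.0, 500.0]
    pulse_widths_us: list[float] = [100.0, 200.0, 400.0, 700.0, 1000.0]
    z_mag_rel_sd: float = 0.01
    phase_sd_deg: float = 1.0
    v_rel_sd: float = 0.01


class InputPaths(BaseModel):
    """Measured-data mode: paths to CSVs written in the package's layouts."""

    model_config = ConfigDict(extra="forbid")

    eis_three_contact: str
    eis_four_contact: str
    cv: str
    transients: list[str]


class DetectorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    baseline_band: float = 0.4
    onset_ratio: float = 3.0


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    generator: Optional[GeneratorSpec] = None
    inputs: Optional[InputPaths] = None
    reactance_freq_hz: float = 10e3
    scan_rate_v_per_s: float = 0.2
    detector: DetectorSettings = DetectorSettings()
    shannon_k: float = 1.8
    out_dir: str = "stimsafe_run"
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError("exactly one of 'generator' or 'inputs' must be set")
        return self


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a RunConfig JSON file."""
    return RunConfig.model_validate(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "stimsafe": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured run; returns (and writes) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {"config": json.loads(cfg.model_dump_json()), "seed": cfg.seed,
                      "versions": _versions()}
    try:
        if cfg.generator is not None:
            records, window, scaling, truth = _run_generated(cfg, out, outputs)
            manifest["generator_truth"] = truth
        else:
            records, window, scaling = _run_measured(cfg, out, outputs)
    except Exception as err:  # annotate stage provenance, re-raise
        raise RuntimeError(f"pipeline failed: {err}") from err

    params = fit_full_model(records) if scaling is not None else fit_full_model(
        records, fix_k6=1.0
    )
    outputs["safety_params"] = sio.write_params(params, out / "safety_params")
    outputs["window"] = sio.write_params(window, out / "electrolysis_window")
    if scaling is not None:
        outputs["scaling_params"] = sio.write_params(scaling, out / "scaling_params")
        _write_safety_map(cfg, params, scaling, window, out, outputs)

    manifest["outputs"] = {
        name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
        for name, p in sorted(outputs.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _run_generated(cfg: RunConfig, out: Path, outputs: dict):
    g = cfg.generator
    if g.material not in PRESETS:
        raise ValueError(f"unknown material preset {g.material!r}")
    preset = PRESETS[g.material]
    noise = NoiseSpec(
        z_mag_rel_sd=g.z_mag_rel_sd, phase_sd_deg=g.phase_sd_deg,
        v_rel_sd=g.v_rel_sd, seed=cfg.seed,
    )
    currents = [c * 1e-6 for c in g.currents_ua]
    widths = [w * 1e-6 for w in g.pulse_widths_us]

    records = []
    scaling_pairs = []
    window = None
    truth_export = {}
    for d_um in g.diameters_um:
        spec = ElectrodeSpec(
            material=g.material, diameter_m=d_um * 1e-6,
            separation_factor=g.separation_factor, medium=g.medium,
        )
        tag = f"d{int(round(d_um))}um"
        truth = electrode_truth(spec, preset, noise.seed)
        truth.pop("circuit")
        truth_export[tag] = truth

        spectra = generate_eis_dataset(spec, preset, noise=noise)
        for s in spectra:
            outputs[f"eis_{s.config}_{tag}"] = sio.write_eis(s, out / f"eis_{s.config}_{tag}")
        by_config = {s.config: s for s in spectra}
        iface = delineate_interface(by_config["three_contact"], by_config["four_contact"])
        z_im = reactance_at(iface, cfg.reactance_freq_hz)
        scaling_pairs.append((spec.diameter_m, z_im))

        cv = generate_cv(spec, preset, scan_rate=cfg.scan_rate_v_per_s, noise=noise)
        outputs[f"cv_{tag}"] = sio.write_cv(cv, out / f"cv_{tag}")
        w = detect_electrolysis_window(
            cv, baseline_band=cfg.detector.baseline_band,
            onset_ratio=cfg.detector.onset_ratio,
        )
        if window is None:
            window = w

        transients = generate_transient_dataset(
            spec, preset, currents=currents, pulse_widths=widths, noise=noise
        )
        feats = [extract_cathodal_excitation(vt) for vt in transients]
        outputs[f"features_{tag}"] = sio.write_features_table(feats, out / f"features_{tag}")
        records += [
            (f.pulse.i_inj, f.pulse.t_pw, z_im, f.v_elec) for f in feats
        ]

    scaling = (
        fit_impedance_scaling(scaling_pairs) if len(set(p[0] for p in scaling_pairs)) >= 3
        else None
    )
    return records, window, scaling, truth_export


def _run_measured(cfg: RunConfig, out: Path, outputs: dict):
    inp = cfg.inputs
    z3 = sio.read_eis(inp.eis_three_contact)
    z4 = sio.read_eis(inp.eis_four_contact)
    iface = delineate_interface(z3, z4)
    z_im = reactance_at(iface, cfg.reactance_freq_hz)

    cv = sio.read_cv(inp.cv)
    window = detect_electrolysis_window(
        cv, baseline_band=cfg.detector.baseline_band, onset_ratio=cfg.detector.onset_ratio
    )
    feats = [extract_cathodal_excitation(sio.read_transient(p)) for p in inp.transients]
    outputs["features"] = sio.write_features_table(feats, out / "features")
    records = [(f.pulse.i_inj, f.pulse.t_pw, z_im, f.v_elec) for f in feats]
    return records, window, None


def _write_safety_map(cfg, params, scaling, window, out: Path, outputs: dict):
    """Model vs Shannon current limits over the diameter ladder."""
    if np.isnan(window.e_mc):
        return
    e_mc = abs(window.e_mc)
    rows = []
    for d in DIAMETERS_M:
        for t_pw in (100e-6, 500e-6, 1000e-6):
            rows.append(
                {
                    "diameter_m": d,
                    "t_pw_s": t_pw,
                    "i_limit_model_a": ilimit_vs_diameter(params, scaling, e_mc, t_pw, d),
                    "i_limit_shannon_a": shannon_limit(d, t_pw, cfg.shannon_k).i_limit_a,
                }
            )
    path = out / "safety_map.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    outputs["safety_map"] = path
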