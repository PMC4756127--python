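"""NIfTI readers/writers, declarative configuration, and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .params import CompartmentParams, ModelParams, default_model_params
from .sequence import RFPulse, SequenceSpec

__all__ = ["read_nifti", "write_nifti", "RunConfig", "load_config", "provenance_record"]

log = logging.getLogger("brainpv")


def read_nifti(path):
    """Load a NIfTI volume.  Returns (data, voxel_size_mm, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    return data, voxel, img.affine


def write_nifti(data, path, voxel_size_mm=(1.0, 1.0, 1.0), affine=None) -> None:
    """Write a float32 NIfTI volume; the affine defaults to a scaled
    identity built from the voxel size."""
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_size_mm) + img.header.get_zooms()[3:])
    nib.save(img, str(path))


def _model_from_dict(d: dict) -> ModelParams:
    defaults = default_model_params().to_dict()
    missing = [k for k in defaults if k not in d]
    if missing:
        log.info("model parameters %s not in config; using calibrated defaults", missing)
    merged = {**defaults, **{k: float(v) for k, v in d.items() if k in defaults}}
    unknown = set(d) - set(defaults)
    if unknown:
        raise KeyError(f"unknown model parameter keys: {sorted(unknown)}")
    comp = {name: CompartmentParams(r1=merged[f"r1_{name}"], r2=merged[f"r2_{name}"],
                                    pd=merged[f"pd_{name}"])
            for name in ("my", "cl", "fw", "epw")}
    return ModelParams(my=comp["my"], cl=comp["cl"], fw=comp["fw"], epw=comp["epw"],
                       k_my_cl=merged["k_my_cl"])


def _sequence_from_dict(d: dict) -> SequenceSpec:
    d = dict(d)
    for key in ("sat_pulse", "exc_pulse", "refocus_pulse"):
        if key in d:
            d[key] = RFPulse(**d[key])
    for key in ("te_ms", "td_ms"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    if "shape" in d:
        raise KeyError("pulse shapes belong under sat_pulse/exc_pulse/refocus_pulse")
    return SequenceSpec(**d)


@dataclass
class RunConfig:
    """Validated, fully-serializable run configuration."""

    model: ModelParams = field(default_factory=default_model_params)
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    seed: int = 0
    grid_step_pct: float = 1.0
    grid_sim_step_pct: float = 5.0
    v_my_cap_pct: float = 40.0
    n_restarts: int = 100
    output_dir: str = "."
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "sequence": self.sequence.to_dict(),
            "seed": self.seed,
            "grid_step_pct": self.grid_step_pct,
            "grid_sim_step_pct": self.grid_sim_step_pct,
            "v_my_cap_pct": self.v_my_cap_pct,
            "n_restarts": self.n_restarts,
            "output_dir": self.output_dir,
            "paths": self.paths,
        }


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing sections fall back to the
    calibrated defaults with a logged notice."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"model", "sequence", "seed", "grid_step_pct", "grid_sim_step_pct",
             "v_my_cap_pct", "n_restarts", "output_dir", "paths"}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "model" in raw:
        cfg.model = _model_from_dict(raw["model"] or {})
    else:
        log.info("no model section in config; using calibrated defaults")
    if "sequence" in raw:
        cfg.sequence = _sequence_from_dict(raw["sequence"] or {})
    for key in ("seed", "grid_step_pct", "grid_sim_step_pct", "v_my_cap_pct",
                "n_restarts", "output_dir", "paths"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def provenance_record(cfg: RunConfig, extra: dict | None = None) -> dict:
    """JSON-serializable provenance: config hash, seed, package version."""
    from . import __version__

    blob = json.dumps(cfg.to_dict(), sort_keys=True)
    rec = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "brainpv_version": __version__,
    }
    if extra:
        rec.update(extra)
    return rec
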