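"""Clinical volumetrics from partial-volume maps.

Total compartment volumes are partial-volume sums over the intracranial
mask times the voxel volume.  Derived quantities:

* BPV = ICV - FWV (brain parenchyma excludes bulk CSF), BPF = BPV/ICV;
* MYF / CF / EPWF = MYV / CV / EPWV over BPV;
* MWF = (V_MY PD_MY) / (V_CL PD_CL + V_EPW PD_EPW) per voxel -- the
  myelin-water share of the observable medium-time water;
* aqueous content = sum of V_p PD_p over the four compartments; the
  non-aqueous remainder reflects macromolecular content.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

from .params import ModelParams, VoxelComposition
from .lookup import PartialVolumeMaps

__all__ = [
    "VolumeReport",
    "compute_volumes",
    "mwf",
    "aqueous_content",
    "pv_histograms",
    "roi_stats",
]


@dataclass(frozen=True)
class VolumeReport:
    """Total volumes (mL) and fractions (%) over an intracranial mask."""

    myv: float
    cv: float
    fwv: float
    epwv: float
    icv: float
    bpv: float
    bpf: float
    myf: float
    cf: float
    epwf: float
    degenerate: bool = False  # BPV == 0: fractions undefined

    def rounded(self) -> dict:
        """Report-style rounding: whole mL, one decimal percent."""
        out = {k: round(v) for k, v in
               (("myv", self.myv), ("cv", self.cv), ("fwv", self.fwv),
                ("epwv", self.epwv), ("bpv", self.bpv), ("icv", self.icv))}
        out.update({k: round(v, 1) for k, v in
                    (("bpf", self.bpf), ("myf", self.myf),
                     ("cf", self.cf), ("epwf", self.epwf))})
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def compute_volumes(pv: PartialVolumeMaps, voxel_volume_ml: float | None = None) -> VolumeReport:
    """Sum partial volumes over the mask into total volumes and fractions."""
    if not np.any(pv.mask):
        raise ValueError("empty mask")
    vv = pv.voxel_volume_ml if voxel_volume_ml is None else voxel_volume_ml
    if vv <= 0:
        raise ValueError("voxel volume must be positive")
    m = pv.mask
    myv = float(pv.v_my[m].sum()) / 100.0 * vv
    cv = float(pv.v_cl[m].sum()) / 100.0 * vv
    fwv = float(pv.v_fw[m].sum()) / 100.0 * vv
    epwv = float(pv.v_epw[m].sum()) / 100.0 * vv
    icv = float(m.sum()) * vv
    bpv = icv - fwv
    degenerate = bpv <= 0
    frac = (lambda v: 100.0 * v / bpv) if not degenerate else (lambda v: np.nan)
    return VolumeReport(myv=myv, cv=cv, fwv=fwv, epwv=epwv, icv=icv, bpv=bpv,
                        bpf=100.0 * bpv / icv, myf=frac(myv), cf=frac(cv),
                        epwf=frac(epwv), degenerate=degenerate)


def _comp_percent(comp) -> tuple[float, float, float, float]:
    if isinstance(comp, VoxelComposition):
        return comp.as_percent()
    v = tuple(float(x) for x in comp)
    if len(v) != 4:
        raise ValueError("composition must have four entries (my, cl, fw, epw)")
    return v


def mwf(comp, model: ModelParams) -> float:
    """Myelin water fraction in percent:
    MWF = (V_MY PD_MY) / (V_CL PD_CL + V_EPW PD_EPW).

    ``comp`` is a VoxelComposition or a 4-sequence of percent partial
    volumes.  Undefined (raises) when the voxel holds neither cellular
    nor excess water.
    """
    v_my, v_cl, _, v_epw = _comp_percent(comp)
    den = v_cl * model.cl.pd + v_epw * model.epw.pd
    if den <= 0:
        raise ValueError("MWF undefined: no cellular or excess water in the voxel")
    return 100.0 * (v_my * model.my.pd) / den


def aqueous_content(comp, model: ModelParams) -> float:
    """Total aqueous content in percent: the PD-weighted sum of all four
    partial volumes.  The non-aqueous remainder is 100 minus this."""
    v = np.asarray(_comp_percent(comp)) / 100.0
    pd_vals = np.array([c.pd for c in model.compartments])
    return float(v @ pd_vals)


def pv_histograms(pv: PartialVolumeMaps, n_bins: int = 100):
    """Partial-volume histograms as percent of ICV.

    Returns (hists, edges): ``hists`` has shape (4, n_bins) in compartment
    order (my, cl, fw, epw); bins are [k, k+1) percent with the top bin
    closed.  Each histogram sums to 100 (percent of ICV voxels).
    """
    if not np.any(pv.mask):
        raise ValueError("empty mask")
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    n_icv = pv.mask.sum()
    hists = np.empty((4, n_bins))
    for i, vol in enumerate((pv.v_my, pv.v_cl, pv.v_fw, pv.v_epw)):
        h, _ = np.histogram(vol[pv.mask], bins=edges)
        hists[i] = 100.0 * h / n_icv
    return hists, edges


def roi_stats(pv: PartialVolumeMaps, rois: np.ndarray, model: ModelParams) -> pd.DataFrame:
    """Per-ROI means of V_MY, V_CL, V_EPW and voxelwise MWF.

    ``rois`` is an integer label volume (0 = background).  Empty labels
    (no voxels inside the mask) are flagged.
    """
    rois = np.asarray(rois)
    if rois.shape != pv.mask.shape:
        raise ValueError("ROI labels must match map shape")
    rows = []
    den_w = np.array([model.cl.pd, model.epw.pd])
    for label in np.unique(rois):
        if label == 0:
            continue
        sel = (rois == label) & pv.mask
        if not np.any(sel):
            rows.append({"label": int(label), "n_voxels": 0, "v_my": np.nan,
                         "v_cl": np.nan, "v_epw": np.nan, "mwf": np.nan,
                         "empty": True})
            continue
        v_my, v_cl, v_epw = pv.v_my[sel], pv.v_cl[sel], pv.v_epw[sel]
        den = v_cl * den_w[0] + v_epw * den_w[1]
        voxel_mwf = np.where(den > 0, 100.0 * v_my * model.my.pd / np.where(den > 0, den, 1.0),
                             np.nan)
        rows.append({
            "label": int(label), "n_voxels": int(sel.sum()),
            "v_my": float(v_my.mean()), "v_cl": float(v_cl.mean()),
            "v_epw": float(v_epw.mean()), "mwf": float(np.nanmean(voxel_mwf)),
            "empty": False,
        })
    return pd.DataFrame(rows).set_index("label")
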