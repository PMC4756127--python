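"""Composition lattice lookup: forward manifold and voxel inversion.

The forward model maps a voxel composition (V_MY, V_CL, V_FW, V_EPW) to
fitted (R1, R2, PD).  Enumerating compositions on a lattice (myelin
capped at 40 %, free and excess water free, cellular the remainder)
yields a curved 3-parameter manifold in (R1, R2, PD) space that contains
the healthy FW-CL-MY curve and the myelin-loss/edema surface as faces.
Inversion maps a measured triple to the nearest lattice sample in
variance-normalized coordinates.

Simulation runs on a coarse lattice (default 5 % steps) plus the
fine-stepped FW-CL and MY-CL edge curves, then the fitted triples are
linearly interpolated onto the requested fine lattice (default 1 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .params import ModelParams, VoxelComposition
from .sequence import SequenceSpec
from .bloch import simulate_batch
from .qmapfit import QMaps, fit_signal_batch
from .calibration import manifold_compositions

__all__ = ["LookupGrid", "PartialVolumeMaps", "build_grid", "invert_voxel", "invert_volume"]


def _lattice(step: float, v_my_cap: float) -> np.ndarray:
    """All (v_my, v_fw, v_epw) percent triples on the simplex lattice with
    v_my <= cap and v_cl = 100 - sum >= 0; returns (N, 4) fractions."""
    if abs(100.0 / step - round(100.0 / step)) > 1e-9:
        raise ValueError("step must divide 100")
    vals = np.arange(0.0, 100.0 + step / 2, step)
    my = vals[vals <= v_my_cap + 1e-9]
    rows = []
    for vm in my:
        for vf in vals[vals <= 100.0 - vm + 1e-9]:
            for ve in vals[vals <= 100.0 - vm - vf + 1e-9]:
                rows.append([vm, 100.0 - vm - vf - ve, vf, ve])
    return np.asarray(rows) / 100.0


@dataclass
class LookupGrid:
    """Sampled forward-model manifold over voxel compositions.

    ``comps_pct`` holds compositions in percent (my, cl, fw, epw);
    ``triples`` the matching fitted (R1, R2, PD); ``sigma2`` the per-axis
    normalization variances of the inversion metric.
    """

    comps_pct: np.ndarray  # (N, 4)
    triples: np.ndarray    # (N, 3)
    step_pct: float
    v_my_cap: float
    sigma2: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.comps_pct.shape[0] != self.triples.shape[0]:
            raise ValueError("comps and triples must align")
        if not np.all(np.isfinite(self.triples)):
            raise ValueError("fitted triples must be finite")
        sums = self.comps_pct.sum(axis=1)
        if np.any(np.abs(sums - 100.0) > 1e-6):
            raise ValueError("compositions must sum to 100%")
        if np.any(self.comps_pct[:, 0] > self.v_my_cap + 1e-9):
            raise ValueError("v_my exceeds the cap")
        # the pure-FW and pure-CL vertices anchor the healthy curve
        for vertex in ([0.0, 100.0, 0.0, 0.0], [0.0, 0.0, 100.0, 0.0]):
            if not np.any(np.all(np.isclose(self.comps_pct, vertex, atol=1e-6), axis=1)):
                raise ValueError("grid must contain the pure-CL and pure-FW vertices")
        self._tree = None

    def _norm(self, triples: np.ndarray) -> np.ndarray:
        return triples / np.sqrt(np.asarray(self.sigma2))

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self._norm(self.triples))
        return self._tree

    def save(self, path) -> None:
        meta = dict(self.meta)
        meta.update({"step_pct": self.step_pct, "v_my_cap": self.v_my_cap,
                     "sigma2": list(self.sigma2), "format_version": 1})
        np.savez_compressed(path, comps_pct=self.comps_pct, triples=self.triples,
                            meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "LookupGrid":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(comps_pct=z["comps_pct"], triples=z["triples"],
                       step_pct=meta.pop("step_pct"), v_my_cap=meta.pop("v_my_cap"),
                       sigma2=tuple(meta.pop("sigma2")), meta=meta)


def _hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def build_grid(model: ModelParams, seq: SequenceSpec, step: float = 1.0,
               v_my_cap: float = 40.0, sim_step: float = 5.0,
               sigma2: tuple[float, float, float] | None = None,
               fit_b1: bool = True) -> LookupGrid:
    """Simulate + fit the composition lattice and densify by interpolation.

    Compositions are simulated on the ``sim_step`` lattice together with
    the 1 %-stepped FW-CL and MY-CL edge curves, fitted, PD-normalized to
    the pure-FW vertex, and linearly interpolated onto the ``step``
    lattice in (v_my, v_fw, v_epw) space.  ``sigma2`` defaults to the
    per-axis variance of the grid triples; pass the calibration ridge
    variances to share the calibration metric.
    """
    sim_comps = _lattice(sim_step, v_my_cap)
    edges = manifold_compositions(v_my_cap)
    sim_comps = np.unique(np.round(np.vstack([sim_comps, edges]), 10), axis=0)

    sig, converged = simulate_batch(sim_comps, model, seq)
    fit = fit_signal_batch(sig, seq, fit_b1=fit_b1)
    bad = ~np.isfinite(fit["r1"])
    if np.any(bad):
        raise RuntimeError(
            "simulation/fit failed for compositions (percent): "
            f"{(sim_comps[bad][:5] * 100).tolist()}")
    fw_idx = np.nonzero(np.all(np.isclose(sim_comps, [0, 0, 1.0, 0]), axis=1))[0][0]
    pd_fit = 100.0 * fit["m0"] / fit["m0"][fw_idx]
    sim_triples = np.stack([fit["r1"], fit["r2"], pd_fit], axis=1)

    if step == sim_step:
        comps, triples = sim_comps, sim_triples
    else:
        target = _lattice(step, v_my_cap)
        xi_sim = sim_comps[:, [0, 2, 3]]  # (v_my, v_fw, v_epw) determine v_cl
        xi_tgt = target[:, [0, 2, 3]]
        interp = LinearNDInterpolator(xi_sim, sim_triples)
        triples = interp(xi_tgt)
        # exact simulated values where the lattices coincide
        tree = cKDTree(xi_sim)
        dist, idx = tree.query(xi_tgt)
        exact = dist < 1e-9
        triples[exact] = sim_triples[idx[exact]]
        hole = ~np.all(np.isfinite(triples), axis=1)
        if np.any(hole):  # points outside the convex hull (rounding slivers)
            triples[hole] = sim_triples[tree.query(xi_tgt[hole])[1]]
        comps = target

    # collapse physically degenerate samples (e.g. the v_cl = 0 plane,
    # where excess water has no exchange partner and is indistinguishable
    # from free water) onto the tie-break representative: smallest v_epw,
    # then smallest v_my
    order = np.lexsort((comps[:, 0], comps[:, 3]))
    comps, triples = comps[order], triples[order]
    key = np.round(triples, 7)
    _, first = np.unique(key, axis=0, return_index=True)
    keep = np.sort(first)
    comps, triples = comps[keep], triples[keep]

    if sigma2 is None:
        sigma2 = tuple(float(np.var(triples[:, k])) for k in range(3))
    meta = {"model": _hash(model.to_dict()), "sequence": _hash(seq.to_dict()),
            "sim_step_pct": sim_step, "converged": bool(np.all(converged))}
    return LookupGrid(comps_pct=comps * 100.0, triples=triples, step_pct=step,
                      v_my_cap=v_my_cap, sigma2=sigma2, meta=meta)


def _query(grid: LookupGrid, pts: np.ndarray):
    """Nearest grid sample per point with deterministic tie-breaking
    toward smaller v_epw, then smaller v_my."""
    q = grid._norm(pts)
    k = min(4, len(grid.triples))
    dist, idx = grid.tree.query(q, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best = dist[:, :1]
    ties = dist <= best * (1 + 1e-12) + 1e-15
    # among ties prefer smaller v_epw, then smaller v_my
    vep = grid.comps_pct[idx][:, :, 3]
    vmy = grid.comps_pct[idx][:, :, 0]
    key = np.where(ties, vep * 1e4 + vmy, np.inf)
    pick = np.argmin(key, axis=1)
    rows = np.arange(len(q))
    return idx[rows, pick], dist[rows, pick]


def invert_voxel(r1: float, r2: float, pd: float, grid: LookupGrid):
    """Map one measured (R1, R2, PD) triple to the nearest lattice
    composition.  Returns (VoxelComposition, normalized distance)."""
    pt = np.asarray([[r1, r2, pd]], dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ValueError("inputs must be finite")
    idx, dist = _query(grid, pt)
    c = grid.comps_pct[idx[0]] / 100.0
    comp = VoxelComposition(v_my=c[0], v_cl=c[1], v_fw=c[2], v_epw=c[3])
    return comp, float(dist[0])


@dataclass
class PartialVolumeMaps:
    """Voxelwise partial-volume maps in percent, plus inversion quality."""

    v_my: np.ndarray
    v_cl: np.ndarray
    v_fw: np.ndarray
    v_epw: np.ndarray
    distance: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 4.0)
    #: normalized distance above which a voxel is considered off-manifold
    qc_threshold: float = 3.0

    def __post_init__(self) -> None:
        m = self.mask
        total = (self.v_my + self.v_cl + self.v_fw + self.v_epw)[m]
        if m.any() and not np.allclose(total, 100.0, atol=1e-6):
            raise ValueError("partial volumes must sum to 100% inside the mask")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def off_manifold(self) -> np.ndarray:
        return self.mask & (self.distance > self.qc_threshold)

    def qc_report(self) -> dict:
        n = int(self.mask.sum())
        return {
            "n_voxels": n,
            "n_off_manifold": int(self.off_manifold.sum()),
            "median_distance": float(np.median(self.distance[self.mask])) if n else np.nan,
            "qc_threshold": self.qc_threshold,
        }


def invert_volume(qmaps: QMaps, grid: LookupGrid,
                  icv_mask: np.ndarray | None = None) -> PartialVolumeMaps:
    """Voxelwise inversion of R1/R2/PD maps into partial-volume maps."""
    mask = qmaps.mask if icv_mask is None else (np.asarray(icv_mask, dtype=bool) & qmaps.mask)
    if mask.shape != qmaps.r1.shape:
        raise ValueError(f"mask shape {mask.shape} does not match maps {qmaps.r1.shape}")
    pts = np.stack([qmaps.r1[mask], qmaps.r2[mask], qmaps.pd[mask]], axis=1)
    idx, dist = _query(grid, pts)
    comps = grid.comps_pct[idx]

    def scatter(vals, fill=np.nan):
        vol = np.full(mask.shape, fill)
        vol[mask] = vals
        return vol

    return PartialVolumeMaps(
        v_my=scatter(comps[:, 0]), v_cl=scatter(comps[:, 1]),
        v_fw=scatter(comps[:, 2]), v_epw=scatter(comps[:, 3]),
        distance=scatter(dist), mask=mask,
        voxel_size_mm=qmaps.voxel_size_mm,
    )
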