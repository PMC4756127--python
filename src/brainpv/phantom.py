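"""Synthetic brain phantom: composition fields with ground truth.

The phantom emulates the tissue classes the partial-volume model is
built for: an ellipsoidal intracranial volume holding a gray-matter
shell (low myelin, ~5 %), a white-matter core (~30 % myelin), pure
free-water ventricles, and optional lesions with elevated excess
parenchymal water (edema, up to ~55 %) and reduced myelin.  Tissue
borders are mixed over a configurable width so compositions span the
full mixing manifold, as acquisition voxels do at real tissue
interfaces.  Compositions are quantized to a 1 % lattice, which both
matches the inversion lattice and makes composition-cached acquisition
simulation cheap.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .params import ModelParams
from .sequence import SequenceSpec
from .bloch import simulate_batch

__all__ = ["Lesion", "PhantomSpec", "Phantom", "make_phantom", "simulate_acquisition",
           "ms_lesions", "small_phantom_spec"]

#: tissue label codes
BACKGROUND, GM, WM, VENTRICLE, DEEP_GM, LESION = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class Lesion:
    """Spherical lesion: center offset from the brain center in mm."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    v_epw_pct: float = 40.0
    v_my_pct: float = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue composition and acquisition-noise description."""

    shape: tuple[int, int, int] = (46, 56, 44)
    voxel_mm: float = 3.0
    #: ICV ellipsoid semi-axes, mm (defaults give ~1.2 L)
    icv_semi_axes_mm: tuple[float, float, float] = (62.0, 78.0, 59.0)
    #: subarachnoid CSF layer between the cortex and the ICV boundary, mm
    csf_shell_mm: float = 3.0
    #: cortical shell thickness, mm (GM between the CSF layer and WM core)
    gm_shell_mm: float = 12.0
    #: lateral-ventricle ellipsoid semi-axes and x-offsets, mm
    ventricle_semi_axes_mm: tuple[float, float, float] = (8.0, 25.0, 10.0)
    ventricle_offset_mm: float = 12.0
    #: deep gray matter sleeve around the ventricles (caudate/thalamus
    #: analogue: nearly unmyelinated tissue lining the ventricle walls)
    deep_gm_shell_mm: float = 6.0
    deep_gm_v_my_pct: float = 2.0
    gm_v_my_pct: float = 5.0
    wm_v_my_pct: float = 30.0
    lesions: tuple[Lesion, ...] = ()
    #: tissue-border mixing width (Gaussian sigma), mm
    mix_width_mm: float = 2.0
    #: composition quantization lattice, percent
    quantize_pct: float = 1.0
    #: acquisition noise, percent of the mean in-mask signal
    noise_sigma_pct: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(2 * ax >= n * self.voxel_mm for ax, n in
               zip(self.icv_semi_axes_mm, self.shape)):
            raise ValueError("ICV ellipsoid does not fit the grid")
        if not (0 <= self.gm_v_my_pct <= 40 and 0 <= self.wm_v_my_pct <= 40):
            raise ValueError("tissue myelin content must lie in [0, 40]%")


def ms_lesions() -> tuple[Lesion, ...]:
    """A small set of periventricular white-matter lesions."""
    return (
        Lesion(center_mm=(28.0, 20.0, 8.0), radius_mm=8.0, v_epw_pct=40.0, v_my_pct=5.0),
        Lesion(center_mm=(-26.0, -24.0, -6.0), radius_mm=7.0, v_epw_pct=55.0, v_my_pct=0.0),
        Lesion(center_mm=(20.0, -30.0, 12.0), radius_mm=5.0, v_epw_pct=30.0, v_my_pct=10.0),
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Coarse phantom for tests: same anatomy on a 6 mm grid, with
    ventricles enlarged so pure-CSF interior voxels survive the border
    mixing at this resolution."""
    base = dict(shape=(24, 28, 22), voxel_mm=6.0, mix_width_mm=3.0,
                ventricle_semi_axes_mm=(13.0, 32.0, 15.0))
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class Phantom:
    """Composition volumes plus ground truth."""

    comps: np.ndarray       # (X, Y, Z, 4) fractions
    icv_mask: np.ndarray    # (X, Y, Z) bool
    labels: np.ndarray      # (X, Y, Z) int tissue codes
    spec: PhantomSpec

    @property
    def truth_pct(self) -> dict:
        """Ground-truth partial-volume maps in percent."""
        names = ("v_my", "v_cl", "v_fw", "v_epw")
        return {n: self.comps[..., i] * 100.0 for i, n in enumerate(names)}


def _quantize_rows(rows_pct: np.ndarray, step: float) -> np.ndarray:
    """Round each composition to the lattice, preserving the 100% sum by
    largest-remainder apportionment."""
    units = rows_pct / step
    base = np.floor(units)
    remainder = units - base
    short = np.round(units.sum(axis=1) - base.sum(axis=1)).astype(int)
    order = np.argsort(-remainder, axis=1, kind="stable")
    add = np.zeros_like(base)
    for j in range(4):
        sel = short > j
        add[sel, order[sel, j]] = 1.0
    return (base + add) * step


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the composition field, ICV mask and label map."""
    nx, ny, nz = spec.shape
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_mm for n in spec.shape
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")

    def ellipsoid(center, semi):
        return (((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2
                + ((z - center[2]) / semi[2]) ** 2) <= 1.0

    icv = ellipsoid((0, 0, 0), spec.icv_semi_axes_mm)
    brain_semi = tuple(max(a - spec.csf_shell_mm, 1.0) for a in spec.icv_semi_axes_mm)
    brain = ellipsoid((0, 0, 0), brain_semi)
    wm_semi = tuple(max(a - spec.csf_shell_mm - spec.gm_shell_mm, 1.0)
                    for a in spec.icv_semi_axes_mm)
    wm = ellipsoid((0, 0, 0), wm_semi)
    vent = np.zeros_like(icv)
    deep = np.zeros_like(icv)
    for sgn in (+1.0, -1.0):
        center = (sgn * spec.ventricle_offset_mm, 0, 0)
        vent |= ellipsoid(center, spec.ventricle_semi_axes_mm)
        deep |= ellipsoid(center, tuple(a + spec.deep_gm_shell_mm
                                        for a in spec.ventricle_semi_axes_mm))
    vent &= icv
    deep &= icv

    labels = np.full(spec.shape, BACKGROUND, dtype=int)
    labels[icv] = VENTRICLE  # subarachnoid CSF shares the free-water class
    labels[brain & icv] = GM
    labels[wm & icv] = WM
    labels[deep] = DEEP_GM
    labels[vent] = VENTRICLE
    for les in spec.lesions:
        sphere = ellipsoid(les.center_mm, (les.radius_mm,) * 3) & icv
        if np.any(labels[sphere] == VENTRICLE):
            warnings.warn("lesion overlaps a ventricle; lesion wins", stacklevel=2)
        labels[sphere] = LESION

    # per-tissue compositions in percent (my, cl, fw, epw)
    tissue_comp = {
        GM: (spec.gm_v_my_pct, 100.0 - spec.gm_v_my_pct, 0.0, 0.0),
        WM: (spec.wm_v_my_pct, 100.0 - spec.wm_v_my_pct, 0.0, 0.0),
        DEEP_GM: (spec.deep_gm_v_my_pct, 100.0 - spec.deep_gm_v_my_pct, 0.0, 0.0),
        VENTRICLE: (0.0, 0.0, 100.0, 0.0),
    }
    lesion_fields = []
    for i, les in enumerate(spec.lesions):
        code = LESION + i
        comp = (les.v_my_pct, 100.0 - les.v_my_pct - les.v_epw_pct, 0.0, les.v_epw_pct)
        tissue_comp[code] = comp
        lesion_fields.append((code, ellipsoid(les.center_mm, (les.radius_mm,) * 3) & icv))

    indicator = {}
    for code in (GM, WM, DEEP_GM, VENTRICLE):
        indicator[code] = (labels == code).astype(float)
    for code, sphere in lesion_fields:
        # lesion indicator overrides underlying tissue
        for other in indicator.values():
            other[sphere] = 0.0
        indicator[code] = sphere.astype(float)

    sigma_vox = spec.mix_width_mm / spec.voxel_mm
    if sigma_vox > 0:
        for code in list(indicator):
            indicator[code] = gaussian_filter(indicator[code], sigma_vox)

    total = sum(indicator.values())
    comps = np.zeros(spec.shape + (4,))
    safe = np.where(total > 0, total, 1.0)
    for code, ind in indicator.items():
        frac = np.where(icv, ind / safe, 0.0)
        comps += frac[..., None] * (np.asarray(tissue_comp[code]) / 100.0)

    flat = comps[icv] * 100.0
    comps[icv] = _quantize_rows(flat, spec.quantize_pct) / 100.0
    comps[~icv] = 0.0
    return Phantom(comps=comps, icv_mask=icv, labels=labels, spec=spec)


def make_manifold_phantom(voxels_per_comp: int = 24, v_my_cap: float = 40.0,
                          noise_sigma_pct: float = 1.0, seed: int = 0) -> Phantom:
    """Mixture-series calibration phantom.

    Physical relaxometry calibration phantoms are built as series of
    known mixtures; this is the digital analogue: one region per
    calibration composition (the FW-CL mixing series at 1 % steps and
    the MY-CL series up to the myelin cap), each ``voxels_per_comp``
    voxels.  Every composition of the healthy manifold is therefore
    present, which makes the ridge-calibration problem fully
    identifiable -- unlike anatomical phantoms, where no tissue is purer
    than the cortical ~2 % myelin and the pure-cellular point is only
    constrained by extrapolation.
    """
    from .calibration import manifold_compositions

    comps_list = manifold_compositions(v_my_cap)  # (N, 4)
    n = len(comps_list)
    comps = np.broadcast_to(comps_list[:, None, None, :],
                            (n, voxels_per_comp, 1, 4)).copy()
    mask = np.ones((n, voxels_per_comp, 1), dtype=bool)
    labels = np.broadcast_to(np.arange(1, n + 1)[:, None, None],
                             mask.shape).copy()
    spec = PhantomSpec(noise_sigma_pct=noise_sigma_pct, seed=seed)
    return Phantom(comps=comps, icv_mask=mask, labels=labels, spec=spec)


def simulate_acquisition(phantom: Phantom, model: ModelParams, seq: SequenceSpec,
                         noise_sigma_pct: float | None = None,
                         seed: int | None = None,
                         rician: bool = False) -> np.ndarray:
    """Simulate the 20-image acquisition of a phantom.

    The Bloch simulation runs once per unique composition (the quantized
    lattice keeps that count small) and the results are scattered back.
    Gaussian noise with sigma = ``noise_sigma_pct`` percent of the mean
    in-mask signal is added; ``rician=True`` applies it as magnitude
    (Rician) noise instead.  Defaults come from the phantom spec.
    """
    sigma_pct = phantom.spec.noise_sigma_pct if noise_sigma_pct is None else noise_sigma_pct
    seed = phantom.spec.seed if seed is None else seed
    mask = phantom.icv_mask
    rows = phantom.comps[mask]
    uniq, inverse = np.unique(np.round(rows, 6), axis=0, return_inverse=True)
    sig_u, _ = simulate_batch(uniq, model, seq)
    n_te, n_td = sig_u.shape[1:]
    series = np.zeros(phantom.comps.shape[:3] + (n_te, n_td))
    series[mask] = sig_u[inverse]

    if sigma_pct > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma_pct / 100.0 * float(series[mask].mean())
        if rician:
            noise_r = rng.normal(0.0, sigma, series.shape)
            noise_i = rng.normal(0.0, sigma, series.shape)
            series = np.sqrt((series + noise_r) ** 2 + noise_i**2)
        else:
            series = series + rng.normal(0.0, sigma, series.shape)
    return series
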