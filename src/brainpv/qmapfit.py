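"""Fitting R1, R2 and PD maps from the 5 x 4 (TE x TD) signal matrix.

The quantification model is a product of a mono-exponential echo decay
and a saturation-recovery curve::

    I(TE, TD) = A PD exp(-R2 TE) *
        (1 - (1 - cos(B1 th)) exp(-R1 TD) - cos(B1 th) exp(-R1 TR))
        / (1 - cos(B1 al) cos(B1 th) exp(-R1 TR))

with saturation flip ``th``, excitation flip ``al`` and relative RF
amplitude ``B1``.  The model is deliberately mono-exponential in both R1
and R2, so a multi-compartment voxel yields the rates of its *dominant*
relaxation component -- this is exactly the observable that the
four-compartment forward model is matched against.

``A`` (coil sensitivity, RF chain, voxel volume) and PD enter only as the
product ``A*PD``; PD in percent requires an amplitude reference, by
convention a pure-CSF (free water) voxel mapped to 100 %.

The least-squares core is a vectorized Levenberg-Marquardt in
``(log A*PD, log R1, log R2[, B1])`` that fits every voxel of a batch
simultaneously; a deterministic initialization uses a log-linear echo
fit for R2 and a coarse rate scan for R1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .sequence import SequenceSpec
from .bloch import SignalMatrix

__all__ = [
    "QFitResult",
    "QMaps",
    "quantification_signal",
    "fit_signal_batch",
    "fit_qmaps",
    "fit_volume",
    "synthesize_weighted",
]

R1_BOUNDS = (0.05, 30.0)
R2_BOUNDS = (0.1, 100.0)


def quantification_signal(te_ms, td_ms, m0, r1, r2, b1=1.0, sat_flip_deg=120.0,
                          exc_flip_deg=90.0, tr_ms=2950.0) -> np.ndarray:
    """Evaluate the quantification model on a TE x TD grid.

    ``m0 = A*PD`` is the joint amplitude.  Parameters may be scalars or
    (N,) arrays; the result has shape (N, n_te, n_td) (leading axis
    dropped for scalar input).
    """
    te = np.asarray(te_ms, dtype=float)[None, :, None] * 1e-3
    td = np.asarray(td_ms, dtype=float)[None, None, :] * 1e-3
    tr = tr_ms * 1e-3
    scalar = all(np.ndim(v) == 0 for v in (m0, r1, r2, b1))
    m0, r1, r2, b1 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float)) for v in (m0, r1, r2, b1))
    )
    m0, r1, r2, b1 = (v[:, None, None] for v in (m0, r1, r2, b1))
    ct = np.cos(b1 * math.radians(sat_flip_deg))
    ca = np.cos(b1 * math.radians(exc_flip_deg))
    e_tr = np.exp(-r1 * tr)
    rec = (1.0 - (1.0 - ct) * np.exp(-r1 * td) - ct * e_tr) / (1.0 - ca * ct * e_tr)
    out = m0 * np.exp(-r2 * te) * rec
    return out[0] if scalar else out


def _pack(signal) -> np.ndarray:
    """Accept SignalMatrix, (n_te, n_td) or (N, n_te, n_td); return (N, n_te, n_td)."""
    if isinstance(signal, SignalMatrix):
        signal = signal.intensities
    arr = np.asarray(signal, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def _initialize(data: np.ndarray, seq: SequenceSpec):
    """Deterministic starting values: R2 from a log-linear regression of
    the echoes at the longest delay, R1 from a coarse logarithmic rate
    scan against the first-echo recovery curve, amplitude by
    extrapolation to TE = 0."""
    n, n_te, n_td = data.shape
    te = np.asarray(seq.te_ms) * 1e-3
    eps = 1e-30

    y = np.log(np.clip(data[:, :, -1], eps, None))  # (N, n_te)
    t_c = te - te.mean()
    slope = (y * t_c).sum(axis=1) / (t_c**2).sum()
    r2 = np.clip(-slope, *R2_BOUNDS)
    amp_last = np.exp(y.mean(axis=1) + slope * (-te.mean()))  # at TE=0, longest TD

    r1_grid = np.geomspace(0.07, 25.0, 48)
    g = np.abs(quantification_signal(
        [0.0], seq.td_ms, 1.0, r1_grid, 1e-9, 1.0,
        seq.sat_flip_deg, seq.exc_flip_deg, seq.tr_ms)[:, 0, :])  # (G, n_td)
    first = data[:, 0, :]  # (N, n_td)
    scale = first @ g.T / np.maximum((g * g).sum(axis=1), eps)  # (N, G)
    resid = (first[:, None, :] - scale[:, :, None] * g[None]) ** 2
    best = resid.sum(axis=2).argmin(axis=1)
    r1 = r1_grid[best]
    g_last = g[best, -1]
    m0 = np.clip(amp_last / np.maximum(g_last, eps), eps, None)
    return m0, r1, r2


def fit_signal_batch(signal, seq: SequenceSpec, b1: float = 1.0,
                     fit_b1: bool = False, max_iter: int = 60):
    """Least-squares fit of the quantification model to a batch of signal
    matrices.  Returns a dict of (N,) arrays: m0, r1, r2, b1,
    residual_rms, converged.  All-zero inputs are flagged and left NaN.
    """
    data = _pack(signal)
    n = data.shape[0]
    flat = data.reshape(n, -1)
    ok = np.any(flat != 0.0, axis=1)

    m0, r1, r2 = _initialize(data, seq)
    n_par = 4 if fit_b1 else 3
    x = np.zeros((n, n_par))
    x[:, 0] = np.log(m0)
    x[:, 1] = np.log(np.clip(r1, *R1_BOUNDS))
    x[:, 2] = np.log(np.clip(r2, *R2_BOUNDS))
    if fit_b1:
        x[:, 3] = b1

    lo = np.log([R1_BOUNDS[0], R2_BOUNDS[0]])
    hi = np.log([R1_BOUNDS[1], R2_BOUNDS[1]])

    def model(xv):
        # magnitude of the signed model: acquired images are magnitude
        # images, so the saturation-recovery zero crossing folds over
        bb1 = xv[:, 3] if fit_b1 else np.full(xv.shape[0], b1)
        out = quantification_signal(
            seq.te_ms, seq.td_ms, np.exp(xv[:, 0]), np.exp(xv[:, 1]),
            np.exp(xv[:, 2]), bb1, seq.sat_flip_deg, seq.exc_flip_deg, seq.tr_ms)
        return np.abs(out).reshape(xv.shape[0], -1)

    lam = np.full(n, 1e-3)
    res = model(x) - flat
    cost = (res**2).sum(axis=1)
    eps_j = 1e-7
    active = ok.copy()
    for _ in range(max_iter):
        if not np.any(active):
            break
        jac = np.empty((n, flat.shape[1], n_par))
        for p in range(n_par):
            xp = x.copy()
            xp[:, p] += eps_j
            jac[:, :, p] = (model(xp) - (res + flat)) / eps_j
        jtj = np.einsum("nij,nik->njk", jac, jac)
        jtr = np.einsum("nij,ni->nj", jac, res)
        diag = np.einsum("njj->nj", jtj)
        a = jtj + (lam[:, None] * np.maximum(diag, 1e-12))[:, :, None] * np.eye(n_par)[None]
        try:
            step = -np.linalg.solve(a, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(a.reshape(-1, n_par), jtr.reshape(-1), rcond=None)[0]
        x_new = x + step
        x_new[:, 1:3] = np.clip(x_new[:, 1:3], lo, hi)
        if fit_b1:
            x_new[:, 3] = np.clip(x_new[:, 3], 0.2, 2.0)
        res_new = model(x_new) - flat
        cost_new = (res_new**2).sum(axis=1)
        better = (cost_new < cost) & active
        x[better] = x_new[better]
        res[better] = res_new[better]
        lam = np.where(better, lam * 0.3, lam * 8.0)
        lam = np.clip(lam, 1e-12, 1e8)
        moved = np.max(np.abs(step), axis=1)
        active = active & ((moved > 1e-11) | ~better) & (lam < 1e7)
        cost = np.where(better, cost_new, cost)

    r1_f = np.exp(x[:, 1])
    r2_f = np.exp(x[:, 2])
    at_bound = (
        np.isclose(r1_f, R1_BOUNDS[0]) | np.isclose(r1_f, R1_BOUNDS[1])
        | np.isclose(r2_f, R2_BOUNDS[0]) | np.isclose(r2_f, R2_BOUNDS[1])
    )
    out = {
        "m0": np.where(ok, np.exp(x[:, 0]), np.nan),
        "r1": np.where(ok, r1_f, np.nan),
        "r2": np.where(ok, r2_f, np.nan),
        "b1": np.where(ok, x[:, 3] if fit_b1 else b1, np.nan),
        "residual_rms": np.where(ok, np.sqrt(cost / flat.shape[1]), np.nan),
        "converged": ok & ~at_bound,
    }
    return out


@dataclass(frozen=True)
class QFitResult:
    """Single-voxel quantification fit."""

    r1: float
    r2: float
    pd: float  # joint amplitude A*PD unless an amplitude scale was applied
    a: float
    b1: float
    residual_rms: float
    converged: bool


def fit_qmaps(signal, seq: SequenceSpec, b1: float = 1.0, fit_b1: bool = False,
              a_scale: float = 1.0) -> QFitResult:
    """Fit one signal matrix.  ``a_scale`` divides the joint amplitude to
    express PD in percent (use the pure-CSF amplitude / 100)."""
    out = fit_signal_batch(signal, seq, b1=b1, fit_b1=fit_b1)
    m0 = float(out["m0"][0])
    return QFitResult(
        r1=float(out["r1"][0]),
        r2=float(out["r2"][0]),
        pd=m0 / a_scale if np.isfinite(m0) else np.nan,
        a=a_scale,
        b1=float(out["b1"][0]),
        residual_rms=float(out["residual_rms"][0]),
        converged=bool(out["converged"][0]),
    )


@dataclass
class QMaps:
    """Voxelwise R1, R2 and PD maps on a common grid."""

    r1: np.ndarray
    r2: np.ndarray
    pd: np.ndarray
    a: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 4.0)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.r1, self.r2, self.pd, self.a, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        if not np.all(np.isfinite(self.r1[self.mask])):
            raise ValueError("fitted voxels must be finite")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def fit_volume(series: np.ndarray, seq: SequenceSpec, mask: np.ndarray,
               b1: float = 1.0, fit_b1: bool = False,
               a_scale: float | None = None,
               reference_mask: np.ndarray | None = None,
               voxel_size_mm=(1.0, 1.0, 4.0)) -> QMaps:
    """Voxelwise quantification fit of a (X, Y, Z, n_te, n_td) series.

    PD calibration: if ``a_scale`` is given the joint amplitude is divided
    by it; otherwise, if ``reference_mask`` marks pure-CSF voxels, the
    scale is their mean amplitude / 100 %; otherwise amplitudes are
    reported unscaled (A = 1).
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    spatial = series.shape[:-2]
    if series.ndim != 5 or series.shape[-2:] != (len(seq.te_ms), len(seq.td_ms)):
        raise ValueError("series must have shape (X, Y, Z, n_te, n_td) matching the sequence")
    if mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} does not match series {spatial}")

    out = fit_signal_batch(series[mask], seq, b1=b1, fit_b1=fit_b1)
    if a_scale is None:
        if reference_mask is not None:
            ref = fit_signal_batch(series[reference_mask], seq, b1=b1, fit_b1=fit_b1)
            a_scale = float(np.nanmean(ref["m0"])) / 100.0
        else:
            a_scale = 1.0

    def scatter(vals, fill=np.nan):
        vol = np.full(spatial, fill)
        vol[mask] = vals
        return vol

    return QMaps(
        r1=scatter(out["r1"]),
        r2=scatter(out["r2"]),
        pd=scatter(out["m0"] / a_scale),
        a=scatter(np.full(mask.sum(), a_scale)),
        mask=mask & scatter(out["converged"].astype(float), 0.0).astype(bool),
        voxel_size_mm=tuple(voxel_size_mm),
    )


def csf_amplitude_scale(model, seq: SequenceSpec, fit_b1: bool = True) -> float:
    """Amplitude scale mapping fitted joint amplitudes to PD in percent.

    Simulates a pure free-water (CSF) voxel through the forward model and
    fits it; dividing fitted amplitudes by the returned scale expresses
    PD as percent of pure water.  Use when the data come from the same
    forward model (phantom studies); for measured data prefer a CSF
    reference region.
    """
    from .bloch import simulate_batch

    sig, _ = simulate_batch(np.array([[0.0, 0.0, 1.0, 0.0]]), model, seq)
    out = fit_signal_batch(sig, seq, fit_b1=fit_b1)
    return float(out["m0"][0]) / 100.0


def synthesize_weighted(qmaps: QMaps, te_ms: float = 100.0, tr_ms: float = 4500.0) -> np.ndarray:
    """Synthesize a spin-echo weighted image from quantitative maps:
    I = A PD exp(-R2 TE) (1 - exp(-R1 TR))."""
    if te_ms < 0 or tr_ms <= 0:
        raise ValueError("TE must be >= 0 and TR > 0")
    img = (qmaps.a * qmaps.pd * np.exp(-qmaps.r2 * te_ms * 1e-3)
           * (1.0 - np.exp(-qmaps.r1 * tr_ms * 1e-3)))
    return np.where(qmaps.mask, img, 0.0)
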