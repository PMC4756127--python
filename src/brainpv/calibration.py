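"""Calibrating the free model parameters against cohort histogram ridges.

The healthy brain occupies a one-dimensional curve in (R1, R2, PD) space:
from pure free water through pure cellular tissue toward (at most 40 %)
myelin.  The calibration extracts that curve empirically as the ridge of
the three pairwise 2D histograms of a control cohort's maps, then tunes
the six free model parameters (R1_MY, PD_MY, k_MY-CL, R1_CL, R2_CL,
PD_CL) so the forward-simulated curve matches the ridge.

Procedure: for each parameter set, 141 compositions are simulated and
fitted (101 FW-CL mixtures at 1 % steps plus 40 MY-CL mixtures, myelin
capped at 40 %), each model point is matched to its nearest ridge point,
and the cost is the mean variance-normalized squared residual over the
two coordinates that the ridge point's scan direction did not index.
The cost is minimized by cyclic coordinate descent with geometrically
shrinking steps from many random restarts; confidence bounds come from a
profile scan holding the cost itself below the chi-square bound 9.488
(see :func:`default_ci_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np
from scipy import stats

from .params import CompartmentParams, ModelParams, default_model_params
from .sequence import SequenceSpec
from .bloch import simulate_batch
from .qmapfit import QMaps, fit_signal_batch

__all__ = [
    "HIST_RANGES",
    "Histogram2DSet",
    "RidgeSet",
    "CalibrationResult",
    "build_histograms",
    "extract_ridge",
    "manifold_compositions",
    "model_manifold_points",
    "cost",
    "chi2_threshold",
    "default_ci_threshold",
    "optimize",
    "confidence_interval",
]

#: histogram axis ranges: R1 0-2 1/s, R2 0-15 1/s, PD 50-100 %
HIST_RANGES = ((0.0, 2.0), (0.0, 15.0), (50.0, 100.0))
N_BINS = 200


@dataclass(frozen=True)
class Histogram2DSet:
    """The three pairwise 200 x 200 histograms of (R1, R2, PD)."""

    h_r1r2: np.ndarray
    h_r1pd: np.ndarray
    h_r2pd: np.ndarray
    ranges: tuple = HIST_RANGES

    def __post_init__(self) -> None:
        for h in (self.h_r1r2, self.h_r1pd, self.h_r2pd):
            if h.shape != (N_BINS, N_BINS) or np.any(h < 0):
                raise ValueError("histograms must be 200x200 with non-negative counts")
        totals = {h.sum() for h in (self.h_r1r2, self.h_r1pd, self.h_r2pd)}
        if len(totals) != 1:
            raise ValueError("histogram totals must agree (common voxel set)")

    def to_csv(self, prefix) -> None:
        import pandas as pd

        for name, h in (("r1r2", self.h_r1r2), ("r1pd", self.h_r1pd), ("r2pd", self.h_r2pd)):
            pd.DataFrame(h).to_csv(f"{prefix}_{name}.csv", index=False)


def _bin_centers(axis: int) -> np.ndarray:
    lo, hi = HIST_RANGES[axis]
    edges = np.linspace(lo, hi, N_BINS + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def build_histograms(qmaps: QMaps, mask: np.ndarray | None = None) -> Histogram2DSet:
    """Bin all in-range masked voxels into the three pairwise histograms.

    A voxel outside any axis range is excluded from *all three* grids so
    the totals stay equal.
    """
    mask = qmaps.mask if mask is None else (np.asarray(mask, dtype=bool) & qmaps.mask)
    if not np.any(mask):
        raise ValueError("empty mask")
    vals = np.stack([qmaps.r1[mask], qmaps.r2[mask], qmaps.pd[mask]], axis=1)
    keep = np.all(np.isfinite(vals), axis=1)
    for ax in range(3):
        lo, hi = HIST_RANGES[ax]
        keep &= (vals[:, ax] >= lo) & (vals[:, ax] <= hi)
    vals = vals[keep]

    def h2(i, j):
        h, _, _ = np.histogram2d(vals[:, i], vals[:, j], bins=N_BINS,
                                 range=[HIST_RANGES[i], HIST_RANGES[j]])
        return h

    return Histogram2DSet(h_r1r2=h2(0, 1), h_r1pd=h2(0, 2), h_r2pd=h2(1, 2))


@dataclass(frozen=True)
class RidgeSet:
    """Ridge maxima triples with the axis that indexed each scan.

    ``axis`` is 0/1/2 for scans along R1/R2/PD; ``sigma2`` holds the
    per-axis variances of the ridge values used to normalize residuals.
    """

    r1: np.ndarray
    r2: np.ndarray
    pd: np.ndarray
    axis: np.ndarray
    sigma2: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = len(self.r1)
        if not (len(self.r2) == len(self.pd) == len(self.axis) == n) or n == 0:
            raise ValueError("ridge arrays must be equal-length and non-empty")
        if any(s <= 0 for s in self.sigma2):
            raise ValueError("ridge variances must be positive")

    @property
    def values(self) -> np.ndarray:
        return np.stack([self.r1, self.r2, self.pd], axis=1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "r1": self.r1.tolist(), "r2": self.r2.tolist(), "pd": self.pd.tolist(),
                "axis": self.axis.tolist(), "sigma2": list(self.sigma2),
            }, fh, indent=1)


def extract_ridge(hset: Histogram2DSet, min_count: int = 5) -> RidgeSet:
    """Per-bin argmax triples from the three pairwise histograms.

    For every bin along every axis the most populated bin of each paired
    axis is recorded (ties broken toward the lower bin index); columns
    holding fewer than ``min_count`` voxels are skipped.  Up to 600
    triples result for fully populated histograms.
    """
    grids = {
        (0, 1): hset.h_r1r2, (0, 2): hset.h_r1pd,
        (1, 2): hset.h_r2pd,
    }

    def paired(scan_ax, other_ax):
        if (scan_ax, other_ax) in grids:
            return grids[(scan_ax, other_ax)]
        return grids[(other_ax, scan_ax)].T

    rows = []
    axes = []
    for scan_ax in range(3):
        others = [a for a in range(3) if a != scan_ax]
        h_a = paired(scan_ax, others[0])  # (scan, other0)
        h_b = paired(scan_ax, others[1])
        counts = h_a.sum(axis=1)
        for b in range(N_BINS):
            if counts[b] < min_count:
                continue
            triple = np.empty(3)
            triple[scan_ax] = _bin_centers(scan_ax)[b]
            triple[others[0]] = _bin_centers(others[0])[int(np.argmax(h_a[b]))]
            triple[others[1]] = _bin_centers(others[1])[int(np.argmax(h_b[b]))]
            rows.append(triple)
            axes.append(scan_ax)
    if not rows:
        raise ValueError("no populated ridge columns (histograms empty?)")
    arr = np.asarray(rows)
    sigma2 = tuple(float(np.var(arr[:, ax])) for ax in range(3))
    if any(s <= 0 for s in sigma2):
        raise ValueError("degenerate ridge: zero variance along an axis")
    return RidgeSet(r1=arr[:, 0], r2=arr[:, 1], pd=arr[:, 2],
                    axis=np.asarray(axes, dtype=int), sigma2=sigma2)


# ---------------------------------------------------------------------------
# forward model: the 141 calibration compositions
# ---------------------------------------------------------------------------

def manifold_compositions(v_my_cap: float = 40.0) -> np.ndarray:
    """The 141 calibration compositions as (N, 4) fractions: the FW-CL
    mixing curve (V_FW = 0..100 %) and the MY-CL branch (V_MY = 1..cap %),
    both at 1 % steps."""
    rows = []
    for v_fw in range(0, 101):
        rows.append([0.0, (100 - v_fw) / 100.0, v_fw / 100.0, 0.0])
    for v_my in range(1, int(round(v_my_cap)) + 1):
        rows.append([v_my / 100.0, (100 - v_my) / 100.0, 0.0, 0.0])
    return np.asarray(rows)


def model_manifold_points(model: ModelParams, seq: SequenceSpec,
                          fit_b1: bool = True) -> np.ndarray:
    """Simulate + fit the 141 calibration compositions.

    Returns (141, 3) fitted (R1, R2, PD) triples; PD is normalized so the
    pure free-water composition reads 100 %.
    """
    comps = manifold_compositions()
    sig, _ = simulate_batch(comps, model, seq)
    fit = fit_signal_batch(sig, seq, fit_b1=fit_b1)
    bad = ~np.isfinite(fit["r1"])
    if np.any(bad):
        raise RuntimeError(f"fit failed for compositions {np.nonzero(bad)[0].tolist()}")
    m0_fw = fit["m0"][100]  # v_fw = 100 % entry
    pd = 100.0 * fit["m0"] / m0_fw
    return np.stack([fit["r1"], fit["r2"], pd], axis=1)


def cost(model_points: np.ndarray, ridge: RidgeSet) -> float:
    """Mean variance-normalized squared residual between model points and
    their selected ridge points.

    The selection pairs each model point with a *distinct* ridge point
    (greedy one-to-one assignment in ascending variance-normalized 3D
    distance); the cost then averages, over the model points, the squared
    residuals of the two coordinates that the partner's scan axis did not
    index, each normalized by its ridge variance.  One-to-one selection
    is essential: reusing ridge points lets a degenerate parameter set
    collapse the whole manifold onto one dense data cluster.
    """
    pts = np.asarray(model_points, dtype=float)
    ridge_vals = ridge.values  # (M, 3)
    n, m = len(pts), len(ridge_vals)
    sig2 = np.asarray(ridge.sigma2)
    diff = (pts[:, None, :] - ridge_vals[None, :, :]) ** 2 / sig2[None, None, :]  # (N, M, 3)
    d3 = diff.sum(axis=2)
    # zero out the indexing coordinate of each ridge point
    w = np.ones((m, 3))
    w[np.arange(m), ridge.axis] = 0.0
    d2 = np.einsum("nmk,mk->nm", diff, w)
    if m <= n:  # fewer ridge points than model points: nearest matching
        return float(np.mean(d2.min(axis=1)))
    used_n = np.zeros(n, dtype=bool)
    used_m = np.zeros(m, dtype=bool)
    total = 0.0
    count = 0
    for flat in np.argsort(d3, axis=None):
        i, j = divmod(int(flat), m)
        if used_n[i] or used_m[j]:
            continue
        used_n[i] = True
        used_m[j] = True
        total += d2[i, j]
        count += 1
        if count == n:
            break
    return total / count


def chi2_threshold(a: float = 0.05, df: int = 5) -> float:
    """Upper-tail chi-square quantile used as the confidence bound."""
    if not (0.0 < a < 1.0):
        raise ValueError("significance level must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - a, df))


def default_ci_threshold() -> float:
    """The confidence bound used by the parameter-uncertainty scan, 9.488.

    This is the established threshold for this calibration (the 5 %
    upper-tail chi-square point at 4 degrees of freedom, 9.488); note
    that the df = 5 quantile would be 11.07.
    """
    return chi2_threshold(0.05, 4)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

#: free parameters and their search ranges (generously bracketing the
#: healthy-brain optimum)
PARAM_RANGES = {
    "r1_my": (0.3, 30.0),
    "pd_my": (10.0, 100.0),
    "k_my_cl": (0.0, 30.0),
    "r1_cl": (0.3, 1.5),
    "r2_cl": (5.0, 15.0),
    "pd_cl": (60.0, 100.0),
}
PARAM_NAMES = tuple(PARAM_RANGES)


def _assemble(theta: dict, fixed: ModelParams) -> ModelParams | None:
    """Build a ModelParams from free parameters; None when the relaxation
    ordering constraints are violated."""
    try:
        my = CompartmentParams(r1=theta["r1_my"], r2=fixed.my.r2, pd=theta["pd_my"])
        cl = CompartmentParams(r1=theta["r1_cl"], r2=theta["r2_cl"], pd=theta["pd_cl"])
        return ModelParams(my=my, cl=cl, fw=fixed.fw, epw=fixed.epw,
                           k_my_cl=theta["k_my_cl"])
    except ValueError:
        return None


@dataclass
class CalibrationResult:
    """Best-fit model parameters with optimization provenance."""

    model: ModelParams
    min_cost: float
    theta: dict
    restarts: list = field(default_factory=list)  # (theta, cost) per restart
    seed: int | None = None
    bounds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "theta": self.theta,
                "min_cost": self.min_cost,
                "seed": self.seed,
                "bounds": self.bounds,
                "restarts": [{"theta": t, "cost": c} for t, c in self.restarts],
            }, fh, indent=1)


def _coordinate_descent(theta0, eval_cost, step_frac0=0.1, shrink=0.5, tol=1e-3):
    """Cyclic coordinate descent over PARAM_RANGES with geometric step
    shrinkage; returns (theta, cost, n_evals)."""
    theta = dict(theta0)
    c = eval_cost(theta)
    spans = {k: hi - lo for k, (lo, hi) in PARAM_RANGES.items()}
    frac = step_frac0
    n_ev = 1
    while frac >= tol:
        improved = False
        for name in PARAM_NAMES:
            lo, hi = PARAM_RANGES[name]
            step = frac * spans[name]
            for sgn in (+1.0, -1.0):
                cand = dict(theta)
                cand[name] = float(np.clip(theta[name] + sgn * step, lo, hi))
                if cand[name] == theta[name]:
                    continue
                cc = eval_cost(cand)
                n_ev += 1
                if cc < c:
                    theta, c = cand, cc
                    improved = True
                    break
        if not improved:
            frac *= shrink
    return theta, c, n_ev


def optimize(ridge: RidgeSet, seq: SequenceSpec,
             fixed: ModelParams | None = None,
             n_restarts: int = 100, seed: int | None = None,
             fit_b1: bool = True) -> CalibrationResult:
    """Multi-restart cyclic coordinate descent on the ridge-matching cost.

    ``fixed`` supplies the non-free parameters (water compartments and
    R2_MY); random initializations are rejection-sampled to satisfy the
    relaxation ordering constraints.  Reproducible given ``seed``.
    """
    fixed = fixed if fixed is not None else default_model_params()
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}

    def eval_cost(theta: dict) -> float:
        key = tuple(round(theta[k], 12) for k in PARAM_NAMES)
        if key not in cache:
            model = _assemble(theta, fixed)
            if model is None:
                cache[key] = np.inf
            else:
                pts = model_manifold_points(model, seq, fit_b1=fit_b1)
                cache[key] = cost(pts, ridge)
        return cache[key]

    def draw_theta() -> dict:
        for _ in range(1000):
            theta = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in PARAM_RANGES.items()}
            if _assemble(theta, fixed) is not None:
                return theta
        raise RuntimeError("could not draw a feasible initialization")

    best_theta, best_cost = None, np.inf
    log = []
    for _ in range(n_restarts):
        theta0 = draw_theta()
        theta, c, _ = _coordinate_descent(theta0, eval_cost)
        log.append((theta, c))
        if c < best_cost:
            best_theta, best_cost = theta, c

    model = _assemble(best_theta, fixed)
    assert model is not None  # descent never accepts an infeasible point
    return CalibrationResult(model=model, min_cost=best_cost, theta=best_theta,
                             restarts=log, seed=seed)


def confidence_interval(result: CalibrationResult, ridge: RidgeSet,
                        param_name: str, seq: SequenceSpec | None = None,
                        fixed: ModelParams | None = None,
                        threshold: float | None = None,
                        use_delta: bool = False,
                        n_scan: int = 40,
                        cost_fn=None, fit_b1: bool = True):
    """Profile-likelihood style confidence bounds for one parameter.

    The named parameter is scanned outward from the optimum while all
    others are re-minimized; the bound is the last scanned value whose
    cost stays at or below ``threshold`` (the chi-square quantile 9.488
    by default, compared against the cost itself as printed; pass
    ``use_delta=True`` for the conventional cost-increase criterion).
    Returns (lo, hi, open_ended) where ``open_ended`` flags bounds that
    never crossed the threshold inside the parameter range.

    ``cost_fn(theta) -> float`` may replace the forward-model cost, e.g.
    for analytically known cost surfaces.
    """
    if param_name not in PARAM_RANGES:
        raise KeyError(param_name)
    thr = default_ci_threshold() if threshold is None else threshold
    if use_delta:
        thr = result.min_cost + thr
    if result.min_cost > thr:
        raise ValueError("cost at the optimum already exceeds the threshold")
    fixed = fixed if fixed is not None else default_model_params()

    if cost_fn is None:
        if seq is None:
            raise ValueError("seq is required unless cost_fn is supplied")

        def cost_fn(theta):
            model = _assemble(theta, fixed)
            if model is None:
                return np.inf
            return cost(model_manifold_points(model, seq, fit_b1=fit_b1), ridge)

    others = [k for k in PARAM_NAMES if k != param_name]

    def profile(value: float) -> float:
        theta = dict(result.theta)
        theta[param_name] = value

        def sub_eval(th):
            return cost_fn(th)

        # re-minimize the other parameters with a short descent
        spans = {k: PARAM_RANGES[k][1] - PARAM_RANGES[k][0] for k in others}
        c = sub_eval(theta)
        frac = 0.05
        while frac >= 5e-3:
            improved = False
            for name in others:
                lo, hi = PARAM_RANGES[name]
                for sgn in (+1.0, -1.0):
                    cand = dict(theta)
                    cand[name] = float(np.clip(theta[name] + sgn * frac * spans[name], lo, hi))
                    if cand[name] == theta[name]:
                        continue
                    cc = sub_eval(cand)
                    if cc < c:
                        theta, c = cand, cc
                        improved = True
                        break
            if not improved:
                frac *= 0.5
        return c

    lo_rng, hi_rng = PARAM_RANGES[param_name]
    x0 = result.theta[param_name]
    bounds = []
    open_flags = []
    for direction, limit in ((-1.0, lo_rng), (+1.0, hi_rng)):
        grid = np.linspace(x0, limit, n_scan + 1)[1:]
        bound = x0
        crossed = False
        for v in grid:
            if profile(float(v)) <= thr:
                bound = float(v)
            else:
                crossed = True
                break
        bounds.append(bound)
        open_flags.append(not crossed)
    return bounds[0], bounds[1], (open_flags[0], open_flags[1])
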