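"""Coupled Bloch simulation of the four-compartment exchange system.

The magnetization of every slice-profile element is a set of four
3-vectors, one per compartment.  Each integration step applies, in
order: transverse relaxation/exchange, longitudinal relaxation/exchange
(with recovery toward equilibrium), the slice-select gradient rotation
about z, and the RF rotation about x or y.

Relaxation and exchange are expressed as 4x4 update matrices over the
compartments.  Longitudinal step (recovery column appended)::

    mz' = A_L mz + (1 - E1)

with, in (my, cl, fw, epw) order::

    A_L = [ E1my - S_MY(1-K)   S_MY(1-K)                    0      0          ]
          [ S_CLa(1-K)         E1cl - S_CLa(1-K) - S_CLb    0      S_CLb      ]
          [ 0                  0                            E1fw   0          ]
          [ 0                  S_EPW                        0      E1epw-S_EPW]

where ``E1p = exp(-dt R1p)``, ``K = exp(-dt k_my_cl)`` and the S factors
weight each coupling by the partner's share of proton density:
``S_MY = w_cl/(w_my+w_cl)``, ``S_CLa = w_my/(w_my+w_cl)``,
``S_CLb = w_epw/(w_epw+w_cl)``, ``S_EPW = w_cl/(w_epw+w_cl)`` with
``w_p = V_p PD_p``.  The EPW<->CL coupling carries no ``(1-K)``
attenuation: the full S fraction is exchanged every step, which
equilibrates the two pools within a few microsecond steps -- the
infinite-exchange limit.  The transverse matrix ``A_T`` has the same
structure with ``E2`` factors and no recovery column.  An exchange pair
is only active when both partners carry nonzero proton-density weight.

Free (RF-free) intervals are propagated exactly by binary powers of the
one-step matrices; ``propagation="stepwise"`` forces explicit 1-step
iteration everywhere and serves as the brute-force reference.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np

from .params import ModelParams, VoxelComposition
from .sequence import GAMMA_HZ_PER_T, SequenceSpec

__all__ = [
    "SignalMatrix",
    "rf_rotation",
    "gradient_rotation",
    "exchange_step_matrices",
    "relaxation_exchange_step",
    "simulate_sequence",
    "simulate_batch",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rf_rotation(flip_deg: float, axis: str, magnetization) -> np.ndarray:
    """Right-handed rotation of a 3-vector by ``flip_deg`` about x or y.

    Convention: a 90 deg rotation about +x maps +z to -y.
    """
    m = np.asarray(magnetization, dtype=float)
    if m.shape != (3,) or not np.all(np.isfinite(m)) or not math.isfinite(flip_deg):
        raise ValueError("magnetization must be a finite 3-vector with finite flip angle")
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    a = math.radians(flip_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = m
    if axis == "x":
        return np.array([x, c * y - s * z, s * y + c * z])
    return np.array([c * x + s * z, y, -s * x + c * z])


def gradient_rotation(grad_t_per_m: float, d_i_m: float, dt_s: float, magnetization) -> np.ndarray:
    """Rotation about z by the gradient-induced phase w = 2 pi gamma G d t."""
    m = np.asarray(magnetization, dtype=float)
    if m.shape != (3,) or not np.all(np.isfinite(m)):
        raise ValueError("magnetization must be a finite 3-vector")
    if not all(map(math.isfinite, (grad_t_per_m, d_i_m, dt_s))):
        raise ValueError("gradient parameters must be finite")
    w = 2.0 * math.pi * GAMMA_HZ_PER_T * grad_t_per_m * d_i_m * dt_s
    c, s = math.cos(w), math.sin(w)
    x, y, z = m
    return np.array([c * x - s * y, s * x + c * y, z])


def _pair_fractions(w_a: np.ndarray, w_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S factors for an exchange pair: fraction of the partner's weight.

    Returns (s_into_a, s_into_b) = (w_b/(w_a+w_b), w_a/(w_a+w_b)); zero when
    either partner has zero weight (no partner -> no exchange).
    """
    den = w_a + w_b
    active = (w_a > 0) & (w_b > 0)
    safe = np.where(den > 0, den, 1.0)
    return np.where(active, w_b / safe, 0.0), np.where(active, w_a / safe, 0.0)


def exchange_step_matrices(model: ModelParams, comps: np.ndarray, dt: float):
    """One-step longitudinal and transverse update matrices.

    Parameters
    ----------
    comps : (..., 4) array of partial-volume fractions in (my, cl, fw, epw)
        order.
    dt : step length in seconds.

    Returns
    -------
    a_l : (..., 4, 4) longitudinal matrix, r : (4,) recovery column,
    a_t : (..., 4, 4) transverse matrix.
    """
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    pd = np.array([c.pd for c in model.compartments])
    r1 = np.array([c.r1 for c in model.compartments])
    r2 = np.array([c.r2 for c in model.compartments])
    e1 = np.exp(-dt * r1)
    e2 = np.exp(-dt * r2)
    kf = 1.0 - math.exp(-dt * model.k_my_cl)

    w = comps * pd  # (..., 4) proton-density weights
    s_my, s_cla = _pair_fractions(w[..., 0], w[..., 1])
    s_epw, s_clb = _pair_fractions(w[..., 3], w[..., 1])

    n = comps.shape[0]
    a_l = np.zeros((n, 4, 4))
    a_t = np.zeros((n, 4, 4))
    for a, e in ((a_l, e1), (a_t, e2)):
        a[:, 0, 0] = e[0] - s_my * kf
        a[:, 0, 1] = s_my * kf
        a[:, 1, 0] = s_cla * kf
        a[:, 1, 1] = e[1] - s_cla * kf - s_clb
        a[:, 1, 3] = s_clb
        a[:, 2, 2] = e[2]
        a[:, 3, 1] = s_epw
        a[:, 3, 3] = e[3] - s_epw
    recovery = np.broadcast_to(1.0 - e1, (n, 4)).copy()
    return a_l, recovery, a_t


def relaxation_exchange_step(mz, mxy, comp: VoxelComposition, model: ModelParams, dt: float):
    """Apply one relaxation-and-exchange step to (mz, mxy) 4-vectors.

    ``mxy`` may be complex; the same real transverse matrix acts on both
    quadratures.  Warns when ``dt`` is large enough that any exponential
    factor drops below 0.99 (the step-splitting assumption degrades).
    """
    rates = [c.r1 for c in model.compartments] + [c.r2 for c in model.compartments]
    if dt * max(rates) > -math.log(0.99):
        warnings.warn("dt too coarse: relaxation factors below 0.99 per step", stacklevel=2)
    a_l, r, a_t = exchange_step_matrices(model, comp.as_array()[None, :], dt)
    mz = np.asarray(mz, dtype=float)
    mxy = np.asarray(mxy)
    if mz.shape != (4,) or mxy.shape != (4,):
        raise ValueError("mz and mxy must be 4-vectors")
    return a_l[0] @ mz + r[0], a_t[0] @ mxy


# ---------------------------------------------------------------------------
# signal container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalMatrix:
    """Simulated intensities I(TE, TD): rows are echoes, columns delays."""

    intensities: np.ndarray  # (n_te, n_td)
    te_ms: tuple[float, ...]
    td_ms: tuple[float, ...]
    converged: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (len(self.te_ms), len(self.td_ms)):
            raise ValueError("intensity matrix shape must be (n_te, n_td)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", arr)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.intensities,
            index=[f"TE={te:g}ms" for te in self.te_ms],
            columns=[f"TD={td:g}ms" for td in self.td_ms],
        )
        df.to_csv(path)


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------

class _FreePropagator:
    """Propagates RF-free intervals, either exactly (matrix powers of the
    one-step update, with cached binary powers) or by explicit stepping."""

    def __init__(self, a_l, r, a_t, stepwise: bool):
        b = a_l.shape[0]
        self.stepwise = stepwise
        self.a_l, self.r, self.a_t = a_l, r, a_t
        # augmented 5x5 longitudinal map [[A, r], [0, 1]] so recovery
        # accumulates under matrix powering
        aug = np.zeros((b, 5, 5))
        aug[:, :4, :4] = a_l
        aug[:, :4, 4] = r
        aug[:, 4, 4] = 1.0
        self._aug = aug
        self._pow_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _powers(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        if n not in self._pow_cache:
            bl, bt = None, None
            sq_l, sq_t = self._aug, self.a_t
            m = n
            while m:
                if m & 1:
                    bl = sq_l if bl is None else np.einsum("bij,bjk->bik", bl, sq_l)
                    bt = sq_t if bt is None else np.einsum("bij,bjk->bik", bt, sq_t)
                m >>= 1
                if m:
                    sq_l = np.einsum("bij,bjk->bik", sq_l, sq_l)
                    sq_t = np.einsum("bij,bjk->bik", sq_t, sq_t)
            self._pow_cache[n] = (bl, bt)
        return self._pow_cache[n]

    def apply(self, state, n: int) -> None:
        if n <= 0:
            return
        mx, my, mz = state
        if self.stepwise:
            for _ in range(n):
                mz[...] = np.einsum("bij,bej->bei", self.a_l, mz) + self.r[:, None, :]
                mx[...] = np.einsum("bij,bej->bei", self.a_t, mx)
                my[...] = np.einsum("bij,bej->bei", self.a_t, my)
            return
        bl, bt = self._powers(n)
        mz[...] = np.einsum("bij,bej->bei", bl[:, :4, :4], mz) + bl[:, :4, 4][:, None, :]
        mx[...] = np.einsum("bij,bej->bei", bt, mx)
        my[...] = np.einsum("bij,bej->bei", bt, my)


def _apply_z_phase(state, phi) -> None:
    """Per-element rotation about z; phi has shape (n_elements,)."""
    mx, my, _ = state
    c = np.cos(phi)[None, :, None]
    s = np.sin(phi)[None, :, None]
    mx[...], my[...] = c * mx - s * my, s * mx + c * my


def _apply_rotation(state, angle: float, axis: str) -> None:
    """Uniform rotation of all elements/pools about x or y."""
    mx, my, mz = state
    c, s = math.cos(angle), math.sin(angle)
    if axis == "x":
        my[...], mz[...] = c * my - s * mz, s * my + c * mz
    else:
        mx[...], mz[...] = c * mx + s * mz, -s * mx + c * mz


class _ShapedPulse:
    """Precomputed shaped-pulse propagation: per-step flip increments and
    the constant per-element gradient phase per step."""

    def __init__(self, pulse, flip_deg, axis, seq: SequenceSpec, width_factor=1.0,
                 selective=True):
        dt = seq.dt_rf
        env = pulse.envelope(dt)
        self.alpha = env * dt * math.radians(flip_deg)  # rad per step
        self.axis = axis
        self.n_steps = len(self.alpha)
        grad = seq.slice_gradient_t_per_m(pulse, width_factor) if selective else 0.0
        d = seq.element_positions_m
        self.phi = 2.0 * math.pi * GAMMA_HZ_PER_T * grad * d * dt
        # residual slice-dephasing after the pulse end, measured from the
        # pulse center (isodelay = half duration for a symmetric pulse)
        self.rephase = -0.5 * self.n_steps * self.phi

    def apply(self, state, prop: _FreePropagator) -> None:
        mx, my, mz = state
        cphi = np.cos(self.phi)[None, :, None]
        sphi = np.sin(self.phi)[None, :, None]
        a_l, r, a_t = prop.a_l, prop.r[:, None, :], prop.a_t
        for a in self.alpha:
            mx[...] = np.einsum("bij,bej->bei", a_t, mx)
            my[...] = np.einsum("bij,bej->bei", a_t, my)
            mz[...] = np.einsum("bij,bej->bei", a_l, mz) + r
            mx[...], my[...] = cphi * mx - sphi * my, sphi * mx + cphi * my
            c, s = math.cos(a), math.sin(a)
            if self.axis == "x":
                my[...], mz[...] = c * my - s * mz, s * my + c * mz
            else:
                mx[...], mz[...] = c * mx + s * mz, -s * mx + c * mz

    def effective_cos_flip(self) -> np.ndarray:
        """Per-element Mz after applying the pulse to equilibrium, used to
        seed the steady-state iteration (relaxation-free propagation)."""
        e = len(self.phi)
        state = (np.zeros((1, e, 1)), np.zeros((1, e, 1)), np.ones((1, e, 1)))
        ident = _FreePropagator(np.ones((1, 1, 1)), np.zeros((1, 1)),
                                np.ones((1, 1, 1)), stepwise=False)
        self.apply(state, ident)
        return state[2][0, :, 0]


def _steps(ms: float, dt: float) -> int:
    return int(round(ms * 1e-3 / dt))


def _steady_state_init(model: ModelParams, seq: SequenceSpec, td_ms: float,
                       cos_t, cos_a, cos_r) -> np.ndarray:
    """Analytic single-pool pre-saturation steady state, per element/pool.

    Composes, per element, the affine longitudinal cycle map: saturation
    (effective cos flip), recovery over TD, excitation, the refocusing
    train (each pulse scales Mz by its effective cos flip), and recovery
    to TR; the fixed point seeds the steady-state iteration.  Exchange is
    ignored here -- the subsequent preparation cycles absorb it.
    """
    r1 = np.array([c.r1 for c in model.compartments])[None, :]  # (1, 4)
    te = np.asarray(seq.te_ms, dtype=float)
    prev = np.concatenate([[0.0], te[:-1]])
    ref_off = (prev + te) / 2.0  # refocus centers after excitation, ms

    def expand(c):
        return np.asarray(c, dtype=float)[:, None]

    events = [(0.0, expand(cos_t)), (td_ms, expand(cos_a))]
    events += [(td_ms + off, expand(cos_r)) for off in ref_off]

    # affine map m_pre -> a*m_pre + b over one TR
    e_shape = (len(np.asarray(cos_t)), 4)
    a = np.ones(e_shape)
    b = np.zeros(e_shape)
    t_prev = 0.0
    for t_ev, c in events:
        e = np.exp(-r1 * (t_ev - t_prev) * 1e-3)
        a, b = a * e, (1.0 - e) + e * b
        a, b = a * c, b * c
        t_prev = t_ev
    e = np.exp(-r1 * (seq.tr_ms - t_prev) * 1e-3)
    a, b = a * e, (1.0 - e) + e * b
    return b / (1.0 - a)  # (E, 4)


def simulate_batch(comps, model: ModelParams, seq: SequenceSpec,
                   propagation: str = "exact"):
    """Simulate the quantification sequence for a batch of compositions.

    Parameters
    ----------
    comps : (B, 4) array of partial-volume fractions, (my, cl, fw, epw).
    propagation : "exact" propagates RF-free intervals with matrix powers
        of the one-step update; "stepwise" iterates every microsecond step
        explicitly (brute-force reference; identical physics).

    Returns
    -------
    intensities : (B, n_te, n_td) echo intensities (PD-weighted transverse
        magnitude averaged over slice-profile elements).
    converged : (B,) bool steady-state convergence flags.
    """
    if propagation not in ("exact", "stepwise"):
        raise ValueError(f"unknown propagation {propagation!r}")
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    if comps.shape[1] != 4:
        raise ValueError("comps must have shape (B, 4)")
    b = comps.shape[0]
    dt = seq.dt_rf
    hard = seq.pulse_mode == "hard"
    e_n = 1 if hard else seq.n_elements

    a_l, r, a_t = exchange_step_matrices(model, comps, dt)
    prop = _FreePropagator(a_l, r, a_t, stepwise=(propagation == "stepwise"))

    pd = np.array([c.pd for c in model.compartments])
    weights = comps * pd  # (B, 4)

    sat_a = math.radians(seq.sat_flip_deg)
    exc_a = math.radians(seq.exc_flip_deg)
    ref_a = math.radians(seq.refocus_flip_deg)

    if hard:
        n_sat = n_exc = n_ref = 0
        cos_t = np.full(1, math.cos(sat_a))
        cos_a = np.full(1, math.cos(exc_a))
        cos_r = np.full(1, math.cos(ref_a))
        sat_p = exc_p = ref_p = None
        crusher_phi = None
    else:
        sat_p = _ShapedPulse(seq.sat_pulse, seq.sat_flip_deg, seq.sat_axis, seq,
                             width_factor=seq.sat_width_factor)
        exc_p = _ShapedPulse(seq.exc_pulse, seq.exc_flip_deg, seq.exc_axis, seq)
        ref_p = _ShapedPulse(seq.refocus_pulse, seq.refocus_flip_deg, seq.refocus_axis,
                             seq, width_factor=seq.refocus_width_factor,
                             selective=seq.refocus_selective)
        n_sat, n_exc, n_ref = sat_p.n_steps, exc_p.n_steps, ref_p.n_steps
        cos_t = sat_p.effective_cos_flip()
        cos_a = exc_p.effective_cos_flip()
        cos_r = ref_p.effective_cos_flip()
        d = seq.element_positions_m
        extent = seq.profile_extent_mm * 1e-3
        crusher_phi = 2.0 * math.pi * seq.crusher_cycles * d / extent

    n_tr = _steps(seq.tr_ms, dt)
    te = np.asarray(seq.te_ms, dtype=float)
    # refocusing pulse centers: midway between the previous echo (or the
    # excitation) and the next echo -- the spin-echo condition
    prev = np.concatenate([[0.0], te[:-1]])
    ref_ms = (prev + te) / 2.0

    out = np.zeros((b, len(te), len(seq.td_ms)))
    converged = np.ones(b, dtype=bool)

    for j_td, td in enumerate(seq.td_ms):
        # timeline in integer steps; saturation center defines t = 0
        c_exc = _steps(td, dt)
        ref_c = [c_exc + _steps(m, dt) for m in ref_ms]
        echo_c = [c_exc + _steps(m, dt) for m in te]

        zero_mask = weights.sum(axis=1) == 0

        if hard:
            # the full cycle (transverse spoiled at both ends) is an affine
            # map Mz -> P Mz + q of the 4-pool longitudinal state; probe it
            # with basis columns and solve for the exact steady state
            probe_mz = np.zeros((b, 5, 4))
            probe_mz[:, :4, :] = np.eye(4)[None]
            probe = (np.zeros((b, 5, 4)), np.zeros((b, 5, 4)), probe_mz)
            _run_cycle(probe, prop, seq, hard, sat_p, exc_p, ref_p,
                       crusher_phi, sat_a, exc_a, ref_a,
                       n_sat, n_exc, n_ref, c_exc, ref_c, echo_c,
                       n_tr, dt, weights)
            q = probe[2][:, 4, :]                      # (B, 4)
            p = probe[2][:, :4, :].swapaxes(1, 2) - q[:, :, None]
            mz_ss = np.linalg.solve(np.eye(4)[None] - p, q[..., None])[..., 0]
            state = (np.zeros((b, 1, 4)), np.zeros((b, 1, 4)), mz_ss[:, None, :])
            echoes = _run_cycle(state, prop, seq, hard, sat_p, exc_p, ref_p,
                                crusher_phi, sat_a, exc_a, ref_a,
                                n_sat, n_exc, n_ref, c_exc, ref_c, echo_c,
                                n_tr, dt, weights)
            out[:, :, j_td] = echoes
            continue

        mz0 = _steady_state_init(model, seq, td, cos_t, cos_a, cos_r)  # (E,4)
        mx = np.zeros((b, e_n, 4))
        my = np.zeros((b, e_n, 4))
        mz = np.broadcast_to(mz0[None], (b, e_n, 4)).copy()
        state = (mx, my, mz)
        # only pools that carry proton-density weight matter for the signal
        w_mask = (weights > 0)[:, None, :]

        prev_end = None
        ok = np.zeros(b, dtype=bool)
        for cycle in range(seq.n_prep_cycles):
            echoes = _run_cycle(state, prop, seq, hard, sat_p, exc_p, ref_p,
                                crusher_phi, sat_a, exc_a, ref_a,
                                n_sat, n_exc, n_ref, c_exc, ref_c, echo_c,
                                n_tr, dt, weights)
            end = mz.copy()
            if prev_end is not None:
                delta = np.max(np.abs(end - prev_end) * w_mask, axis=(1, 2))
                ok = delta < seq.ss_tol
                if np.all(ok | zero_mask):
                    break
            prev_end = end
        converged &= ok | zero_mask
        out[:, :, j_td] = echoes
    return out, converged


def _run_cycle(state, prop, seq, hard, sat_p, exc_p, ref_p, crusher_phi,
               sat_a, exc_a, ref_a, n_sat, n_exc, n_ref,
               c_exc, ref_c, echo_c, n_tr, dt, weights):
    """One full TR: saturation, delay, CPMG train, recovery.  Returns the
    echo intensities recorded during this cycle."""
    mx, my, mz = state
    echoes = np.zeros((weights.shape[0], len(echo_c)))

    # saturation pulse (center at t=0; shaped pulse occupies [-n/2, n/2])
    if hard:
        _apply_rotation(state, sat_a, seq.sat_axis)
        t = 0
    else:
        sat_p.apply(state, prop)
        t = n_sat - n_sat // 2  # pulse end relative to its center
    # idealized spoiling of the saturation's transverse magnetization
    mx[...] = 0.0
    my[...] = 0.0

    # free until excitation
    exc_start = c_exc - n_exc // 2
    prop.apply(state, exc_start - t)
    t = exc_start
    if hard:
        _apply_rotation(state, exc_a, seq.exc_axis)
    else:
        exc_p.apply(state, prop)
        _apply_z_phase(state, exc_p.rephase)
        t += n_exc

    for k, (rc, ec) in enumerate(zip(ref_c, echo_c)):
        ref_start = rc - n_ref // 2
        prop.apply(state, ref_start - t)
        t = ref_start
        if hard:
            _apply_rotation(state, ref_a, seq.refocus_axis)
        else:
            # equal lobes straddle each refocusing pulse, so the primary
            # spin-echo pathway is rephased; the lobe area grows along the
            # train (irrational increments) so indirect and stimulated
            # pathways from imperfect flips never rephase
            phi_k = crusher_phi * (1.0 + 0.6180339887 * k)
            _apply_z_phase(state, phi_k)
            ref_p.apply(state, prop)
            _apply_z_phase(state, phi_k)
            t += n_ref
        prop.apply(state, ec - t)
        t = ec
        sig = np.einsum("bp,bep->b", weights, mx) + 1j * np.einsum("bp,bep->b", weights, my)
        echoes[:, k] = np.abs(sig) / mx.shape[1]

    # recovery until the next saturation (center at n_tr); spoil residual
    # transverse magnetization at the end of the readout
    mx[...] = 0.0
    my[...] = 0.0
    next_start = n_tr - (n_sat // 2 if not hard else 0)
    prop.apply(state, next_start - t)
    return echoes


def simulate_sequence(comp: VoxelComposition, model: ModelParams, seq: SequenceSpec,
                      propagation: str = "exact") -> SignalMatrix:
    """Simulate the 5 x 4 signal matrix for a single voxel composition."""
    intensities, converged = simulate_batch(comp.as_array()[None, :], model, seq,
                                            propagation=propagation)
    if not converged[0]:
        warnings.warn("steady state not reached within n_prep_cycles", stacklevel=2)
    return SignalMatrix(intensities=intensities[0], te_ms=tuple(seq.te_ms),
                        td_ms=tuple(seq.td_ms), converged=bool(converged[0]))
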