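"""Acquisition description for the multi-echo, multi-delay quantification scan.

The sequence is a multi-slice saturation-recovery spin-echo: a 120deg
slice-selective saturation pulse, a delay TD, then a CPMG readout
(90deg(x) excitation followed by 180deg(y) refocusing pulses straddled by
crusher gradients) collecting 5 echoes at 14 ms multiples.  Four
interleavings of the multi-slice loop realize four saturation delays, so
one scan yields a 5 (TE) x 4 (TD) image matrix per slice.  Here the
slice-shift bookkeeping is abstracted into the four TD values.

Slice-profile physics is modeled by spreading ``n_elements`` isochromats
over ``profile_extent_mm`` in the slice direction; the slice-select
gradient amplitude is chosen so the RF pulse bandwidth maps onto
``slice_thickness_mm``.  A ``pulse_mode="hard"`` variant replaces every
pulse by an instantaneous on-axis rotation of a single element, which is
exact for an ideal slice profile and orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = ["RFPulse", "SequenceSpec", "default_sequence", "hard_pulse_sequence"]

#: gyromagnetic ratio of 1H, Hz/T
GAMMA_HZ_PER_T = 42.577478518e6


@dataclass(frozen=True)
class RFPulse:
    """Named RF envelope: shape, duration and time-bandwidth product."""

    shape: str = "hann_sinc"  # "hann_sinc" | "hard"
    duration_ms: float = 1.0
    time_bandwidth: float = 4.0

    def __post_init__(self) -> None:
        if self.shape not in ("hann_sinc", "hard"):
            raise ValueError(f"unknown RF shape {self.shape!r}")
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if self.time_bandwidth <= 0:
            raise ValueError("time-bandwidth product must be positive")

    @property
    def bandwidth_hz(self) -> float:
        """Full bandwidth of the pulse main lobe, Hz."""
        return self.time_bandwidth / (self.duration_ms * 1e-3)

    def envelope(self, dt: float) -> np.ndarray:
        """Unit-area amplitude samples on a grid of step ``dt`` seconds.

        The returned samples integrate (sum * dt) to 1; multiplying by the
        desired flip angle in radians gives the rotation per step directly,
        alpha_n = 2*pi*gamma*B1_n*dt with the B1 scale absorbed.
        """
        n = max(2, int(round(self.duration_ms * 1e-3 / dt)))
        t = (np.arange(n) + 0.5) / n - 0.5  # in units of duration, centered
        if self.shape == "hard":
            amp = np.ones(n)
        else:
            x = self.time_bandwidth * t
            amp = np.sinc(x) * (0.5 + 0.5 * np.cos(2 * np.pi * t))
        area = amp.sum() * dt
        return amp / area


@dataclass(frozen=True)
class SequenceSpec:
    """Timings, flip angles and slice-profile description of the scan."""

    tr_ms: float = 2950.0
    te_ms: tuple[float, ...] = (14.0, 28.0, 42.0, 56.0, 70.0)
    td_ms: tuple[float, ...] = (100.0, 400.0, 1380.0, 2860.0)
    sat_flip_deg: float = 120.0
    sat_axis: str = "x"
    exc_flip_deg: float = 90.0
    exc_axis: str = "x"
    refocus_flip_deg: float = 180.0
    refocus_axis: str = "y"
    slice_thickness_mm: float = 4.0
    profile_extent_mm: float = 15.0
    n_elements: int = 150
    sat_pulse: RFPulse = field(default_factory=lambda: RFPulse("hann_sinc", 1.2, 4.0))
    exc_pulse: RFPulse = field(default_factory=lambda: RFPulse("hann_sinc", 1.0, 4.0))
    refocus_pulse: RFPulse = field(default_factory=lambda: RFPulse("hann_sinc", 1.0, 4.0))
    #: when True the refocusing pulses are slice-selective with
    #: ``refocus_width_factor`` times the excitation slice width; the
    #: default is non-selective refocusing (no slice gradient), which
    #: keeps the CPMG condition exactly across the whole profile.
    refocus_selective: bool = False
    refocus_width_factor: float = 3.0
    #: saturation slice width relative to the excitation slice; saturating
    #: a wider band gives the whole excited profile a uniform saturation
    #: flip, as in-product saturation pulses are designed to do.
    sat_width_factor: float = 2.0
    #: crusher gradient phase spread across the profile extent, in cycles
    #: (applied identically before and after each refocusing pulse).
    crusher_cycles: float = 4.25
    #: RF integration step, seconds
    dt_rf: float = 1e-6
    #: steady-state preparation: iterate full-TR cycles until the largest
    #: longitudinal change falls below ss_tol, capped at n_prep_cycles.
    n_prep_cycles: int = 10
    ss_tol: float = 1e-4
    #: "shaped": full slice-profile integration; "hard": ideal
    #: instantaneous rotations on a single element.
    pulse_mode: str = "shaped"

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        td = np.asarray(self.td_ms, dtype=float)
        if te.size < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("te_ms must be strictly increasing")
        if td.size < 1 or np.any(np.diff(td) <= 0):
            raise ValueError("td_ms must be strictly increasing")
        if np.any(td >= self.tr_ms):
            raise ValueError("all saturation delays must be shorter than TR")
        if td[-1] + te[-1] >= self.tr_ms:
            raise ValueError("echo train must finish within TR for the longest delay")
        if self.n_elements < 1 or (self.pulse_mode == "shaped" and self.n_elements < 2):
            raise ValueError("need at least 2 slice-profile elements in shaped mode")
        if self.dt_rf <= 0:
            raise ValueError("dt_rf must be positive")
        if self.pulse_mode not in ("shaped", "hard"):
            raise ValueError(f"unknown pulse_mode {self.pulse_mode!r}")
        for ax in (self.sat_axis, self.exc_axis):
            if ax not in ("x", "y"):
                raise ValueError("RF axes must be 'x' or 'y'")
        if self.refocus_axis not in ("x", "y"):
            raise ValueError("RF axes must be 'x' or 'y'")

    # -- derived geometry -------------------------------------------------

    @property
    def element_positions_m(self) -> np.ndarray:
        """Isochromat offsets from the slice center, meters."""
        if self.pulse_mode == "hard" or self.n_elements == 1:
            return np.zeros(1)
        half = self.profile_extent_mm * 1e-3 / 2.0
        return np.linspace(-half, half, self.n_elements)

    def slice_gradient_t_per_m(self, pulse: RFPulse, width_factor: float = 1.0) -> float:
        """Slice-select gradient amplitude mapping the pulse bandwidth to
        ``width_factor`` times the nominal slice thickness."""
        thickness = self.slice_thickness_mm * 1e-3 * width_factor
        return pulse.bandwidth_hz / (GAMMA_HZ_PER_T * thickness)

    def replace(self, **kwargs) -> "SequenceSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "tr_ms": self.tr_ms,
            "te_ms": list(self.te_ms),
            "td_ms": list(self.td_ms),
            "sat_flip_deg": self.sat_flip_deg,
            "exc_flip_deg": self.exc_flip_deg,
            "refocus_flip_deg": self.refocus_flip_deg,
            "slice_thickness_mm": self.slice_thickness_mm,
            "profile_extent_mm": self.profile_extent_mm,
            "n_elements": self.n_elements,
            "pulse_mode": self.pulse_mode,
            "dt_rf": self.dt_rf,
        }


def default_sequence() -> SequenceSpec:
    """The full slice-profile description with stand-in Hann-sinc pulses."""
    return SequenceSpec()


def hard_pulse_sequence(**overrides) -> SequenceSpec:
    """Ideal hard-pulse variant: instantaneous rotations, no slice profile.

    Identical timings to :func:`default_sequence`; intended for fast
    exploration, calibration and tests.
    """
    base = dict(pulse_mode="hard", n_elements=1)
    base.update(overrides)
    return SequenceSpec(**base)
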