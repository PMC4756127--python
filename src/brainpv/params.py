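"""Compartment parameters and voxel compositions.

The tissue model describes every acquisition voxel as a mixture of four
partial-volume compartments:

* ``my``  -- myelin: myelin water plus the myelin sheet semi-solids.  Very
  fast relaxation; exchanges magnetization with the cellular compartment
  at a combined forward+backward rate ``k_my_cl``.
* ``cl``  -- cellular: intra/extracellular water, axonal water and
  non-myelin macromolecules.  Medium-time relaxation.
* ``fw``  -- free water: bulk CSF, physically separated from parenchyma,
  no magnetization exchange with anything.
* ``epw`` -- excess parenchymal water: an edema proxy that dilutes the
  cellular compartment; its exchange with ``cl`` is infinitely fast, so
  the two behave as a single merged pool wherever both are present.

Each compartment carries longitudinal and transverse relaxation rates
(``r1``, ``r2`` in s^-1) and a proton density (``pd``, percent of pure
water at 37 degC).  ``default_model_params`` returns the calibrated
healthy-brain values at 1.5 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

__all__ = [
    "CompartmentParams",
    "ModelParams",
    "VoxelComposition",
    "default_model_params",
]


@dataclass(frozen=True)
class CompartmentParams:
    """Relaxation rates and proton density of one compartment.

    Parameters
    ----------
    r1, r2 : float
        Longitudinal / transverse relaxation rates in s^-1.  Physical
        compartments always satisfy ``r2 >= r1``.
    pd : float
        Proton density in percent of pure water at 37 degC, in (0, 100].
    """

    r1: float
    r2: float
    pd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r1) and math.isfinite(self.r2) and math.isfinite(self.pd)):
            raise ValueError("compartment parameters must be finite")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError(f"relaxation rates must be positive, got r1={self.r1}, r2={self.r2}")
        if not (0 < self.pd <= 100):
            raise ValueError(f"proton density must be in (0, 100], got {self.pd}")
        if self.r2 < self.r1:
            raise ValueError(f"r2 ({self.r2}) must be >= r1 ({self.r1})")


@dataclass(frozen=True)
class ModelParams:
    """Full four-compartment parameter set.

    ``fw`` and ``epw`` must share identical relaxation rates (both are
    water; the distinction is purely whether the compartment exchanges
    with ``cl``).  The relaxation ordering ``fw < cl < my`` in both R1
    and R2 is enforced: it is what makes the myelin-induced shift of the
    dominant component identifiable.
    """

    my: CompartmentParams
    cl: CompartmentParams
    fw: CompartmentParams
    epw: CompartmentParams
    #: combined forward+backward MY<->CL magnetization exchange rate, s^-1
    k_my_cl: float = 6.7
    #: the EPW<->CL exchange rate is infinite by construction; kept as a
    #: descriptive flag so serialized parameter files are explicit.
    epw_cl_exchange: str = "infinite"

    def __post_init__(self) -> None:
        if self.k_my_cl < 0 or not math.isfinite(self.k_my_cl):
            raise ValueError(f"k_my_cl must be finite and >= 0, got {self.k_my_cl}")
        if not (self.fw.r1 < self.cl.r1 < self.my.r1):
            raise ValueError(
                "R1 ordering violated: need fw.r1 < cl.r1 < my.r1, got "
                f"{self.fw.r1}, {self.cl.r1}, {self.my.r1}"
            )
        if not (self.fw.r2 < self.cl.r2 < self.my.r2):
            raise ValueError(
                "R2 ordering violated: need fw.r2 < cl.r2 < my.r2, got "
                f"{self.fw.r2}, {self.cl.r2}, {self.my.r2}"
            )
        if self.fw.r1 != self.epw.r1 or self.fw.r2 != self.epw.r2:
            raise ValueError("fw and epw must share identical relaxation rates")
        if self.epw_cl_exchange != "infinite":
            raise ValueError("epw_cl_exchange is 'infinite' by model construction")

    @property
    def compartments(self) -> tuple[CompartmentParams, ...]:
        """Compartments in canonical (my, cl, fw, epw) order."""
        return (self.my, self.cl, self.fw, self.epw)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with selected fields replaced (validates again)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = {}
        for name, c in zip(("my", "cl", "fw", "epw"), self.compartments):
            out[f"r1_{name}"] = c.r1
            out[f"r2_{name}"] = c.r2
            out[f"pd_{name}"] = c.pd
        out["k_my_cl"] = self.k_my_cl
        return out


def default_model_params() -> ModelParams:
    """Calibrated healthy-brain model parameters at 1.5 T.

    Fixed values: free/excess water at CSF literature values
    (R1 = 0.24 s^-1, R2 = 0.87 s^-1, PD = 100 %) and myelin R2 = 77 s^-1
    (T2 about 13 ms).  The remaining six parameters are the cohort
    optimum: R1_MY = 16.6 s^-1, PD_MY = 42 %, k = 6.7 s^-1,
    R1_CL = 0.78 s^-1, R2_CL = 10.3 s^-1, PD_CL = 85 %.
    """
    water = CompartmentParams(r1=0.24, r2=0.87, pd=100.0)
    return ModelParams(
        my=CompartmentParams(r1=16.6, r2=77.0, pd=42.0),
        cl=CompartmentParams(r1=0.78, r2=10.3, pd=85.0),
        fw=water,
        epw=water,
        k_my_cl=6.7,
    )


_SUM_TOL = 1e-9


@dataclass(frozen=True)
class VoxelComposition:
    """Partial volumes of the four compartments, as fractions in [0, 1].

    The fractions must sum to exactly 1 (tolerance 1e-9): a voxel is
    always completely filled.  The all-zero composition is additionally
    admitted as the "empty voxel" used outside the intracranial mask.
    """

    v_my: float
    v_cl: float
    v_fw: float
    v_epw: float

    def __post_init__(self) -> None:
        vals = (self.v_my, self.v_cl, self.v_fw, self.v_epw)
        for v in vals:
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"partial volumes must lie in [0, 1], got {vals}")
        total = sum(vals)
        if abs(total - 1.0) > _SUM_TOL and total != 0.0:
            raise ValueError(f"partial volumes must sum to 1 (or 0 for an empty voxel), got {total}")

    @classmethod
    def from_percent(cls, v_my: float = 0.0, v_cl: float = 0.0, v_fw: float = 0.0,
                     v_epw: float = 0.0) -> "VoxelComposition":
        return cls(v_my / 100.0, v_cl / 100.0, v_fw / 100.0, v_epw / 100.0)

    def as_array(self):
        import numpy as np

        return np.array([self.v_my, self.v_cl, self.v_fw, self.v_epw], dtype=float)

    def as_percent(self):
        return tuple(100.0 * v for v in (self.v_my, self.v_cl, self.v_fw, self.v_epw))
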