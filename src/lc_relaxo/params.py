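"""Core parameter containers: acquisition protocol and tissue parameters.

Units are fixed package-wide: times in milliseconds, flip angles in degrees
at every public interface (converted to radians internally, once), off-
resonance in Hz, relaxation *rates* (R1 = 1/T1, R2 = 1/T2) in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AcquisitionProtocol", "TissueParameters"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-flip-angle SPGR + phase-cycled bSSFP + double-angle B1 protocol.

    Defaults reproduce a 3T BMC-mcDESPOT brain protocol: SPGR at
    TE/TR = 1.48/5 ms with flip angles 2..20 deg, bSSFP at TE/TR = 2.8/5.9 ms
    with flip angles 2..60 deg and RF phase increments of 0 and pi, and a
    fast-spin-echo double-angle pair at 45/90 deg (TE/TR = 102/3000 ms).
    """

    spgr_te_tr: tuple[float, float] = (1.48, 5.0)
    spgr_flip_angles: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
    bssfp_te_tr: tuple[float, float] = (2.8, 5.9)
    bssfp_flip_angles: tuple[float, ...] = (2, 4, 7, 11, 16, 24, 32, 40, 50, 60)
    bssfp_phase_increments: tuple[float, ...] = (0.0, np.pi)
    dam_flip_angles: tuple[float, float] = (45.0, 90.0)
    dam_te_tr: tuple[float, float] = (102.0, 3000.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, (te, tr) in (
            ("spgr_te_tr", self.spgr_te_tr),
            ("bssfp_te_tr", self.bssfp_te_tr),
            ("dam_te_tr", self.dam_te_tr),
        ):
            if not (tr > te > 0):
                raise ValueError(f"{name}: need TR > TE > 0, got TE={te}, TR={tr}")
        for name, angles, lo, hi in (
            ("spgr_flip_angles", self.spgr_flip_angles, 0.0, 90.0),
            ("bssfp_flip_angles", self.bssfp_flip_angles, 0.0, 180.0),
        ):
            a = np.asarray(angles, dtype=float)
            if a.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if np.any(np.diff(a) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if a[0] <= lo or (name == "spgr_flip_angles" and a[-1] > hi) or (
                name == "bssfp_flip_angles" and a[-1] >= hi
            ):
                raise ValueError(f"{name} out of valid range ({lo}, {hi}]")
        a1, a2 = self.dam_flip_angles
        if not np.isclose(a2, 2.0 * a1):
            raise ValueError(
                f"dam_flip_angles: second angle must be twice the first, got {a1}, {a2}"
            )
        if not (0 < a1 <= 90):
            raise ValueError("dam_flip_angles: first angle must lie in (0, 90]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def spgr_tr(self) -> float:
        return self.spgr_te_tr[1]

    @property
    def bssfp_tr(self) -> float:
        return self.bssfp_te_tr[1]

    def with_noise(self, noise_sd: float) -> "AcquisitionProtocol":
        return replace(self, noise_sd=noise_sd)


@dataclass
class TissueParameters:
    """Per-voxel tissue parameters for single- and two-component signal models.

    Every field may be a scalar or an ndarray (all arrays broadcastable to a
    common grid), so one instance can describe either a single voxel or a
    whole volume.

    The two-component (myelin water / intra-extracellular water) model is
    non-exchanging: ``mwf`` is the signal fraction of the short-T1/T2 pool,
    and both pools share ``m0``, ``off_resonance`` and ``b1_scale``.
    ``b1_scale`` is the dimensionless flip-angle scale kappa estimated by the
    double-angle method.
    """

    m0: float | np.ndarray = 1.0
    t1_single: float | np.ndarray = 1000.0
    t2_single: float | np.ndarray = 80.0
    mwf: float | np.ndarray = 0.0
    t1_short: float | np.ndarray = 400.0
    t1_long: float | np.ndarray = 1100.0
    t2_short: float | np.ndarray = 20.0
    t2_long: float | np.ndarray = 90.0
    off_resonance: float | np.ndarray = 0.0
    b1_scale: float | np.ndarray = 1.0

    def validate(self) -> None:
        for name in ("t1_single", "t2_single", "t1_short", "t1_long", "t2_short", "t2_long"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be > 0")
        if np.any(np.asarray(self.mwf) < 0) or np.any(np.asarray(self.mwf) > 1):
            raise ValueError("mwf must lie in [0, 1]")
        if np.any(np.asarray(self.t1_short) >= np.asarray(self.t1_long)):
            raise ValueError("t1_short must be < t1_long")
        if np.any(np.asarray(self.t2_short) >= np.asarray(self.t2_long)):
            raise ValueError("t2_short must be < t2_long")
        if np.any(np.asarray(self.b1_scale) <= 0):
            raise ValueError("b1_scale must be > 0")

    # Relaxation rates on the reporting scale (1/s, times stored in ms).
    @property
    def r1(self) -> float | np.ndarray:
        return 1000.0 / self.t1_single

    @property
    def r2(self) -> float | np.ndarray:
        return 1000.0 / self.t2_single

    def short_pool(self) -> "TissueParameters":
        """Single-component view of the short (myelin water) pool."""
        return TissueParameters(
            m0=self.m0,
            t1_single=self.t1_short,
            t2_single=self.t2_short,
            off_resonance=self.off_resonance,
            b1_scale=self.b1_scale,
        )

    def long_pool(self) -> "TissueParameters":
        """Single-component view of the long (intra/extra-cellular) pool."""
        return TissueParameters(
            m0=self.m0,
            t1_single=self.t1_long,
            t2_single=self.t2_long,
            off_resonance=self.off_resonance,
            b1_scale=self.b1_scale,
        )
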