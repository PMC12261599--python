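"""Voxel-wise relaxometry estimation: double-angle B1, DESPOT1 (T1/R1),
DESPOT2 (T2/R2), and the volume driver combining them with the Bayesian
Monte-Carlo MWF estimator.

Status codes (per voxel, ``QmriMapSet.status``):
    0 = ok, 1 = clamped (B1 ratio outside the arccos domain),
    2 = degenerate input (e.g. zero signal), 3 = non-converged /
    out-of-range fit. Failed voxels carry NaN in the maps and are excluded
    from all ROI means downstream — never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .forward import bssfp_signal
from .params import AcquisitionProtocol, TissueParameters

__all__ = [
    "STATUS_OK",
    "STATUS_CLAMPED",
    "STATUS_DEGENERATE",
    "STATUS_FAILED",
    "B1Map",
    "QmriMapSet",
    "fit_dam_b1",
    "interpolate_b1",
    "fit_despot1",
    "fit_despot2",
    "fit_volume",
]

STATUS_OK = 0
STATUS_CLAMPED = 1
STATUS_DEGENERATE = 2
STATUS_FAILED = 3

_DEG = np.pi / 180.0


@dataclass
class B1Map:
    """Per-voxel flip-angle scale kappa with validity bookkeeping.

    Voxels where the double-angle ratio was undefined are flagged in
    ``status`` (never silently set to 1.0); ``interpolated`` records whether
    the map was resampled from a lower-resolution acquisition.
    """

    kappa: np.ndarray
    voxel_size: tuple[float, float, float] | float = 1.0
    status: np.ndarray | None = None
    interpolated: bool = False

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.status is None:
            self.status = np.full(self.kappa.shape, STATUS_OK, dtype=np.int8)

    def ok(self) -> np.ndarray:
        return self.status == STATUS_OK


@dataclass
class QmriMapSet:
    """Co-registered R1 / R2 / MWF maps plus fit diagnostics.

    Rates are reported in 1/s (fits run on millisecond time constants).
    """

    r1: np.ndarray
    r2: np.ndarray
    mwf: np.ndarray
    m0: np.ndarray
    status: np.ndarray
    residual: np.ndarray
    voxel_size: float = 0.5
    rate_unit: str = "1/s"

    def ok_mask(self) -> np.ndarray:
        return self.status == STATUS_OK


def fit_dam_b1(
    dam_pair: tuple[np.ndarray, np.ndarray] | np.ndarray,
    nominal_angle: float = 45.0,
) -> B1Map:
    """Double-angle B1 mapping: kappa = arccos(S2 / (2 S1)) / nominal angle.

    The ratio is clamped to the arccos domain; clamped voxels are flagged
    (status 1) and zero-signal voxels are marked undefined (status 2).
    """
    s1 = np.asarray(dam_pair[0], dtype=float)
    s2 = np.asarray(dam_pair[1], dtype=float)
    status = np.full(s1.shape, STATUS_OK, dtype=np.int8)
    defined = s1 > 0
    status[~defined] = STATUS_DEGENERATE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, s2 / (2.0 * np.where(defined, s1, 1.0)), np.nan)
    clamped = defined & ((ratio < -1.0) | (ratio > 1.0))
    status[clamped] = STATUS_CLAMPED
    kappa = np.arccos(np.clip(ratio, -1.0, 1.0)) / (nominal_angle * _DEG)
    kappa = np.where(defined, kappa, np.nan)
    return B1Map(kappa=kappa, status=status)


def interpolate_b1(
    b1: B1Map,
    target_shape: tuple[int, int, int],
    target_voxel_size: float | tuple[float, float, float],
    source_voxel_size: float | tuple[float, float, float] | None = None,
) -> B1Map:
    """Trilinear resampling of a (typically low-resolution) B1 map.

    Grids are aligned at the corner of voxel (0,0,0); a constant field maps
    to a constant field, and any affine (linear-ramp) field is reproduced
    exactly at interior points.
    """
    src_vs = np.broadcast_to(
        np.asarray(source_voxel_size if source_voxel_size is not None else b1.voxel_size,
                   dtype=float), (3,)
    )
    tgt_vs = np.broadcast_to(np.asarray(target_voxel_size, dtype=float), (3,))
    src_extent = np.asarray(b1.kappa.shape) * src_vs
    tgt_extent = np.asarray(target_shape) * tgt_vs
    if np.any(tgt_extent <= 0) or np.any(src_extent <= 0):
        raise ValueError("degenerate grid")
    # world coordinate of each target voxel center, in source voxel index units
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * v for n, v in zip(target_shape, tgt_vs)],
        indexing="ij",
    )
    if all(c.max() > e for c, e in zip(coords, src_extent)):
        raise ValueError("target grid lies outside the B1 source grid")
    idx = [c / v - 0.5 for c, v in zip(coords, src_vs)]
    kappa = ndimage.map_coordinates(
        b1.kappa, np.stack(idx), order=1, mode="nearest"
    )
    status = ndimage.map_coordinates(
        b1.status.astype(float), np.stack(idx), order=0, mode="nearest"
    ).astype(np.int8)
    return B1Map(
        kappa=kappa, voxel_size=tuple(tgt_vs), status=status, interpolated=True
    )


def fit_despot1(
    spgr: np.ndarray,
    flip_angles: np.ndarray | tuple[float, ...],
    tr: float,
    kappa: np.ndarray | float = 1.0,
):
    """Linearized DESPOT1: T1 and M0 from multi-flip-angle SPGR.

    Regresses Y = S/sin(k a) on X = S/tan(k a) per voxel (unweighted least
    squares, the classic estimator); slope = E1 gives T1 = -TR / ln(slope)
    and the intercept gives M0. Slopes outside (0, 1) mark the voxel failed.

    ``spgr`` has the flip-angle axis first; returns (t1, m0, status,
    residual) arrays over the remaining axes.
    """
    s = np.asarray(spgr, dtype=float)
    alphas = np.asarray(flip_angles, dtype=float)
    if alphas.size < 2:
        raise ValueError("need at least two flip angles")
    if s.shape[0] != alphas.size:
        raise ValueError("signal stack does not match flip-angle list")
    k = np.asarray(kappa, dtype=float)
    extra = (slice(None),) + (None,) * (s.ndim - 1)
    a = alphas[extra] * k[None, ...] * _DEG if k.ndim else alphas[extra] * k * _DEG
    y = s / np.sin(a)
    x = s / np.tan(a)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = ym - slope * xm
    status = np.full(np.shape(slope), STATUS_OK, dtype=np.int8)
    bad = ~np.isfinite(slope) | (slope <= 0) | (slope >= 1) | (sxx <= 0)
    zero = (s <= 0).all(axis=0)
    status[bad] = STATUS_FAILED
    status[zero] = STATUS_DEGENERATE
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(bad, np.nan, -tr / np.log(np.where(bad, 0.5, slope)))
        m0 = np.where(bad, np.nan, intercept / (1.0 - np.where(bad, 0.5, slope)))
    resid = np.sqrt(((y - (slope * x + intercept)) ** 2).sum(axis=0))
    return t1, m0, status, resid


def _despot2_linearized(s_pi, alphas, tr, kappa, t1):
    """Single-cycle (pi phase increment) linearized DESPOT2.

    On resonance the pi-cycle signal obeys S/sin = m S/tan + b with
    m = (E1 - E2)/(1 - E1 E2), so E2 = (E1 - m)/(1 - m E1).
    """
    a = alphas * kappa * _DEG
    y = s_pi / np.sin(a)
    x = s_pi / np.tan(a)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx <= 0:
        return np.nan, np.nan, STATUS_FAILED
    m = ((x - xm) * (y - ym)).sum() / sxx
    b = ym - m * xm
    e1 = np.exp(-tr / t1)
    e2 = (e1 - m) / (1.0 - m * e1)
    if not (0 < e2 < 1):
        return np.nan, np.nan, STATUS_FAILED
    t2 = -tr / np.log(e2)
    m0 = b * (1.0 - e1 * e2) / (1.0 - e1)  # includes the constant TE decay
    return t2, m0, STATUS_OK


def fit_despot2(
    bssfp: np.ndarray,
    flip_angles: np.ndarray | tuple[float, ...],
    phase_increments: tuple[float, ...],
    te_tr: tuple[float, float],
    kappa: float,
    t1: float,
    path: str = "joint",
    t2_bounds: tuple[float, float] = (1.0, 500.0),
    n_starts: int = 3,
):
    """DESPOT2 T2 estimation for one voxel from phase-cycled bSSFP.

    ``bssfp`` is (n_cycles, n_angles). The default ``joint`` path runs a
    bounded nonlinear least-squares fit of (M0, T2, off-resonance) over both
    phase cycles using the full steady-state model, multi-started over
    off-resonance to avoid the periodic ambiguity; the ``linearized`` path
    is the classic single-cycle estimator on the pi cycle (exact on
    resonance, biased off resonance — retained as an oracle and for speed).

    Returns (t2, m0, off_resonance, status, residual).
    """
    s = np.asarray(bssfp, dtype=float)
    alphas = np.asarray(flip_angles, dtype=float)
    if s.ndim != 2 or s.shape[1] != alphas.size:
        raise ValueError("bssfp must be (n_cycles, n_angles) matching the protocol")
    if alphas.size < 2:
        raise ValueError("need at least two flip angles per cycle")
    if not np.isfinite(t1) or t1 <= 0:
        return np.nan, np.nan, np.nan, STATUS_FAILED, np.nan
    if (s <= 0).all():
        return np.nan, np.nan, np.nan, STATUS_DEGENERATE, np.nan
    te, tr = te_tr
    cycles = tuple(phase_increments)

    try:
        i_pi = int(np.argmin([abs(c - np.pi) for c in cycles]))
    except ValueError:
        i_pi = 0
    t2_lin, m0_lin, st_lin = _despot2_linearized(s[i_pi], alphas, tr, kappa, t1)

    if path == "linearized":
        resid = np.nan
        return t2_lin, m0_lin, 0.0, st_lin, resid
    if path != "joint":
        raise ValueError(f"unknown DESPOT2 path: {path!r}")

    data = s.ravel()
    scale = data.max()

    def model(theta):
        m0, t2, df = theta
        p = TissueParameters(
            m0=m0, t1_single=t1, t2_single=t2, off_resonance=df, b1_scale=kappa
        )
        return np.concatenate(
            [bssfp_signal(p, alphas, dphi, te_tr) for dphi in cycles]
        )

    def resid_fn(theta):
        return model(theta) - data

    df_max = 500.0 / tr  # 1/(2 TR) in Hz with TR in ms
    t2_init = t2_lin if st_lin == STATUS_OK else 80.0
    t2_init = float(np.clip(t2_init, t2_bounds[0] * 1.01, t2_bounds[1] * 0.99))
    m0_init = m0_lin / np.exp(-te / t2_init) if st_lin == STATUS_OK else scale * 10
    if not np.isfinite(m0_init) or m0_init <= 0:
        m0_init = scale * 10

    best = None
    for df0 in (0.0, 0.6 * df_max, -0.6 * df_max)[:n_starts]:
        try:
            sol = optimize.least_squares(
                resid_fn,
                x0=[m0_init, t2_init, df0],
                bounds=([0.0, t2_bounds[0], -df_max], [np.inf, t2_bounds[1], df_max]),
                xtol=1e-11, ftol=1e-11, gtol=1e-11,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < (1e-9 * scale) ** 2:
            break
    if best is None:
        return np.nan, np.nan, np.nan, STATUS_FAILED, np.nan
    m0, t2, df = best.x
    resid = float(np.sqrt(2.0 * best.cost))
    status = STATUS_OK if best.success else STATUS_FAILED
    if t2 <= t2_bounds[0] * 1.001 or t2 >= t2_bounds[1] * 0.999:
        status = STATUS_FAILED
    return float(t2), float(m0), float(df), status, resid


def fit_volume(
    stacks,
    protocol: AcquisitionProtocol,
    b1: B1Map,
    mask: np.ndarray | None = None,
    despot2_path: str = "joint",
    despot2_starts: int = 3,
    fit_mwf_maps: bool = False,
    bmc_config=None,
) -> QmriMapSet:
    """Voxel-wise R1/R2 (and optionally MWF) maps from a signal stack set.

    Voxels are fitted independently (no spatial coupling), optionally
    restricted to ``mask``; everything outside the mask, and every failed
    fit, carries NaN plus a status code. MWF fitting (Bayesian Monte-Carlo,
    see `lc_relaxo.mwf`) is opt-in because of its cost.
    """
    from .mwf import BmcConfig, fit_mwf  # local import avoids a cycle

    grid = stacks.grid_shape
    if b1.kappa.shape != grid:
        raise ValueError(
            f"B1 grid {b1.kappa.shape} does not match signal grid {grid}"
        )
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid:
            raise ValueError(f"mask grid {mask.shape} does not match signal grid {grid}")

    t1_map, m0_map, d1_status, d1_resid = fit_despot1(
        stacks.spgr, protocol.spgr_flip_angles, protocol.spgr_tr, b1.kappa
    )
    status = np.where(b1.ok(), d1_status, np.maximum(d1_status, STATUS_FAILED)).astype(np.int8)

    t2_map = np.full(grid, np.nan)
    df_map = np.full(grid, np.nan)
    resid_map = np.where(mask, d1_resid, np.nan)
    mwf_map = np.full(grid, np.nan)

    alphas = np.asarray(protocol.bssfp_flip_angles, dtype=float)
    for index in np.argwhere(mask):
        idx = tuple(index)
        if status[idx] != STATUS_OK:
            continue
        svox = stacks.bssfp[(slice(None), slice(None)) + idx]
        t2, _, df, st2, r2res = fit_despot2(
            svox, alphas, protocol.bssfp_phase_increments, protocol.bssfp_te_tr,
            float(b1.kappa[idx]), float(t1_map[idx]), path=despot2_path,
            n_starts=despot2_starts,
        )
        t2_map[idx] = t2
        df_map[idx] = df
        status[idx] = max(status[idx], st2)
        if np.isfinite(r2res):
            resid_map[idx] = np.hypot(resid_map[idx], r2res)

    if fit_mwf_maps:
        config = bmc_config if bmc_config is not None else BmcConfig()
        for index in np.argwhere(mask):
            idx = tuple(index)
            if status[idx] != STATUS_OK:
                continue
            est, _diag = fit_mwf(
                stacks.voxel(idx), protocol, float(b1.kappa[idx]), config
            )
            mwf_map[idx] = est

    t1_map = np.where(mask & (status == STATUS_OK), t1_map, np.nan)
    m0_map = np.where(mask & (status == STATUS_OK), m0_map, np.nan)
    t2_map = np.where(mask & (status == STATUS_OK), t2_map, np.nan)
    status = np.where(mask, status, STATUS_DEGENERATE).astype(np.int8)

    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = 1000.0 / t1_map
        r2 = 1000.0 / t2_map
    return QmriMapSet(
        r1=r1, r2=r2, mwf=mwf_map, m0=m0_map,
        status=status, residual=resid_map, voxel_size=stacks.voxel_size,
    )
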