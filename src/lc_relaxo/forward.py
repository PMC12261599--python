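"""Steady-state forward signal models: SPGR, phase-cycled bSSFP, double-angle pair.

Conventions
-----------
* Flip angles in degrees at the interface; the B1 scale ``kappa`` multiplies
  the nominal angle (B1 enters only through the product ``kappa * alpha``).
* SPGR and the fast-spin-echo double-angle pair: the TE decay is a constant
  multiplicative factor across flip angles and is absorbed into ``m0`` —
  it cancels in every ratio-based estimator built on these models.
* bSSFP: the per-TR free-precession angle is ``beta = 2*pi*df*TR - dphi``
  (off-resonance ``df`` in Hz, TR in ms, RF phase increment ``dphi`` in
  radians). The signal is evaluated at the echo, TE = TR/2 by protocol,
  with the ``exp(-TE/T2)`` decay applied; the echo-time precession rotates
  the transverse magnetization but does not change its magnitude.

`bssfp_signal` evaluates the closed-form solution of the 3x3 steady-state
fixed point (vectorized); `bssfp_signal_matrix` solves the same fixed point
by explicit linear algebra for a single parameter set, and the two agree to
machine precision. Brute-force Bloch iteration references
(`bloch_spgr_steady_state`, `bloch_bssfp_steady_state`) are provided as
independent validation oracles.
"""

from __future__ import annotations

import numpy as np

from .params import AcquisitionProtocol, TissueParameters

__all__ = [
    "spgr_signal",
    "bssfp_signal",
    "bssfp_signal_matrix",
    "two_component_spgr",
    "two_component_bssfp",
    "two_component_signal",
    "dam_signal_pair",
    "bloch_spgr_steady_state",
    "bloch_bssfp_steady_state",
]

_DEG = np.pi / 180.0


def spgr_signal(
    params: TissueParameters,
    flip_angle: float | np.ndarray,
    te_tr: tuple[float, float] = (1.48, 5.0),
) -> np.ndarray:
    """Noiseless spoiled-gradient-echo steady-state magnitude.

    S = M0 (1 - E1) sin(k a) / (1 - E1 cos(k a)),  E1 = exp(-TR/T1).

    This is the single-component signal model underlying DESPOT1 T1 mapping.
    """
    alpha = np.asarray(flip_angle, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("flip_angle must be > 0")
    _, tr = te_tr
    a = np.asarray(params.b1_scale) * alpha * _DEG
    e1 = np.exp(-tr / np.asarray(params.t1_single, dtype=float))
    return np.asarray(params.m0) * (1.0 - e1) * np.sin(a) / (1.0 - e1 * np.cos(a))


def _bssfp_transverse(m0, t1, t2, a, theta, tr):
    """Closed-form steady-state transverse components just after the RF pulse.

    Solves the fixed point M = E * Rz(theta) * Rx(a) * M + (0, 0, M0(1-E1))
    analytically.  Returns (Mx, My) for RF rotation about x.
    """
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    cos_a, sin_a = np.cos(a), np.sin(a)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    d = (1.0 - e1 * cos_a) * (1.0 - e2 * cos_t) - e2 * (e1 - cos_a) * (e2 - cos_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = m0 * (1.0 - e1) * sin_a * e2 * sin_t / d
        my = m0 * (1.0 - e1) * sin_a * (1.0 - e2 * cos_t) / d
    return mx, my, d


def bssfp_signal(
    params: TissueParameters,
    flip_angle: float | np.ndarray,
    phase_increment: float = 0.0,
    te_tr: tuple[float, float] = (2.8, 5.9),
) -> np.ndarray:
    """Phase-cycled balanced-SSFP steady-state magnitude at the echo.

    Free precession per TR is beta = 2*pi*df*TR - dphi; with the effective
    precession equal to pi this reduces (up to the constant echo decay
    exp(-TE/T2)) to the classic on-resonance form
    S = M0 sin(a) (1 - E1) / (1 - (E1 - E2) cos(a) - E1 E2).
    """
    alpha = np.asarray(flip_angle, dtype=float)
    te, tr = te_tr
    t1 = np.asarray(params.t1_single, dtype=float)
    t2 = np.asarray(params.t2_single, dtype=float)
    a = np.asarray(params.b1_scale) * alpha * _DEG
    theta = 2.0 * np.pi * np.asarray(params.off_resonance) * tr * 1e-3 - phase_increment
    mx, my, d = _bssfp_transverse(np.asarray(params.m0), t1, t2, a, theta, tr)
    if np.any(np.abs(d) < 1e-300):
        raise ValueError("singular bSSFP fixed-point system for these parameters")
    return np.hypot(mx, my) * np.exp(-te / t2)


def bssfp_signal_matrix(
    params: TissueParameters,
    flip_angle: float,
    phase_increment: float = 0.0,
    te_tr: tuple[float, float] = (2.8, 5.9),
) -> float:
    """bSSFP steady state for one parameter set via the explicit 3x3 solve.

    Numerically identical to `bssfp_signal`; kept as the transparent
    reference implementation of the fixed point.
    """
    te, tr = te_tr
    t1, t2 = float(params.t1_single), float(params.t2_single)
    a = float(params.b1_scale) * flip_angle * _DEG
    theta = 2.0 * np.pi * float(params.off_resonance) * tr * 1e-3 - phase_increment
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a), np.sin(a)], [0, -np.sin(a), np.cos(a)]]
    )
    rz = np.array(
        [[np.cos(theta), np.sin(theta), 0], [-np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    e = np.diag([e2, e2, e1])
    m0 = float(params.m0)
    b = np.array([0.0, 0.0, m0 * (1.0 - e1)])
    system = np.eye(3) - e @ rz @ rx
    try:
        m_pre = np.linalg.solve(system, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise ValueError("singular bSSFP fixed-point system") from exc
    m_post = rx @ m_pre
    return float(np.hypot(m_post[0], m_post[1]) * np.exp(-te / t2))


def two_component_spgr(
    params: TissueParameters,
    flip_angle: float | np.ndarray,
    te_tr: tuple[float, float] = (1.48, 5.0),
) -> np.ndarray:
    """Two-pool non-exchanging SPGR: mwf-weighted sum of short/long pools."""
    f = np.asarray(params.mwf)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("mwf must lie in [0, 1]")
    return f * spgr_signal(params.short_pool(), flip_angle, te_tr) + (1.0 - f) * spgr_signal(
        params.long_pool(), flip_angle, te_tr
    )


def two_component_bssfp(
    params: TissueParameters,
    flip_angle: float | np.ndarray,
    phase_increment: float = 0.0,
    te_tr: tuple[float, float] = (2.8, 5.9),
) -> np.ndarray:
    """Two-pool non-exchanging bSSFP; both pools share off-resonance and B1.

    The pool signals are summed as magnitudes; a shared off-resonance phase
    is the dominant common factor and, at the echo of a balanced sequence,
    pool phases are refocused to first order.
    """
    f = np.asarray(params.mwf)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("mwf must lie in [0, 1]")
    return f * bssfp_signal(params.short_pool(), flip_angle, phase_increment, te_tr) + (
        1.0 - f
    ) * bssfp_signal(params.long_pool(), flip_angle, phase_increment, te_tr)


def two_component_signal(params: TissueParameters, protocol: AcquisitionProtocol):
    """All protocol signals for one voxel under the two-pool model.

    Returns a dict with keys ``spgr`` (n_spgr_angles,), ``bssfp``
    (n_cycles, n_bssfp_angles) and ``dam`` (2,).
    """
    spgr = two_component_spgr(
        params, np.asarray(protocol.spgr_flip_angles), protocol.spgr_te_tr
    )
    bssfp = np.stack(
        [
            two_component_bssfp(
                params, np.asarray(protocol.bssfp_flip_angles), dphi, protocol.bssfp_te_tr
            )
            for dphi in protocol.bssfp_phase_increments
        ]
    )
    dam = np.asarray(dam_signal_pair(params, protocol.dam_flip_angles))
    return {"spgr": spgr, "bssfp": bssfp, "dam": dam}


def dam_signal_pair(
    params: TissueParameters, dam_angles: tuple[float, float] = (45.0, 90.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Fast-spin-echo double-angle pair (c sin(k a), c sin(2 k a)).

    Assumes complete T1 recovery over the long TR, so the common scale c
    (M0 times the echo-train decay) cancels in the S2/S1 ratio used for
    B1 mapping.
    """
    a1, a2 = dam_angles
    if not np.isclose(a2, 2.0 * a1):
        raise ValueError(f"double-angle pair must satisfy a2 = 2*a1, got {a1}, {a2}")
    ka = np.asarray(params.b1_scale) * a1 * _DEG
    c = np.asarray(params.m0)
    return c * np.sin(ka), c * np.sin(2.0 * ka)


# ---------------------------------------------------------------------------
# Brute-force Bloch iteration references
# ---------------------------------------------------------------------------

def bloch_spgr_steady_state(
    params: TissueParameters,
    flip_angle: float,
    te_tr: tuple[float, float] = (1.48, 5.0),
    n_tr: int = 5000,
) -> float | np.ndarray:
    """SPGR steady state by iterating n_tr excitations with ideal spoiling.

    Longitudinal recursion only (transverse magnetization is destroyed each
    TR): Mz <- E1 Mz cos(k a) + M0 (1 - E1); signal = Mz sin(k a).
    """
    _, tr = te_tr
    a = np.asarray(params.b1_scale) * flip_angle * _DEG
    e1 = np.exp(-tr / np.asarray(params.t1_single, dtype=float))
    m0 = np.asarray(params.m0, dtype=float)
    mz = np.broadcast_arrays(m0 + 0.0 * e1 + 0.0 * a)[0].copy()
    for _ in range(n_tr):
        mz = e1 * mz * np.cos(a) + m0 * (1.0 - e1)
    out = mz * np.sin(a)
    return float(out) if np.ndim(out) == 0 else out


def bloch_bssfp_steady_state(
    params: TissueParameters,
    flip_angle: float,
    phase_increment: float = 0.0,
    te_tr: tuple[float, float] = (2.8, 5.9),
    n_tr: int = 20000,
) -> float | np.ndarray:
    """bSSFP steady state by explicit per-TR rotation/precession/relaxation.

    Supports broadcasting over vectorized tissue parameters; used to check
    the closed-form and matrix solutions on random parameter grids.
    """
    te, tr = te_tr
    t1 = np.asarray(params.t1_single, dtype=float)
    t2 = np.asarray(params.t2_single, dtype=float)
    a = np.asarray(params.b1_scale) * flip_angle * _DEG
    theta = 2.0 * np.pi * np.asarray(params.off_resonance) * tr * 1e-3 - phase_increment
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    m0 = np.asarray(params.m0, dtype=float)

    shape = np.broadcast(t1, t2, a, theta, m0).shape
    mx = np.zeros(shape)
    my = np.zeros(shape)
    mz = np.broadcast_to(m0, shape).astype(float).copy()
    cos_a, sin_a = np.cos(a), np.sin(a)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    for _ in range(n_tr):
        # RF rotation about x
        my, mz = cos_a * my + sin_a * mz, -sin_a * my + cos_a * mz
        # free precession about z, then relaxation over TR
        mx, my = cos_t * mx + sin_t * my, -sin_t * mx + cos_t * my
        mx *= e2
        my *= e2
        mz = e1 * mz + m0 * (1.0 - e1)
    # one more RF pulse, then read the echo magnitude with TE decay
    my, mz = cos_a * my + sin_a * mz, -sin_a * my + cos_a * mz
    out = np.hypot(mx, my) * np.exp(-te / t2)
    return float(out) if np.ndim(out) == 0 else out
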