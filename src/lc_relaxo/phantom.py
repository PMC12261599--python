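"""Synthetic LC phantom and acquisition simulation.

The phantom is a pair of parallel circular cylinders (left and right locus
coeruleus) embedded in a uniform brainstem-like background, generated
directly on the analysis grid (no registration step is simulated). The LC
is on average about 14.5 mm long and 2.5 mm thick, and the default phantom
uses exactly those dimensions on a 0.5 mm isotropic grid. Tissue parameters
inside the tubes are linearly interpolated along the rostro-caudal axis
between a rostral and a caudal parameter set, giving a known ground-truth
topographic gradient for every metric.

Voxels belong to a tube if their *center* falls inside the analytic
cylinder (center-of-voxel inclusion; no partial-volume weighting).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import forward
from .params import AcquisitionProtocol, TissueParameters
from .topography import LcMask

__all__ = [
    "PhantomSpec",
    "SignalStackSet",
    "generate_phantom",
    "make_b1_field",
    "simulate_acquisition",
]

_INTERP_FIELDS = (
    "m0",
    "t1_single",
    "t2_single",
    "mwf",
    "t1_short",
    "t1_long",
    "t2_short",
    "t2_long",
    "off_resonance",
)


def _default_background() -> TissueParameters:
    # pons-like background tissue
    return TissueParameters(
        m0=100.0, t1_single=1100.0, t2_single=75.0, mwf=0.12,
        t1_short=400.0, t1_long=1250.0, t2_short=20.0, t2_long=90.0,
    )


def _default_rostral() -> TissueParameters:
    # LC rostral end: shorter T1 (neuromelanin-rich), lower R2 develops with
    # age — these defaults are plausible mid-life values, not literature
    # constants (in-vivo LC ranges are reported graphically only).
    return TissueParameters(
        m0=100.0, t1_single=900.0, t2_single=60.0, mwf=0.10,
        t1_short=350.0, t1_long=1050.0, t2_short=18.0, t2_long=75.0,
    )


def _default_caudal() -> TissueParameters:
    return TissueParameters(
        m0=100.0, t1_single=1000.0, t2_single=70.0, mwf=0.05,
        t1_short=380.0, t1_long=1150.0, t2_short=20.0, t2_long=85.0,
    )


@dataclass
class PhantomSpec:
    """Geometry and ground-truth parameters of the bilateral LC phantom.

    ``rostrocaudal_axis`` indexes the grid axis running along the LC;
    ``rostral_direction`` is +1 if slice index 0 is the rostral end, -1 if
    the last slice is rostral.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 40)
    voxel_size: float = 0.5
    lc_length: float = 14.5
    lc_thickness: float = 2.5
    lc_center_offsets: tuple[float, float] = (-3.0, 3.0)
    background_params: TissueParameters = field(default_factory=_default_background)
    lc_params_rostral: TissueParameters = field(default_factory=_default_rostral)
    lc_params_caudal: TissueParameters = field(default_factory=_default_caudal)
    rostrocaudal_axis: int = 2
    rostral_direction: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.lc_length / self.voxel_size < 3:
            raise ValueError("lc_length must span at least 3 slices")
        if self.rostrocaudal_axis not in (0, 1, 2):
            raise ValueError("rostrocaudal_axis must be 0, 1 or 2")
        if self.rostral_direction not in (-1, 1):
            raise ValueError("rostral_direction must be +1 or -1")
        for p in (self.background_params, self.lc_params_rostral, self.lc_params_caudal):
            p.validate()


@dataclass
class SignalStackSet:
    """Simulated magnitude images for all sequences of one protocol.

    ``spgr``: (n_spgr_angles, *grid); ``bssfp``: (n_cycles, n_bssfp_angles,
    *grid); ``dam``: (2, *grid). All arrays share one grid.
    """

    spgr: np.ndarray
    bssfp: np.ndarray
    dam: np.ndarray
    protocol: AcquisitionProtocol
    voxel_size: float

    def __post_init__(self) -> None:
        n_cyc = len(self.protocol.bssfp_phase_increments)
        if self.spgr.shape[0] != len(self.protocol.spgr_flip_angles):
            raise ValueError("spgr stack does not match protocol flip-angle list")
        if self.bssfp.shape[:2] != (n_cyc, len(self.protocol.bssfp_flip_angles)):
            raise ValueError("bssfp stack does not match protocol")
        if self.dam.shape[0] != 2:
            raise ValueError("dam stack must hold exactly two images")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.spgr.shape[1:])

    def voxel(self, index: tuple[int, ...]) -> dict:
        """Signals of a single voxel, in the layout `fit_mwf` consumes."""
        return {
            "spgr": self.spgr[(slice(None),) + index],
            "bssfp": self.bssfp[(slice(None), slice(None)) + index],
            "dam": self.dam[(slice(None),) + index],
        }


def generate_phantom(spec: PhantomSpec) -> tuple[TissueParameters, LcMask]:
    """Build the ground-truth parameter volume and its exact LC mask.

    Inside the tubes every tissue field is linearly interpolated along the
    rostro-caudal axis from ``lc_params_rostral`` (rostral end) to
    ``lc_params_caudal``; all other voxels carry ``background_params``.
    Deterministic: the geometry involves no randomness.
    """
    shape = tuple(spec.grid_shape)
    ax = spec.rostrocaudal_axis
    lat_axes = [i for i in range(3) if i != ax]
    n_slices = int(round(spec.lc_length / spec.voxel_size))
    if n_slices > shape[ax]:
        raise ValueError(
            f"LC tube ({n_slices} slices) exceeds grid along axis {ax} "
            f"({shape[ax]} slices)"
        )
    radius = spec.lc_thickness / 2.0
    # voxel centers in mm
    centers = [(np.arange(shape[i]) + 0.5) * spec.voxel_size for i in range(3)]
    mid = [shape[i] * spec.voxel_size / 2.0 for i in range(3)]

    # in-plane discs for the two tubes; offsets applied along the first
    # lateral axis, both tubes centered on the second
    u = centers[lat_axes[0]][:, None] - mid[lat_axes[0]]
    v = centers[lat_axes[1]][None, :] - mid[lat_axes[1]]
    disc = np.zeros((shape[lat_axes[0]], shape[lat_axes[1]]), dtype=bool)
    for off in spec.lc_center_offsets:
        if abs(off) + radius > shape[lat_axes[0]] * spec.voxel_size / 2.0:
            raise ValueError(
                f"LC tube at lateral offset {off} mm exceeds grid along axis "
                f"{lat_axes[0]}"
            )
        disc |= (u - off) ** 2 + v**2 <= radius**2 + 1e-12
    if radius > shape[lat_axes[1]] * spec.voxel_size / 2.0:
        raise ValueError(f"LC tube radius exceeds grid along axis {lat_axes[1]}")

    s0 = (shape[ax] - n_slices) // 2
    along = np.zeros(shape[ax], dtype=bool)
    along[s0 : s0 + n_slices] = True

    # broadcast disc (lat0, lat1) and along (ax) into grid axis order
    full = along[:, None, None] & disc[None, :, :]  # (ax, lat0, lat1)
    mask = np.moveaxis(full, [0, 1, 2], [ax, lat_axes[0], lat_axes[1]])

    # interpolation fraction per slice: 0 at the rostral end, 1 caudal
    t = np.zeros(shape[ax])
    j = np.arange(n_slices)
    frac = j / max(n_slices - 1, 1)
    if spec.rostral_direction == -1:
        frac = frac[::-1]
    t[s0 : s0 + n_slices] = frac
    t_grid = np.moveaxis(
        np.broadcast_to(t[:, None, None], (shape[ax], shape[lat_axes[0]], shape[lat_axes[1]])),
        [0, 1, 2],
        [ax, lat_axes[0], lat_axes[1]],
    )

    fields = {}
    for name in _INTERP_FIELDS:
        bg = float(getattr(spec.background_params, name))
        ro = float(getattr(spec.lc_params_rostral, name))
        ca = float(getattr(spec.lc_params_caudal, name))
        vol = np.full(shape, bg, dtype=float)
        vol[mask] = ((1.0 - t_grid) * ro + t_grid * ca)[mask]
        fields[name] = vol
    params = TissueParameters(b1_scale=1.0, **fields)

    lc_mask = LcMask(
        data=mask,
        voxel_size=spec.voxel_size,
        rostrocaudal_axis=ax,
        rostral_direction=spec.rostral_direction,
    )
    return params, lc_mask


def make_b1_field(
    grid_shape: tuple[int, int, int],
    mode: str = "constant",
    value: float = 1.0,
    ramp_axis: int = 0,
    ramp_range: tuple[float, float] = (0.9, 1.1),
) -> np.ndarray:
    """Smooth multiplicative B1 (flip-angle scale) field for simulation.

    ``constant``: kappa = value everywhere. ``ramp``: linear in voxel index
    along ``ramp_axis`` from ramp_range[0] to ramp_range[1] — a low-order
    field that trilinear interpolation reproduces exactly.
    """
    if mode == "constant":
        return np.full(grid_shape, float(value))
    if mode == "ramp":
        n = grid_shape[ramp_axis]
        ramp = np.linspace(ramp_range[0], ramp_range[1], n)
        shape = [1, 1, 1]
        shape[ramp_axis] = n
        return np.broadcast_to(ramp.reshape(shape), grid_shape).copy()
    raise ValueError(f"unknown B1 field mode: {mode!r}")


def simulate_acquisition(
    params: TissueParameters,
    protocol: AcquisitionProtocol,
    seed: int = 0,
    b1_field: np.ndarray | None = None,
    noise_model: str = "gaussian",
    two_component: bool = False,
    voxel_size: float = 0.5,
) -> SignalStackSet:
    """Simulate the full SPGR + phase-cycled bSSFP + double-angle protocol.

    Signals come from the forward models evaluated voxel-wise with each
    voxel's parameters and B1 scale; noise of SD ``protocol.noise_sd`` is
    added per the chosen model. ``gaussian`` is additive on the magnitude
    (high-SNR Rician limit, clipped at zero); ``rician`` applies the exact
    two-channel magnitude. ``two_component=True`` uses the two-pool model
    (required for meaningful MWF fitting).
    """
    grid = np.broadcast(np.asarray(params.t1_single), np.asarray(params.m0)).shape
    if b1_field is not None:
        if np.asarray(b1_field).shape != grid:
            raise ValueError(
                f"B1 field shape {np.asarray(b1_field).shape} does not match "
                f"parameter grid {grid}"
            )
        params = dataclasses.replace(params, b1_scale=np.asarray(b1_field))
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model: {noise_model!r}")

    spgr_fn = forward.two_component_spgr if two_component else forward.spgr_signal
    bssfp_fn = forward.two_component_bssfp if two_component else forward.bssfp_signal

    spgr = np.stack(
        [spgr_fn(params, a, protocol.spgr_te_tr) * np.ones(grid)
         for a in protocol.spgr_flip_angles]
    )
    bssfp = np.stack(
        [
            np.stack(
                [bssfp_fn(params, a, dphi, protocol.bssfp_te_tr) * np.ones(grid)
                 for a in protocol.bssfp_flip_angles]
            )
            for dphi in protocol.bssfp_phase_increments
        ]
    )
    s1, s2 = forward.dam_signal_pair(params, protocol.dam_flip_angles)
    dam = np.stack([s1 * np.ones(grid), s2 * np.ones(grid)])

    sd = protocol.noise_sd
    if sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            spgr = np.clip(spgr + rng.normal(0.0, sd, spgr.shape), 0.0, None)
            bssfp = np.clip(bssfp + rng.normal(0.0, sd, bssfp.shape), 0.0, None)
            dam = np.clip(dam + rng.normal(0.0, sd, dam.shape), 0.0, None)
        else:
            spgr = np.hypot(spgr + rng.normal(0.0, sd, spgr.shape),
                            rng.normal(0.0, sd, spgr.shape))
            bssfp = np.hypot(bssfp + rng.normal(0.0, sd, bssfp.shape),
                             rng.normal(0.0, sd, bssfp.shape))
            dam = np.hypot(dam + rng.normal(0.0, sd, dam.shape),
                           rng.normal(0.0, sd, dam.shape))

    return SignalStackSet(
        spgr=spgr, bssfp=bssfp, dam=dam, protocol=protocol, voxel_size=voxel_size
    )
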