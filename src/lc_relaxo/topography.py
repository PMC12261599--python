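"""Locus coeruleus ROI sampling: rostro-caudal slice profiles, subregions,
and the sensitivity-analysis masks (dilated shell, lateral shifts).

Percentile convention: slice k of n mask-intersecting slices (k = 0 most
rostral) receives the midpoint percentile 100 * (k + 0.5) / n.  A single
threshold at the 66th percentile splits the profile into the rostral-middle
(< 66) and caudal (>= 66) subregions; finer bands (rostral 0-44, restricted
caudal 86-100) are exposed as optional outputs. Assigning boundary slices by
their midpoint avoids double-counting and is symmetric under flipping the
rostro-caudal direction.

Left and right LC are pooled into one ROI; callers wanting per-side output
can mask each side separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import QmriMapSet

__all__ = [
    "LcMask",
    "SliceProfile",
    "SubregionSummary",
    "slice_profile",
    "split_subregions",
    "dilated_shell_mask",
    "shifted_mask",
]

METRICS = ("r1", "r2", "mwf")


@dataclass
class LcMask:
    """Binary ROI on the analysis grid with a rostro-caudal axis convention.

    ``rostral_direction`` = +1 means slice index 0 along ``rostrocaudal_axis``
    is the rostral end; -1 means the last slice is rostral.
    """

    data: np.ndarray
    voxel_size: float = 0.5
    rostrocaudal_axis: int = 2
    rostral_direction: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if self.rostral_direction not in (-1, 1):
            raise ValueError("rostral_direction must be +1 or -1")
        if self.data.any():
            n_comp = ndimage.label(self.data)[1]
            if n_comp > 2:
                warnings.warn(
                    f"LC mask has {n_comp} connected components "
                    "(expected one per side)",
                    stacklevel=2,
                )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def flipped(self) -> "LcMask":
        """Same voxels, opposite rostro-caudal polarity."""
        return replace(self, rostral_direction=-self.rostral_direction)


@dataclass
class SliceProfile:
    """Per-slice ROI means along the rostro-caudal axis, rostral first.

    ``table`` columns: slice_index (grid index), percentile (midpoint rule),
    n_voxels (ok-status voxels averaged), and one column per metric. Slices
    with no usable voxels carry NaN metrics and are listed in
    ``missing_slices``.
    """

    table: pd.DataFrame
    rostrocaudal_axis: int
    rostral_direction: int
    missing_slices: list[int] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.table)

    @property
    def percentiles(self) -> np.ndarray:
        return self.table["percentile"].to_numpy()


@dataclass
class SubregionSummary:
    """Whole-LC and subregion means per metric (voxel-count weighted)."""

    whole: dict[str, float]
    rostral_middle: dict[str, float]
    caudal: dict[str, float]
    extra_bands: dict[str, dict[str, float]]
    n_voxels: dict[str, int]
    n_slices: dict[str, int]
    flags: dict[str, str] = field(default_factory=dict)


def slice_profile(maps: "QmriMapSet", mask: LcMask) -> SliceProfile:
    """Average each qMRI metric over the mask, slice by slice.

    Only voxels with ok fit status contribute; a mask slice with zero usable
    voxels yields NaN means and is recorded in ``missing_slices``.
    """
    if not mask.data.any():
        raise ValueError("empty LC mask")
    if mask.data.shape != maps.r1.shape:
        raise ValueError(
            f"mask grid {mask.data.shape} does not match map grid {maps.r1.shape}"
        )
    ax = mask.rostrocaudal_axis
    ok = maps.ok_mask()
    lat = tuple(i for i in range(3) if i != ax)
    slice_has_mask = mask.data.any(axis=lat)
    indices = np.nonzero(slice_has_mask)[0]
    if mask.rostral_direction == -1:
        indices = indices[::-1]
    n = len(indices)
    rows, missing = [], []
    for k, idx in enumerate(indices):
        sl = [slice(None)] * 3
        sl[ax] = idx
        sl = tuple(sl)
        vox = mask.data[sl] & ok[sl]
        count = int(vox.sum())
        row = {
            "slice_index": int(idx),
            "percentile": 100.0 * (k + 0.5) / n,
            "n_voxels": count,
        }
        for m in METRICS:
            vals = getattr(maps, m)[sl][vox]
            row[m] = float(vals.mean()) if count else np.nan
        if count == 0:
            missing.append(int(idx))
        rows.append(row)
    return SliceProfile(
        table=pd.DataFrame(rows),
        rostrocaudal_axis=ax,
        rostral_direction=mask.rostral_direction,
        missing_slices=missing,
    )


def split_subregions(
    profile: SliceProfile,
    cut: float = 66.0,
    extra_bands: dict[str, tuple[float, float]] | None = None,
) -> SubregionSummary:
    """Split the profile at the rostro-caudal percentile ``cut``.

    Slices with midpoint percentile < cut form the rostral-middle subregion,
    >= cut the caudal subregion. Subregion means are voxel-count weighted, so
    the whole-LC mean is exactly their weighted combination. The default
    extra bands are the finer rostral (0-44) and restricted caudal (86-100)
    windows.
    """
    if profile.n_slices == 0:
        raise ValueError("empty slice profile")
    if extra_bands is None:
        extra_bands = {"rostral": (0.0, 44.0), "restricted_caudal": (86.0, 100.0)}
    tab = profile.table
    flags = {}

    def _weighted(rows: pd.DataFrame) -> tuple[dict, int, int]:
        usable = rows[rows["n_voxels"] > 0]
        n_vox = int(usable["n_voxels"].sum())
        if n_vox == 0:
            return {m: float("nan") for m in METRICS}, 0, len(rows)
        w = usable["n_voxels"].to_numpy(dtype=float)
        means = {
            m: float(np.average(usable[m].to_numpy(), weights=w)) for m in METRICS
        }
        return means, n_vox, len(rows)

    whole, n_whole, s_whole = _weighted(tab)
    rm_rows = tab[tab["percentile"] < cut]
    ca_rows = tab[tab["percentile"] >= cut]
    rostral_middle, n_rm, s_rm = _weighted(rm_rows)
    caudal, n_ca, s_ca = _weighted(ca_rows) if len(ca_rows) else (
        {m: float("nan") for m in METRICS}, 0, 0,
    )
    if len(ca_rows) == 0:
        flags["caudal"] = "undefined: no slice at or beyond the percentile cut"
    if len(rm_rows) == 0:
        flags["rostral_middle"] = "undefined: no slice below the percentile cut"

    extras = {}
    for name, (lo, hi) in extra_bands.items():
        rows = tab[(tab["percentile"] >= lo) & (tab["percentile"] < hi)]
        if name.endswith("caudal"):  # closed at 100 so the last slice is kept
            rows = tab[(tab["percentile"] >= lo) & (tab["percentile"] <= hi)]
        means, n_vox, _ = _weighted(rows) if len(rows) else (
            {m: float("nan") for m in METRICS}, 0, 0,
        )
        if len(rows) == 0:
            flags[name] = "undefined: no slice in band"
        extras[name] = means

    return SubregionSummary(
        whole=whole,
        rostral_middle=rostral_middle,
        caudal=caudal,
        extra_bands=extras,
        n_voxels={"whole": n_whole, "rostral_middle": n_rm, "caudal": n_ca},
        n_slices={"whole": s_whole, "rostral_middle": s_rm, "caudal": s_ca},
        flags=flags,
    )


def dilated_shell_mask(mask: LcMask, radius_voxels: int = 3) -> LcMask:
    """Shell of surrounding tissue: dilate by ``radius_voxels``, remove the LC.

    Dilation uses the 6-connected structuring element applied iteratively,
    so the shell is the set of voxels within city-block distance
    ``radius_voxels`` of the ROI, minus the ROI itself. Always disjoint from
    the original mask.
    """
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    structure = ndimage.generate_binary_structure(3, 1)
    dilated = ndimage.binary_dilation(
        mask.data, structure=structure, iterations=radius_voxels
    )
    # detect clipping at the grid boundary
    edge = np.zeros_like(mask.data)
    for axis in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[axis] = end
            edge[tuple(sl)] = True
    if (dilated & edge).any():
        warnings.warn("dilated shell clipped at the grid boundary", stacklevel=2)
    return replace(mask, data=dilated & ~mask.data)


def shifted_mask(
    mask: LcMask, shift_mm: float, axis: int
) -> tuple[LcMask, dict[str, int]]:
    """Translate the mask laterally by a whole number of voxels.

    Emulates a deliberate mislocalization of the ROI (default use: +/-1.5 mm,
    i.e. 3 voxels on a 0.5 mm grid). Any shifted voxel overlapping the
    original mask is removed; the diagnostics report how many were removed
    and how many were shifted off the grid.
    """
    shift_vox = shift_mm / mask.voxel_size
    if abs(shift_vox - round(shift_vox)) > 1e-9:
        raise ValueError(
            f"shift of {shift_mm} mm is not an integer number of "
            f"{mask.voxel_size} mm voxels; resample the mask first"
        )
    shift_vox = int(round(shift_vox))
    data = mask.data
    out = np.zeros_like(data)
    n = data.shape[axis]
    if shift_vox >= 0:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[axis] = slice(0, n - shift_vox)
        dst[axis] = slice(shift_vox, n)
    else:
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[axis] = slice(-shift_vox, n)
        dst[axis] = slice(0, n + shift_vox)
    out[tuple(dst)] = data[tuple(src)]
    shifted_out = int(data.sum() - out.sum())
    overlap = out & data
    diagnostics = {
        "overlap_removed": int(overlap.sum()),
        "shifted_out_of_grid": shifted_out,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shifted ROI may split components
        new = replace(mask, data=out & ~data)
    return new, diagnostics
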