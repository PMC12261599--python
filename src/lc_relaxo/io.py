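"""File I/O: NIfTI volumes and stacks, masks, CSV tables, YAML configs.

Volumes are written with a diagonal affine scaled by the voxel size.
Signal stacks can be written either as one 4-D NIfTI per sequence (flip
angle on the 4th axis) or as one 3-D file per flip angle; both dialects are
readable.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .topography import LcMask

__all__ = [
    "save_volume",
    "load_volume",
    "save_stack",
    "load_stack",
    "save_mask",
    "load_mask",
    "load_yaml",
    "save_yaml",
]


def _affine(voxel_size: float | tuple[float, float, float]) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return np.diag([vs[0], vs[1], vs[2], 1.0])


def save_volume(data: np.ndarray, voxel_size, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size)), path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=np.float64), voxel


def save_stack(
    stack: np.ndarray, voxel_size, path: str | Path, per_angle: bool = False
) -> list[Path]:
    """Write an (n_angles, *grid) stack as 4-D NIfTI or one file per angle."""
    stack = np.asarray(stack)
    path = Path(path)
    if not per_angle:
        # NIfTI puts the stacking dimension last
        return [save_volume(np.moveaxis(stack, 0, -1), voxel_size, path)]
    paths = []
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    for i in range(stack.shape[0]):
        paths.append(save_volume(stack[i], voxel_size, path.parent / f"{stem}_{i:02d}.nii.gz"))
    return paths


def load_stack(paths: str | Path | list) -> tuple[np.ndarray, float]:
    """Read a stack from one 4-D NIfTI or an ordered list of 3-D files."""
    if isinstance(paths, (str, Path)):
        data, voxel = load_volume(paths)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D stack in {paths}, got {data.ndim}-D")
        return np.moveaxis(data, -1, 0), voxel
    vols = [load_volume(p) for p in paths]
    voxel = vols[0][1]
    return np.stack([v for v, _ in vols]), voxel


def save_mask(mask: LcMask, path: str | Path) -> Path:
    p = save_volume(mask.data.astype(np.uint8), mask.voxel_size, path)
    meta = {
        "rostrocaudal_axis": mask.rostrocaudal_axis,
        "rostral_direction": mask.rostral_direction,
        "voxel_size": mask.voxel_size,
    }
    save_yaml(meta, Path(path).with_suffix("").with_suffix("").parent /
              (Path(path).name.removesuffix(".nii.gz").removesuffix(".nii") + ".yaml"))
    return p


def load_mask(path: str | Path) -> LcMask:
    data, voxel = load_volume(path)
    meta_path = Path(path).parent / (
        Path(path).name.removesuffix(".nii.gz").removesuffix(".nii") + ".yaml"
    )
    meta = load_yaml(meta_path) if meta_path.exists() else {}
    return LcMask(
        data=data > 0.5,
        voxel_size=float(meta.get("voxel_size", voxel)),
        rostrocaudal_axis=int(meta.get("rostrocaudal_axis", 2)),
        rostral_direction=int(meta.get("rostral_direction", 1)),
    )


def save_yaml(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def load_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)
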