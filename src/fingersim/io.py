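"""File I/O: label volumes (NIfTI-1 or raw + JSON sidecar), surface meshes
(marching cubes -> optional Laplacian smoothing -> binary STL) and image
export (32-bit float TIFF, HDF5 stacks)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import trimesh
from skimage import measure

from .mcsim import SpectralImageStack
from .phantom import TissueLabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "export_mesh",
    "write_image_tiff",
    "write_stack_h5",
    "read_stack_h5",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_volume(vol: TissueLabelVolume, path) -> None:
    """Write a label volume losslessly (labels and pitch round-trip).

    ``.nii``/``.nii.gz`` writes NIfTI-1 with the pitch in the header zooms;
    any other suffix writes raw little-endian voxel data plus a ``.json``
    sidecar carrying shape, dtype, order and pitch.
    """
    path = Path(path)
    if _is_nifti(path):
        data = vol.labels.astype(np.int16, copy=False)
        affine = np.diag([*vol.pitch, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.pitch)
        img.header.set_data_dtype(np.int16)
        nib.save(img, path)
    else:
        data = np.ascontiguousarray(vol.labels.astype(np.int16))
        path.write_bytes(data.tobytes())
        sidecar = {
            "shape": list(vol.labels.shape),
            "dtype": "<i2",
            "order": "C",
            "pitch_mm": list(vol.pitch),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path) -> TissueLabelVolume:
    """Read a label volume written by :func:`write_volume`.

    Non-integer voxel data and missing pitch metadata are rejected.
    """
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(
                f"{path.name}: label volumes must hold integer data, got {data.dtype}"
            )
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError(f"{path.name}: missing or invalid voxel pitch in header")
        return TissueLabelVolume(np.asarray(data), tuple(float(z) for z in zooms))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"raw volume sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if "pitch_mm" not in meta:
        raise ValueError(f"{sidecar_path.name}: missing pitch_mm")
    dtype = np.dtype(meta["dtype"])
    if not np.issubdtype(dtype, np.integer):
        raise ValueError(f"{sidecar_path.name}: label volumes must hold integer data")
    data = np.frombuffer(path.read_bytes(), dtype=dtype).reshape(meta["shape"])
    return TissueLabelVolume(data.copy(), tuple(meta["pitch_mm"]))


def export_mesh(
    vol: TissueLabelVolume,
    tissue_id: int,
    path=None,
    smoothing_iters: int = 0,
) -> trimesh.Trimesh:
    """Marching-cubes isosurface of one tissue, optionally Laplacian
    smoothed, written as little-endian binary STL when a path is given.

    The mask is zero-padded first so surfaces at the grid boundary close;
    degenerate (zero-area) faces are dropped before smoothing; smoothing
    moves vertices but preserves vertex and face counts.
    """
    mask = vol.labels == tissue_id
    if not mask.any():
        raise ValueError(f"tissue {tissue_id} not present in the volume")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=vol.pitch)
    verts -= np.asarray(vol.pitch)  # undo padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    if smoothing_iters > 0:
        trimesh.smoothing.filter_laplacian(
            mesh, lamb=0.5, iterations=int(smoothing_iters), volume_constraint=False
        )
    if path is not None:
        Path(path).write_bytes(mesh.export(file_type="stl"))
    return mesh


def write_image_tiff(image: np.ndarray, path) -> None:
    """32-bit float TIFF, deterministic bytes for identical data."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_stack_h5(stack: SpectralImageStack, path, attrs: dict | None = None) -> None:
    """Spectral sweep stack as HDF5 (timestamps disabled for byte-stable
    output)."""
    with h5py.File(path, "w", track_order=False) as f:
        for name in (
            "wavelengths",
            "reflectance",
            "transmittance",
            "total_reflectance",
            "total_transmittance",
            "total_absorbed",
        ):
            f.create_dataset(name, data=getattr(stack, name), track_times=False)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def read_stack_h5(path) -> SpectralImageStack:
    with h5py.File(path, "r") as f:
        return SpectralImageStack(
            wavelengths=f["wavelengths"][()],
            reflectance=f["reflectance"][()],
            transmittance=f["transmittance"][()],
            total_reflectance=f["total_reflectance"][()],
            total_transmittance=f["total_transmittance"][()],
            total_absorbed=f["total_absorbed"][()],
        )
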