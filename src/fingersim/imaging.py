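"""Tissue thickness projections and spectral post-processing.

A thickness projection sums the path length of one tissue along a grid
axis (voxel count times pitch per pixel), as used for sagittal thickness
maps and tomography-style tissue-distribution views.  Spectral
integration averages a simulated image stack over a wavelength band
(e.g. 650-760 nm, the range most sensitive to arthritic change), and the
log display maps transmittance images to log10 for visualization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcsim import SpectralImageStack
from .phantom import TissueLabelVolume

__all__ = [
    "ThicknessProjection",
    "thickness_projection",
    "spectral_integrate",
    "to_log_display",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ThicknessProjection:
    """2D map of summed tissue path length (mm) along one axis."""

    thickness_mm: np.ndarray
    tissue_id: int
    axis: str

    @property
    def total_volume_mm3(self) -> float:
        """Summed thickness times pixel area; equals the tissue volume."""
        return float(self.thickness_mm.sum()) * self._pixel_area

    _pixel_area: float = 0.0


def thickness_projection(vol: TissueLabelVolume, tissue_id: int, axis: str = "x") -> ThicknessProjection:
    """Total thickness of one tissue along a named axis.

    Each output pixel is (number of matching voxels along the axis) times
    the voxel pitch, so summing the map times the pixel area recovers the
    tissue volume exactly.
    """
    if tissue_id not in range(1, 16):
        raise ValueError(f"tissue_id must lie in 1..15, got {tissue_id}")
    try:
        ax = _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}") from None
    mask = vol.labels == tissue_id
    thickness = mask.sum(axis=ax) * vol.pitch[ax]
    other = [p for i, p in enumerate(vol.pitch) if i != ax]
    proj = ThicknessProjection(thickness.astype(float), tissue_id, axis)
    proj._pixel_area = float(other[0] * other[1])
    return proj


def spectral_integrate(stack, band_lo: float, band_hi: float, images: str = "transmittance") -> np.ndarray:
    """Unweighted mean of the in-band images of a spectral stack.

    ``stack`` is a :class:`~fingersim.mcsim.SpectralImageStack` or a pair
    ``(wavelengths, images)`` with images shaped (n_wl, nx, ny).  The band
    is inclusive; an empty band raises.
    """
    if isinstance(stack, SpectralImageStack):
        wl = stack.wavelengths
        imgs = getattr(stack, images)
    else:
        wl, imgs = stack
        wl = np.asarray(wl, dtype=float)
        imgs = np.asarray(imgs, dtype=float)
    sel = (wl >= band_lo) & (wl <= band_hi)
    if not sel.any():
        raise ValueError(f"no wavelengths in band [{band_lo}, {band_hi}] nm")
    return imgs[sel].mean(axis=0)


def to_log_display(image: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """log10 of an image with values clamped up to a positive floor;
    monotone, so pixel ordering is preserved."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log10(np.maximum(np.asarray(image, dtype=float), floor))
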