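"""Model manipulations: joint inflammation, tendon rupture, geometry scaling.

All three operate on categorical label volumes, so every resampling step is
nearest-neighbor (interpolation would invent tissues) and unit parameters
are exact identities.

Joint inflammation emulates arthritic change at an interphalangeal joint:
synovial-fluid effusion (cavity volume up by a target factor, 7.5x in the
combined disease preset) and synovial-membrane thickening (3x), with the
surrounding tissues displaced outward.  It is realized as an equal-area
radial remap of each transverse (x-z) slice: in squared elliptical-radius
coordinates the cavity annulus is stretched by the fluid factor, the
membrane annulus by the membrane factor, and everything outside is shifted
outward area-preservingly, so interior tissues such as bone keep their
cross-section.  Slice amplitudes are tapered by a cosine window along the
finger axis and a global amplitude is solved by bisection on the achieved
voxel-count ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import (
    AMBIENT,
    SUBCUTIS,
    SYNOVIAL_CAVITY,
    SYNOVIAL_MEMBRANE,
    TissueLabelVolume,
)

__all__ = [
    "InflammationSpec",
    "inflammation_preset",
    "apply_joint_inflammation",
    "apply_tendon_rupture",
    "scale_geometry",
]


@dataclass(frozen=True)
class InflammationSpec:
    """Targets for arthritic change at one joint.

    joint_y : joint center along the finger axis (mm)
    extent : full axial width of the affected region (mm); tapered to zero
        at its edges so the volume is untouched outside
    fluid_factor : target synovial-cavity volume ratio (>= 1)
    membrane_factor : target synovial-membrane volume ratio (>= 1)
    """

    joint_y: float = 40.0  # proximal interphalangeal joint of the default phantom
    extent: float = 8.0
    fluid_factor: float = 1.0
    membrane_factor: float = 1.0
    cavity_label: int = SYNOVIAL_CAVITY
    membrane_label: int = SYNOVIAL_MEMBRANE

    def __post_init__(self) -> None:
        if self.fluid_factor < 1.0 or self.membrane_factor < 1.0:
            raise ValueError("inflammation factors must be >= 1")
        if self.extent <= 0:
            raise ValueError("axial extent must be positive")


_PRESETS = {
    "inflamed-membrane": (1.0, 3.0),
    "inflamed-fluid": (7.5, 1.0),
    "inflamed-combined": (7.5, 3.0),
}


def inflammation_preset(name: str, joint_y: float = 40.0, extent: float = 8.0) -> InflammationSpec:
    """Named disease presets: membrane thickening only (x3), fluid effusion
    only (x7.5), or the combined arthritic state (x7.5 fluid, x3 membrane)."""
    try:
        fluid, membrane = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    return InflammationSpec(joint_y=joint_y, extent=extent, fluid_factor=fluid, membrane_factor=membrane)


class _Remapper:
    """Slice-wise equal-area radial remap around a joint center."""

    def __init__(self, vol: TissueLabelVolume, spec: InflammationSpec):
        labels = vol.labels
        nx, ny, nz = labels.shape
        px, py, pz = vol.pitch
        self.vol = vol
        self.spec = spec

        half = spec.extent / 2.0
        jlo = max(int(np.floor((spec.joint_y - half) / py - 0.5)) + 1, 0)
        jhi = min(int(np.ceil((spec.joint_y + half) / py - 0.5)), ny - 1)
        self.jlo, self.jhi = jlo, jhi
        self.slices = np.arange(jlo, jhi + 1)
        ys = (self.slices + 0.5) * py
        self.taper = 0.5 * (1.0 + np.cos(np.pi * np.clip((ys - spec.joint_y) / half, -1, 1)))

        region = labels[:, jlo : jhi + 1, :]
        cav = region == spec.cavity_label
        if not cav.any():
            raise ValueError("no synovial-cavity voxels inside the inflammation extent")
        mem = region == spec.membrane_label

        xs = (np.arange(nx) + 0.5) * px
        zs = (np.arange(nz) + 0.5) * pz
        ci, _, ck = np.nonzero(cav)
        self.xc = float(xs[ci].mean())
        self.zc = float(zs[ck].mean())
        # in-plane aspect of the cavity, from its bounding box
        ax = max((xs[ci].max() - xs[ci].min()) / 2.0 + px / 2.0, 0.5)
        az = max((zs[ck].max() - zs[ck].min()) / 2.0 + pz / 2.0, 0.5)
        self.ax, self.az = ax, az

        dx = (xs - self.xc) / ax
        dz = (zs - self.zc) / az
        self.r2 = dx[:, None] ** 2 + dz[None, :] ** 2  # squared elliptical radius, (nx, nz)

        # per-slice annulus boundaries in r2, measured from the input volume
        nsl = len(self.slices)
        self.uc = np.zeros(nsl)
        self.um = np.zeros(nsl)
        for k in range(nsl):
            cmask = cav[:, k, :]
            mmask = mem[:, k, :] | cmask
            if cmask.any():
                self.uc[k] = self.r2[cmask].max()
            if mmask.any():
                self.um[k] = max(self.r2[mmask].max(), self.uc[k])

        self.base_cavity = int((labels == spec.cavity_label).sum())
        self.base_membrane = int((labels == spec.membrane_label).sum())
        self.xs, self.zs = xs, zs
        self.px, self.pz = px, pz

    def remap(self, beta_c: float, beta_m: float) -> tuple[np.ndarray, bool]:
        """Apply slice factors fc = 1 + (F-1)*beta*taper; returns the new
        label array and a flag marking content pushed onto the grid border."""
        spec = self.spec
        labels = self.vol.labels
        nx, _, nz = labels.shape
        out = labels.copy()
        violated = False
        r2 = self.r2
        for k, j in enumerate(self.slices):
            fc = 1.0 + (spec.fluid_factor - 1.0) * beta_c * self.taper[k]
            fm = 1.0 + (spec.membrane_factor - 1.0) * beta_m * self.taper[k]
            uc, um = self.uc[k], self.um[k]
            if (fc == 1.0 and fm == 1.0) or um == 0.0:
                continue
            k1 = fc * uc
            k2 = k1 + fm * (um - uc)
            delta = (fc - 1.0) * uc + (fm - 1.0) * (um - uc)
            u = np.where(
                r2 <= k1,
                r2 / fc,
                np.where(r2 <= k2, uc + (r2 - k1) / fm, r2 - delta),
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(r2 > 0, np.sqrt(u / r2), 1.0)
            xi = np.rint((self.xc + (self.xs[:, None] - self.xc) * scale) / self.px - 0.5).astype(np.intp)
            zi = np.rint((self.zc + (self.zs[None, :] - self.zc) * scale) / self.pz - 0.5).astype(np.intp)
            np.clip(xi, 0, nx - 1, out=xi)
            np.clip(zi, 0, nz - 1, out=zi)
            sl = labels[xi, j, zi]
            out[:, j, :] = sl
            if (
                (sl[0, :] != AMBIENT).any()
                or (sl[-1, :] != AMBIENT).any()
                or (sl[:, 0] != AMBIENT).any()
                or (sl[:, -1] != AMBIENT).any()
            ):
                violated = True
        return out, violated

    def achieved(self, arr: np.ndarray, label: int, base: int) -> float:
        return float((arr == label).sum()) / base


def _bisect_amplitude(remapper, which: str, target: float, other_beta: float, tol: float = 0.003):
    """Solve the global amplitude so the achieved voxel-count ratio matches
    the target factor.  Raises if the target cannot be met inside the grid."""
    if target == 1.0:
        return 0.0
    spec = remapper.spec
    label = spec.cavity_label if which == "cavity" else spec.membrane_label
    base = remapper.base_cavity if which == "cavity" else remapper.base_membrane

    def ratio(beta):
        bc = beta if which == "cavity" else other_beta
        bm = beta if which == "membrane" else other_beta
        arr, violated = remapper.remap(bc, bm)
        return remapper.achieved(arr, label, base), violated

    lo, hi = 0.0, 1.0
    r_hi, viol = ratio(hi)
    while r_hi < target:
        if viol or hi > 32.0:
            raise ValueError(
                f"target {which} volume factor {target} unreachable within the grid"
            )
        hi *= 1.6
        r_hi, viol = ratio(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r_mid, _ = ratio(mid)
        if abs(r_mid - target) <= tol * target:
            return mid
        if r_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_joint_inflammation(vol: TissueLabelVolume, spec: InflammationSpec) -> TissueLabelVolume:
    """Inflate the synovial cavity and membrane at one joint.

    Transverse slices within the axial extent are radially rescaled around
    the joint so the cavity voxel count reaches ``fluid_factor`` times its
    original value and the membrane count ``membrane_factor`` times (each
    within voxelization tolerance); surrounding tissues are displaced
    outward and the volume is untouched outside the extent.
    """
    if spec.fluid_factor == 1.0 and spec.membrane_factor == 1.0:
        return vol.copy()
    remapper = _Remapper(vol, spec)
    if remapper.base_membrane == 0 and spec.membrane_factor != 1.0:
        raise ValueError("no synovial-membrane voxels inside the inflammation extent")
    beta_m0 = 1.0 if spec.membrane_factor != 1.0 else 0.0
    beta_c = _bisect_amplitude(remapper, "cavity", spec.fluid_factor, beta_m0)
    beta_m = _bisect_amplitude(remapper, "membrane", spec.membrane_factor, beta_c)
    arr, violated = remapper.remap(beta_c, beta_m)
    if violated:
        raise ValueError("inflamed geometry exceeds the grid; factors unreachable")
    return TissueLabelVolume(arr, vol.pitch)


def apply_tendon_rupture(
    vol: TissueLabelVolume,
    tendon_id: int,
    y_range: tuple[float, float],
    fill_label: int = SUBCUTIS,
) -> TissueLabelVolume:
    """Relabel tendon voxels with y in ``[y0, y1)`` mm as the filler tissue.

    No contraction or deformation is modeled: all other voxels are
    bit-identical to the input.  A zero-width range is an identity.
    """
    labels = vol.labels
    if not (labels == tendon_id).any():
        raise ValueError(f"tendon label {tendon_id} not present in the volume")
    y0, y1 = y_range
    out = labels.copy()
    if y1 <= y0:
        return TissueLabelVolume(out, vol.pitch)
    py = vol.pitch[1]
    ys = (np.arange(labels.shape[1]) + 0.5) * py
    in_range = (ys >= y0) & (ys < y1)
    sub = out[:, in_range, :]
    sub[sub == tendon_id] = fill_label
    out[:, in_range, :] = sub
    return TissueLabelVolume(out, vol.pitch)


def scale_geometry(
    vol: TissueLabelVolume, factors: tuple[float, float, float]
) -> TissueLabelVolume:
    """Nearest-neighbor rescaling of the label grid by per-axis factors.

    The physical pitch is unchanged, so the anatomy physically grows or
    shrinks; new dimensions are ``round(f * n)`` per axis and the output
    label set is a subset of the input's.
    """
    fx, fy, fz = (float(f) for f in factors)
    if min(fx, fy, fz) <= 0:
        raise ValueError("scale factors must be positive")
    shape = vol.labels.shape
    new_shape = tuple(int(round(f * n)) for f, n in zip((fx, fy, fz), shape))
    if min(new_shape) < 1:
        raise ValueError(f"scaling {factors} collapses the grid to {new_shape}")
    idx = []
    for f, n_old, n_new in zip((fx, fy, fz), shape, new_shape):
        src = np.rint((np.arange(n_new) + 0.5) / f - 0.5).astype(np.intp)
        idx.append(np.clip(src, 0, n_old - 1))
    out = vol.labels[np.ix_(*idx)]
    return TissueLabelVolume(out.copy(), vol.pitch)
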