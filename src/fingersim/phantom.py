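"""Procedural 15-tissue voxel phantom of a human index finger.

The phantom is a labeled 3D grid (default 160 x 320 x 133 voxels at 0.2 mm
isotropic pitch, 6,809,600 voxels) in which every voxel carries a tissue
identity from 1 to 15 (0 = ambient medium).  Axes follow the convention
x = finger width, y = finger long axis, z = depth (the light-propagation
axis).  The anatomy is idealized: a superellipse finger cross-section with
a tapered fingertip, skin shells of uniform geometric thickness (epidermis,
dermis over a subcutis fill), three capsule-shaped phalanx bones, two
cartilage-capped interphalangeal joints each with a synovial cavity wrapped
in a synovial membrane / joint capsule shell, flexor and extensor tendons,
the A4 pulley ring, collateral ligaments, volar plates, paired digital
arteries, veins and nerves, and Pacinian corpuscles in the volar subcutis.

Overlapping structures are resolved by a tissue prioritization list in
which thin or fine structures outrank bulky ones, so that features only
one or two voxels thick are never overwritten.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = [
    "AMBIENT",
    "Tissue",
    "TissueTable",
    "TissueLabelVolume",
    "PhantomParams",
    "PhantomSizeError",
    "PhantomReport",
    "default_tissue_table",
    "generate_phantom",
    "resolve_overlaps",
    "cleanup_labels",
    "validate_phantom",
]

AMBIENT = 0

# Tissue IDs, in the order the model enumerates them.
SUBCUTIS = 1
PACINIAN = 2
NERVE = 3
VEIN = 4
ARTERY = 5
TENDON = 6
LIGAMENT = 7
VOLAR_PLATE = 8
PULLEY_A4 = 9
BONE = 10
CARTILAGE = 11
SYNOVIAL_CAVITY = 12
SYNOVIAL_MEMBRANE = 13  # also known as the joint capsule
EPIDERMIS = 14
DERMIS = 15


@dataclass(frozen=True)
class Tissue:
    """One tissue definition: ID, canonical name, overlap-priority rank.

    ``priority`` is a total order used when several structures claim the
    same voxel: rank 1 wins over rank 2, and so on.  ``aliases`` carries
    alternative anatomical names (label 13 is both the synovial membrane
    and the joint capsule).
    """

    id: int
    name: str
    priority: int
    aliases: tuple[str, ...] = ()


#: Fine structures first: vessels, nerve, corpuscle, cartilage, membrane,
#: cavity, pulley, ligament, volar plate, tendon, bone, skin, subcutis last.
_DEFAULT_TISSUES = (
    Tissue(ARTERY, "artery", 1),
    Tissue(VEIN, "vein", 2),
    Tissue(NERVE, "nerve", 3),
    Tissue(PACINIAN, "Pacinian corpuscle", 4),
    Tissue(CARTILAGE, "cartilage", 5),
    Tissue(SYNOVIAL_MEMBRANE, "synovial membrane", 6, ("joint capsule",)),
    Tissue(SYNOVIAL_CAVITY, "synovial cavity", 7),
    Tissue(PULLEY_A4, "pulley A4", 8),
    Tissue(LIGAMENT, "collateral ligament", 9),
    Tissue(VOLAR_PLATE, "volar plate", 10),
    Tissue(TENDON, "tendon", 11),
    Tissue(BONE, "bone", 12),
    Tissue(EPIDERMIS, "epidermis", 13),
    Tissue(DERMIS, "dermis", 14),
    Tissue(SUBCUTIS, "subcutis", 15),
)


@dataclass(frozen=True)
class TissueTable:
    """Ordered set of the 15 tissue definitions with unique priority ranks."""

    entries: tuple[Tissue, ...] = _DEFAULT_TISSUES

    def __post_init__(self) -> None:
        ids = [t.id for t in self.entries]
        if len(self.entries) != 15:
            raise ValueError(f"expected 15 tissue entries, got {len(self.entries)}")
        if sorted(ids) != list(range(1, 16)):
            raise ValueError("tissue IDs must be unique and cover 1..15")
        ranks = [t.priority for t in self.entries]
        if len(set(ranks)) != len(ranks):
            raise ValueError("priority ranks must be unique (total order)")

    def priority_of(self, tissue_id: int) -> int:
        for t in self.entries:
            if t.id == tissue_id:
                return t.priority
        raise KeyError(f"unknown tissue id {tissue_id}")

    def name_of(self, tissue_id: int) -> str:
        for t in self.entries:
            if t.id == tissue_id:
                return t.name
        raise KeyError(f"unknown tissue id {tissue_id}")

    def by_priority(self) -> list[Tissue]:
        """Entries sorted from highest priority (rank 1) to lowest."""
        return sorted(self.entries, key=lambda t: t.priority)


def default_tissue_table() -> TissueTable:
    return TissueTable()


@dataclass
class TissueLabelVolume:
    """3D integer grid of tissue IDs with voxel pitch in mm.

    ``labels[ix, iy, iz]`` holds the tissue ID of the voxel whose center is
    at ``((ix+0.5)*pitch[0], (iy+0.5)*pitch[1], (iz+0.5)*pitch[2])`` mm
    (0-based indices, half-open physical extents).
    """

    labels: np.ndarray
    pitch: tuple[float, float, float] = (0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        if isinstance(self.pitch, (int, float)):
            self.pitch = (float(self.pitch),) * 3
        self.pitch = tuple(float(p) for p in self.pitch)
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError("pitch must be three strictly positive lengths (mm)")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 15):
            raise ValueError("labels must lie in 0..15")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * p for n, p in zip(self.labels.shape, self.pitch))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.pitch))

    def label_counts(self) -> dict[int, int]:
        """Voxel count per non-ambient label present in the volume."""
        counts = np.bincount(self.labels.ravel(), minlength=16)
        return {lab: int(c) for lab, c in enumerate(counts) if lab != AMBIENT and c > 0}

    def distinct_labels(self) -> set[int]:
        return {int(v) for v in np.unique(self.labels) if v != AMBIENT}

    def copy(self) -> "TissueLabelVolume":
        return TissueLabelVolume(self.labels.copy(), self.pitch)


class PhantomSizeError(ValueError):
    """The requested grid cannot contain the parameterized anatomy."""


@dataclass(frozen=True)
class _Bone:
    y0: float  # mm, start of the full bone extent
    y1: float  # mm, end (may exceed the grid for an open proximal cut)
    radius: float  # mm


@dataclass(frozen=True)
class _Joint:
    y: float  # mm, joint center along the finger axis
    cavity_semi: tuple[float, float, float]  # mm, (x, y, z) semi-axes
    membrane_semi: tuple[float, float, float]  # mm, outer semi-axes of the capsule
    cartilage_t: float = 0.5  # mm, cap thickness


@dataclass
class PhantomParams:
    """Geometric parameters of the synthetic finger (all lengths in mm).

    Defaults reproduce the structural statistics of the reference model:
    a (160, 320, 133) grid at 0.2 mm pitch (6,809,600 voxels) with all 15
    tissue types present.  ``seed`` only jitters Pacinian-corpuscle
    placement; generation is deterministic for fixed params and seed.
    """

    grid_shape: tuple[int, int, int] = (160, 320, 133)
    pitch: float = 0.2

    # outer finger shape
    finger_rx: float = 7.5
    finger_rz: float = 6.5
    superellipse_p: float = 2.5
    tip_y: float = 1.0  # where the fingertip cap begins
    tip_len: float = 10.0  # axial length of the tapered tip region

    # skin shells (geometric thickness, measured by 3D distance to ambient)
    epidermis_t: float = 0.3
    dermis_t: float = 1.2

    bones: tuple[_Bone, ...] = (
        _Bone(4.0, 16.0, 2.0),  # distal phalanx
        _Bone(20.0, 38.0, 2.6),  # middle phalanx
        _Bone(42.0, 1e9, 3.2),  # proximal phalanx, open proximal cut
    )
    joints: tuple[_Joint, ...] = (
        _Joint(18.0, (2.4, 1.1, 2.0), (3.0, 1.8, 2.6)),  # DIP
        _Joint(40.0, (3.0, 1.3, 2.5), (3.8, 2.1, 3.2)),  # PIP
    )
    #: index into ``joints`` of the proximal interphalangeal joint
    pip_joint_index: int = 1

    # tendons: elliptical tubes along y (dz relative to the finger center)
    flexor_dz: float = -4.2
    flexor_semi: tuple[float, float] = (1.8, 0.7)
    extensor_dz: float = 4.0
    extensor_semi: tuple[float, float] = (1.6, 0.5)
    tendon_y0: float = 5.0

    pulley_y: tuple[float, float] = (27.5, 30.5)
    pulley_t: float = 0.5

    ligament_radius: float = 0.8
    ligament_half_len: float = 2.5
    plate_semi: tuple[float, float, float] = (2.5, 1.8, 0.6)
    plate_dz: float = -3.4

    artery_dx: float = 5.2
    artery_dz: float = -2.2
    artery_r: float = 0.5
    vein_dx: float = 5.0
    vein_dz: float = 2.4
    vein_r: float = 0.6
    nerve_dx: float = 5.6
    nerve_dz: float = -1.4
    nerve_r: float = 0.4

    corpuscle_y: tuple[float, ...] = (12.0, 24.0, 33.0, 44.0, 52.0, 58.0)
    corpuscle_dx: float = 4.2
    corpuscle_dz: float = -3.4
    corpuscle_r: float = 0.55
    corpuscle_jitter: float = 0.3

    # feature toggles
    include_joints: bool = True
    include_tendons: bool = True
    include_pulley: bool = True
    include_ligaments: bool = True
    include_volar_plates: bool = True
    include_vessels: bool = True
    include_nerves: bool = True
    include_corpuscles: bool = True

    seed: int = 0
    run_cleanup: bool = True

    table: TissueTable = field(default_factory=default_tissue_table)

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        if min(nx, ny, nz) < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        for name in ("finger_rx", "finger_rz", "epidermis_t", "dermis_t", "tip_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lx, ly, lz = nx * self.pitch, ny * self.pitch, nz * self.pitch
        margin = 2 * self.pitch
        if 2 * self.finger_rx + 2 * margin > lx or 2 * self.finger_rz + 2 * margin > lz:
            raise PhantomSizeError(
                f"grid {self.grid_shape} at pitch {self.pitch} mm cannot contain a "
                f"finger of radii ({self.finger_rx}, {self.finger_rz}) mm plus margin"
            )
        for j in self.joints:
            if not (0.0 < j.y < ly):
                raise PhantomSizeError(f"joint at y={j.y} mm lies outside the grid (0..{ly} mm)")
        if self.tip_y + self.tip_len >= ly:
            raise PhantomSizeError("fingertip region does not fit along the finger axis")
        interior_rx = self.finger_rx - self.epidermis_t - self.dermis_t
        for b in self.bones:
            if b.radius >= interior_rx:
                raise PhantomSizeError("bone radius exceeds the subcutis interior")
        if not (0 <= self.pip_joint_index < len(self.joints)):
            raise ValueError("pip_joint_index out of range")

    @property
    def center_xz(self) -> tuple[float, float]:
        nx, _, nz = self.grid_shape
        return (nx * self.pitch / 2.0, nz * self.pitch / 2.0)

    @property
    def pip_joint(self) -> _Joint:
        return self.joints[self.pip_joint_index]


# ---------------------------------------------------------------------------
# geometry primitives (voxel-centered coordinate fields)
# ---------------------------------------------------------------------------

def _axes(params: PhantomParams):
    nx, ny, nz = params.grid_shape
    p = params.pitch
    x = ((np.arange(nx) + 0.5) * p).reshape(nx, 1, 1)
    y = ((np.arange(ny) + 0.5) * p).reshape(1, ny, 1)
    z = ((np.arange(nz) + 0.5) * p).reshape(1, 1, nz)
    return x, y, z


def _radius_profile(y: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Multiplier on the finger semi-axes: 0 before the tip, quarter-ellipse
    taper over the fingertip, 1 over the finger body."""
    f = np.ones_like(y)
    t0, tl = params.tip_y, params.tip_len
    tip = (y >= t0) & (y < t0 + tl)
    f = np.where(tip, np.sqrt(np.clip(1.0 - ((t0 + tl - y) / tl) ** 2, 0.0, 1.0)), f)
    f = np.where(y < t0, 0.0, f)
    return f


def _finger_outer_mask(params: PhantomParams) -> np.ndarray:
    x, y, z = _axes(params)
    xc, zc = params.center_xz
    f = _radius_profile(y, params)
    rx = params.finger_rx * f
    rz = params.finger_rz * f
    ok = (rx > 1e-6) & (rz > 1e-6)
    p = params.superellipse_p
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (np.abs(x - xc) / np.where(ok, rx, 1.0)) ** p + (
            np.abs(z - zc) / np.where(ok, rz, 1.0)
        ) ** p
    return ok & (val <= 1.0)


def _capsule(x, y, z, xc, zc, c0, c1, r) -> np.ndarray:
    """Sphere-capped cylinder along y with sphere centers at y=c0 and y=c1."""
    dy = np.maximum(np.maximum(c0 - y, y - c1), 0.0)
    return (x - xc) ** 2 + (z - zc) ** 2 + dy**2 <= r * r


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    sx, sy, sz = semi
    return ((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2 <= 1.0


def _tube(x, z, xc, zc, sx, sz) -> np.ndarray:
    return ((x - xc) / sx) ** 2 + ((z - zc) / sz) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def _build_masks(params: PhantomParams) -> dict[int, np.ndarray]:
    x, y, z = _axes(params)
    xc, zc = params.center_xz
    pitch = params.pitch

    outer = _finger_outer_mask(params)
    if not outer.any():
        raise PhantomSizeError("finger surface is empty for these parameters")

    # Skin shells by 3D Euclidean distance to ambient: geometrically uniform
    # thickness even over the fingertip cap.
    depth = ndimage.distance_transform_edt(outer, sampling=(pitch, pitch, pitch))
    epidermis = outer & (depth <= params.epidermis_t)
    dermis = outer & (depth > params.epidermis_t) & (depth <= params.epidermis_t + params.dermis_t)
    interior = depth > params.epidermis_t + params.dermis_t  # subcutis fill region

    masks: dict[int, np.ndarray] = {
        EPIDERMIS: epidermis,
        DERMIS: dermis,
        SUBCUTIS: interior.copy(),
    }

    ly = params.grid_shape[1] * pitch
    bone = np.zeros_like(outer)
    for b in params.bones:
        c0 = b.y0 + b.radius
        c1 = min(b.y1, ly + 10.0) - (b.radius if b.y1 < ly else -10.0)
        if b.y1 >= ly:  # open proximal cut: plain cylinder to the grid edge
            c1 = ly + 10.0
        bone |= _capsule(x, y, z, xc, zc, c0, c1, b.radius)
    bone &= interior
    masks[BONE] = bone

    if params.include_joints:
        cartilage = np.zeros_like(outer)
        cavity = np.zeros_like(outer)
        membrane = np.zeros_like(outer)
        for j in params.joints:
            # cartilage caps on the two bone ends facing the joint
            for b in params.bones:
                if abs(b.y1 - j.y) < 5.0 and b.y1 <= j.y:  # distal-side bone
                    cend, sgn = b.y1 - b.radius, +1.0
                elif abs(b.y0 - j.y) < 5.0 and b.y0 >= j.y:  # proximal-side bone
                    cend, sgn = b.y0 + b.radius, -1.0
                else:
                    continue
                cap = (x - xc) ** 2 + (y - cend) ** 2 + (z - zc) ** 2 <= (
                    b.radius + j.cartilage_t
                ) ** 2
                cap &= sgn * (y - cend) >= 0.0
                cartilage |= cap
            cav = _ellipsoid(x, y, z, (xc, j.y, zc), j.cavity_semi)
            mem = _ellipsoid(x, y, z, (xc, j.y, zc), j.membrane_semi) & ~cav
            cavity |= cav
            membrane |= mem
        cartilage &= interior & ~bone
        cavity &= interior & ~bone & ~cartilage
        membrane &= interior & ~bone & ~cartilage
        masks[CARTILAGE] = cartilage
        masks[SYNOVIAL_CAVITY] = cavity
        masks[SYNOVIAL_MEMBRANE] = membrane

    flexor_core = _tube(x, z, xc, zc + params.flexor_dz, *params.flexor_semi)
    if params.include_tendons:
        tendon = np.zeros_like(outer)
        tendon |= flexor_core & (y >= params.tendon_y0)
        tendon |= _tube(x, z, xc, zc + params.extensor_dz, *params.extensor_semi) & (
            y >= params.tendon_y0
        )
        masks[TENDON] = tendon & interior

    if params.include_pulley:
        sx, sz = params.flexor_semi
        ring = _tube(x, z, xc, zc + params.flexor_dz, sx + params.pulley_t, sz + params.pulley_t)
        ring = ring & ~flexor_core
        ring = ring & (y >= params.pulley_y[0]) & (y < params.pulley_y[1])
        masks[PULLEY_A4] = ring & interior

    if params.include_ligaments:
        lig = np.zeros_like(outer)
        for j in params.joints:
            rb = max(b.radius for b in params.bones)
            dx = rb + params.ligament_radius + 0.2
            hl = params.ligament_half_len
            for sx_sign in (-1.0, 1.0):
                lig |= _capsule(
                    x,
                    y,
                    z,
                    xc + sx_sign * dx,
                    zc,
                    j.y - hl + params.ligament_radius,
                    j.y + hl - params.ligament_radius,
                    params.ligament_radius,
                )
        masks[LIGAMENT] = lig & interior

    if params.include_volar_plates:
        plate = np.zeros_like(outer)
        for j in params.joints:
            plate |= _ellipsoid(x, y, z, (xc, j.y, zc + params.plate_dz), params.plate_semi)
        plate &= interior & ~masks[BONE]
        masks[VOLAR_PLATE] = plate

    if params.include_vessels:
        artery = _tube(x, z, xc - params.artery_dx, zc + params.artery_dz, params.artery_r, params.artery_r)
        artery |= _tube(x, z, xc + params.artery_dx, zc + params.artery_dz, params.artery_r, params.artery_r)
        vein = _tube(x, z, xc - params.vein_dx, zc + params.vein_dz, params.vein_r, params.vein_r)
        vein |= _tube(x, z, xc + params.vein_dx, zc + params.vein_dz, params.vein_r, params.vein_r)
        masks[ARTERY] = artery & interior
        masks[VEIN] = vein & interior

    if params.include_nerves:
        nerve = _tube(x, z, xc - params.nerve_dx, zc + params.nerve_dz, params.nerve_r, params.nerve_r)
        nerve |= _tube(x, z, xc + params.nerve_dx, zc + params.nerve_dz, params.nerve_r, params.nerve_r)
        masks[NERVE] = nerve & interior

    if params.include_corpuscles:
        rng = np.random.default_rng(params.seed)
        pac = np.zeros_like(outer)
        for i, cy in enumerate(params.corpuscle_y):
            side = -1.0 if i % 2 == 0 else 1.0
            jx, jy, jz = rng.uniform(-params.corpuscle_jitter, params.corpuscle_jitter, 3)
            cx = xc + side * params.corpuscle_dx + jx
            cz = zc + params.corpuscle_dz + jz
            pac |= (x - cx) ** 2 + (y - (cy + jy)) ** 2 + (z - cz) ** 2 <= params.corpuscle_r**2
        masks[PACINIAN] = pac & interior

    return masks


# ---------------------------------------------------------------------------
# overlap resolution & cleanup
# ---------------------------------------------------------------------------

def resolve_overlaps(
    masks: dict[int, np.ndarray],
    table: TissueTable | None = None,
    pitch: float | tuple[float, float, float] = 0.2,
) -> TissueLabelVolume:
    """Merge per-tissue binary masks into one label volume.

    Every voxel claimed by at least one mask receives the claimant with the
    best (numerically smallest) priority rank; unclaimed voxels stay
    ambient.  All masks must share one grid shape.
    """
    if not masks:
        raise ValueError("no masks given")
    table = table or default_tissue_table()
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError(f"masks disagree on grid shape: {sorted(shapes)}")
    shape = shapes.pop()
    labels = np.zeros(shape, dtype=np.int16)
    # paint from lowest priority to highest so the best rank lands last
    order = sorted(masks, key=lambda tid: table.priority_of(tid), reverse=True)
    for tid in order:
        labels[masks[tid]] = tid
    return TissueLabelVolume(labels, pitch)


@njit(cache=True)
def _cleanup_inplace(labels):  # pragma: no cover - exercised via cleanup_labels
    nx, ny, nz = labels.shape
    total = 0
    changed = True
    while changed:
        changed = False
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    lab = labels[ix, iy, iz]
                    nb = np.empty(6, dtype=np.int16)
                    nb[0] = labels[ix - 1, iy, iz] if ix > 0 else 0
                    nb[1] = labels[ix + 1, iy, iz] if ix < nx - 1 else 0
                    nb[2] = labels[ix, iy - 1, iz] if iy > 0 else 0
                    nb[3] = labels[ix, iy + 1, iz] if iy < ny - 1 else 0
                    nb[4] = labels[ix, iy, iz - 1] if iz > 0 else 0
                    nb[5] = labels[ix, iy, iz + 1] if iz < nz - 1 else 0
                    same = False
                    for k in range(6):
                        if nb[k] == lab:
                            same = True
                            break
                    if same:
                        continue
                    # majority among the 6 neighbors; ties -> smallest label
                    best_lab = nb[0]
                    best_cnt = 0
                    for k in range(6):
                        cnt = 0
                        for j in range(6):
                            if nb[j] == nb[k]:
                                cnt += 1
                        if cnt > best_cnt or (cnt == best_cnt and nb[k] < best_lab):
                            best_cnt = cnt
                            best_lab = nb[k]
                    labels[ix, iy, iz] = best_lab
                    changed = True
                    total += 1
    return total


def cleanup_labels(vol: TissueLabelVolume) -> TissueLabelVolume:
    """Remove isolated single voxels and fill single-voxel holes.

    A voxel with no 6-neighbor of its own label (out-of-grid neighbors count
    as ambient) is reassigned to the majority label among its 6 neighbors
    (ties broken toward the smallest label).  Voxels are fixed sequentially
    in scan order and passes repeat until a fixed point, so the operation is
    idempotent: every voxel in the result has at least one same-label
    6-neighbor.
    """
    out = vol.labels.astype(np.int16, copy=True)
    _cleanup_inplace(out)
    return TissueLabelVolume(out.astype(vol.labels.dtype, copy=False), vol.pitch)


# ---------------------------------------------------------------------------
# generation & validation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams | None = None) -> TissueLabelVolume:
    """Generate the synthetic 15-tissue index-finger label volume.

    Deterministic for fixed params and seed.  With default parameters the
    result contains all 15 tissue IDs on a (160, 320, 133) grid.
    """
    params = params or PhantomParams()
    params.validate()
    masks = _build_masks(params)
    vol = resolve_overlaps(masks, params.table, params.pitch)
    if params.run_cleanup:
        vol = cleanup_labels(vol)
    return vol


@dataclass
class PhantomReport:
    """Validation report: per-label counts plus structural pass/fail checks."""

    label_counts: dict[int, int]
    checks: dict[str, bool]
    details: dict[str, str]
    components: dict[int, int]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def _labels_touching_ambient(labels: np.ndarray) -> set[int]:
    """Non-ambient labels with a 6-neighbor that is ambient (within-grid)."""
    touching: set[int] = set()
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(labels, shift, axis=axis)
            # exclude the wrap-around plane
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            edge = tuple(sl)
            valid = np.ones_like(labels, dtype=bool)
            valid[edge] = False
            hit = (labels != AMBIENT) & (rolled == AMBIENT) & valid
            touching.update(int(v) for v in np.unique(labels[hit]))
    return touching


def validate_phantom(vol: TissueLabelVolume, params: PhantomParams | None = None) -> PhantomReport:
    """Structural checks on a phantom: label coverage, skin nesting, bone
    interiority, per-label connectivity.  Never raises; the report carries
    pass/fail flags."""
    labels = vol.labels
    counts = vol.label_counts()
    checks: dict[str, bool] = {}
    details: dict[str, str] = {}

    present = set(counts)
    checks["all_15_labels_present"] = present == set(range(1, 16))
    details["all_15_labels_present"] = f"present: {sorted(present)}"

    nonzero = int((labels != AMBIENT).sum())
    checks["label_partition"] = sum(counts.values()) == nonzero
    details["label_partition"] = f"sum(counts)={sum(counts.values())}, nonzero={nonzero}"

    touching = _labels_touching_ambient(labels)
    surface_ok = touching <= {EPIDERMIS}
    checks["skin_nesting"] = surface_ok
    details["skin_nesting"] = f"labels 6-adjacent to ambient: {sorted(touching)}"
    checks["bone_interior"] = BONE not in touching
    details["bone_interior"] = "bone touches ambient" if BONE in touching else "ok"

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    components: dict[int, int] = {}
    for lab in sorted(present):
        _, n = ndimage.label(labels == lab, structure=structure)
        components[lab] = int(n)

    if params is not None and params.include_joints:
        ok = True
        half = params.pitch / 2
        for j in params.joints:
            jlo = max(int((j.y - j.membrane_semi[1]) / params.pitch), 0)
            jhi = int((j.y + j.membrane_semi[1]) / params.pitch) + 1
            region = labels[:, jlo:jhi, :]
            ok &= bool((region == SYNOVIAL_CAVITY).any())
            ok &= bool((region == SYNOVIAL_MEMBRANE).any())
            ok &= bool((region == CARTILAGE).any())
        checks["joints_complete"] = ok
        details["joints_complete"] = "cartilage+cavity+membrane at each joint" if ok else "missing joint tissue"
        del half

    return PhantomReport(counts, checks, details, components)
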