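"""Weighted-packet Monte Carlo photon transport in a labeled voxel grid.

MCML-style hop-drop-spin transport extended to fully 3D voxelated
geometry: packets of photons with a weight of one are launched as a
perfectly collimated source uniform over the z = 0 entry face, free paths
are sampled as s = -ln(u)/mu_t, the dimensionless step is spent voxel by
voxel along the ray (so heterogeneous media are handled exactly), a
fraction mu_a/mu_t of the weight is absorbed in the voxel of each
interaction, new directions are drawn from the Henyey-Greenstein phase
function, and packets whose weight falls below a threshold play Russian
roulette.  At every voxel face where the refractive index changes the
packet is specularly reflected or Snell-refracted with the unpolarized
Fresnel probability; lateral (x, y) grid limits apply a mirror boundary
condition, while packets crossing the z limits exit and deposit their
weight in the reflectance (backward) or transmittance (forward) image at
the pixel of exit.

The engine is deterministic: a master seed spawns one independent
splitmix64 substream per packet, so results are bit-identical for a fixed
seed regardless of how packets are scheduled.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .optics import OpticalSpectraTable
from .phantom import TissueLabelVolume

__all__ = [
    "PhotonPacket",
    "SimulationConfig",
    "RadianceImages",
    "SpectralImageStack",
    "default_wavelength_grid",
    "launch_packet",
    "sample_step",
    "scatter_hg",
    "fresnel",
    "roulette",
    "traverse",
    "run_simulation",
    "spectral_sweep",
]

logger = logging.getLogger("fingersim")

_GRAZE_EPS = 1e-12  # |direction component| below which a face hit is pure reflection
_MAX_EVENTS = 10_000_000


@dataclass
class PhotonPacket:
    """One photon packet: continuous position (mm), unit direction,
    statistical weight in (0, 1], containing-voxel index and alive flag."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    voxel: tuple[int, int, int] = (0, 0, 0)
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, |d| = {norm}")
        if self.alive and not (0.0 < self.weight <= 1.0):
            raise ValueError("weight of a live packet must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Transport run configuration.

    w_threshold / roulette_m are the Russian-roulette parameters: packets
    below the threshold survive with probability 1/m and are reweighted by
    m (unbiased).  The source is a collimated +z beam uniform over the
    entry face.
    """

    n_photons: int = 100_000
    seed: int = 0
    wavelength_nm: float = 860.0
    w_threshold: float = 1e-4
    roulette_m: float = 10.0
    record_absorption: bool = False
    ambient_n: float = 1.0
    max_events: int = _MAX_EVENTS

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0.0 < self.w_threshold < 1.0):
            raise ValueError("w_threshold must lie in (0, 1)")
        if self.roulette_m <= 1.0:
            raise ValueError("roulette divisor m must exceed 1")


@dataclass
class RadianceImages:
    """Simulation output, all weights as fractions of launched weight.

    ``reflectance``/``transmittance`` are (nx, ny) images of exiting packet
    weight (backward / forward); ``absorbed`` is the optional 3D deposited
    weight grid.  ``total_*`` are the scalars R, T, A; ``lost`` is weight
    removed by roulette (statistically zero-mean against the reweighting).
    """

    reflectance: np.ndarray
    transmittance: np.ndarray
    absorbed: np.ndarray | None
    total_reflectance: float
    total_transmittance: float
    total_absorbed: float
    lost: float
    n_photons: int
    wavelength_nm: float


@dataclass
class SpectralImageStack:
    """Per-wavelength image stacks from a spectral sweep."""

    wavelengths: np.ndarray
    reflectance: np.ndarray  # (n_wl, nx, ny)
    transmittance: np.ndarray  # (n_wl, nx, ny)
    total_reflectance: np.ndarray
    total_transmittance: np.ndarray
    total_absorbed: np.ndarray


def default_wavelength_grid() -> np.ndarray:
    """400-1100 nm in 10 nm steps (71 wavelengths)."""
    return np.arange(400.0, 1101.0, 10.0)


# ---------------------------------------------------------------------------
# RNG: counter-seeded splitmix64, one substream per packet
# ---------------------------------------------------------------------------

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _sm_mix(z):
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _sm_next(state):
    state = state + _SM_GAMMA
    return state, _sm_mix(state)


@njit(cache=True, inline="always")
def _u01(z):
    # uniform in (0, 1), never exactly 0 or 1
    return (np.float64(z >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _packet_state(seed, pid):
    return _sm_mix(np.uint64(seed) ^ _sm_mix(np.uint64(pid) + np.uint64(0x5851F42D4C957F2D)))


# ---------------------------------------------------------------------------
# elementary physics (scalar, shared by kernel and Python-level API)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hg_cos(g, u):
    """Henyey-Greenstein inverse CDF for the scattering-angle cosine."""
    if abs(g) < 1e-8:
        ct = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _fresnel(n_i, n_t, cos_i):
    """Unpolarized Fresnel reflectance and transmitted-angle cosine.

    Returns (R, cos_t); R = 1 and cos_t = 0 beyond the critical angle.
    """
    if n_i == n_t:
        return 0.0, cos_i
    sin_t2 = (n_i / n_t) * (n_i / n_t) * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """Rotate a unit direction by scattering angle acos(ct), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


# ---------------------------------------------------------------------------
# transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _transport_kernel(
    labels,
    pitch,
    mua,
    mus,
    g_arr,
    n_arr,
    n_photons,
    seed,
    w_th,
    m_roul,
    n_ambient,
    max_events,
    record_abs,
    absorbed,
    refl,
    trans,
):  # pragma: no cover - exercised through run_simulation
    nx, ny, nz = labels.shape
    lx = nx * pitch
    ly = ny * pitch
    tot_r = 0.0
    tot_t = 0.0
    tot_a = 0.0
    tot_lost = 0.0

    for pid in range(n_photons):
        state = _packet_state(seed, pid)
        state, z1 = _sm_next(state)
        state, z2 = _sm_next(state)
        x = _u01(z1) * lx
        y = _u01(z2) * ly
        zp = 0.0
        ix = min(int(x / pitch), nx - 1)
        iy = min(int(y / pitch), ny - 1)
        iz = 0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0

        # Fresnel event at the entry face (ambient -> first voxel)
        lab = labels[ix, iy, iz]
        if n_arr[lab] != n_ambient:
            R, _ = _fresnel(n_ambient, n_arr[lab], 1.0)
            state, zr = _sm_next(state)
            if _u01(zr) < R:
                refl[ix, iy] += w
                tot_r += w
                continue

        s = 0.0  # remaining dimensionless step
        events = 0
        while True:
            events += 1
            if events > max_events:
                tot_lost += w
                break
            lab = labels[ix, iy, iz]
            mt = mua[lab] + mus[lab]
            if s <= 0.0 and mt > 0.0:
                state, zr = _sm_next(state)
                s = -math.log(_u01(zr))

            # distance to the next voxel face along the ray
            if ux > 0.0:
                tx = ((ix + 1) * pitch - x) / ux
            elif ux < 0.0:
                tx = (ix * pitch - x) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = ((iy + 1) * pitch - y) / uy
            elif uy < 0.0:
                ty = (iy * pitch - y) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = ((iz + 1) * pitch - zp) / uz
            elif uz < 0.0:
                tz = (iz * pitch - zp) / uz
            else:
                tz = 1e30
            db = tx
            axis = 0
            if ty < db:
                db = ty
                axis = 1
            if tz < db:
                db = tz
                axis = 2
            if db < 0.0:
                db = 0.0

            if mt > 0.0 and mt * db >= s:
                # interaction inside the current voxel
                d = s / mt
                x += ux * d
                y += uy * d
                zp += uz * d
                s = 0.0
                dw = w * mua[lab] / mt
                w -= dw
                tot_a += dw
                if record_abs:
                    absorbed[ix, iy, iz] += dw
                if w <= 0.0:
                    break
                state, z1 = _sm_next(state)
                state, z2 = _sm_next(state)
                ct = _hg_cos(g_arr[lab], _u01(z1))
                phi = 2.0 * math.pi * _u01(z2)
                ux, uy, uz = _spin(ux, uy, uz, ct, phi)
                if w < w_th:
                    state, zr = _sm_next(state)
                    if _u01(zr) * m_roul < 1.0:
                        w *= m_roul
                    else:
                        tot_lost += w
                        break
                continue

            # move to the face
            if mt > 0.0:
                s -= mt * db
            x += ux * db
            y += uy * db
            zp += uz * db

            if axis == 0:
                step = 1 if ux > 0.0 else -1
                x = (ix + 1) * pitch if step > 0 else ix * pitch
                nxt = ix + step
                if nxt < 0 or nxt >= nx:
                    ux = -ux  # mirror boundary
                    continue
                n1 = n_arr[lab]
                n2 = n_arr[labels[nxt, iy, iz]]
                if n1 != n2:
                    ci = abs(ux)
                    if ci < _GRAZE_EPS:
                        ux = -ux
                        continue
                    R, ct_t = _fresnel(n1, n2, ci)
                    state, zr = _sm_next(state)
                    if _u01(zr) < R:
                        ux = -ux
                        continue
                    ratio = n1 / n2
                    uy *= ratio
                    uz *= ratio
                    ux = ct_t if ux > 0.0 else -ct_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                ix = nxt
                continue
            if axis == 1:
                step = 1 if uy > 0.0 else -1
                y = (iy + 1) * pitch if step > 0 else iy * pitch
                nxt = iy + step
                if nxt < 0 or nxt >= ny:
                    uy = -uy
                    continue
                n1 = n_arr[lab]
                n2 = n_arr[labels[ix, nxt, iz]]
                if n1 != n2:
                    ci = abs(uy)
                    if ci < _GRAZE_EPS:
                        uy = -uy
                        continue
                    R, ct_t = _fresnel(n1, n2, ci)
                    state, zr = _sm_next(state)
                    if _u01(zr) < R:
                        uy = -uy
                        continue
                    ratio = n1 / n2
                    ux *= ratio
                    uz *= ratio
                    uy = ct_t if uy > 0.0 else -ct_t
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                iy = nxt
                continue
            # axis == 2: z face, possible exit
            step = 1 if uz > 0.0 else -1
            zp = (iz + 1) * pitch if step > 0 else iz * pitch
            nxt = iz + step
            inside = 0 <= nxt < nz
            n1 = n_arr[lab]
            n2 = n_arr[labels[ix, iy, nxt]] if inside else n_ambient
            if n1 != n2:
                ci = abs(uz)
                if ci < _GRAZE_EPS:
                    uz = -uz
                    continue
                R, ct_t = _fresnel(n1, n2, ci)
                state, zr = _sm_next(state)
                if _u01(zr) < R:
                    uz = -uz
                    continue
                ratio = n1 / n2
                ux *= ratio
                uy *= ratio
                uz = ct_t if uz > 0.0 else -ct_t
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
            if inside:
                iz = nxt
                continue
            if step < 0:
                refl[ix, iy] += w
                tot_r += w
            else:
                trans[ix, iy] += w
                tot_t += w
            break

    return tot_r, tot_t, tot_a, tot_lost


# ---------------------------------------------------------------------------
# Python-level elementary operations
# ---------------------------------------------------------------------------

def launch_packet(config: SimulationConfig, rng: np.random.Generator, vol: TissueLabelVolume | None = None) -> PhotonPacket:
    """Launch one packet: weight 1, direction +z, position uniform over the
    z = 0 entry face (the full grid face when a volume is given, the unit
    square otherwise)."""
    if vol is not None:
        lx, ly, _ = vol.extent_mm
        pitch = vol.pitch[0]
    else:
        lx = ly = 1.0
        pitch = 1.0
    x = rng.uniform(0.0, lx)
    y = rng.uniform(0.0, ly)
    return PhotonPacket(
        position=np.array([x, y, 0.0]),
        direction=np.array([0.0, 0.0, 1.0]),
        weight=1.0,
        voxel=(int(x / pitch), int(y / pitch), 0),
    )


def sample_step(mu_t: float, u: float) -> float:
    """Exponential free path s = -ln(u)/mu_t (mm); infinite for mu_t = 0
    (ballistic to the next boundary)."""
    if mu_t < 0:
        raise ValueError("mu_t must be non-negative")
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie in (0, 1)")
    if mu_t == 0.0:
        return math.inf
    return -math.log(u) / mu_t


def scatter_hg(direction: np.ndarray, g: float, u1: float, u2: float) -> np.ndarray:
    """New unit direction after a Henyey-Greenstein scattering event."""
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie strictly in (-1, 1)")
    ux, uy, uz = (float(v) for v in direction)
    ct = _hg_cos(g, u1)
    phi = 2.0 * math.pi * u2
    return np.array(_spin(ux, uy, uz, ct, phi))


def hg_cos_theta(g: float, u) -> np.ndarray | float:
    """Scattering-angle cosine(s) from the HG inverse CDF (vectorized in u)."""
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-8:
        ct = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(ct, -1.0, 1.0)


def fresnel(n_i: float, n_t: float, cos_theta_i: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance and refracted-angle cosine.

    Beyond the critical angle the reflectance is 1 (total internal
    reflection) and the returned cosine is 0.
    """
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 < cos_theta_i <= 1.0):
        raise ValueError("cos_theta_i must lie in (0, 1]")
    return _fresnel(n_i, n_t, cos_theta_i)


def roulette(packet: PhotonPacket, w_th: float, m: float, u: float) -> PhotonPacket:
    """Russian roulette: packets below the threshold survive with
    probability 1/m and are reweighted by m; unbiased in expectation."""
    if packet.weight >= w_th or not packet.alive:
        return packet
    if u * m < 1.0:
        packet.weight *= m
    else:
        packet.alive = False
    return packet


@dataclass
class TraverseEvent:
    """Outcome of one traversal leg: ``kind`` is 'interaction', 'face'
    (refractive-index mismatch), 'mirror' (lateral limit, direction already
    reflected) or 'exit' (crossed a z limit; ``side`` is -1 backward /
    +1 forward).  ``remaining_step`` is the unspent dimensionless step."""

    kind: str
    remaining_step: float
    side: int = 0
    n_in: float = 0.0
    n_out: float = 0.0


def traverse(
    packet: PhotonPacket,
    vol: TissueLabelVolume,
    props: dict[str, np.ndarray],
    step: float,
    ambient_n: float = 1.0,
) -> TraverseEvent:
    """Walk one packet through the voxel grid until the sampled
    dimensionless step is spent (interaction) or a face event occurs.

    Reference Python implementation of the kernel's traversal: consumes
    mu_t * segment-length per voxel sub-segment, mirror-reflects at lateral
    limits and stops at faces where the refractive index changes.  The
    packet is updated in place; the returned event says why it stopped.
    """
    labels = vol.labels
    nx, ny, nz = labels.shape
    pitch = vol.pitch[0]
    mua, mus, n_arr = props["mu_a"], props["mu_s"], props["n"]
    x, y, zp = (float(v) for v in packet.position)
    ux, uy, uz = (float(v) for v in packet.direction)
    ix, iy, iz = packet.voxel
    s = float(step)

    for _ in range(10_000_000):
        lab = labels[ix, iy, iz]
        mt = mua[lab] + mus[lab]
        dists = []
        for comp, pos, idx in ((ux, x, ix), (uy, y, iy), (uz, zp, iz)):
            if comp > 0:
                dists.append(((idx + 1) * pitch - pos) / comp)
            elif comp < 0:
                dists.append((idx * pitch - pos) / comp)
            else:
                dists.append(math.inf)
        axis = int(np.argmin(dists))
        db = max(dists[axis], 0.0)

        if mt > 0.0 and mt * db >= s:
            d = s / mt
            x += ux * d
            y += uy * d
            zp += uz * d
            packet.position = np.array([x, y, zp])
            packet.voxel = (ix, iy, iz)
            return TraverseEvent("interaction", 0.0)

        if mt > 0.0:
            s -= mt * db
        x += ux * db
        y += uy * db
        zp += uz * db
        comp = (ux, uy, uz)[axis]
        step_dir = 1 if comp > 0 else -1
        idx = (ix, iy, iz)[axis]
        face = (idx + 1) * pitch if step_dir > 0 else idx * pitch
        if axis == 0:
            x = face
        elif axis == 1:
            y = face
        else:
            zp = face
        nxt = idx + step_dir
        dim = (nx, ny, nz)[axis]

        if axis < 2 and (nxt < 0 or nxt >= dim):
            if axis == 0:
                ux = -ux
            else:
                uy = -uy
            packet.position = np.array([x, y, zp])
            packet.direction = np.array([ux, uy, uz])
            packet.voxel = (ix, iy, iz)
            return TraverseEvent("mirror", s)

        inside = 0 <= nxt < dim
        n1 = n_arr[lab]
        if inside:
            nb = [ix, iy, iz]
            nb[axis] = nxt
            n2 = n_arr[labels[nb[0], nb[1], nb[2]]]
        else:
            n2 = ambient_n
        packet.position = np.array([x, y, zp])
        packet.direction = np.array([ux, uy, uz])
        if n1 != n2:
            packet.voxel = (ix, iy, iz)
            return TraverseEvent("face", s, n_in=n1, n_out=n2)
        if not inside:  # z exit with matched indices
            packet.voxel = (ix, iy, iz)
            return TraverseEvent("exit", s, side=step_dir)
        if axis == 0:
            ix = nxt
        elif axis == 1:
            iy = nxt
        else:
            iz = nxt
        packet.voxel = (ix, iy, iz)
    raise RuntimeError("traverse did not terminate")


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_simulation(
    vol: TissueLabelVolume,
    spectra: OpticalSpectraTable,
    config: SimulationConfig,
) -> RadianceImages:
    """Transport ``config.n_photons`` packets through the volume at one
    wavelength and accumulate exit images and totals.

    Reproducible: a fixed (volume, spectra, config) triple gives
    bit-identical images.
    """
    px, py, pz = vol.pitch
    if not (abs(px - py) < 1e-12 and abs(py - pz) < 1e-12):
        raise ValueError("transport requires isotropic voxels")
    present = [int(v) for v in np.unique(vol.labels)]
    spectra.require_rows(present)
    props = spectra.property_arrays(config.wavelength_nm)

    labels = np.ascontiguousarray(vol.labels.astype(np.int8, copy=False))
    nx, ny, nz = labels.shape
    refl = np.zeros((nx, ny))
    trans = np.zeros((nx, ny))
    absorbed = np.zeros(labels.shape) if config.record_absorption else np.zeros((1, 1, 1))

    tot_r, tot_t, tot_a, tot_lost = _transport_kernel(
        labels,
        px,
        props["mu_a"],
        props["mu_s"],
        props["g"],
        props["n"],
        config.n_photons,
        np.uint64(config.seed & 0xFFFFFFFFFFFFFFFF),
        config.w_threshold,
        config.roulette_m,
        config.ambient_n,
        config.max_events,
        config.record_absorption,
        absorbed,
        refl,
        trans,
    )
    n = float(config.n_photons)
    images = RadianceImages(
        reflectance=refl / n,
        transmittance=trans / n,
        absorbed=(absorbed / n) if config.record_absorption else None,
        total_reflectance=tot_r / n,
        total_transmittance=tot_t / n,
        total_absorbed=tot_a / n,
        lost=tot_lost / n,
        n_photons=config.n_photons,
        wavelength_nm=config.wavelength_nm,
    )
    logger.info(
        "run: seed=%d photons=%d lambda=%.0fnm R=%.5f T=%.5f A=%.5f lost=%.2e",
        config.seed,
        config.n_photons,
        config.wavelength_nm,
        images.total_reflectance,
        images.total_transmittance,
        images.total_absorbed,
        images.lost,
    )
    return images


def spectral_sweep(
    vol: TissueLabelVolume,
    spectra: OpticalSpectraTable,
    wavelengths,
    config: SimulationConfig,
) -> SpectralImageStack:
    """One transport run per wavelength with independent seeded substreams
    (wavelength index j runs with seed ``config.seed + j``, so a
    single-wavelength sweep is bit-identical to ``run_simulation``)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength list")
    nx, ny, _ = vol.labels.shape
    stack_r = np.zeros((wavelengths.size, nx, ny))
    stack_t = np.zeros((wavelengths.size, nx, ny))
    tot_r = np.zeros(wavelengths.size)
    tot_t = np.zeros(wavelengths.size)
    tot_a = np.zeros(wavelengths.size)
    for j, wl in enumerate(wavelengths):
        cfg = replace(config, wavelength_nm=float(wl), seed=config.seed + j)
        img = run_simulation(vol, spectra, cfg)
        stack_r[j] = img.reflectance
        stack_t[j] = img.transmittance
        tot_r[j] = img.total_reflectance
        tot_t[j] = img.total_transmittance
        tot_a[j] = img.total_absorbed
    return SpectralImageStack(wavelengths, stack_r, stack_t, tot_r, tot_t, tot_a)
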