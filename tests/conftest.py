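"""Shared fixtures: the default phantom (session-scoped; generation takes a
few seconds), a consistent miniature phantom for cheap unit tests, and a
wavelength-flat near-infrared synthetic property set used by the
transport demonstrations."""
from __future__ import annotations

import numpy as np
import pytest

import fingersim as fs
from fingersim.phantom import PhantomParams, _Bone, _Joint
from fingersim.optics import OpticalProperties


@pytest.fixture(scope="session")
def default_phantom() -> fs.TissueLabelVolume:
    return fs.generate_phantom()


def make_small_params(**overrides) -> PhantomParams:
    """A consistent miniature finger on an (80, 160, 68) grid (~0.9 M voxels)."""
    kwargs = dict(
        grid_shape=(80, 160, 68),
        finger_rx=3.8,
        finger_rz=3.2,
        tip_y=0.5,
        tip_len=5.0,
        dermis_t=0.8,
        bones=(_Bone(2.0, 8.0, 1.0), _Bone(10.0, 19.0, 1.3), _Bone(21.0, 1e9, 1.6)),
        joints=(
            _Joint(9.0, (1.2, 0.6, 1.0), (1.6, 1.0, 1.4), 0.4),
            _Joint(20.0, (1.5, 0.7, 1.2), (2.0, 1.1, 1.6), 0.4),
        ),
        flexor_dz=-2.2,
        flexor_semi=(0.9, 0.4),
        extensor_dz=2.0,
        extensor_semi=(0.8, 0.3),
        tendon_y0=2.5,
        pulley_y=(13.0, 15.0),
        pulley_t=0.4,
        ligament_radius=0.4,
        ligament_half_len=1.2,
        plate_semi=(1.2, 0.9, 0.35),
        plate_dz=-1.8,
        artery_dx=2.3,
        artery_dz=-1.0,
        artery_r=0.25,
        vein_dx=2.2,
        vein_dz=1.1,
        vein_r=0.3,
        nerve_dx=2.5,
        nerve_dz=-0.6,
        nerve_r=0.2,
        corpuscle_y=(6.0, 14.0, 24.0),
        corpuscle_dx=1.9,
        corpuscle_dz=-1.5,
        corpuscle_r=0.3,
        corpuscle_jitter=0.1,
    )
    kwargs.update(overrides)
    return PhantomParams(**kwargs)


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return make_small_params()


@pytest.fixture(scope="session")
def small_phantom(small_params) -> fs.TissueLabelVolume:
    return fs.generate_phantom(small_params)


#: Wavelength-flat synthetic optical properties in the near-infrared tissue
#: window (mu_a mm^-1, mu_s mm^-1, g, n), explicitly specified rather than
#: taken from the shipped default table.
NIR_DEMO_PROPERTIES: dict[int, OpticalProperties] = {
    1: OpticalProperties(0.010, 10.0, 0.90, 1.44),  # subcutis
    2: OpticalProperties(0.020, 11.0, 0.90, 1.40),
    3: OpticalProperties(0.020, 11.0, 0.90, 1.40),
    4: OpticalProperties(0.500, 70.0, 0.97, 1.37),  # blood
    5: OpticalProperties(0.500, 70.0, 0.97, 1.37),
    6: OpticalProperties(0.030, 20.0, 0.94, 1.50),  # collagen structures
    7: OpticalProperties(0.030, 20.0, 0.94, 1.50),
    8: OpticalProperties(0.030, 20.0, 0.94, 1.50),
    9: OpticalProperties(0.030, 20.0, 0.94, 1.50),
    10: OpticalProperties(0.050, 30.0, 0.92, 1.55),  # bone
    11: OpticalProperties(0.020, 3.0, 0.90, 1.38),  # cartilage
    12: OpticalProperties(0.003, 0.3, 0.90, 1.34),  # synovial fluid
    13: OpticalProperties(0.030, 8.0, 0.90, 1.38),
    14: OpticalProperties(0.030, 10.0, 0.85, 1.42),
    15: OpticalProperties(0.020, 10.0, 0.85, 1.40),
}


@pytest.fixture(scope="session")
def nir_spectra() -> fs.OpticalSpectraTable:
    return fs.uniform_spectra(NIR_DEMO_PROPERTIES)


def slab_volume(shape, label=10, pitch=0.2) -> fs.TissueLabelVolume:
    return fs.TissueLabelVolume(np.full(shape, label, dtype=np.int16), pitch)
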