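import numpy as np
import pytest

from npquant import synthetic as syn
from npquant.grids import VoxelGrid


@pytest.fixture(scope="session")
def small_phantom():
    return syn.build_phantom(
        cell_semiaxes_um=(8.0, 6.0, 4.0), nucleus_semiaxes_um=(3.0, 2.5, 1.8)
    )


@pytest.fixture(scope="session")
def tiny_scene():
    """A small noisy three-channel scene with known ground truth."""
    phantom = syn.build_phantom(
        cell_semiaxes_um=(6.0, 5.0, 3.5), nucleus_semiaxes_um=(2.2, 1.8, 1.4)
    )
    emitters = syn.sample_particles(
        phantom, n_inside=25, n_outside=8, particle_diameter_nm=85.0,
        brightness=2.0e4, margin_nm=600.0, min_separation_nm=350.0, seed=1,
    )
    scene = syn.simulate_scene(phantom, emitters, seed=1)
    scene["emitters"] = emitters
    return scene


def single_emitter(position_nm, brightness=2.0e4, diameter_nm=85.0):
    return syn.EmitterSet(
        positions_nm=np.asarray([position_nm], dtype=float),
        brightness=np.asarray([brightness], dtype=float),
        diameter_nm=np.asarray([diameter_nm], dtype=float),
        cluster_id=np.asarray([0]),
        inside=np.asarray([True]),
    )


def emitter_row(positions_nm, brightness=2.0e4, diameter_nm=85.0):
    pos = np.asarray(positions_nm, dtype=float)
    n = len(pos)
    return syn.EmitterSet(
        positions_nm=pos,
        brightness=np.full(n, float(brightness)),
        diameter_nm=np.full(n, float(diameter_nm)),
        cluster_id=np.arange(n),
        inside=np.ones(n, dtype=bool),
    )


def noisy_background(shape=(20, 60, 60), level=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return VoxelGrid(
        rng.poisson(level, shape).astype(float), (130.0, 30.0, 30.0), "nanoparticle"
    )
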