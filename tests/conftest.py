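import numpy as np
import pytest

from forcekit import (
    AdhesionDipole,
    ProtrusionSource,
    SubstrateModel,
    SyntheticCell,
    SyntheticScene,
)


@pytest.fixture
def substrate():
    return SubstrateModel(pixel_size_um=0.5)


def single_protrusion_scene(
    force_pn=50.0, pos=(24.0, 24.0), noise_sd_nm=0.0, seed=0, **prot_kwargs
):
    prot = ProtrusionSource(
        position_um=(0.0, 0.0),
        force_series_pn=np.array([force_pn]),
        **prot_kwargs,
    )
    cell = SyntheticCell(
        trajectory_um=np.array([list(pos)]),
        body_radius_um=12.0,
        protrusions=[prot],
        central_indentation_amplitude_nm=0.0,
    )
    return SyntheticScene(
        field_size_um=(48.0, 48.0),
        frame_interval_s=5.0,
        n_frames=1,
        cells=[cell],
        noise_sd_nm=noise_sd_nm,
        rng_seed=seed,
    )


def single_dipole_scene(
    force_nn=1.0, pos=(24.0, 24.0), axis_angle=0.0, noise_sd_nm=0.0, seed=0
):
    dip = AdhesionDipole(
        position_um=(0.0, 0.0), axis_angle=axis_angle, force_nn=force_nn
    )
    cell = SyntheticCell(
        trajectory_um=np.array([list(pos)]),
        body_radius_um=12.0,
        adhesions=[dip],
        central_indentation_amplitude_nm=0.0,
    )
    return SyntheticScene(
        field_size_um=(48.0, 48.0),
        frame_interval_s=5.0,
        n_frames=1,
        cells=[cell],
        noise_sd_nm=noise_sd_nm,
        rng_seed=seed,
    )
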