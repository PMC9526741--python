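"""Shared fixtures: optical geometries and small rendered scenes."""

from dataclasses import replace

import numpy as np
import pytest

from speckletrack import OpticalConfig
from speckletrack.scenes import (
    Motion,
    SubObject,
    apply_motion,
    disk_sprite,
    linear_motion,
    make_dotfield_scene,
    star_sprite,
    make_multishape_scene,
)
from speckletrack.speckle_sim import ScatteringScreen, SpeckleFrame, render_sequence


@pytest.fixture(scope="session")
def config():
    """Default transmission geometry (He-Ne, L_o=430 mm, L_s=50 mm)."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def tracking_config(config):
    """Geometry with a memory range of ~31 object px on the 256² grid."""
    return replace(config, L=0.065)


@pytest.fixture(scope="session")
def physical_config():
    """Small-scale geometry adequate for the thin-screen physical backend."""
    return OpticalConfig(
        wavelength=632.8e-6,
        sigma=0.15,
        L=0.1,
        L_o=50.0,
        L_s=25.0,
        detector_pixel_pitch=5e-3,
        object_pixel_pitch=1e-2,
    )


def frame_of(arr, pitch=1.0):
    return SpeckleFrame(intensity=np.asarray(arr, dtype=float), pitch=pitch)


@pytest.fixture(scope="session")
def moving_star_frames(tracking_config):
    """10-frame dot field with the star advancing 12 px/frame (col)."""
    pp = tracking_config.object_pixel_pitch
    seq = make_dotfield_scene(
        n_dots=60,
        dot_radius=2.0,
        star_size=10,
        grid=(256, 256),
        seed=3,
        pixel_pitch=pp,
        star_anchor_px=(0, -55),
    )
    seq = apply_motion(
        seq, len(seq.sub_objects) - 1, linear_motion((0.0, 12.0), 10, pp)
    )
    screen = ScatteringScreen(seed=11, shape=(256, 256))
    frames = render_sequence(seq, screen, tracking_config)
    return frames, (0.0, 12.0)
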