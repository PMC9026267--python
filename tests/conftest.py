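"""Shared fixtures: a desk-scale simulation geometry reused across tests.

The small geometry uses 128² hologram frames at the physical sample-plane
pixel pitch (5.2 µm / 106×) and a 64³ phantom grid covering the same
field of view, with a 2 µm bead — big enough to exercise every stage,
small enough to keep the suite fast.
"""

import numpy as np
import pytest

import sixpacktomo as st

FRAME_N = 128
GRID_N = 64
BEAD_RADIUS_UM = 1.0


@pytest.fixture(scope="session")
def optics():
    return st.OpticalConfig()


@pytest.fixture(scope="session")
def geometry(optics):
    pitch = optics.pixel_pitch_um
    dv = FRAME_N * pitch / GRID_N
    center = (GRID_N // 2 * dv,) * 3
    phantom = st.make_sphere_phantom((GRID_N,) * 3, dv, center, BEAD_RADIUS_UM,
                                     1.457, optics.n_medium)
    return {
        "optics": optics,
        "phantom": phantom,
        "voxel_size": dv,
        "center_um": center,
        "illum": st.make_illumination_set(),
        "layout": st.default_carrier_layout(optics, (FRAME_N, FRAME_N)),
        "coherence": st.CoherenceModel(),
        "frame_shape": (FRAME_N, FRAME_N),
        "mask": st.sphere_mask((GRID_N,) * 3, dv, center, BEAD_RADIUS_UM),
    }


@pytest.fixture(scope="session")
def frames(geometry):
    """Noiseless quantized frame pair + background pair + input fields."""
    return st.simulate_frame_pair(
        geometry["phantom"], geometry["illum"], geometry["optics"],
        geometry["layout"], geometry["coherence"],
        frame_shape=geometry["frame_shape"], seed=7, return_fields=True)


@pytest.fixture(scope="session")
def raw_recon(geometry, frames):
    """Unconstrained small-scale reconstruction (no non-negativity, no TV)."""
    return st.reconstruct_frame(frames["sample"], frames["background"],
                                geometry["optics"], geometry["illum"],
                                geometry["layout"], grid_n=GRID_N,
                                nonneg=False, tv=False)


@pytest.fixture(scope="session")
def nn_recon(geometry, frames):
    """Small-scale reconstruction with the non-negativity stage."""
    return st.reconstruct_frame(frames["sample"], frames["background"],
                                geometry["optics"], geometry["illum"],
                                geometry["layout"], grid_n=GRID_N,
                                nonneg=True, tv=False)
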