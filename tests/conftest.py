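import warnings

import numpy as np
import pytest

from bampquant import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_empty_mask_warnings():
    # individual tests re-enable warnings when they assert on them
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def circle_masks():
    """Concentric circular base/full masks for protrusion scenes."""
    h = w = 128
    rr, cc = np.ogrid[:h, :w]
    d2 = (rr - 64) ** 2 + (cc - 64) ** 2
    return d2 <= 30**2, d2 <= 42**2


@pytest.fixture
def small_ruffle_scene():
    """A compact ruffle movie with one drifting event, for fast tests."""
    scene = syn.SceneSpec(height=96, width=96, n_frames=24, cell_center=(48, 48),
                          cell_axes=(30, 34), seed=11)
    events = syn.RuffleSpec([
        syn.RuffleEvent(edge_angle=0.7, area_fraction_of_cell=0.08,
                        onset_frame=4, duration_frames=8, amplitude=200.0,
                        drift_px_per_frame=2.0)
    ])
    return scene, events
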