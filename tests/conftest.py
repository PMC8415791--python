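import numpy as np
import pytest

from lsavol.image_io import RegionLabelMask, ScalarVolume
from lsavol.synth import Segment, render_angiogram


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def oblique_cylinder():
    """Factory: render a hard-edged cylinder in generic (off-lattice, oblique)
    position, returning (volume, truth, analytic pi*r^2*L volume in mm^3)."""

    def make(
        diameter_vox=3,
        shape=(64, 64, 64),
        spacing=(0.4, 0.4, 0.4),
        vessel_intensity=200.0,
        background_intensity=40.0,
        edge_softness_mm=0.0,
        noise_sigma=0.0,
        seed=7,
    ):
        r = diameter_vox / 2.0 * min(spacing)
        extent = np.asarray(shape) * np.asarray(spacing)
        p0 = np.array([0.23, 0.27, 0.12]) * extent
        p1 = np.array([0.61, 0.52, 0.88]) * extent
        seg = Segment(0, None, np.array([p0, p1]), r, 0)
        vol, truth = render_angiogram(
            [seg],
            shape,
            spacing,
            vessel_intensity=vessel_intensity,
            background_intensity=background_intensity,
            edge_softness_mm=edge_softness_mm,
            noise_sigma=noise_sigma,
            seed=seed,
        )
        analytic = np.pi * r * r * float(np.linalg.norm(p1 - p0))
        return vol, truth, analytic

    return make


@pytest.fixture
def whole_grid_roi():
    """Factory: a single-region ROI covering an entire grid."""

    def make(shape, spacing=(0.4, 0.4, 0.4), name="roi"):
        return RegionLabelMask(
            np.ones(shape, dtype=np.int16), {name: 1}, spacing=spacing
        )

    return make


@pytest.fixture
def bimodal_enhanced():
    """Factory: a synthetic 'enhanced' map with a clean intensity gap —
    vessel voxels >= high, background <= low — plus its truth mask."""

    def make(shape=(32, 32, 32), low=0.2, high=0.8, vessel_frac=0.04, seed=3):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0.0, low, size=shape)
        n = int(np.prod(shape) * vessel_frac)
        # one solid blob of vessel voxels so components are meaningful
        c = np.asarray(shape) // 2
        half = max(1, int(round(n ** (1 / 3) / 2)))
        sl = tuple(slice(cc - half, cc + half + 1) for cc in c)
        truth = np.zeros(shape, dtype=bool)
        truth[sl] = True
        data[truth] = rng.uniform(high, 1.0, size=int(truth.sum()))
        vol = ScalarVolume(data, spacing=(0.4, 0.4, 0.4))
        return vol, truth

    return make
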