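import numpy as np
import pytest

import cowflow as cf
from cowflow.segmentation import SegmentationMask

# The imaging phantom for recovery checks: 10 outlets, every vessel at
# least 3 voxels in radius at 0.32 mm spacing, compact extent.
PHANTOM_KW = dict(scale=0.8, min_radius=0.96, leaf_radius_range=(0.96, 1.3))
SPACING = 0.32


@pytest.fixture(scope="session")
def cow10():
    return cf.generate_cow_template(10, seed=1, **PHANTOM_KW)


@pytest.fixture(scope="session")
def cow10_imaging(cow10):
    """Noise-free volume + ground truth of the 10-outlet phantom."""
    return cf.rasterize_network(cow10, spacing=SPACING, noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def cow10_noisy_imaging(cow10):
    """Same phantom with additive noise at 10% of the lumen contrast."""
    return cf.rasterize_network(cow10, spacing=SPACING, noise_sd=10.0, seed=3)


@pytest.fixture(scope="session")
def cow10_segmented(cow10_imaging):
    volume, gt = cow10_imaging
    seeds = cf.seeds_from_openings(gt.openings, volume)
    return cf.segment_volume(volume, seeds)


@pytest.fixture(scope="session")
def cow10_noisy_segmented(cow10_noisy_imaging):
    volume, gt = cow10_noisy_imaging
    seeds = cf.seeds_from_openings(gt.openings, volume)
    return cf.segment_volume(volume, seeds)


@pytest.fixture(scope="session")
def cow60():
    return cf.generate_cow_template(60, seed=0, scale=0.8, min_radius=0.85,
                                    leaf_radius_range=(0.85, 1.25))


@pytest.fixture(scope="session")
def tube_net():
    """Oblique straight tube (grid-aligned tubes skeletonize poorly)."""
    net = cf.VesselNetwork()
    net.add_node("in", [0, 1, 0.5], kind="inlet", label="IN")
    net.add_node("out", [20, 7, 4.5], kind="outlet", label="OUT")
    net.add_edge("in", "out", "t", radius=1.6)
    return net


@pytest.fixture(scope="session")
def tube_imaging(tube_net):
    return cf.rasterize_network(tube_net, spacing=SPACING, noise_sd=0.0, seed=0)


@pytest.fixture()
def y_network():
    net = cf.VesselNetwork()
    net.add_node("in", [0, 1, 0.5], kind="inlet", label="IN")
    net.add_node("j", [12, 2, 1])
    net.add_node("o1", [22, 8, 3], kind="outlet", label="O1")
    net.add_node("o2", [21, -5, -2], kind="outlet", label="O2")
    net.add_edge("in", "j", "t", radius=1.6)
    net.add_edge("j", "o1", "b1", radius=1.3)
    net.add_edge("j", "o2", "b2", radius=1.3)
    return net


def gt_mask_to_segmentation(volume, gt):
    return SegmentationMask(mask=gt.mask, spacing=volume.spacing,
                            origin=volume.origin)


@pytest.fixture(scope="session")
def steady_waveform():
    return cf.generate_inflow_waveform(1e-3, 1.0, 0.0, label="IN")
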