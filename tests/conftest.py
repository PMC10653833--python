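import numpy as np
import pytest

from polarsig import CellMesh, DetectionParams, FluorFrame, SimParams

PIXEL = 0.065


@pytest.fixture
def det_params():
    return DetectionParams()


@pytest.fixture
def noise_free():
    """Study conditions with all noise disabled."""
    return SimParams(poisson_noise=False, read_noise_sd=0.0)


def make_rect_mesh(n_segments=20, seg_px=3, height=9, pixel_size=PIXEL,
                   cell_id="r0", pad=2):
    """A rectangular cell with equal-width axial segments (exact geometry)."""
    width = n_segments * seg_px + 2 * pad
    shape = (height + 2 * pad, width)
    segs = []
    for k in range(n_segments):
        cols = np.arange(pad + k * seg_px, pad + (k + 1) * seg_px)
        rows = np.arange(pad, pad + height)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        segs.append((rr * shape[1] + cc).ravel())
    return CellMesh(
        cell_id=cell_id, frame=0, segments=segs,
        axial_extents_px=np.full(n_segments, float(seg_px)),
        pole0=(pad + height / 2, pad), pole1=(pad + height / 2, width - pad - 1),
        image_shape=shape, pixel_size=pixel_size,
    )


def frame_from_segment_values(mesh, values, pixel_size=PIXEL):
    """A background-corrected frame whose pixels equal per-segment constants."""
    img = np.zeros(mesh.image_shape, dtype=float).ravel()
    for seg, v in zip(mesh.segments, values):
        img[seg] = v
    return FluorFrame(img.reshape(mesh.image_shape), pixel_size=pixel_size,
                      background_corrected=True)


@pytest.fixture
def rect_mesh():
    return make_rect_mesh()


def exact_binomial_bounds(n, p, conf=0.99):
    """Exact central binomial acceptance interval for a count at given p."""
    from scipy.stats import binom

    alpha = (1.0 - conf) / 2.0
    return int(binom.ppf(alpha, n, p)), int(binom.isf(alpha, n, p))
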