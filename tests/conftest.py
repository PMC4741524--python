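import numpy as np
import pytest

from dualpet import (
    AcquisitionSpec,
    Region,
    RegionSpec,
    TracerSpec,
    insert_tumor,
    make_brain_phantom,
)

BRAIN_ONLY = {Region.BRAIN: RegionSpec(Region.BRAIN, 1.0, 1.0)}


def uptakes(tumor_fch=None, tumor_fdg=1.0, hotspot_fch=None):
    """Region-uptake table for a phantom; omitted regions are absent."""
    table = dict(BRAIN_ONLY)
    if tumor_fch is not None:
        table[Region.TUMOR] = RegionSpec(Region.TUMOR, tumor_fch, tumor_fdg)
    if hotspot_fch is not None:
        table[Region.HOTSPOT] = RegionSpec(Region.HOTSPOT, hotspot_fch, 1.0)
    return table


def fch_tracer(**kw):
    return TracerSpec("FCH", uptakes(**kw))


def fdg_tracer(**kw):
    return TracerSpec("FDG", uptakes(**kw))


# sharp acquisition: PSF far below the voxel scale, i.e. effectively no blur
SHARP = AcquisitionSpec(psf_fwhm_mm=1e-3)


@pytest.fixture(scope="session")
def brain():
    return make_brain_phantom()


@pytest.fixture(scope="session")
def tumor_phantom():
    return insert_tumor(make_brain_phantom(), 3.5)
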