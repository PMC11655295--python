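import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hicpaint import GenomicRegion, SceneSpec, make_scene

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MARK_OF_STATE = {"A": "H3K27ac", "B": "H3K9me3", "C": "H3K27me3"}
MARK_COLORS = {"H3K27ac": "#00C800", "H3K9me3": "#8000B4", "H3K27me3": "#FFA500"}


@pytest.fixture
def region10():
    """Tiny 10-bin region at 100 bp resolution."""
    return GenomicRegion("chrT", 0, 1000, 100)


@pytest.fixture(scope="session")
def scene():
    """The default three-state synthetic scene, in memory."""
    return make_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def scene_files(tmp_path_factory):
    """The same scene written to disk (cool, dense text, bedGraph, bigWig, BED9)."""
    outdir = tmp_path_factory.mktemp("scene")
    return make_scene(SceneSpec(seed=1), outdir=outdir)


def planted_classes(scene):
    """Expected per-bin class labels from the planted state vector."""
    return np.array(
        [MARK_OF_STATE.get(s, "unassigned") for s in scene.state_of_bin],
        dtype=object,
    )
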