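import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import swellanchor as sa


@pytest.fixture(scope="session")
def demo_results():
    """The packaged 2D demo run for all three co-polymer compositions.

    One run per composition on the fixed-seed disc geometry; shared across
    the trend tests and the end-to-end acceptance checks.
    """
    results = {}
    for comp in ("90/10", "85/15", "80/20"):
        cfg = sa.demo_config(comp)
        results[comp] = sa.run_pipeline(cfg, write_outputs=False)
    return results


@pytest.fixture
def default_params():
    return sa.RemodelingParams()


@pytest.fixture
def single_element_mesh_2d():
    labels = sa.make_block_labels((1, 1))
    return sa.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")


@pytest.fixture
def small_pipeline_config(tmp_path):
    """A very small, fast pipeline configuration for I/O and determinism tests."""
    from swellanchor.pipeline import ImageConfig, ROIConfig, MaterialsConfig
    return sa.demo_config(
        "85/15",
        output=str(tmp_path / "run"),
        image=ImageConfig(shape=(32, 32), voxel_size=0.3, seed=3),
        domain_radius=4.6,
        materials=MaterialsConfig(anchor_modulus=100.0),
        remodeling=sa.RemodelingParams(resolve_every=500, max_steps=3000),
        roi=ROIConfig(inner_radius=4.0, thickness=0.4,
                      far_inner_radius=4.2, far_thickness=0.4),
    )
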