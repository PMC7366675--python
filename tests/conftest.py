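import numpy as np
import pytest

from beatfield import RunConfig, run_pipeline
from beatfield.leadfield import LeadFieldSet
from beatfield.mesh import ROISpec, build_layered_sphere_mesh, define_rois, place_electrodes
from beatfield.validation import fem_vs_analytic_study, superposition_study


@pytest.fixture(scope="session")
def five_layer_mesh():
    """Default 5-tissue head at the demo resolution."""
    return build_layered_sphere_mesh(target_edge_length=10.0, seed=0)


@pytest.fixture(scope="session")
def head_setup(five_layer_mesh):
    """Mesh + 8 candidate electrodes + deep-target/cortex ROIs."""
    aug, electrodes = place_electrodes(five_layer_mesh, 8)
    roi = define_rois(aug, (0.0, 0.0, 37.0), 6.0)
    return aug, electrodes, roi


@pytest.fixture(scope="session")
def toy_leadfields():
    """Synthetic 5-candidate lead fields over 40 nodes, with a local ROI.

    Field magnitudes are scaled so that typical envelope amplitudes straddle
    the 0.2 V/m feasibility threshold.
    """
    rng = np.random.default_rng(7)
    ids = [f"E{i:02d}" for i in range(5)]
    fields = {e: 0.25 * rng.normal(size=(40, 3)) for e in ids}
    lf = LeadFieldSet(fields=fields, reference_id="REF", mesh_fingerprint="toy")
    roi = ROISpec(target_nodes=np.arange(8), cortex_nodes=np.arange(8, 40))
    return lf, roi


@pytest.fixture(scope="session")
def fem_study():
    """FEM vs analytic-series refinement study (shared: it is expensive)."""
    return fem_vs_analytic_study()


@pytest.fixture(scope="session")
def superpos_study():
    return superposition_study()


@pytest.fixture(scope="session")
def demo16(tmp_path_factory):
    """Full 16-electrode demo pipeline run (all four comparison conditions)."""
    outdir = tmp_path_factory.mktemp("demo16")
    cfg = RunConfig()
    cfg.output_directory = str(outdir)
    run_pipeline(cfg)
    return cfg, outdir
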