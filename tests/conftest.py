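import numpy as np
import pytest

from netsync.config import PipelineConfig
from netsync.design import StudyDesign
from netsync.simulate import default_truth, synthesize_study


def make_design(n_per_group: int, groups=("control", "depressed"), seed: int = 0):
    rng = np.random.default_rng(seed)
    n = n_per_group * len(groups)
    return StudyDesign(
        subject_ids=[f"{i:03d}" for i in range(n)],
        group=np.array(
            [g for g in groups for _ in range(n_per_group)], dtype=object
        ),
        age=np.round(rng.normal(70.0, 7.0, size=n), 1),
        depression_score=np.zeros(n),
        executive_score=np.zeros(n),
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 6+6-subject, 3-network phantom study on disk (session-scoped)."""
    data_dir = tmp_path_factory.mktemp("small_study")
    truth = default_truth(
        grid=(14, 14, 14),
        k=3,
        blob_radius=2.0,
        seed=1,
        noise_sd=0.3,
        subject_corr_sd=0.2,
        motion_confound_strength=0.3,
    )
    design = make_design(6)
    record = synthesize_study(
        design, truth, t_points=100, out_dir=data_dir, seed=7
    )
    return {
        "data_dir": data_dir,
        "truth": truth,
        "design": design,
        "record": record,
    }


@pytest.fixture()
def small_config():
    return PipelineConfig(
        n_components=3,
        n_mc_sims=200,
        n_perm_voxelwise=50,
        run_voxelwise=False,
        rng_seed=7,
    )
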