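import numpy as np
import pytest

from qrelax.phantom import (
    PhantomSpec,
    RegionBox,
    build_ground_truth,
    generate_study,
)
from qrelax.pipeline import StudyConfig, run_study


def mini_layout() -> dict[int, RegionBox]:
    """Small two-hemisphere layout: WM slab + one deep-gray box per side."""
    lay = {
        2: RegionBox("Cerebral-white-matter", "left", "wm", (2, 12), (2, 22), (2, 22)),
        41: RegionBox("Cerebral-white-matter", "right", "wm", (16, 26), (2, 22), (2, 22)),
        11: RegionBox("Caudate", "left", "gm", (4, 10), (6, 12), (6, 12)),
        50: RegionBox("Caudate", "right", "gm", (18, 24), (6, 12), (6, 12)),
    }
    return lay


def mini_gm_r2star() -> dict:
    return {
        ("Caudate", "left", "migraine-free"): 20.6,
        ("Caudate", "left", "migraine"): 21.6,
        ("Caudate", "right", "migraine-free"): 20.8,
        ("Caudate", "right", "migraine"): 19.7,
    }


def make_mini_spec(seed: int = 7, n_days: int = 5, **overrides) -> PhantomSpec:
    schedule = ["migraine-free"] * n_days
    schedule[n_days // 2] = "migraine"
    defaults = dict(
        grid_shape=(28, 24, 24),
        region_layout=mini_layout(),
        true_r2star_by_region_condition=mini_gm_r2star(),
        day_schedule=tuple(schedule),
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def mini_spec():
    return make_mini_spec()


@pytest.fixture
def mini_gt(mini_spec):
    return build_ground_truth(mini_spec)


@pytest.fixture
def noiseless_mini_gt():
    return build_ground_truth(make_mini_spec(noise_sigma=0.0, day_jitter_sd=0.0))


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """Full default 21-day study on disk plus its analysis results."""
    study_dir = tmp_path_factory.mktemp("study")
    out_dir = tmp_path_factory.mktemp("run")
    spec = PhantomSpec(seed=20260914)
    manifest = generate_study(spec, study_dir)
    config = StudyConfig(str(study_dir), str(out_dir))
    result = run_study(config)
    return {
        "spec": spec,
        "manifest": manifest,
        "study_dir": study_dir,
        "out_dir": out_dir,
        "result": result,
    }
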