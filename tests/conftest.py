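import pytest

from embryoquant.config import PipelineConfig
from embryoquant.simulate import generate_two_cell_movie, preset


def quick_params(name="default", seed=0, **overrides):
    """Short single-or-few-frame movie params for fast tests."""
    defaults = dict(
        n_frames=1, n_z=3, focal_z=1, neb_frame_ab=None, neb_frame_p1=None
    )
    defaults.update(overrides)
    return preset(name, seed=seed, **defaults)


def iou(a, b):
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_movie():
    """One full-length default movie with NEB events (seed 0)."""
    params = preset("default", seed=0, n_z=3, focal_z=1)
    stack, truth = generate_two_cell_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def quick_movie():
    """Single-frame default movie (seed 0), both nuclei present."""
    params = quick_params(seed=0)
    stack, truth = generate_two_cell_movie(params)
    return params, stack, truth
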