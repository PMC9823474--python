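import pytest

from eyeqc.expert import ESParams
from eyeqc.geometry import AnnotationGeometry
from eyeqc.synth import SceneSpec, generate_frames, render_frame


@pytest.fixture(scope="session")
def default_geometry():
    return AnnotationGeometry()


@pytest.fixture(scope="session")
def default_params():
    return ESParams()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, centered, fully visible pupil."""
    return SceneSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_frame(clean_spec):
    return render_frame(clean_spec, seed=1)


@pytest.fixture(scope="session")
def tiny_suite():
    """A small balanced labeled frame set shared across unit tests."""
    from eyeqc.geometry import LABEL_ORDER

    return generate_frames({lab: 4 for lab in LABEL_ORDER}, seed=77)
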