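import numpy as np
import pytest

from iridens.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom with planted artefacts in both regions."""
    spec = PhantomSpec(
        artefact_fraction_iris=0.02,
        artefact_fraction_lateral=0.035,
        seed=42,
    )
    frame, masks, truth = make_phantom(spec)
    return spec, frame, masks, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
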