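import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pointworlds import InformationFile, InformationLayer, worked_example

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_pair():
    return worked_example()


def make_random_dataset(rng: np.random.Generator, n: int | None = None):
    """A random valid dataset with injective coordinates (seeded)."""
    from pointworlds import Dataset

    if n is None:
        n = int(rng.integers(1, 30))
    pts = rng.normal(0, 10, size=(n, 3))
    pts += np.arange(n)[:, None] * 1e-6  # injectivity tag
    name = "ds-" + "".join(rng.choice(list("abcdefgh"), size=6))
    return Dataset(name=name, points=pts, chain=bool(rng.integers(0, 2)))


def make_random_information(rng: np.random.Generator,
                            n: int | None = None,
                            surjective: bool = True) -> InformationFile:
    """A random valid information file; surjective => no empty classes."""
    if n is None:
        n = int(rng.integers(1, 30))
    layers = []
    for _ in range(int(rng.integers(1, 4))):
        k = int(rng.integers(1, min(6, n + 1)))
        if surjective:
            values = np.concatenate(
                [np.arange(k), rng.integers(0, k, size=n - k)])
            rng.shuffle(values)
        else:
            values = rng.integers(0, k, size=n)
        name = None
        labels = None
        if rng.integers(0, 2):
            name = "layer-" + "".join(rng.choice(list("mnopqr"), size=4))
        if rng.integers(0, 2):
            labels = [f"class {c}" for c in range(k)]
        layers.append(InformationLayer(num_classes=k, values=values,
                                       name=name, labels=labels))
    return InformationFile(layers=layers)
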