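import numpy as np
import pytest

import stcokriging as sk


@pytest.fixture
def small_dataset():
    """Nine samples of two variables on a 3-point, multi-year layout."""
    pts = [
        sk.STPoint(0.0, 0.0, 2010.0),
        sk.STPoint(100.0, 0.0, 2010.0),
        sk.STPoint(0.0, 100.0, 2011.0),
    ]
    samples = []
    for i, p in enumerate(pts):
        samples.append(sk.STSample(p, "Cu", 1.0 + i, f"cu{i}"))
        samples.append(sk.STSample(p, "Zn", 10.0 - i, f"zn{i}"))
    samples.append(sk.STSample(sk.STPoint(50.0, 50.0, 2012.0), "Cu", 5.0, "cu9"))
    return sk.STDataset(samples)


def random_dataset(rng, n=30, variables=("u", "v"), extent=1000.0,
                   years=(0.0, 1.0, 2.0), missing=0.0):
    """Scattered heterotopic dataset with uniform random values."""
    samples = []
    sid = 0
    for i in range(n):
        p = sk.STPoint(
            float(rng.uniform(0, extent)),
            float(rng.uniform(0, extent)),
            float(rng.choice(years)),
        )
        for v in variables:
            if missing and rng.random() < missing:
                continue
            samples.append(sk.STSample(p, v, float(rng.normal()), f"s{sid}"))
            sid += 1
    return sk.STDataset(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_model_set():
    """A valid single-structure two-variable coregionalization."""
    models = [
        sk.BilonickModel("u", "u", 0.1, 0.0, 1.0, 500.0, 0.5, 300.0),
        sk.BilonickModel("v", "v", 0.1, 0.0, 1.0, 500.0, 0.5, 300.0),
        sk.BilonickModel("u", "v", 0.05, 0.0, 0.8, 500.0, 0.4, 300.0),
    ]
    return sk.ModelSet.from_models(models, sk.SharedAnisotropy(400.0))
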