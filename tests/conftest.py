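import numpy as np
import pytest

from purecl.synthetic import (LabeledImage, SyntheticDatasetSpec,
                              generate_synthetic_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 8 images at 64x64 — shared across read-only tests."""
    spec = SyntheticDatasetSpec(n_classes=3, n_per_class=8, seed=42)
    return generate_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def tiny_images():
    """Six 32x32 textured images in two classes, for cheap encoder passes."""
    gen = np.random.default_rng(7)
    return [
        LabeledImage(pixels=gen.random((3, 32, 32), dtype=np.float32),
                     label=i % 2, id=f"t{i}")
        for i in range(6)
    ]


def numeric_gradcheck(f, tensors, eps=1e-6, atol=1e-5):
    """Central-difference gradient check for float64 graphs."""
    for t in tensors:
        t.grad = None
        t._grad_shared = False
    out = f()
    out.backward(np.ones_like(out.data))
    for t in tensors:
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = t.data[i]
            t.data[i] = old + eps
            up = f().data.sum()
            t.data[i] = old - eps
            dn = f().data.sum()
            t.data[i] = old
            num[i] = (up - dn) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=atol,
                                   err_msg=f"gradient mismatch for shape {t.shape}")
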