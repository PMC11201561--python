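import numpy as np
import pytest

from nodulegp.simgrowth import ImagePatch, NodulePair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_patch(values) -> ImagePatch:
    v = np.asarray(values, dtype=np.float64)
    return ImagePatch(values=v, pixel_spacing_mm=0.5,
                      side_mm=v.shape[0] * 0.5)


@pytest.fixture
def random_patch_pair(rng):
    a = make_patch(rng.random((64, 64)))
    b = make_patch(rng.random((64, 64)))
    return a, b


def tiny_pairs(rng, n: int = 6, size: int = 16) -> list[NodulePair]:
    """Small random baseline/follow-up pairs for fast trainer tests."""
    pairs = []
    for i in range(n):
        base = make_patch(rng.random((size, size)))
        fup = make_patch(rng.random((size, size)))
        pairs.append(NodulePair(base, fup, 12.0,
                                "malignant" if i % 2 else "benign",
                                f"T{i:03d}"))
    return pairs


def finite_difference_grads(f, arrays, eps: float = 1e-6):
    """Central finite-difference gradients of scalar f(*arrays)."""
    grads = []
    for j, a in enumerate(arrays):
        g = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index

            def evaluate(delta):
                mod = [arr.copy() for arr in arrays]
                mod[j][idx] += delta
                return f(*mod)

            g[idx] = (evaluate(eps) - evaluate(-eps)) / (2 * eps)
        grads.append(g)
    return grads
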