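import numpy as np
import pytest

from magnet import MagNet, MagNetConfig, SlideSpec, generate_slide

# widths small enough for CPU test runs; architecture shape is unchanged
TINY_MODEL = dict(
    branch_channels=2,
    backbone_channels=(4, 8),
    aux_channels=(4, 8),
    gru_hidden=8,
    head_sizes=(16, 8),
)


@pytest.fixture(scope="session")
def small_slide():
    """A positive macro-lesion slide, 512 px / 4 levels."""
    spec = SlideSpec(level0_side=512, mmax=4, lesion_scale="macro", label=1)
    pyramid, truth = generate_slide(spec, seed=7)
    return pyramid, truth


@pytest.fixture(scope="session")
def tiny_model_323():
    cfg = MagNetConfig(layers=3, patches=(3, 2, 3), **TINY_MODEL)
    return MagNet(cfg, rng=np.random.default_rng(0)).eval()


def gradcheck(func, tensors, eps=1e-5, rtol=1e-4, atol=1e-6):
    """Compare analytic gradients of scalar-valued ``func`` against central
    finite differences (tensors must be float64)."""
    out = func(*tensors)
    for t in tensors:
        t.grad = None
    out.backward()
    for t in tensors:
        assert t.dtype == np.float64, "gradcheck requires float64 inputs"
        analytic = t.grad if t.grad is not None else np.zeros_like(t.data)
        numeric = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        num_flat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(func(*tensors).data)
            flat[i] = orig - eps
            lo = float(func(*tensors).data)
            flat[i] = orig
            num_flat[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)
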