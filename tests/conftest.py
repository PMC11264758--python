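import numpy as np
import pytest

from stcunet.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(fn, tensors, seed_grad, eps=1e-6):
    """Central finite differences of sum(fn(*tensors) * seed_grad) w.r.t.
    every tensor, by perturbing entries in place (float64 inputs expected)."""
    grads = []
    for t in tensors:
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = float((fn(*tensors).data * seed_grad).sum())
            flat[i] = orig - eps
            fm = float((fn(*tensors).data * seed_grad).sum())
            flat[i] = orig
            num.ravel()[i] = (fp - fm) / (2.0 * eps)
        grads.append(num)
    return grads


def gradcheck(fn, *arrays, tol=1e-5, eps=1e-6, rng_seed=99):
    """Assert analytic gradients match finite differences for all inputs."""
    tensors = [Tensor(np.asarray(a, dtype=np.float64), requires_grad=True)
               for a in arrays]
    out = fn(*tensors)
    seed_grad = np.random.default_rng(rng_seed).normal(size=out.shape)
    out.backward(seed_grad)
    numeric = numeric_gradient(fn, tensors, seed_grad, eps=eps)
    for t, num in zip(tensors, numeric):
        scale = max(1.0, float(np.abs(num).max()))
        err = float(np.abs(num - t.grad).max()) / scale
        assert err < tol, f"gradient mismatch: relative error {err:.2e}"


def module_gradcheck(module, x, tol=1e-4, eps=1e-6):
    """Finite-difference check of d sum(module(x)) / dx for a float64 module."""
    xt = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)
    out = module(xt).sum()
    out.backward()
    analytic = xt.grad.copy()
    num = np.zeros_like(xt.data)
    flat = xt.data.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = module(xt).sum().item()
        flat[i] = orig - eps
        fm = module(xt).sum().item()
        flat[i] = orig
        num.ravel()[i] = (fp - fm) / (2.0 * eps)
    scale = max(1.0, float(np.abs(num).max()))
    err = float(np.abs(num - analytic).max()) / scale
    assert err < tol, f"module gradient mismatch: relative error {err:.2e}"
    return analytic
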