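import numpy as np
import pytest

from tabanom.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def grad_check(inputs, fwd, tol: float = 1e-5) -> float:
    """Max relative error between autograd and finite-difference gradients."""
    for t in inputs:
        t.grad = None
    fwd().backward()
    worst = 0.0
    for t in inputs:
        ng = numerical_grad(lambda: fwd().item(), t.data)
        err = np.abs(ng - t.grad).max() / (np.abs(ng).max() + 1e-8)
        worst = max(worst, err)
    assert worst < tol, f"gradient mismatch: {worst:.2e} >= {tol}"
    return worst


@pytest.fixture
def tablet64():
    from tabanom.synth import TabletSpec, render_normal
    return render_normal(TabletSpec(), 64, seed=0)


def make_tensor(rng, shape, requires_grad=True):
    return Tensor(rng.normal(size=shape), requires_grad=requires_grad)
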