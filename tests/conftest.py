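import numpy as np
import networkx as nx
import pytest

from netattack import Network, from_networkx


def random_network(rng: np.random.Generator, n: int, p: float) -> Network:
    """Erdos-Renyi G(n, p) instance as a Network (may be disconnected)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return from_networkx(g)


def dense_exp_taylor(a: np.ndarray, tol: float = 1e-13) -> np.ndarray:
    """Truncated Taylor series for expm with a rigorous tail bound.

    Independent oracle: no scipy expm, no scaling-and-squaring.  Terms
    are added until the remainder bound
    ``||A||^{K+1} / (K+1)! * 1 / (1 - ||A||/(K+2))`` drops below tol
    (valid once K + 2 > ||A||).
    """
    a = np.asarray(a, dtype=np.float64)
    n = a.shape[0]
    norm = np.linalg.norm(a, 1)
    total = np.eye(n)
    term = np.eye(n)
    k = 0
    while True:
        k += 1
        term = term @ a / k
        total += term
        if k + 2 > norm:
            tail = np.linalg.norm(term, 1) * norm / (k + 1)
            tail /= max(1 - norm / (k + 2), 1e-3)
            if tail < tol:
                return total
        if k > 500:  # pragma: no cover - safety net
            raise RuntimeError("Taylor series failed to converge")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230918)
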