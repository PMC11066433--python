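import numpy as np
import pytest

from tgfswitch import (
    CoreParams,
    DEFAULT_EXTENDED,
    build_reduced_network,
    substitute_endogenous,
)
from tgfswitch.bifurcation import k1_scan_params


@pytest.fixture(scope="session")
def endo_params() -> CoreParams:
    """Core model with the fitted endogenous substitution (γ=3.5, K̃1, K̃2)."""
    return substitute_endogenous(DEFAULT_EXTENDED)


@pytest.fixture(scope="session")
def near_fold_params() -> CoreParams:
    """K1-scan demonstration set near the K1 fold (bistable, both basins)."""
    return k1_scan_params(14.0)


@pytest.fixture(scope="session")
def network():
    """Default reduced pathway network, equilibrated once per session."""
    return build_reduced_network()


def brute_force_roots(params: CoreParams, upper: float, n: int = 100_000) -> np.ndarray:
    """Independent fixed-point oracle: sign-change scan of T − f(T) on a dense
    grid (log-spaced near the origin plus linear), refined by bisection on the
    residual itself — no shared code with the package's Newton path."""

    def residual(t):
        t = np.asarray(t, dtype=float)
        tna = t**params.na
        tnb = t**params.nb
        th = (params.a / params.d1) * tna / (tna + params.Ka)
        f = (params.b / params.d2) * params.Kb / (tnb + params.Kb)
        fmap = (params.c / params.d3) * (th / (th + params.K1)) * (
            params.K2 / (f + params.K2)
        )
        return t - fmap

    grid = np.unique(
        np.concatenate([[0.0], np.geomspace(1e-12, upper, n // 2),
                        np.linspace(1e-12, upper, n - n // 2)])
    )
    r = residual(grid)
    roots = [0.0]
    sign = np.sign(r)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        a, b = grid[i], grid[i + 1]
        if a == 0.0:
            a = 1e-15
            if np.sign(residual(a)) == np.sign(residual(b)):
                continue
        for _ in range(200):
            m = 0.5 * (a + b)
            if np.sign(residual(m)) == np.sign(residual(a)):
                a = m
            else:
                b = m
        roots.append(0.5 * (a + b))
    return np.array(sorted(roots))
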