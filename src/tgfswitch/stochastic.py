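"""Ornstein–Uhlenbeck stochastic extension and multimodality testing.

The stochastic model keeps TGF-β1 deterministic: each path first relaxes

    d[TGFβ1]/dt = f(T) − T        (forward Euler, random uniform start)

to its basin's fixed point T̄, then THBS1 and FMOD fluctuate around their
steady maps as mean-reverting OU processes

    dX = (f_X(T̄) − X) dt + σ dB(t)

simulated by Euler–Maruyama with non-negative clamping.  With unit
relaxation rate the stationary distribution of each coordinate is Gaussian
with mean f_X(T̄) and SD σ/√2, so the population THBS1 marginal is a
mixture over basins — bimodal near the fold, unimodal away from it.

Multimodality is assessed by the Silverman critical-bandwidth bootstrap:
h_crit is the smallest Gaussian-KDE bandwidth at which the density has at
most k modes, and the p-value is the proportion of variance-rescaled
smoothed resamples whose KDE at h_crit exceeds k modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CoreParams, reduced_map, steady_fmod, steady_thbs1

__all__ = ["SDEConfig", "Ensemble", "relax_tgfb1", "simulate_ensemble", "silverman_test"]


@dataclass(frozen=True)
class SDEConfig:
    """Configuration of the stochastic ensemble.

    Defaults follow the bimodality simulation: σ1 = σ2 = 0.2,
    [TGFβ1]max = 0.2, 10,000 paths; the alternative printed regime is
    σ1 = σ2 = 0.05 with [TGFβ1]max = 1.0.  ``t_stationary`` = 20 unit
    relaxation times ≫ the OU mixing time.
    """

    sigma1: float = 0.2
    sigma2: float = 0.2
    tgfb1_max: float = 0.2
    n_paths: int = 10_000
    dt: float = 0.01
    t_relax: float = 200.0
    t_stationary: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt >= 1:
            raise ValueError("dt must be < 1 (explicit scheme, unit relaxation rate)")
        if self.tgfb1_max < 0:
            raise ValueError("tgfb1_max must be >= 0")


@dataclass(frozen=True)
class Ensemble:
    """Terminal (THBS1, FMOD) samples with each path's relaxed TGF-β1."""

    thbs1: np.ndarray
    fmod: np.ndarray
    tgfb1_bar: np.ndarray
    config: SDEConfig
    params: CoreParams
    clamped_fraction: float = 0.0
    clamp_counts_thbs1: np.ndarray | None = None
    clamp_counts_fmod: np.ndarray | None = None
    relax_warnings: int = 0

    def __post_init__(self) -> None:
        n = self.config.n_paths
        if not (len(self.thbs1) == len(self.fmod) == len(self.tgfb1_bar) == n):
            raise ValueError("sample arrays must have n_paths entries")

    @property
    def n_steps(self) -> int:
        return int(round(self.config.t_stationary / self.config.dt))

    def clamped_fraction_of(self, mask=None, variable: str = "thbs1") -> float:
        """Fraction of clamped Euler–Maruyama updates, optionally per sub-ensemble."""
        counts = self.clamp_counts_thbs1 if variable == "thbs1" else self.clamp_counts_fmod
        if counts is None:
            return 0.0
        if mask is None:
            mask = np.ones(len(counts), dtype=bool)
        denom = self.n_steps * int(mask.sum())
        return float(counts[mask].sum() / denom) if denom else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path_id": np.arange(len(self.thbs1)),
                "tgfb1_bar": self.tgfb1_bar,
                "thbs1": self.thbs1,
                "fmod": self.fmod,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def relax_tgfb1(
    initial,
    params: CoreParams,
    cfg: SDEConfig = SDEConfig(),
    step_tol: float = 1e-9,
):
    """Relax d T/dt = f(T) − T by forward Euler to its basin's fixed point.

    Vectorized over initial conditions.  Integration stops when every path's
    per-step change falls below ``step_tol`` or ``t_relax`` is reached; a
    path still moving at the horizon counts as a convergence warning.
    Returns ``(tgfb1_bar, n_unconverged)`` for array input, or the scalar
    fixed point for scalar input.
    """
    t = np.asarray(initial, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).copy()
    if np.any(t < 0):
        raise ValueError("initial TGF-β1 must be >= 0")
    dt = cfg.dt
    n_steps = int(round(cfg.t_relax / dt))
    delta = np.full_like(t, np.inf)
    for _ in range(n_steps):
        step = dt * (reduced_map(t, params) - t)
        t = np.clip(t + step, 0.0, None)
        delta = np.abs(step)
        if delta.max() < step_tol:
            break
    n_unconverged = int(np.count_nonzero(delta >= step_tol))
    if scalar:
        return float(t[0])
    return t, n_unconverged


def simulate_ensemble(params: CoreParams, cfg: SDEConfig = SDEConfig()) -> Ensemble:
    """Simulate the two-stage stochastic ensemble.

    Per path: TGFβ1(0) ~ U(0, tgfb1_max) and THBS1(0) = FMOD(0) = 0; the
    TGF-β1 coordinate is relaxed deterministically to T̄, then (THBS1, FMOD)
    follow the OU equations by Euler–Maruyama for ``t_stationary`` with
    negative excursions clamped to zero.  Deterministic given the seed:
    per-path substreams are spawned from one SeedSequence, so enlarging
    n_paths leaves earlier paths' draws unchanged.
    """
    n = cfg.n_paths
    children = np.random.SeedSequence(cfg.seed).spawn(n + 1)
    init_rng = np.random.Generator(np.random.PCG64(children[0]))
    t0 = init_rng.uniform(0.0, cfg.tgfb1_max, size=n) if cfg.tgfb1_max > 0 else np.zeros(n)

    tbar, n_unconverged = relax_tgfb1(t0, params, cfg)
    mean_th = np.asarray(steady_thbs1(tbar, params), dtype=float)
    mean_f = np.asarray(steady_fmod(tbar, params), dtype=float)

    dt = cfg.dt
    n_steps = int(round(cfg.t_stationary / dt))
    sqdt = np.sqrt(dt)
    th = np.zeros(n)
    fm = np.zeros(n)
    clamp_th = np.zeros(n, dtype=np.int64)
    clamp_fm = np.zeros(n, dtype=np.int64)
    if cfg.sigma1 == 0.0 and cfg.sigma2 == 0.0:
        # noiseless OU collapses onto its mean exactly at stationarity
        th = mean_th.copy()
        fm = mean_f.copy()
    else:
        s1, s2 = cfg.sigma1 * sqdt, cfg.sigma2 * sqdt
        chunk = 1024  # paths per vectorized block (bounds noise memory)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            m = stop - start
            # per-path substream: the noise block of path i is a pure
            # function of (seed, i), so growing n_paths never reshuffles it
            noise = np.stack(
                [
                    np.random.Generator(np.random.PCG64(children[i + 1]))
                    .standard_normal((n_steps, 2))
                    for i in range(start, stop)
                ]
            )
            x = np.zeros(m)
            y = np.zeros(m)
            mth = mean_th[start:stop]
            mf = mean_f[start:stop]
            for j in range(n_steps):
                x += dt * (mth - x) + s1 * noise[:, j, 0]
                y += dt * (mf - y) + s2 * noise[:, j, 1]
                neg_x = x < 0.0
                neg_y = y < 0.0
                clamp_th[start:stop] += neg_x
                clamp_fm[start:stop] += neg_y
                x[neg_x] = 0.0
                y[neg_y] = 0.0
            th[start:stop] = x
            fm[start:stop] = y
    per_var = n_steps * n if n_steps else 1
    return Ensemble(
        thbs1=th,
        fmod=fm,
        tgfb1_bar=np.asarray(tbar, dtype=float),
        config=cfg,
        params=params,
        clamped_fraction=float((clamp_th.sum() + clamp_fm.sum()) / (2 * per_var)),
        clamp_counts_thbs1=clamp_th,
        clamp_counts_fmod=clamp_fm,
        relax_warnings=n_unconverged,
    )


# ---------------------------------------------------------------------------
# Silverman critical-bandwidth multimodality test
# ---------------------------------------------------------------------------

_GRID_SIZE = 512


def _count_modes(samples: np.ndarray, h: float, grid: np.ndarray) -> int:
    """Number of local maxima of the Gaussian KDE with bandwidth h on a grid."""
    # binned evaluation: histogram then exact Gaussian smoothing of bin mass
    dens = np.zeros_like(grid)
    # exact KDE on the grid (n_samples x grid can be large; chunked)
    chunk = max(1, int(2e6 // len(grid)))
    for start in range(0, len(samples), chunk):
        block = samples[start:start + chunk, None]
        dens += np.exp(-0.5 * ((grid[None, :] - block) / h) ** 2).sum(axis=0)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return int(np.count_nonzero(interior))


def _critical_bandwidth(samples: np.ndarray, k: int, grid: np.ndarray,
                        rel_tol: float = 1e-3) -> float:
    """Smallest bandwidth whose KDE has at most k modes (binary search)."""
    s = samples.std()
    lo = 1e-4 * s
    hi = 4.0 * (samples.max() - samples.min())
    if _count_modes(samples, lo, grid) <= k:
        return lo
    while hi - lo > rel_tol * s:
        mid = 0.5 * (lo + hi)
        if _count_modes(samples, mid, grid) <= k:
            hi = mid
        else:
            lo = mid
    return hi


def silverman_test(
    samples,
    k: int = 1,
    n_boot: int = 999,
    seed: int = 0,
) -> dict:
    """Silverman's critical-bandwidth bootstrap test of k-modality.

    Tests H0: the density has at most ``k`` modes.  Returns a dict with the
    critical bandwidth ``h_crit`` and the bootstrap p-value: small p rejects
    k-modality (e.g. k = 1 rejected ⇒ evidence of multimodality).

    Resamples are smoothed with the critical bandwidth and rescaled to
    preserve the sample variance, the standard correction for the smoothed
    bootstrap.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError(f"need at least 10 samples, got {len(x)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")

    span = np.ptp(x)
    sigma2 = x.var()
    # two passes: a provisional grid to locate h_crit, then a grid extended
    # by 3 critical bandwidths on which h_crit is re-derived and the
    # bootstrap mode counts are evaluated
    h0 = 1.06 * x.std() * len(x) ** -0.2
    grid = np.linspace(x.min() - 3 * max(h0, 0.05 * span),
                       x.max() + 3 * max(h0, 0.05 * span), _GRID_SIZE)
    h_crit = _critical_bandwidth(x, k, grid)
    grid = np.linspace(x.min() - 3 * h_crit, x.max() + 3 * h_crit, _GRID_SIZE)
    h_crit = _critical_bandwidth(x, k, grid)

    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(1.0 + h_crit**2 / sigma2)
    exceed = 0
    n = len(x)
    for _ in range(n_boot):
        resample = rng.choice(x, size=n, replace=True)
        smoothed = scale * (resample + h_crit * rng.standard_normal(n))
        if _count_modes(smoothed, h_crit, grid) > k:
            exceed += 1
    p = exceed / n_boot
    return {"k": k, "h_crit": float(h_crit), "p": float(p), "n_boot": n_boot, "seed": seed}
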