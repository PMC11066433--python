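"""Seeded generators for every input the analysis consumes.

Each generator is a pure function of (true parameters, design, seed) and
emulates the statistical structure of the corresponding measurement:
monotone Hill-shaped dose responses, PDL-dependent shifts, replicate noise
(multiplicative lognormal by default — expression data are positive and
their spread scales with the mean), and mixture cell populations from the
stochastic ensemble.  Default designs copy the study conditions: doses on
the 0–4 ng/mL scale, PDLs {24, 36, 47}, eight time points up to 48 h, N = 3
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoreParams, ExtendedParams, steady_fmod, steady_thbs1
from .fitting import DoseResponseDataset, PDLDataset
from .pathway import OBSERVABLES, DEFAULT_TIMES_H, ReactionNetwork, StimulusProtocol, normalize_minmax, simulate
from .stochastic import SDEConfig, simulate_ensemble

__all__ = [
    "NoiseSpec",
    "DEFAULT_DOSES",
    "DEFAULT_PDLS",
    "gen_dose_response",
    "gen_pdl_series",
    "gen_timecourse",
    "gen_cell_population",
]

#: TGF-β1 dose design (assay-scale labels, ng/mL).
DEFAULT_DOSES = (0.0, 0.2, 0.8, 4.0)

#: Replicative-senescence stages: early, intermediate, late PDL.
DEFAULT_PDLS = (24.0, 36.0, 47.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-noise model: family, coefficient of variation, design size."""

    family: str = "lognormal"
    cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def apply(self, means: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Replicate matrix (len(means), n_replicates) around the mean curve."""
        means = np.asarray(means, dtype=float)[:, None]
        shape = (means.shape[0], self.n_replicates)
        if self.cv == 0:
            return np.broadcast_to(means, shape).copy()
        if self.family == "gaussian":
            out = means * (1.0 + self.cv * rng.standard_normal(shape))
            return np.clip(out, 0.0, None)
        # lognormal with unit mean and the requested CV
        s2 = np.log1p(self.cv**2)
        factors = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=shape)
        return means * factors


def gen_dose_response(
    true_params: CoreParams = CoreParams(),
    doses=DEFAULT_DOSES,
    noise: NoiseSpec = NoiseSpec(),
) -> DoseResponseDataset:
    """Dose–response replicates from the steady-state THBS1/FMOD curves."""
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose grid")
    if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be non-negative and strictly increasing")
    rng = np.random.default_rng(noise.seed)
    th = np.asarray(steady_thbs1(doses, true_params))
    fm = np.asarray(steady_fmod(doses, true_params))
    return DoseResponseDataset(
        doses=doses,
        thbs1_obs=noise.apply(th, rng),
        fmod_obs=noise.apply(fm, rng),
        meta=f"synthetic; {noise.family} noise cv={noise.cv}",
    )


def gen_pdl_series(
    true_ext: ExtendedParams = ExtendedParams(),
    pdls=DEFAULT_PDLS,
    noise: NoiseSpec = NoiseSpec(),
) -> PDLDataset:
    """PDL-series replicates of THBS1, FMOD and endogenous TGF-β1 levels."""
    pdls = np.asarray(pdls, dtype=float)
    if pdls.size == 0:
        raise ValueError("empty PDL grid")
    if np.any(pdls < 0):
        raise ValueError("pdls must be non-negative")
    rng = np.random.default_rng(noise.seed)
    e = true_ext
    th = e.alpha * pdls / (pdls + e.Kalpha)
    fm = e.beta * e.Kbeta / (pdls + e.Kbeta)
    tg = e.gamma * (th / (th + e.K1t)) * (e.K2t / (fm + e.K2t))
    return PDLDataset(
        pdls=pdls,
        thbs1_obs=noise.apply(th, rng),
        fmod_obs=noise.apply(fm, rng),
        tgfb1_obs=noise.apply(tg, rng),
    )


def gen_timecourse(
    network: ReactionNetwork,
    protocol: StimulusProtocol | None = None,
    times=DEFAULT_TIMES_H,
    noise: NoiseSpec = NoiseSpec(cv=0.05),
    observables=("pSMAD3", "cFos", "THBS1", "pAkt", "FMOD"),
) -> pd.DataFrame:
    """Training table from a pathway simulation at the sampling times.

    Simulates the stimulated protocol, samples the requested observables,
    min-max normalizes each, and adds replicate noise.  Returns a long
    table (time, replicate, observable, value).
    """
    times = tuple(float(t) for t in times)
    if protocol is None:
        protocol = StimulusProtocol(tgfb1_dose=1.0, t_grid=times)
    if max(times) > max(protocol.t_grid):
        raise ValueError("sampling times exceed the protocol horizon")
    rng = np.random.default_rng(noise.seed)
    traj = simulate(network, protocol, horizon=max(times))
    rows = []
    idx = {t: i for i, t in enumerate(traj.times)}
    sel = [idx[t] for t in times]
    for obs in observables:
        if obs not in OBSERVABLES:
            raise ValueError(f"unknown observable {obs!r}")
        raw = traj.species[OBSERVABLES[obs]].to_numpy()[sel]
        norm = normalize_minmax(raw)
        reps = noise.apply(norm, rng)
        for i, t in enumerate(times):
            for r in range(noise.n_replicates):
                rows.append((t, r, obs, reps[i, r]))
    return pd.DataFrame(rows, columns=["time", "replicate", "observable", "value"])


def gen_cell_population(
    params: CoreParams,
    cfg: SDEConfig = SDEConfig(),
    n_cells: int = 1000,
) -> np.ndarray:
    """Per-cell THBS1 intensity sample from the stochastic ensemble.

    Draws n_cells terminal THBS1 values; the result feeds the multimodality
    test directly (bimodal near the fold, unimodal away from it).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cfg = SDEConfig(
        sigma1=cfg.sigma1, sigma2=cfg.sigma2, tgfb1_max=cfg.tgfb1_max,
        n_paths=n_cells, dt=cfg.dt, t_relax=cfg.t_relax,
        t_stationary=cfg.t_stationary, seed=cfg.seed,
    )
    return simulate_ensemble(params, cfg).thbs1
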