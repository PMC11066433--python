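"""Reduced mechanistic TGF-β–VEGF crosstalk network.

A desk-scale ODE model (25 species, 22 reactions) with the stated topology
of the integrated signaling model:

* TGF-βR activation by active TGF-β1, SMAD2/3 phosphorylation, and
  SMAD2–SMAD3–SMAD4 trimer formation (the analogue of the published
  complex-formation reaction), with SMAD7 negative feedback on the receptor;
* an AND gate on the THBS1 promoter — the product of SMAD-trimer and
  AP-1 (c-Fos) Hill terms, so either input at zero silences THBS1;
* THBS1 positive feedback activating the latent TGF-β1 pool;
* FMOD sequestering active TGF-β1 into an inert complex;
* a VEGF arm (VEGFR → Raf → MEK → ERK → FMOD transcription factor)
  driving FMOD expression;
* PI3K–Akt crosstalk: both receptor classes activate PI3K, and pAkt
  represses the FMOD transcription step.

Rate-law conventions: receptor/ligand steps and kinase cascades are mass
action on explicit active/inactive pairs (so every kinase pool is conserved
by stoichiometry); transcription-like steps are Hill.  Trimer formation is
linear in the limiting SMAD4 pool and saturable in the phospho-SMADs — the
measured pools (SMAD4 0.0044 nM ≪ SMAD2 0.060 ≪ SMAD3 0.38) put SMAD4 far
below the other SMADs, which makes the trimer flux, and hence THBS1 output,
disproportionately sensitive to the SMAD4 pool.

Interventions are expressed through :class:`StimulusProtocol`: washout
zeroes the external TGF-β1 input, inhibitor events scale a species'
catalytic activity from a given time, and knockdowns scale initial pools.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "StimulusProtocol",
    "TrajectorySet",
    "SensitivityMatrix",
    "build_reduced_network",
    "simulate",
    "estimate_parameters",
    "training_sse",
    "integral_metric",
    "sensitivity",
    "normalize_minmax",
    "OBSERVABLES",
    "DEFAULT_TIMES_H",
]

#: Observable name → model species; the training readouts of the time-course
#: design (phospho-SMAD2 is a validation readout, withheld from fitting).
OBSERVABLES = {
    "pSMAD3": "pSMAD3",
    "cFos": "AP1",
    "THBS1": "THBS1",
    "pAkt": "pAkt",
    "FMOD": "FMOD",
    "pSMAD2": "pSMAD2",
}

#: The eight sampling times (hours): 0, 15, 30, 60, 120 min, 8, 24, 48 h.
DEFAULT_TIMES_H = (0.0, 0.25, 0.5, 1.0, 2.0, 8.0, 24.0, 48.0)

#: Measured SMAD pools (nM) used as total initial amounts.
SMAD_POOLS_NM = {"SMAD2": 0.060, "SMAD3": 0.38, "SMAD4": 0.0044}

#: Conserved pools: total amount summed over these member species is
#: invariant under the declared stoichiometry.
CONSERVED_POOLS = {
    "SMAD2": ("SMAD2", "pSMAD2", "S234"),
    "SMAD3": ("SMAD3", "pSMAD3", "S234"),
    "SMAD4": ("SMAD4", "S234"),
    "TGFBR": ("TGFBR", "aTGFBR"),
    "VEGFR": ("VEGFR", "aVEGFR"),
    "Raf": ("Raf", "aRaf"),
    "MEK": ("MEK", "aMEK"),
    "ERK": ("ERK", "aERK"),
    "PI3K": ("PI3K", "aPI3K"),
    "Akt": ("Akt", "pAkt"),
    "FTF": ("FTF", "aFTF"),
}


@dataclass(frozen=True)
class Reaction:
    """One (possibly reversible) reaction: net stoichiometry plus a rate law.

    ``rate(c, p)`` receives effective concentrations ``c`` (a mapping that
    also carries the external input as the pseudo-species ``TGFB1_ext``) and
    the parameter table ``p``, and returns the net forward flux.
    """

    name: str
    stoich: dict[str, float]
    rate: Callable[[dict, dict], float]


@dataclass
class ReactionNetwork:
    """Named species with initial concentrations, reactions, and parameters."""

    species: dict[str, float]
    reactions: list[Reaction]
    parameters: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            for sp in rxn.stoich:
                if sp not in self.species:
                    raise ValueError(
                        f"reaction {rxn.name!r} references undeclared species {sp!r}"
                    )

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def initial_state(self) -> np.ndarray:
        return np.array(list(self.species.values()), dtype=float)

    def pool_total(self, state: dict[str, float] | np.ndarray, pool: str) -> float:
        members = CONSERVED_POOLS[pool]
        if isinstance(state, dict):
            return float(sum(state[m] for m in members))
        names = self.species_names
        return float(sum(state[names.index(m)] for m in members))

    def stoichiometry_balance(self, pool: str) -> dict[str, float]:
        """Net change of a conserved pool per unit flux of each reaction."""
        members = set(CONSERVED_POOLS[pool])
        return {
            rxn.name: sum(v for sp, v in rxn.stoich.items() if sp in members)
            for rxn in self.reactions
        }

    def with_parameters(self, overrides: dict[str, float]) -> "ReactionNetwork":
        unknown = set(overrides) - set(self.parameters)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        net = copy.copy(self)
        net.parameters = {**self.parameters, **overrides}
        return net

    def with_initials(self, overrides: dict[str, float]) -> "ReactionNetwork":
        unknown = set(overrides) - set(self.species)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        net = copy.copy(self)
        net.species = {**self.species, **overrides}
        return net

    def to_yaml(self, path) -> None:
        """Persist initials and parameters (topology is rebuilt by the builder)."""
        with open(str(path), "w") as fh:
            yaml.safe_dump(
                {
                    "species": {k: float(v) for k, v in self.species.items()},
                    "parameters": {k: float(v) for k, v in self.parameters.items()},
                    "bounds": {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()},
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        with open(str(path)) as fh:
            data = yaml.safe_load(fh)
        net = build_reduced_network(equilibrate=False)
        net = net.with_parameters(data.get("parameters", {}))
        net = net.with_initials(data.get("species", {}))
        if "bounds" in data:
            net.bounds = {k: (float(a), float(b)) for k, (a, b) in data["bounds"].items()}
        return net


@dataclass(frozen=True)
class StimulusProtocol:
    """Doses, washout, timed inhibitor events, and knockdowns.

    * ``tgfb1_dose`` — external active-TGF-β1 input in multiples of the
      reference stimulation (1.0 ≡ the 4 ng/mL condition; 0 = control).
    * ``washout_time`` — hour at which the external input drops to zero.
    * ``inhibitor_events`` — (species, time, residual_fraction): from that
      time on, the species' catalytic activity is scaled by the residual.
    * ``knockdowns`` — (pool, remaining_fraction) applied to initial pools.
    """

    tgfb1_dose: float = 0.0
    vegf_dose: float = 1.0
    washout_time: float | None = None
    inhibitor_events: tuple[tuple[str, float, float], ...] = ()
    knockdowns: tuple[tuple[str, float], ...] = ()
    t_grid: tuple[float, ...] = DEFAULT_TIMES_H

    def __post_init__(self) -> None:
        if self.tgfb1_dose < 0 or self.vegf_dose < 0:
            raise ValueError("doses must be >= 0")
        if self.washout_time is not None and self.washout_time < 0:
            raise ValueError("washout_time must be >= 0")
        for _, t, frac in self.inhibitor_events:
            if t < 0 or not (0 <= frac <= 1):
                raise ValueError("inhibitor events need time >= 0 and fraction in [0,1]")
        for _, frac in self.knockdowns:
            if not (0 <= frac <= 1):
                raise ValueError("knockdown fractions must lie in [0,1]")

    def external_input(self, t: float) -> float:
        if self.washout_time is not None and t >= self.washout_time:
            return 0.0
        return self.tgfb1_dose

    def activity_scales(self, t: float) -> dict[str, float]:
        scales: dict[str, float] = {}
        for sp, t0, frac in self.inhibitor_events:
            if t >= t0:
                scales[sp] = min(scales.get(sp, 1.0), frac)
        return scales


@dataclass(frozen=True)
class TrajectorySet:
    """Integrated trajectories with raw and (on demand) normalized observables."""

    times: np.ndarray
    species: pd.DataFrame  # one column per species
    protocol: StimulusProtocol

    def observable_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.species[sp].to_numpy() for name, sp in OBSERVABLES.items()},
            index=self.times,
        )

    def normalized_observables(self) -> pd.DataFrame:
        raw = self.observable_table()
        return pd.DataFrame(
            {c: normalize_minmax(raw[c].to_numpy()) for c in raw.columns},
            index=self.times,
        )

    def to_tsv(self, path) -> None:
        out = self.species.copy()
        out.insert(0, "time", self.times)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")


@dataclass(frozen=True)
class SensitivityMatrix:
    """Log-log sensitivity coefficients S_y = ∂ln M / ∂ln y_j."""

    targets: tuple[str, ...]
    coefficients: np.ndarray
    metric: str
    perturbation: float
    target_kind: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=list(self.targets), name="S_y")

    def ranked(self) -> pd.Series:
        s = self.to_series()
        return s.reindex(s.abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# Default network
# ---------------------------------------------------------------------------

def _hill(x, K, n=1.0):
    if x <= 0:
        return 0.0
    xn = x**n
    return xn / (xn + K**n)


def default_parameters() -> dict[str, float]:
    """Shipped rate constants (per hour; concentrations in model units)."""
    return {
        # latent TGF-β1 pool and activation (positive feedback)
        "k_lsyn": 0.5, "k_ldeg": 0.05,
        "k_act0": 0.0002, "k_actT": 2.0, "K_Tact": 2.0, "n_Tact": 2.0,
        "k_tdeg": 0.35,
        # receptor layer and SMAD7 feedback
        "k_ron": 1.5, "k_roff": 1.0, "k_s7i": 2.0,
        # SMAD phosphorylation (fast relative to transcription)
        "k_p2": 5.0, "k_dp2": 1.0, "k_p3": 5.0, "k_dp3": 1.0,
        # trimer: linear in SMAD4, saturable in phospho-SMADs
        "k_tri": 8.0, "K_tri2": 0.02, "K_tri3": 0.1, "k_tdis": 1.0,
        # SMAD7 expression
        "k_s7": 0.4, "K_s7": 0.1, "k_7deg": 0.15,
        # AP-1 (c-Fos) expression
        "k_ap1": 1.2, "K_ap1": 0.25, "k_ap1_0": 0.005, "k_ap1deg": 0.5,
        # THBS1 AND gate
        "k_th": 1.5, "K_thS": 0.002, "K_thA": 1.2, "n_th": 2.0,
        "k_thdeg": 0.08,
        # FMOD expression (ERK-driven TF, Akt-repressed) and turnover
        "k_f": 0.12, "K_fF": 0.15, "K_fA": 0.3, "n_fA": 2.0,
        "k_fdeg": 0.075,
        # FMOD–TGF-β1 sequestration
        "k_fb": 0.004, "k_cdeg": 0.1,
        # VEGF arm
        "k_von": 0.4, "k_voff": 1.0,
        "k_raf": 2.0, "k_raf_off": 1.0,
        "k_mek": 2.0, "k_mek_off": 1.0,
        "k_erk": 2.0, "k_erk_off": 1.0,
        "k_ftf": 2.0, "k_ftf_off": 1.0,
        # PI3K–Akt crosstalk
        "k_pi": 2.0, "w_vegf": 0.01, "k_pi_off": 0.5,
        "k_pa": 2.0, "k_dpa": 1.0,
    }


def _default_species() -> dict[str, float]:
    return {
        "TGFB1_lat": 2.0,
        "TGFB1": 0.0,
        "TGFBR": 1.0, "aTGFBR": 0.0,
        "SMAD2": SMAD_POOLS_NM["SMAD2"], "pSMAD2": 0.0,
        "SMAD3": SMAD_POOLS_NM["SMAD3"], "pSMAD3": 0.0,
        "SMAD4": SMAD_POOLS_NM["SMAD4"],
        "S234": 0.0,
        "SMAD7": 0.0,
        "AP1": 0.0,
        "THBS1": 0.0,
        "FMOD": 0.0,
        "FT_complex": 0.0,
        "VEGF": 1.0,
        "VEGFR": 1.0, "aVEGFR": 0.0,
        "Raf": 1.0, "aRaf": 0.0,
        "MEK": 1.0, "aMEK": 0.0,
        "ERK": 1.0, "aERK": 0.0,
        "PI3K": 1.0, "aPI3K": 0.0,
        "Akt": 1.0, "pAkt": 0.0,
        "FTF": 1.0, "aFTF": 0.0,
    }


def _default_reactions() -> list[Reaction]:
    return [
        Reaction(
            "latent_tgfb1_turnover", {"TGFB1_lat": +1},
            lambda c, p: p["k_lsyn"] - p["k_ldeg"] * c["TGFB1_lat"],
        ),
        Reaction(
            "latent_activation_basal", {"TGFB1_lat": -1, "TGFB1": +1},
            lambda c, p: p["k_act0"] * c["TGFB1_lat"],
        ),
        Reaction(
            "latent_activation_by_thbs1", {"TGFB1_lat": -1, "TGFB1": +1},
            lambda c, p: p["k_actT"] * c["TGFB1_lat"]
            * _hill(c["THBS1"], p["K_Tact"], p["n_Tact"]),
        ),
        Reaction(
            "active_tgfb1_decay", {"TGFB1": -1},
            lambda c, p: p["k_tdeg"] * c["TGFB1"],
        ),
        Reaction(
            "tgfbr_activation", {"TGFBR": -1, "aTGFBR": +1},
            lambda c, p: p["k_ron"] * c["TGFBR"] * (c["TGFB1"] + c["TGFB1_ext"])
            - p["k_roff"] * c["aTGFBR"],
        ),
        Reaction(
            "tgfbr_inhibition_by_smad7", {"aTGFBR": -1, "TGFBR": +1},
            lambda c, p: p["k_s7i"] * c["SMAD7"] * c["aTGFBR"],
        ),
        Reaction(
            "smad2_phosphorylation", {"SMAD2": -1, "pSMAD2": +1},
            lambda c, p: p["k_p2"] * c["aTGFBR"] * c["SMAD2"] - p["k_dp2"] * c["pSMAD2"],
        ),
        Reaction(
            "smad3_phosphorylation", {"SMAD3": -1, "pSMAD3": +1},
            lambda c, p: p["k_p3"] * c["aTGFBR"] * c["SMAD3"] - p["k_dp3"] * c["pSMAD3"],
        ),
        Reaction(
            "smad_trimer_formation",
            {"pSMAD2": -1, "pSMAD3": -1, "SMAD4": -1, "S234": +1},
            lambda c, p: p["k_tri"] * c["SMAD4"]
            * _hill(c["pSMAD2"], p["K_tri2"]) * _hill(c["pSMAD3"], p["K_tri3"])
            - p["k_tdis"] * c["S234"],
        ),
        Reaction(
            "smad7_expression", {"SMAD7": +1},
            lambda c, p: p["k_s7"] * _hill(c["pSMAD3"], p["K_s7"])
            - p["k_7deg"] * c["SMAD7"],
        ),
        Reaction(
            "ap1_expression", {"AP1": +1},
            lambda c, p: p["k_ap1_0"] + p["k_ap1"] * _hill(c["aTGFBR"], p["K_ap1"])
            - p["k_ap1deg"] * c["AP1"],
        ),
        Reaction(
            "thbs1_expression", {"THBS1": +1},
            lambda c, p: p["k_th"]
            * _hill(c["S234"], p["K_thS"], p["n_th"])
            * _hill(c["AP1"], p["K_thA"], p["n_th"])
            - p["k_thdeg"] * c["THBS1"],
        ),
        Reaction(
            "fmod_expression", {"FMOD": +1},
            lambda c, p: p["k_f"] * _hill(c["aFTF"], p["K_fF"])
            * (1.0 - _hill(c["pAkt"], p["K_fA"], p["n_fA"]))
            - p["k_fdeg"] * c["FMOD"],
        ),
        Reaction(
            "fmod_tgfb1_sequestration", {"FMOD": -1, "TGFB1": -1, "FT_complex": +1},
            lambda c, p: p["k_fb"] * c["FMOD"] * c["TGFB1"],
        ),
        Reaction(
            "fmod_complex_decay", {"FT_complex": -1},
            lambda c, p: p["k_cdeg"] * c["FT_complex"],
        ),
        Reaction(
            "vegfr_activation", {"VEGFR": -1, "aVEGFR": +1},
            lambda c, p: p["k_von"] * c["VEGFR"] * c["VEGF"] - p["k_voff"] * c["aVEGFR"],
        ),
        Reaction(
            "raf_activation", {"Raf": -1, "aRaf": +1},
            lambda c, p: p["k_raf"] * c["aVEGFR"] * c["Raf"] - p["k_raf_off"] * c["aRaf"],
        ),
        Reaction(
            "mek_activation", {"MEK": -1, "aMEK": +1},
            lambda c, p: p["k_mek"] * c["aRaf"] * c["MEK"] - p["k_mek_off"] * c["aMEK"],
        ),
        Reaction(
            "erk_activation", {"ERK": -1, "aERK": +1},
            lambda c, p: p["k_erk"] * c["aMEK"] * c["ERK"] - p["k_erk_off"] * c["aERK"],
        ),
        Reaction(
            "ftf_activation", {"FTF": -1, "aFTF": +1},
            lambda c, p: p["k_ftf"] * c["aERK"] * c["FTF"] - p["k_ftf_off"] * c["aFTF"],
        ),
        Reaction(
            "pi3k_activation", {"PI3K": -1, "aPI3K": +1},
            lambda c, p: p["k_pi"] * (c["aTGFBR"] + p["w_vegf"] * c["aVEGFR"]) * c["PI3K"]
            - p["k_pi_off"] * c["aPI3K"],
        ),
        Reaction(
            "akt_phosphorylation", {"Akt": -1, "pAkt": +1},
            lambda c, p: p["k_pa"] * c["aPI3K"] * c["Akt"] - p["k_dpa"] * c["pAkt"],
        ),
    ]


def _default_bounds(params: dict[str, float]) -> dict[str, tuple[float, float]]:
    return {k: (v / 100.0, v * 100.0) for k, v in params.items()}


def build_reduced_network(
    config: dict | None = None,
    equilibrate: bool = True,
    t_equilibrate: float = 500.0,
) -> ReactionNetwork:
    """Construct the default reduced network.

    ``config`` may carry ``parameter_overrides``, ``species_overrides`` and
    ``include_decoy`` (adds a disconnected decoy species/reaction, useful as
    a sensitivity null).  With ``equilibrate`` the unstimulated model is
    pre-relaxed so that a zero-dose simulation starts on its baseline steady
    state.
    """
    config = config or {}
    species = _default_species()
    params = default_parameters()
    reactions = _default_reactions()

    sp_over = config.get("species_overrides", {})
    unknown = set(sp_over) - set(species)
    if unknown:
        raise ValueError(f"species_overrides references unknown species: {sorted(unknown)}")
    species.update(sp_over)

    p_over = config.get("parameter_overrides", {})
    unknown = set(p_over) - set(params)
    if unknown:
        raise ValueError(f"parameter_overrides references unknown parameters: {sorted(unknown)}")
    params.update(p_over)

    if config.get("include_decoy"):
        species["Decoy"] = 1.0
        params["k_decoy"] = 0.3
        reactions.append(
            Reaction(
                "decoy_turnover", {"Decoy": +1},
                lambda c, p: p["k_decoy"] - p["k_decoy"] * c["Decoy"],
            )
        )

    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=params,
        bounds=_default_bounds(params),
    )
    if equilibrate:
        baseline = StimulusProtocol(tgfb1_dose=0.0, t_grid=(0.0, t_equilibrate))
        traj = simulate(net, baseline, horizon=t_equilibrate)
        terminal = {sp: float(traj.species[sp].iloc[-1]) for sp in net.species}
        net = net.with_initials(terminal)
    return net


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _make_rhs(network: ReactionNetwork, ext_input: float,
              scales: dict[str, float],
              rate_scales: dict[str, float] | None):
    names = network.species_names
    idx = {n: i for i, n in enumerate(names)}
    params = network.parameters
    rate_scales = rate_scales or {}
    # per reaction: which inhibited species keep their raw value (the
    # reaction's own reactants/products are never activity-scaled)
    reactions = []
    for rxn in network.reactions:
        restore = [sp for sp in scales if sp in rxn.stoich]
        reactions.append((rxn, restore, rate_scales.get(rxn.name, 1.0)))

    def rhs(_t, y):
        y = np.clip(y, 0.0, None)
        base = {n: y[i] for n, i in idx.items()}
        base["TGFB1_ext"] = ext_input
        eff = dict(base)
        for sp, frac in scales.items():
            eff[sp] = base[sp] * frac
        dydt = np.zeros_like(y)
        for rxn, restore, rscale in reactions:
            if restore:
                c = dict(eff)
                for sp in restore:
                    c[sp] = base[sp]
            else:
                c = eff
            v = rscale * rxn.rate(c, params)
            for sp, coeff in rxn.stoich.items():
                dydt[idx[sp]] += coeff * v
        return dydt

    return rhs


def simulate(
    network: ReactionNetwork,
    protocol: StimulusProtocol,
    horizon: float | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    rate_scales: dict[str, float] | None = None,
    n_dense: int = 241,
) -> TrajectorySet:
    """Integrate the network under a stimulus protocol.

    Protocol events (washout, inhibitor onsets) are integration breakpoints;
    within each segment the external input and activity scales are constant.
    Output times are the protocol grid merged with a uniform dense grid.
    """
    if horizon is None:
        horizon = max(protocol.t_grid)
    event_times = {t for _, t, _ in protocol.inhibitor_events if 0 < t < horizon}
    if protocol.washout_time is not None and 0 < protocol.washout_time < horizon:
        event_times.add(protocol.washout_time)
    if max(protocol.t_grid) > horizon:
        raise ValueError("protocol t_grid extends beyond the horizon")
    breakpoints = sorted({0.0, horizon} | event_times)

    t_eval_all = np.unique(
        np.concatenate([np.asarray(protocol.t_grid, float),
                        np.linspace(0.0, horizon, n_dense)])
    )

    y0 = network.initial_state().copy()
    names = network.species_names
    for pool, frac in protocol.knockdowns:
        members = CONSERVED_POOLS.get(pool, (pool,))
        for m in members:
            if m in names:
                y0[names.index(m)] *= frac
    if protocol.vegf_dose != 1.0 and "VEGF" in names:
        y0[names.index("VEGF")] *= protocol.vegf_dose

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        seg_mid = 0.5 * (a + b)
        rhs = _make_rhs(
            network,
            ext_input=protocol.external_input(seg_mid),
            scales=protocol.activity_scales(seg_mid),
            rate_scales=rate_scales,
        )
        mask = (t_eval_all >= a) & (t_eval_all <= b)
        t_eval = np.unique(np.concatenate([[a], t_eval_all[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), y0, t_eval=t_eval, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{a}, {b}]: {sol.message}"
            )
        y0 = sol.y[:, -1]
        keep = slice(None) if not times_out else slice(1, None)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T)

    times = np.concatenate(times_out)
    states = np.clip(np.vstack(states_out), 0.0, None)
    frame = pd.DataFrame(states, columns=names)
    return TrajectorySet(times=times, species=frame, protocol=protocol)


# ---------------------------------------------------------------------------
# Metrics, sensitivity, estimation
# ---------------------------------------------------------------------------

def normalize_minmax(series) -> np.ndarray:
    """Map a sequence affinely onto [0, 1]; constant input is an error."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("degenerate normalization: series is constant")
    return (x - lo) / (hi - lo)


def integral_metric(traj: TrajectorySet, species: str) -> float:
    """Trapezoidal time-integral of one species over the simulated horizon."""
    if species not in traj.species.columns:
        raise ValueError(f"species {species!r} not in trajectory")
    if len(traj.times) < 2:
        raise ValueError("need at least two time points to integrate")
    return float(np.trapezoid(traj.species[species].to_numpy(), traj.times))


def sensitivity(
    network: ReactionNetwork,
    protocol: StimulusProtocol,
    metric_species: str = "THBS1",
    perturbation: float = 0.01,
    target_kind: str = "reaction",
    targets: Sequence[str] | None = None,
    horizon: float | None = None,
) -> SensitivityMatrix:
    """Finite-difference log-log sensitivity of the integral metric.

    ``reaction`` mode scales one reaction's flux by (1 + ε); ``species``
    mode scales one nonzero initial concentration.  Coefficients are
    Δln M / Δln y with ε = 1% by default.
    """
    if target_kind not in ("reaction", "species"):
        raise ValueError("target_kind must be 'reaction' or 'species'")
    base_traj = simulate(network, protocol, horizon=horizon)
    m0 = integral_metric(base_traj, metric_species)
    if m0 <= 0:
        raise ValueError(
            f"baseline integral of {metric_species!r} is non-positive; "
            "sensitivity coefficients are undefined"
        )
    if targets is None:
        if target_kind == "reaction":
            targets = [r.name for r in network.reactions]
        else:
            targets = [s for s, v in network.species.items() if v > 0]
    coeffs = np.empty(len(targets))
    dln = math.log1p(perturbation)
    for i, tgt in enumerate(targets):
        if target_kind == "reaction":
            traj = simulate(network, protocol, horizon=horizon,
                            rate_scales={tgt: 1.0 + perturbation})
        else:
            if network.species.get(tgt, 0.0) <= 0:
                raise ValueError(f"species target {tgt!r} has zero initial value")
            net = network.with_initials({tgt: network.species[tgt] * (1.0 + perturbation)})
            traj = simulate(net, protocol, horizon=horizon)
        m1 = integral_metric(traj, metric_species)
        coeffs[i] = (math.log(m1) - math.log(m0)) / dln
    return SensitivityMatrix(
        targets=tuple(targets),
        coefficients=coeffs,
        metric=f"integral[{metric_species}]",
        perturbation=perturbation,
        target_kind=target_kind,
    )


def training_sse(
    network: ReactionNetwork,
    training: pd.DataFrame,
    protocol: StimulusProtocol | None = None,
    overrides: dict[str, float] | None = None,
) -> float:
    """Pooled squared error of normalized simulated observables vs. training data.

    ``training`` is a long table (time, replicate, observable, value); each
    simulated observable is sampled at the training times and min-max
    normalized before comparison (the same convention the data carry).
    This is the objective Differential Evolution minimizes.
    """
    if protocol is None:
        protocol = StimulusProtocol(tgfb1_dose=1.0)
    net = network.with_parameters(overrides) if overrides else network
    fit_obs = [o for o in training["observable"].unique() if o in OBSERVABLES]
    times = np.sort(training["time"].unique())
    horizon = float(times.max())
    fit_protocol = StimulusProtocol(
        tgfb1_dose=protocol.tgfb1_dose,
        vegf_dose=protocol.vegf_dose,
        washout_time=protocol.washout_time,
        inhibitor_events=protocol.inhibitor_events,
        knockdowns=protocol.knockdowns,
        t_grid=tuple(times),
    )
    try:
        traj = simulate(net, fit_protocol, horizon=horizon,
                        rtol=1e-6, atol=1e-9, n_dense=61)
    except RuntimeError:
        return 1e6
    obs_idx = {t: i for i, t in enumerate(traj.times)}
    rows = [obs_idx[t] for t in times]
    sse = 0.0
    for o in fit_obs:
        data = (
            training[training["observable"] == o]
            .pivot(index="time", columns="replicate", values="value")
            .reindex(times)
            .to_numpy()
        )
        sim = traj.species[OBSERVABLES[o]].to_numpy()[rows]
        if np.ptp(sim) == 0:
            sse += float(np.nansum(data**2))
            continue
        resid = normalize_minmax(sim)[:, None] - data
        sse += float(np.nansum(resid**2))
    return sse


def estimate_parameters(
    network: ReactionNetwork,
    training: pd.DataFrame,
    free_parameters: Sequence[str],
    protocol: StimulusProtocol | None = None,
    n_runs: int = 30,
    maxiter: int = 30,
    popsize: int = 8,
    seed0: int = 1,
    de_options: dict | None = None,
) -> list[dict]:
    """Seeded Differential-Evolution fits of selected rate constants.

    ``training`` is a long table (time, replicate, observable, value) of
    min-max-normalized readouts under the stimulated protocol.  Each of the
    ``n_runs`` independent runs minimizes the pooled squared residuals
    between normalized simulated observables and every replicate value,
    with the free parameters searched in log space inside their declared
    bounds.  Returns one dict per run: {seed, objective, parameters,
    objective_trace}; elitist DE makes each trace non-increasing.
    """
    for name in free_parameters:
        if name not in network.parameters:
            raise ValueError(f"unknown free parameter {name!r}")
        if name not in network.bounds:
            raise ValueError(f"free parameter {name!r} has no bounds")
    if protocol is None:
        protocol = StimulusProtocol(tgfb1_dose=1.0)
    log_bounds = [
        (math.log(network.bounds[n][0]), math.log(network.bounds[n][1]))
        for n in free_parameters
    ]

    def objective(logvec: np.ndarray) -> float:
        overrides = {
            n: math.exp(v) for n, v in zip(free_parameters, logvec)
        }
        return training_sse(network, training, protocol=protocol, overrides=overrides)

    options = dict(mutation=0.8, recombination=0.9, polish=False,
                   init="latinhypercube", tol=0.0, updating="deferred")
    options.update(de_options or {})

    results = []
    for run in range(n_runs):
        seed = seed0 + run
        trace: list[float] = []

        def callback(xk, convergence=0.0):  # noqa: ARG001
            trace.append(objective(np.asarray(xk)))

        sol = differential_evolution(
            objective, bounds=log_bounds, maxiter=maxiter, popsize=popsize,
            seed=seed, callback=callback, **options,
        )
        trace.append(float(sol.fun))
        # the callback re-evaluates the elitist best, so the trace is
        # non-increasing by construction; enforce monotone recording
        mono = np.minimum.accumulate(np.asarray(trace))
        results.append(
            {
                "seed": seed,
                "objective": float(sol.fun),
                "parameters": {
                    n: float(math.exp(v)) for n, v in zip(free_parameters, sol.x)
                },
                "objective_trace": mono.tolist(),
            }
        )
    return results
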