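"""Deterministic core and endogenous models of the TGF-β1–THBS1–FMOD switch.

The core network couples a double-positive feedback loop (THBS1 activates
latent TGF-β1, TGF-β1 induces THBS1) with a double-negative loop (FMOD
sequesters TGF-β1, TGF-β1 represses FMOD):

    d[THBS1]/dt = a·T^na/(T^na + Ka) − d1·[THBS1]
    d[FMOD]/dt  = b·Kb/(T^nb + Kb)  − d2·[FMOD]
    d[TGFβ1]/dt = c·(TH/(TH + K1))·(K2/(F + K2)) − d3·[TGFβ1]

with T = [TGFβ1], TH = [THBS1], F = [FMOD].  At steady state the system
reduces to a scalar fixed-point problem T = f(T) whose root structure
(one vs. three fixed points) encodes the binary high-/low-TGF-β1 switch.

Degradation rates default to 1, so `a` is interchangeable with the fitted
ratio a/d1 and dynamic time is measured in protein relaxation times; this
matches the unit-relaxation convention of the stochastic extension.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "CoreParams",
    "ExtendedParams",
    "SystemState",
    "FixedPoint",
    "FixedPointSet",
    "PDLRecord",
    "DEFAULT_CORE",
    "DEFAULT_EXTENDED",
    "core_rhs",
    "steady_thbs1",
    "steady_fmod",
    "reduced_map",
    "reduced_map_derivative",
    "find_fixed_points",
    "classify_stability",
    "simulate_deterministic",
    "substitute_endogenous",
    "pdl_modulation",
    "compute_pdl",
    "load_params",
    "dump_params",
]

#: Marginal-stability band on |f'(T) − 1| below which a fixed point is
#: flagged rather than classified (fold vicinity).
MARGINAL_BAND = 1e-6

#: Literal doubling constant of the PDL formula n = 3.32(log10 A − log10 B) + X
#: (kept at the conventional printed value, not 1/log10(2) = 3.3219...).
PDL_LOG_FACTOR = 3.32


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"parameter {name!r} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class CoreParams:
    """Parameters of the core TGF-β1–THBS1–FMOD ODE model.

    Defaults are the nonlinear least-squares fit of the steady-state dose
    responses (a/d1 = 2.36, b/d2 = 0.33, Ka = 0.016, Kb = 0.002, na = 1.6,
    nb = 1.7) under the d1 = d2 = d3 = 1 convention.  ``K1``, ``K2`` and
    ``c`` are left at placeholder values; the endogenous substitution
    (:func:`substitute_endogenous`) installs the fitted endogenous set.
    """

    a: float = 2.36
    d1: float = 1.0
    b: float = 0.33
    d2: float = 1.0
    c: float = 1.0
    d3: float = 1.0
    Ka: float = 0.016
    Kb: float = 0.002
    K1: float = 1.0
    K2: float = 1.0
    na: float = 1.6
    nb: float = 1.7

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))
        if self.na < 1 or self.nb < 1:
            raise ValueError(
                f"Hill coefficients must be >= 1, got na={self.na}, nb={self.nb}"
            )

    @property
    def a_over_d1(self) -> float:
        """Maximal THBS1 level a/d1."""
        return self.a / self.d1

    @property
    def b_over_d2(self) -> float:
        """Maximal FMOD level b/d2."""
        return self.b / self.d2

    @property
    def c_over_d3(self) -> float:
        """Maximal TGF-β1 level c/d3 (γ under the endogenous substitution)."""
        return self.c / self.d3

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "CoreParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown CoreParams fields: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ExtendedParams:
    """Endogenous extension: PDL modulation and endogenous TGF-β1 production.

    Defaults are the fitted endogenous set α = 3, β = 5, γ = 3.5,
    Kα = 10.1, Kβ = 5, K̃1 = 0.46, K̃2 = 0.62.  γ is the normalized
    endogenous TGF-β1 production rate; Kα, Kβ are half-saturation points on
    the PDL axis (doublings).
    """

    alpha: float = 3.0
    beta: float = 5.0
    gamma: float = 3.5
    Kalpha: float = 10.1
    Kbeta: float = 5.0
    K1t: float = 0.46
    K2t: float = 0.62

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ExtendedParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown ExtendedParams fields: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


DEFAULT_CORE = CoreParams()
DEFAULT_EXTENDED = ExtendedParams()


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the three core species (model units)."""

    thbs1: float
    fmod: float
    tgfb1: float

    def __post_init__(self) -> None:
        for name in ("thbs1", "fmod", "tgfb1"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"state component {name!r} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.thbs1, self.fmod, self.tgfb1], dtype=float)


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the reduced scalar map with its stability label."""

    state: SystemState
    stability: Literal["stable", "unstable", "marginal"]
    slope: float
    eigenvalues: tuple[complex, complex, complex] | None = None
    newton_fallback: bool = False


@dataclass(frozen=True)
class FixedPointSet:
    """All fixed points found in a TGF-β1 search interval, sorted by TGF-β1."""

    points: tuple[FixedPoint, ...]
    params: CoreParams
    search_interval: tuple[float, float]

    def __post_init__(self) -> None:
        tg = [p.state.tgfb1 for p in self.points]
        if tg != sorted(tg):
            raise ValueError("fixed points must be sorted by increasing TGF-β1")

    @property
    def stable(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.stability == "stable")

    @property
    def unstable(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.points if p.stability == "unstable")

    @property
    def n_stable(self) -> int:
        return len(self.stable)

    def tgfb1_values(self) -> np.ndarray:
        return np.array([p.state.tgfb1 for p in self.points])


@dataclass(frozen=True)
class PDLRecord:
    """One passage record: population doubling level bookkeeping.

    n = 3.32·(log10 A − log10 B) + X, with A the harvested yield, B the
    seeded count, and X the PDL of the seeded population.
    """

    A: float
    B: float
    X: float
    n: float = field(init=False)

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError(f"cell counts must be > 0, got A={self.A}, B={self.B}")
        object.__setattr__(self, "n", compute_pdl(self.A, self.B, self.X))


# ---------------------------------------------------------------------------
# Right-hand sides and steady-state maps
# ---------------------------------------------------------------------------

def core_rhs(state: SystemState | Sequence[float], params: CoreParams):
    """Right-hand side of the core ODE system.

    Returns the derivative triple (d[THBS1]/dt, d[FMOD]/dt, d[TGFβ1]/dt).
    """
    if isinstance(state, SystemState):
        th, f, t = state.thbs1, state.fmod, state.tgfb1
    else:
        th, f, t = (float(x) for x in state)
        for name, v in (("thbs1", th), ("fmod", f), ("tgfb1", t)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"state component {name!r} must be finite and >= 0, got {v!r}"
                )
    p = params
    tna = t ** p.na
    tnb = t ** p.nb
    d_th = p.a * tna / (tna + p.Ka) - p.d1 * th
    d_f = p.b * p.Kb / (tnb + p.Kb) - p.d2 * f
    d_t = p.c * (th / (th + p.K1)) * (p.K2 / (f + p.K2)) - p.d3 * t
    return (d_th, d_f, d_t)


def _check_dose(tgfb1) -> np.ndarray:
    t = np.asarray(tgfb1, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("tgfb1 must be finite and >= 0")
    return t


def steady_thbs1(tgfb1, params: CoreParams = DEFAULT_CORE):
    """Steady-state THBS1 level (a/d1)·T^na/(T^na + Ka); vectorized."""
    t = _check_dose(tgfb1)
    tna = t ** params.na
    out = params.a_over_d1 * tna / (tna + params.Ka)
    return out if out.ndim else float(out)


def steady_fmod(tgfb1, params: CoreParams = DEFAULT_CORE):
    """Steady-state FMOD level (b/d2)·Kb/(T^nb + Kb); vectorized."""
    t = _check_dose(tgfb1)
    tnb = t ** params.nb
    out = params.b_over_d2 * params.Kb / (tnb + params.Kb)
    return out if out.ndim else float(out)


def reduced_map(tgfb1, params: CoreParams = DEFAULT_CORE):
    """Scalar self-consistency map f(T) for the TGF-β1 steady state.

    f(T) = (c/d3)·(TH/(TH + K1))·(K2/(F + K2)) with TH, F the steady-state
    THBS1 and FMOD levels at TGF-β1 = T.  Fixed points T = f(T) are exactly
    the TGF-β1 steady states of the full three-variable system.
    """
    t = _check_dose(tgfb1)
    th = steady_thbs1(t, params)
    f = steady_fmod(t, params)
    out = params.c_over_d3 * (th / (th + params.K1)) * (params.K2 / (f + params.K2))
    return out if np.ndim(out) else float(out)


def reduced_map_derivative(tgfb1, params: CoreParams = DEFAULT_CORE):
    """Closed-form derivative f'(T) of the reduced map (chain rule)."""
    t = _check_dose(tgfb1)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    p = params
    A, B, C = p.a_over_d1, p.b_over_d2, p.c_over_d3
    tna = t ** p.na
    tnb = t ** p.nb
    th = A * tna / (tna + p.Ka)
    f = B * p.Kb / (tnb + p.Kb)
    u = th / (th + p.K1)
    v = p.K2 / (f + p.K2)
    # dTH/dT and dF/dT; T^(n-1) → 0 as T → 0 for n > 1, finite for n = 1.
    with np.errstate(divide="ignore", invalid="ignore"):
        tpow_a = np.where(t > 0, t ** (p.na - 1.0), 0.0 if p.na > 1 else 1.0)
        tpow_b = np.where(t > 0, t ** (p.nb - 1.0), 0.0 if p.nb > 1 else 1.0)
    dth = A * p.na * p.Ka * tpow_a / (tna + p.Ka) ** 2
    df = -B * p.Kb * p.nb * tpow_b / (tnb + p.Kb) ** 2
    du = p.K1 * dth / (th + p.K1) ** 2
    dv = -p.K2 * df / (f + p.K2) ** 2
    out = C * (du * v + u * dv)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Fixed points and stability
# ---------------------------------------------------------------------------

def _search_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Bracketing grid: log-spaced near the origin plus a linear sweep.

    The reduced map is extremely steep near zero (Ka = 0.016, na = 1.6), and
    the lower nonzero root can sit at ~1e-5, so half the budget goes to a
    geometric grid reaching down to 1e-12.
    """
    lo = max(lo, 0.0)
    n_log = n // 2
    log_part = np.geomspace(1e-12, hi, n_log)
    lin_part = np.linspace(max(lo, 1e-12), hi, n - n_log)
    grid = np.unique(np.concatenate(([0.0] if lo == 0.0 else [lo], log_part, lin_part)))
    return grid[(grid >= lo) & (grid <= hi)]


def find_fixed_points(
    params: CoreParams,
    search_interval: tuple[float, float] | None = None,
    tol: float = 1e-10,
    n_grid: int = 4096,
    max_newton: int = 50,
) -> FixedPointSet:
    """Locate all fixed points of T = f(T) in the search interval.

    Sign changes of the residual r(T) = T − f(T) are bracketed on a dense
    grid and refined by damped Newton iteration (analytic derivative); a
    bracket where Newton fails to converge falls back to bisection and the
    fallback is recorded on the resulting point.  The trivial zero state is
    always included.
    """
    sup = params.c_over_d3
    if search_interval is None:
        search_interval = (0.0, 1.5 * sup + 1.0)
    lo, hi = float(search_interval[0]), float(search_interval[1])
    if lo >= hi:
        raise ValueError(f"inverted search interval ({lo}, {hi})")
    if hi <= sup:
        raise ValueError(
            f"search interval upper bound {hi} must exceed the map supremum c/d3={sup}"
        )

    grid = _search_grid(lo, hi, n_grid)
    resid = grid - reduced_map(grid, params)

    roots: list[tuple[float, bool]] = []
    if lo == 0.0:
        roots.append((0.0, False))

    def _residual(t: float) -> float:
        return t - reduced_map(t, params)

    def _residual_prime(t: float) -> float:
        return 1.0 - reduced_map_derivative(t, params)

    sign = np.sign(resid)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        a_, b_ = float(grid[i]), float(grid[i + 1])
        if a_ == 0.0:  # the zero root itself
            if abs(_residual(b_)) > tol:
                # genuine crossing away from 0 hides inside; bisect on (eps, b)
                a_ = 1e-15
                if np.sign(_residual(a_)) == np.sign(_residual(b_)):
                    continue
            else:
                continue
        t, fallback = _newton_with_fallback(
            _residual, _residual_prime, a_, b_, tol, max_newton
        )
        roots.append((t, fallback))

    # dedupe (Newton from adjacent brackets can land on the same root)
    roots.sort(key=lambda r: r[0])
    deduped: list[tuple[float, bool]] = []
    for t, fb in roots:
        if deduped and abs(t - deduped[-1][0]) <= max(1e-9, 1e-6 * abs(t)):
            continue
        deduped.append((t, fb))

    points = tuple(
        replace(classify_stability(t, params), newton_fallback=fb) for t, fb in deduped
    )
    return FixedPointSet(points=points, params=params, search_interval=(lo, hi))


def _newton_with_fallback(func, fprime, a: float, b: float, tol: float, max_iter: int):
    """Newton from the bracket midpoint, constrained to [a, b]; bisection fallback."""
    fa, fb = func(a), func(b)
    t = 0.5 * (a + b)
    for _ in range(max_iter):
        r = func(t)
        if abs(r) < tol:
            return t, False
        dr = fprime(t)
        if dr == 0:
            break
        step = r / dr
        t_new = t - step
        if not (a <= t_new <= b):
            # keep the bracket: shrink it around the sign change instead
            if np.sign(r) == np.sign(fa):
                a, fa = t, r
            else:
                b, fb = t, r
            t_new = 0.5 * (a + b)
        t = t_new
    # bisection fallback
    from scipy.optimize import brentq

    t = brentq(func, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return t, True


def _full_jacobian(t: float, params: CoreParams) -> np.ndarray:
    p = params
    th = steady_thbs1(t, p)
    f = steady_fmod(t, p)
    tna = t ** p.na
    tnb = t ** p.nb
    if t > 0:
        dth_dt = p.a * p.na * p.Ka * t ** (p.na - 1) / (tna + p.Ka) ** 2
        df_dt = -p.b * p.Kb * p.nb * t ** (p.nb - 1) / (tnb + p.Kb) ** 2
    else:
        dth_dt = 0.0 if p.na > 1 else p.a / p.Ka
        df_dt = 0.0 if p.nb > 1 else -p.b / p.Kb
    u = th / (th + p.K1)
    v = p.K2 / (f + p.K2)
    du_dth = p.K1 / (th + p.K1) ** 2
    dv_df = -p.K2 / (f + p.K2) ** 2
    return np.array(
        [
            [-p.d1, 0.0, dth_dt],
            [0.0, -p.d2, df_dt],
            [p.c * du_dth * v, p.c * u * dv_df, -p.d3],
        ]
    )


def classify_stability(
    tgfb1: float,
    params: CoreParams,
    mode: Literal["reduced", "jacobian"] = "reduced",
    fp_tol: float = 1e-6,
) -> FixedPoint:
    """Attach a stability label to a candidate TGF-β1 fixed point.

    ``reduced`` mode uses the scalar criterion (stable iff f'(T) < 1);
    ``jacobian`` mode uses the sign of the leading eigenvalue of the full
    3×3 Jacobian.  A reduced-mode slope within ``MARGINAL_BAND`` of 1 is
    labeled ``marginal`` with a warning (fold vicinity).
    """
    t = float(tgfb1)
    resid = abs(t - reduced_map(t, params))
    if resid > max(fp_tol, fp_tol * abs(t)):
        raise ValueError(
            f"candidate T={t} violates the fixed-point equation (residual {resid:.3g})"
        )
    state = SystemState(
        thbs1=float(steady_thbs1(t, params)),
        fmod=float(steady_fmod(t, params)),
        tgfb1=t,
    )
    slope = float(reduced_map_derivative(t, params))
    eigs = None
    if mode == "jacobian":
        eigvals = np.linalg.eigvals(_full_jacobian(t, params))
        eigs = tuple(complex(e) for e in eigvals)
        stability = "stable" if max(e.real for e in eigs) < 0 else "unstable"
    elif mode == "reduced":
        if abs(slope - 1.0) < MARGINAL_BAND:
            warnings.warn(
                f"fixed point T={t:.6g} is marginal (|f'-1| < {MARGINAL_BAND}); "
                "fold vicinity",
                stacklevel=2,
            )
            stability = "marginal"
        else:
            stability = "stable" if slope < 1.0 else "unstable"
    else:
        raise ValueError(f"unknown stability mode {mode!r}; use 'reduced' or 'jacobian'")
    return FixedPoint(state=state, stability=stability, slope=slope, eigenvalues=eigs)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def simulate_deterministic(
    initial: SystemState,
    params: CoreParams,
    t_end: float,
    dt: float = 0.01,
    method: Literal["euler", "lsoda"] = "euler",
):
    """Integrate the core ODEs forward in time.

    Explicit Euler with non-negative clamping by default (mirrors the
    clamping convention of the stochastic scheme); ``lsoda`` delegates to an
    adaptive solver.  Returns ``(times, states)`` with states of shape
    (n_steps + 1, 3) ordered (THBS1, FMOD, TGFβ1).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    x0 = initial.as_array()
    if method == "lsoda":
        from scipy.integrate import solve_ivp

        times = np.arange(0.0, t_end + dt / 2, dt)

        def rhs(_t, x):
            return core_rhs(np.clip(x, 0.0, None), params)

        sol = solve_ivp(rhs, (0.0, t_end), x0, t_eval=times, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"adaptive integration failed: {sol.message}")
        return sol.t, np.clip(sol.y.T, 0.0, None)
    if method != "euler":
        raise ValueError(f"unknown method {method!r}")
    n = int(round(t_end / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    states = np.empty((n + 1, 3))
    states[0] = x0
    x = x0.copy()
    for i in range(n):
        dx = np.asarray(core_rhs(x, params))
        x = np.clip(x + dt * dx, 0.0, None)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                f"explicit Euler became non-finite at t={times[i + 1]:.4g}; "
                "reduce dt"
            )
        states[i + 1] = x
    return times, states


# ---------------------------------------------------------------------------
# Endogenous substitution and PDL arithmetic
# ---------------------------------------------------------------------------

def substitute_endogenous(ext: ExtendedParams, core: CoreParams = DEFAULT_CORE) -> CoreParams:
    """Install the endogenous parameters: c/d3 := γ, K1 := K̃1, K2 := K̃2.

    All other core fields (the dose-response fit) are untouched; `c` is set
    to γ·d3 so the ratio convention survives non-unit degradation rates.
    """
    return replace(core, c=ext.gamma * core.d3, K1=ext.K1t, K2=ext.K2t)


def pdl_modulation(pdl: float, ext: ExtendedParams = DEFAULT_EXTENDED) -> tuple[float, float]:
    """PDL-modulated steady THBS1 and FMOD levels.

    Returns (α·PDL/(PDL + Kα), β·Kβ/(PDL + Kβ)): THBS1 rises and FMOD falls
    with replicative age.
    """
    p = np.asarray(pdl, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0):
        raise ValueError("pdl must be finite and >= 0")
    th = ext.alpha * p / (p + ext.Kalpha)
    f = ext.beta * ext.Kbeta / (p + ext.Kbeta)
    if p.ndim:
        return th, f
    return float(th), float(f)


def compute_pdl(A: float, B: float, X: float) -> float:
    """Final population doubling level n = 3.32·(log10 A − log10 B) + X."""
    if A <= 0 or B <= 0:
        raise ValueError(f"cell counts must be > 0, got A={A}, B={B}")
    return PDL_LOG_FACTOR * (math.log10(A) - math.log10(B)) + X


# ---------------------------------------------------------------------------
# Parameter serialization
# ---------------------------------------------------------------------------

def dump_params(params: CoreParams | ExtendedParams, path) -> None:
    """Write a parameter set as a flat YAML (or .json) mapping."""
    data = params.to_dict()
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def load_params(path, kind: Literal["core", "extended"] = "core"):
    """Read a flat YAML/JSON parameter mapping into the requested type."""
    path = str(path)
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    cls = CoreParams if kind == "core" else ExtendedParams
    return cls.from_dict(data)


def packaged_defaults() -> dict:
    """The shipped default parameter file (core fit + endogenous set)."""
    text = resources.files("tgfswitch").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)
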