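"""Least-squares estimation of the steady-state switch models.

Two fitters mirror the two calibration stages of the analysis:

* :func:`fit_dose_response` — joint Hill fit of the steady THBS1 and FMOD
  curves against TGF-β1 dose–response replicates, estimating
  (a/d1, Ka, na) and (b/d2, Kb, nb).
* :func:`fit_endogenous` — joint fit of the PDL-modulated observables
  (α, Kα), (β, Kβ) and the endogenous TGF-β1 production law
  (γ, K̃1, K̃2) against PDL series.

Both pool the replicate-level residuals (each replicate contributes its own
residual, matching the N = 3 structure of the data) and run bounded
trust-region least squares.  Half-saturation constants and amplitudes are
optimized in log space for conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import CoreParams, ExtendedParams

__all__ = [
    "DoseResponseDataset",
    "PDLDataset",
    "FitResult",
    "fit_dose_response",
    "fit_endogenous",
    "residual_profile",
]

# bounds chosen once for monotone Hill curves on normalized expression data;
# the source analysis reports none
DEFAULT_BOUNDS = {
    "amplitude": (1e-6, 100.0),
    "half_saturation": (1e-6, 1e3),
    "hill": (0.5, 6.0),
}


def _check_design(x: np.ndarray, obs: np.ndarray, label: str,
                  strict: bool = True) -> None:
    if strict and np.any(np.diff(x) <= 0):
        raise ValueError(f"{label} values must be strictly increasing")
    if not strict and np.any(np.diff(x) < 0):
        raise ValueError(f"{label} values must be sorted")
    if obs.shape[0] != len(x):
        raise ValueError(f"{label} observation matrix rows must align with the design")
    if np.any(obs < 0):
        raise ValueError("observations must be non-negative")


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicated THBS1/FMOD levels over a TGF-β1 dose grid."""

    doses: np.ndarray
    thbs1_obs: np.ndarray  # (n_doses, n_replicates)
    fmod_obs: np.ndarray
    meta: str = "normalized expression"

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        object.__setattr__(self, "thbs1_obs", np.atleast_2d(np.asarray(self.thbs1_obs, dtype=float)))
        object.__setattr__(self, "fmod_obs", np.atleast_2d(np.asarray(self.fmod_obs, dtype=float)))
        _check_design(self.doses, self.thbs1_obs, "dose")
        _check_design(self.doses, self.fmod_obs, "dose")

    @property
    def n_replicates(self) -> int:
        return self.thbs1_obs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.doses):
            for r in range(self.n_replicates):
                rows.append((d, r, self.thbs1_obs[i, r], self.fmod_obs[i, r]))
        return pd.DataFrame(rows, columns=["dose", "replicate", "thbs1", "fmod"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        df = pd.read_csv(path)
        piv_t = df.pivot(index="dose", columns="replicate", values="thbs1").sort_index()
        piv_f = df.pivot(index="dose", columns="replicate", values="fmod").sort_index()
        return cls(doses=piv_t.index.to_numpy(), thbs1_obs=piv_t.to_numpy(),
                   fmod_obs=piv_f.to_numpy())


@dataclass(frozen=True)
class PDLDataset:
    """Replicated THBS1/FMOD/TGF-β1 levels over a PDL series."""

    pdls: np.ndarray
    thbs1_obs: np.ndarray
    fmod_obs: np.ndarray
    tgfb1_obs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pdls", np.asarray(self.pdls, dtype=float))
        for name in ("thbs1_obs", "fmod_obs", "tgfb1_obs"):
            object.__setattr__(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))
            # duplicate PDLs are legal (repeated passages); the fitter's
            # distinct-design guard handles degeneracy
            _check_design(self.pdls, getattr(self, name), "pdl", strict=False)

    @property
    def n_replicates(self) -> int:
        return self.thbs1_obs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.pdls):
            for r in range(self.n_replicates):
                rows.append((p, r, self.thbs1_obs[i, r], self.fmod_obs[i, r],
                             self.tgfb1_obs[i, r]))
        return pd.DataFrame(rows, columns=["pdl", "replicate", "thbs1", "fmod", "tgfb1"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "PDLDataset":
        df = pd.read_csv(path)
        piv = {
            c: df.pivot(index="pdl", columns="replicate", values=c).sort_index()
            for c in ("thbs1", "fmod", "tgfb1")
        }
        return cls(pdls=piv["thbs1"].index.to_numpy(),
                   thbs1_obs=piv["thbs1"].to_numpy(),
                   fmod_obs=piv["fmod"].to_numpy(),
                   tgfb1_obs=piv["tgfb1"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded least-squares fit."""

    estimates: dict[str, float]
    residual_ss: float
    n_obs: int
    converged: bool
    start: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    message: str = ""

    def __post_init__(self) -> None:
        if self.residual_ss < 0:
            raise ValueError("residual_ss must be >= 0")

    def to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(
                {
                    "estimates": self.estimates,
                    "residual_ss": self.residual_ss,
                    "n_obs": self.n_obs,
                    "converged": self.converged,
                    "start": self.start,
                    "bounds": {k: list(v) for k, v in self.bounds.items()},
                    "message": self.message,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


_DOSE_NAMES = ("a_over_d1", "Ka", "na", "b_over_d2", "Kb", "nb")
_PDL_NAMES = ("alpha", "Kalpha", "beta", "Kbeta", "gamma", "K1t", "K2t")

# which parameters are optimized on a log scale (positive scale parameters)
_LOG_SCALE = {"a_over_d1", "Ka", "b_over_d2", "Kb",
              "alpha", "Kalpha", "beta", "Kbeta", "gamma", "K1t", "K2t"}


def _hill_up(x, amp, K, n):
    xn = x**n
    return amp * xn / (xn + K)


def _hill_down(x, amp, K, n):
    xn = x**n
    return amp * K / (xn + K)


def _default_dose_start(data: DoseResponseDataset) -> dict[str, float]:
    pos = data.doses[data.doses > 0]
    med = float(np.median(pos)) if len(pos) else 1.0
    return {
        "a_over_d1": float(data.thbs1_obs.max()),
        "Ka": med,  # K acts on dose^n; with the n=1 start this is the median dose
        "na": 1.0,
        "b_over_d2": float(data.fmod_obs.max()),
        "Kb": med,
        "nb": 1.0,
    }


def _default_pdl_start(data: PDLDataset) -> dict[str, float]:
    med = float(np.median(data.pdls[data.pdls > 0])) if np.any(data.pdls > 0) else 1.0
    return {
        "alpha": float(data.thbs1_obs.max()),
        "Kalpha": med,
        "beta": float(data.fmod_obs.max()),
        "Kbeta": med,
        "gamma": float(data.tgfb1_obs.max()),
        "K1t": float(data.thbs1_obs.max()) / 2 or 1.0,
        "K2t": float(data.fmod_obs.max()) / 2 or 1.0,
    }


def _default_bounds(names) -> dict[str, tuple[float, float]]:
    out = {}
    for name in names:
        if name in ("na", "nb"):
            out[name] = DEFAULT_BOUNDS["hill"]
        elif name in ("a_over_d1", "b_over_d2", "alpha", "beta", "gamma"):
            out[name] = DEFAULT_BOUNDS["amplitude"]
        else:
            out[name] = DEFAULT_BOUNDS["half_saturation"]
    return out


def _run_fit(names, residual_fn, start, bounds, n_obs) -> FitResult:
    def encode(values: dict[str, float]) -> np.ndarray:
        return np.array(
            [np.log(values[n]) if n in _LOG_SCALE else values[n] for n in names]
        )

    def decode(vec: np.ndarray) -> dict[str, float]:
        return {
            n: float(np.exp(v)) if n in _LOG_SCALE else float(v)
            for n, v in zip(names, vec)
        }

    lo = encode({n: bounds[n][0] for n in names})
    hi = encode({n: bounds[n][1] for n in names})
    x0 = np.clip(encode(start), lo, hi)

    def fun(vec):
        return residual_fn(decode(vec))

    sol = least_squares(fun, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    estimates = decode(sol.x)
    return FitResult(
        estimates=estimates,
        residual_ss=float(np.sum(sol.fun**2)),
        n_obs=n_obs,
        converged=bool(sol.success),
        start=dict(start),
        bounds=dict(bounds),
        message=str(sol.message),
    )


def fit_dose_response(
    data: DoseResponseDataset,
    start: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Jointly fit the steady-state THBS1 and FMOD dose–response curves.

    Estimates {a_over_d1, Ka, na, b_over_d2, Kb, nb} by pooled least squares
    over all replicates of both observables.
    """
    if len(np.unique(data.doses)) < 4:
        raise ValueError(
            "need >= 4 distinct doses to identify six parameters across the two curves"
        )
    start = {**_default_dose_start(data), **(start or {})}
    bounds = {**_default_bounds(_DOSE_NAMES), **(bounds or {})}

    d = data.doses[:, None]

    def residuals(p: dict[str, float]) -> np.ndarray:
        th = _hill_up(d, p["a_over_d1"], p["Ka"], p["na"])
        fm = _hill_down(d, p["b_over_d2"], p["Kb"], p["nb"])
        return np.concatenate(
            [(th - data.thbs1_obs).ravel(), (fm - data.fmod_obs).ravel()]
        )

    n_obs = data.thbs1_obs.size + data.fmod_obs.size
    return _run_fit(_DOSE_NAMES, residuals, start, bounds, n_obs)


def fit_endogenous(
    data: PDLDataset,
    start: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit the endogenous/PDL model to a PDL series.

    THBS1 and FMOD observables follow the PDL-modulation laws; the TGF-β1
    observable follows the endogenous production law with those laws
    substituted.  Estimates {alpha, Kalpha, beta, Kbeta, gamma, K1t, K2t}.
    """
    if len(np.unique(data.pdls)) < 3:
        raise ValueError(
            "need >= 3 distinct PDL values with all three observables "
            "(under-determined design)"
        )
    start = {**_default_pdl_start(data), **(start or {})}
    bounds = {**_default_bounds(_PDL_NAMES), **(bounds or {})}

    pdl = data.pdls[:, None]

    def residuals(p: dict[str, float]) -> np.ndarray:
        th = p["alpha"] * pdl / (pdl + p["Kalpha"])
        fm = p["beta"] * p["Kbeta"] / (pdl + p["Kbeta"])
        tg = p["gamma"] * (th / (th + p["K1t"])) * (p["K2t"] / (fm + p["K2t"]))
        return np.concatenate(
            [
                (th - data.thbs1_obs).ravel(),
                (fm - data.fmod_obs).ravel(),
                (tg - data.tgfb1_obs).ravel(),
            ]
        )

    n_obs = data.thbs1_obs.size + data.fmod_obs.size + data.tgfb1_obs.size
    return _run_fit(_PDL_NAMES, residuals, start, bounds, n_obs)


def residual_profile(
    result: FitResult,
    data,
    parameter: str,
    grid,
) -> pd.DataFrame:
    """Profile the residual sum of squares along one parameter.

    At each grid value the named parameter is pinned (tight bounds) and all
    others are refit from the original estimates.  Returns a DataFrame with
    columns (value, residual_ss); the profile minimum coincides with the
    joint estimate on well-identified problems.
    """
    if parameter not in result.estimates:
        raise ValueError(f"unknown parameter {parameter!r}")
    grid = np.asarray(grid, dtype=float)
    est = result.estimates[parameter]
    if not (grid.min() <= est <= grid.max()):
        import warnings

        warnings.warn(
            f"profile grid [{grid.min()}, {grid.max()}] excludes the estimate "
            f"{parameter}={est:.6g}",
            stacklevel=2,
        )
    fitter = fit_dose_response if isinstance(data, DoseResponseDataset) else fit_endogenous
    rows = []
    for v in grid:
        pinned = dict(result.bounds)
        pinned[parameter] = (v * (1 - 1e-12) if v > 0 else v - 1e-12,
                             v * (1 + 1e-12) if v > 0 else v + 1e-12)
        start = dict(result.estimates)
        start[parameter] = float(v)
        sub = fitter(data, start=start, bounds=pinned)
        rows.append((float(v), sub.residual_ss))
    return pd.DataFrame(rows, columns=["value", "residual_ss"])
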