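"""Parameter scans, saddle-node (fold) detection, and bistability mapping.

The reduced steady-state problem is the scalar fixed-point equation
T = γ·g(T), where g collects the γ-independent Hill factors.  A fold occurs
where the line T touches the curve γ·g(T) tangentially, i.e. at
γ* = min_{T>0} T/g(T): below γ* only the zero state exists, above it a
stable/unstable pair of nonzero states has appeared.  For scans over K1, K2
or γ the fold is located generically by bisection on the fixed-point count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import CoreParams, FixedPointSet, find_fixed_points, reduced_map

__all__ = [
    "BifurcationDiagram",
    "BistabilityMap",
    "scan_parameter",
    "saddle_node_gamma",
    "bistability_map",
]

_SCANNABLE = ("K1", "K2", "gamma")

#: TGF-β1 production rate (c/d3) used for the K1/K2 scan demonstrations.
#: The dose-response fit does not pin c/d3; this value is chosen so that,
#: with K2 = 0.62, the K1 fold sits between 14 and 16 for every K2 —
#: K1 = 14 is then "near the bifurcation point" (bistable, both basins
#: populated) while at K1 = 16 no K2 value produces a bifurcation.
K1_SCAN_C_OVER_D3 = 1.04


def k1_scan_params(K1: float, K2: float = 0.62) -> CoreParams:
    """Core parameters for the K1-scan demonstrations (see K1_SCAN_C_OVER_D3)."""
    return replace(CoreParams(), c=K1_SCAN_C_OVER_D3, K1=float(K1), K2=float(K2))


def _with_param(params: CoreParams, name: str, value: float) -> CoreParams:
    if name == "gamma":
        return replace(params, c=value * params.d3)
    if name in ("K1", "K2"):
        return replace(params, **{name: value})
    raise ValueError(f"unknown scan parameter {name!r}; valid names: {_SCANNABLE}")


@dataclass(frozen=True)
class BifurcationDiagram:
    """Fixed-point branches along a one-parameter scan."""

    param_name: str
    param_values: np.ndarray
    branches: tuple[FixedPointSet, ...]
    fold_points: tuple[float, ...]

    def stable_counts(self) -> np.ndarray:
        return np.array([b.n_stable for b in self.branches])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (param_value, tgfb1, thbs1, fmod, stability)."""
        rows = []
        for v, fps in zip(self.param_values, self.branches):
            for p in fps.points:
                rows.append(
                    (float(v), p.state.tgfb1, p.state.thbs1, p.state.fmod, p.stability)
                )
        return pd.DataFrame(
            rows, columns=["param_value", "tgfb1", "thbs1", "fmod", "stability"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    def folds_to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(
                {"param_name": self.param_name, "fold_points": list(self.fold_points)},
                fh,
                indent=2,
            )
            fh.write("\n")


@dataclass(frozen=True)
class BistabilityMap:
    """Stable-state counts over a (K1, K2) grid (zero state included)."""

    k1_grid: np.ndarray
    k2_grid: np.ndarray
    state_count: np.ndarray  # shape (len(k1_grid), len(k2_grid))
    params: CoreParams

    @property
    def bistable_mask(self) -> np.ndarray:
        return self.state_count >= 2

    def asymmetry_summary(self) -> dict:
        """Extent of the bistable region along each axis through its centroid."""
        mask = self.bistable_mask
        if not mask.any():
            return {"bistable_fraction": 0.0, "k1_extent": 0.0, "k2_extent": 0.0}
        i_c, j_c = (int(round(x)) for x in np.argwhere(mask).mean(axis=0))
        k1_row = mask[:, j_c]
        k2_row = mask[i_c, :]
        k1_ext = float(self.k1_grid[k1_row].max() - self.k1_grid[k1_row].min()) if k1_row.any() else 0.0
        k2_ext = float(self.k2_grid[k2_row].max() - self.k2_grid[k2_row].min()) if k2_row.any() else 0.0
        return {
            "bistable_fraction": float(mask.mean()),
            "k1_extent": k1_ext,
            "k2_extent": k2_ext,
        }

    def to_frame(self) -> pd.DataFrame:
        k1, k2 = np.meshgrid(self.k1_grid, self.k2_grid, indexing="ij")
        return pd.DataFrame(
            {
                "k1": k1.ravel(),
                "k2": k2.ravel(),
                "stable_count": self.state_count.ravel().astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def scan_parameter(
    params: CoreParams,
    param_name: str,
    lo: float,
    hi: float,
    n_points: int = 512,
    log_spaced: bool = True,
    fold_tol: float = 1e-8,
    **fp_kwargs,
) -> BifurcationDiagram:
    """Scan one parameter, assembling fixed-point branches and fold locations.

    Folds (changes of the fixed-point count by 2) are refined by bisection
    between adjacent grid values where the count changes.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if param_name not in _SCANNABLE:
        raise ValueError(f"unknown scan parameter {param_name!r}; valid names: {_SCANNABLE}")
    values = (
        np.geomspace(lo, hi, n_points) if log_spaced and lo > 0 else np.linspace(lo, hi, n_points)
    )
    branches = tuple(
        find_fixed_points(_with_param(params, param_name, float(v)), **fp_kwargs)
        for v in values
    )
    counts = np.array([len(b.points) for b in branches])

    def count_at(v: float) -> int:
        return len(find_fixed_points(_with_param(params, param_name, v), **fp_kwargs).points)

    folds: list[float] = []
    for i in np.nonzero(np.diff(counts) != 0)[0]:
        a, b = float(values[i]), float(values[i + 1])
        ca = counts[i]
        while b - a > fold_tol * max(1.0, abs(b)):
            m = 0.5 * (a + b)
            if count_at(m) == ca:
                a = m
            else:
                b = m
        folds.append(0.5 * (a + b))

    return BifurcationDiagram(
        param_name=param_name,
        param_values=values,
        branches=branches,
        fold_points=tuple(folds),
    )


def saddle_node_gamma(
    params: CoreParams,
    t_range: tuple[float, float] = (1e-6, 1e3),
    rel_tol: float = 1e-9,
) -> float:
    """Fold value γ* of the endogenous production rate.

    Writing the fixed-point equation as T = γ·g(T) with
    g(T) = f(T)/(c/d3), the nonzero branch exists iff γ ≥ T/g(T) for some
    T > 0, so the fold is γ* = min_{T>0} T/g(T).  Minimized in log T by
    bounded golden-section search after a coarse grid bracketing.
    """
    def ratio_log(logt: float) -> float:
        t = float(np.exp(logt))
        g = reduced_map(t, params) / params.c_over_d3
        return np.inf if g <= 0 else t / g

    lo, hi = np.log(t_range[0]), np.log(t_range[1])
    grid = np.linspace(lo, hi, 2048)
    vals = np.array([ratio_log(x) for x in grid])
    i = int(np.argmin(vals))
    if i == 0 or i == len(grid) - 1:
        raise ValueError(
            "T/g(T) minimum hit the search boundary; widen t_range"
        )
    res = minimize_scalar(
        ratio_log,
        bracket=(grid[i - 1], grid[i], grid[i + 1]),
        method="golden",
        options={"xtol": rel_tol},
    )
    return float(res.fun)


def bistability_map(
    params: CoreParams,
    k1_range: tuple[float, float],
    k2_range: tuple[float, float],
    n_k1: int = 101,
    n_k2: int = 101,
    refine_check: bool = False,
    **fp_kwargs,
) -> BistabilityMap:
    """Stable-state count over a (K1, K2) grid; count ≥ 2 marks bistability."""
    if min(k1_range) <= 0 or min(k2_range) <= 0:
        raise ValueError("K1/K2 ranges must be positive")
    k1s = np.linspace(*k1_range, n_k1)
    k2s = np.linspace(*k2_range, n_k2)
    count = np.empty((n_k1, n_k2), dtype=int)
    for i, k1 in enumerate(k1s):
        for j, k2 in enumerate(k2s):
            p = replace(params, K1=float(k1), K2=float(k2))
            count[i, j] = find_fixed_points(p, **fp_kwargs).n_stable
    if refine_check and (count >= 2).any():
        # warn if the grid is too coarse to bracket a fold it implies exists
        along_k1 = np.any(np.diff(count, axis=0) != 0)
        along_k2 = np.any(np.diff(count, axis=1) != 0)
        if not (along_k1 or along_k2):
            warnings.warn(
                "bistability detected but no count change within the grid; "
                "the grid may be too coarse to bracket the fold",
                stacklevel=2,
            )
    return BistabilityMap(k1_grid=k1s, k2_grid=k2s, state_count=count, params=params)
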