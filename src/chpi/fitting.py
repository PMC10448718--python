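"""Two-stage grid-search fitting of the CH-pi parameters.

The parameters (well depth E, optimal separation R0, breadth c) are derived
by fitting the *combined* score (base + CH-pi at unit weighting) to reference
dimer interaction-energy curves.  Stage 1 evaluates every combination on a
coarse grid (0.05 intervals; for the hydrogen-dependent form E = 0.10-0.50,
R0 = 1.50-4.55, c = 0.05-2.00, i.e. 9 x 62 x 40 = 22,320 combinations);
stage 2 refines each parameter by +/-0.05 at 0.01 intervals around the
stage-1 winner, run once.  The objective is the mean over curves of the
per-curve rmsd between model and reference within the curve's fit range,
which starts at the first grid point where the reference energy is negative
and ends at 6.0 A (grid points inside the range, bounds inclusive).  Ties
break to the lexicographically smallest (E, R0, c).

No quantum-mechanical reference tables are shipped: reference curves are
either user-supplied or generated synthetically from known parameters (the
default test path, which doubles as a parameter-recovery check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dimers import DimerSpec, EnergyCurve, build_dimer
from .scoring import (
    PAIR_SCALE,
    ChPiParamsC,
    ChPiParamsH,
    cross_pair_table,
    vina_base_energy,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "NoFitRangeError",
    "fit_range_from_curve",
    "grid_fit",
    "fit_h_independent",
    "default_param_grid",
]

H_INDEP_GEOMETRIES = ("A", "D", "E")


class NoFitRangeError(ValueError):
    """The reference curve never becomes attractive, so no fit range exists."""


def default_param_grid() -> dict[str, tuple[float, float, float]]:
    """Coarse-stage ranges (min, max, step) for (E, R0, c)."""
    return {"E": (0.10, 0.50, 0.05), "R0": (1.50, 4.55, 0.05), "C": (0.05, 2.00, 0.05)}


@dataclass
class FitSpec:
    """Grid-search specification for one model family."""

    curves: list[EnergyCurve]
    param_grid: dict[str, tuple[float, float, float]] = field(default_factory=default_param_grid)
    fit_ranges: list[tuple[float, float]] | None = None
    refine_halfwidth: float = 0.05
    refine_step: float = 0.01

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("empty curve set")
        for lo, hi, step in self.param_grid.values():
            if step <= 0 or hi < lo:
                raise ValueError("parameter grid steps must be positive, max >= min")
        if self.fit_ranges is not None:
            for start, end in self.fit_ranges:
                if not start < end <= 6.0:
                    raise ValueError("fit range must satisfy start < end <= 6.0")


@dataclass
class FitResult:
    params: object          # ChPiParamsH or ChPiParamsC
    avg_rmsd: float
    grid_points_evaluated: int


def fit_range_from_curve(reference: EnergyCurve) -> tuple[float, float]:
    """(start, end): start at the first grid point with negative energy, end
    at 6.0 A.  No interpolation between grid points."""
    neg = np.nonzero(reference.energies < 0)[0]
    if len(neg) == 0:
        raise NoFitRangeError("reference curve has no negative energies")
    return float(reference.abscissa[neg[0]]), 6.0


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def _curve_tables(curve: EnergyCurve, mode: str):
    """Per-point base energies and (f, R) pair tables for the model."""
    meta = curve.meta
    vina = []
    tables = []
    for x in curve.abscissa:
        spec = DimerSpec(
            meta.get("geometry", "A"),
            r_v=float(x),
            r_h=float(meta.get("r_h", 0.0)),
            offset_direction=meta.get("offset_direction", "toward-bond-midpoint"),
        )
        benzene, methane = build_dimer(spec)
        vina.append(vina_base_energy(benzene, methane))
        tables.append(cross_pair_table(benzene, methane, mode))
    return np.array(vina), tables


def _objective(curves, mode, e_grid, r0_grid, c_grid, fit_ranges, caches) -> np.ndarray:
    """Mean-over-curves rmsd for every (E, R0, c) grid combination."""
    obj = np.zeros((len(e_grid), len(r0_grid), len(c_grid)))
    for curve, (start, end), (vina, tables) in zip(curves, fit_ranges, caches):
        sel = (curve.abscissa >= start - 1e-9) & (curve.abscissa <= end + 1e-9)
        idx = np.nonzero(sel)[0]
        # S[point, r0, c] = sum_pairs f * exp(-(R - R0)^2 / c)
        s = np.zeros((len(idx), len(r0_grid), len(c_grid)))
        for k, i in enumerate(idx):
            f, d = tables[i]
            if len(d) == 0:
                continue
            z = (d[:, None] - r0_grid[None, :]) ** 2          # (pairs, r0)
            s[k] = np.einsum(
                "p,prc->rc", f, np.exp(-z[:, :, None] / c_grid[None, None, :])
            )
        ref = curve.energies[idx]
        base = vina[idx]
        # model = base - E * 1/2 * S
        resid = (base[None, :, None, None]
                 - PAIR_SCALE * e_grid[:, None, None, None] * s[None, :, :, :]
                 - ref[None, :, None, None])
        obj += np.sqrt(np.mean(resid ** 2, axis=1))
    return obj / len(curves)


def grid_fit(spec: FitSpec, model: str = "hdep") -> FitResult:
    """Exhaustive coarse grid search followed by one +/-0.05 / 0.01 local
    refinement; returns the winning parameters and their objective value."""
    if model not in ("hdep", "hindep"):
        raise ValueError(f"unknown model {model!r}")
    fit_ranges = spec.fit_ranges or [fit_range_from_curve(c) for c in spec.curves]
    caches = [_curve_tables(c, model) for c in spec.curves]
    e_grid = _grid(*spec.param_grid["E"])
    r0_grid = _grid(*spec.param_grid["R0"])
    c_grid = _grid(*spec.param_grid["C"])

    obj = _objective(spec.curves, model, e_grid, r0_grid, c_grid, fit_ranges, caches)
    i, j, k = np.unravel_index(int(np.argmin(obj)), obj.shape)
    n_eval = obj.size

    # stage 2: +/- refine_halfwidth at refine_step, clipped to the search box
    def refined(center: float, box: tuple[float, float, float]) -> np.ndarray:
        lo = max(box[0], center - spec.refine_halfwidth)
        hi = min(box[1], center + spec.refine_halfwidth)
        return _grid(lo, hi, spec.refine_step)

    e2 = refined(e_grid[i], spec.param_grid["E"])
    r02 = refined(r0_grid[j], spec.param_grid["R0"])
    c2 = refined(c_grid[k], spec.param_grid["C"])
    obj2 = _objective(spec.curves, model, e2, r02, c2, fit_ranges, caches)
    i2, j2, k2 = np.unravel_index(int(np.argmin(obj2)), obj2.shape)
    n_eval += obj2.size

    cls = ChPiParamsH if model == "hdep" else ChPiParamsC
    params = cls(e=float(e2[i2]), r0=float(r02[j2]), c=float(c2[k2]))
    return FitResult(params=params, avg_rmsd=float(obj2[i2, j2, k2]),
                     grid_points_evaluated=n_eval)


def fit_h_independent(spec: FitSpec) -> FitResult:
    """Fit the hydrogen-independent form; requires exactly the A, D and E
    reference curves (the family whose ring-facing C-H has f(theta2) = 1)."""
    labels = [c.meta.get("geometry", "?") for c in spec.curves]
    extras = [l for l in labels if l not in H_INDEP_GEOMETRIES]
    if extras or sorted(labels) != sorted(H_INDEP_GEOMETRIES):
        raise ValueError(
            f"hydrogen-independent fit needs exactly curves {H_INDEP_GEOMETRIES}; "
            f"got {labels} (unexpected: {extras or 'missing labels'})"
        )
    return grid_fit(spec, model="hindep")
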