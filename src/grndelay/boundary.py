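"""Hopf stability boundaries in two-parameter planes.

For each point of a rectangular grid over two kinetic parameters the
equilibrium is re-solved and the critical delay recomputed, giving a matrix
of ``tau_0`` values whose level sets are the stability boundaries.  Points
that are stable for every delay carry the sentinel ``inf``; points of the
complete model that are already unstable at zero delay carry ``0``; failed
solves carry ``nan``.  Each grid point is computed independently (no
continuation), so entries do not depend on traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .models import GRNParams
from .stability_dcnm import UNSTABLE_AT_ZERO, dcnm_critical_delays
from .stability_dsnm import HOPF, dsnm_critical_delays
from .steadystate import solve_steady_states

__all__ = ["BoundaryGrid", "critical_tau_grid", "min_tau_over_axis",
           "STABLE_SENTINEL"]

#: Grid sentinel for "stable for every delay".
STABLE_SENTINEL = np.inf


@dataclass
class BoundaryGrid:
    """Critical-delay surface over a 2-parameter grid.

    ``tau_critical[i, j]`` is the critical delay at ``axis1_values[i]``,
    ``axis2_values[j]`` (inf = stable for all delays, 0 = unstable at zero
    delay, nan = equilibrium solve failed).
    """

    model: str
    base_params: GRNParams
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    tau_critical: np.ndarray


def _critical_tau_point(model: str, params: GRNParams) -> float:
    sslist = solve_steady_states(params)
    positive = [s for s in sslist if s.p_a_bar > 0.0]
    if not positive:
        return np.nan
    # with several equilibria the most delay-fragile one bounds stability
    taus = []
    for ss in positive:
        if model == "dsnm":
            rep = dsnm_critical_delays(params, ss)
            taus.append(rep.tau0 if rep.classification == HOPF else np.inf)
        else:
            rep = dcnm_critical_delays(params, ss)
            if rep.classification == UNSTABLE_AT_ZERO:
                taus.append(0.0)
            elif rep.classification == HOPF:
                taus.append(rep.tau0)
            else:
                taus.append(np.inf)
    return float(min(taus))


def critical_tau_grid(
    model: str,
    base: GRNParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
) -> BoundaryGrid:
    """Critical delay at every point of the (axis1 x axis2) parameter grid."""
    valid = {f.name for f in fields(GRNParams)}
    (name1, vals1), (name2, vals2) = axis1, axis2
    for name in (name1, name2):
        if name not in valid:
            raise ValueError(f"{name!r} is not a parameter field")
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if np.any(vals1 <= 0) or np.any(vals2 <= 0):
        raise ValueError("axis values must be positive")
    grid = np.empty((len(vals1), len(vals2)))
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            params = base.replace(**{name1: float(v1), name2: float(v2)})
            try:
                grid[i, j] = _critical_tau_point(model, params)
            except (ArithmeticError, RuntimeError):
                grid[i, j] = np.nan
    return BoundaryGrid(
        model=model,
        base_params=base,
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        tau_critical=grid,
    )


def min_tau_over_axis(grid: BoundaryGrid, axis: int) -> np.ndarray:
    """Per-row (axis=1) or per-column (axis=2) minimum finite critical
    delay; entries where no finite value exists are the stable sentinel.

    ``axis=1`` minimises over axis1 (returns one value per axis2 entry) and
    vice versa — i.e. the answer to "over all values of that parameter, how
    small can the critical delay get?".
    """
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    reduce_dim = 0 if axis == 1 else 1
    vals = grid.tau_critical
    # non-finite entries (sentinel or failed solves) never win the minimum
    masked = np.where(np.isfinite(vals), vals, STABLE_SENTINEL)
    return masked.min(axis=reduce_dim)
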