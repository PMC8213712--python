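"""CLUE-S-style iterative spatial allocation of class-area demands.

Given per-class suitability surfaces, a current map, conversion
elasticities and an allowed-conversion matrix, each simulated year is
solved by iterating:

1. score every cell for every class its current class may convert to:
   ``TPROP = P(cell, class) + ELAS_class · [class == current] + offset_class``;
2. assign each cell the argmax class;
3. compare allocated areas with the year's demand and nudge each class
   offset by a damped relative deficit, until every class matches its
   demand within tolerance.

The elasticity term is an incumbency bonus — a class with high ELAS is
expensive to displace from cells it already occupies. Offsets are the
scalar balancing variables that inflate under-allocated classes and
deflate over-allocated ones. A deterministic exact-finish phase then
swaps the cheapest cells between over- and under-allocated classes to
close any residual integer-cell deficit; the allocator as a whole uses
no random numbers, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .demand import DemandTable
from .rasterkit import CLASS_CODES, N_CLASSES, Grid, LULCMap

__all__ = [
    "ScenarioConfig",
    "AllocationResult",
    "total_probability",
    "allocate",
    "run_scenario",
]

_NEG = -1e18  # score mask for disallowed conversions


@dataclass
class ScenarioConfig:
    """Everything one named scenario needs to drive the allocator.

    ``elas`` maps class code → conversion elasticity in [0, 1];
    ``allowed`` is the 6×6 boolean conversion matrix (rows = source,
    diagonal forced true); ``tolerance_ha`` defaults per class to
    max(one cell's area, 0.1% of that class's demand).
    """

    name: str
    elas: Mapping[int, float] | Sequence[float]
    demand: DemandTable
    allowed: np.ndarray | None = None
    max_iterations: int = 2000
    tolerance_ha: float | None = None
    damping: float = 0.5
    exact_finish: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.elas, Mapping):
            e = np.array([float(self.elas[c]) for c in CLASS_CODES])
        else:
            e = np.asarray(self.elas, dtype=float)
        if e.shape != (N_CLASSES,):
            raise ValueError("elas needs one value per class")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("elasticities must lie in [0, 1]")
        self.elas = e
        if self.allowed is None:
            self.allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
        else:
            a = np.asarray(self.allowed, dtype=bool)
            if a.shape != (N_CLASSES, N_CLASSES):
                raise ValueError("allowed matrix must be 6×6")
            if not a.diagonal().all():
                raise ValueError("the diagonal of the allowed matrix must be true")
            self.allowed = a
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")


@dataclass
class AllocationResult:
    """One year's allocation outcome plus convergence diagnostics."""

    map: LULCMap
    iterations_used: int
    final_offsets: dict[int, float]
    deviation_ha: dict[int, float]
    converged: bool
    history: list[dict[int, float]] = field(default_factory=list)


def total_probability(
    suitability: float,
    elas: float,
    is_current: bool,
    offset: float = 0.0,
) -> float:
    """TPROP for one (cell, class) pair: suitability + incumbency + offset."""
    return float(suitability) + (float(elas) if is_current else 0.0) + float(offset)


def _suitability_matrix(
    suitability: Mapping[int, Grid], geom: Grid, mask: np.ndarray
) -> np.ndarray:
    S = np.empty((N_CLASSES, int(mask.sum())))
    for ci, c in enumerate(CLASS_CODES):
        g = suitability[c]
        if not g.same_geometry(geom):
            raise ValueError(f"suitability layer for class {c} has mismatched geometry")
        S[ci] = np.asarray(g.values, dtype=float)[mask]
    return S


def _largest_remainder_counts(demand: np.ndarray, total_cells: int) -> np.ndarray:
    share = demand / demand.sum()
    raw = share * total_cells
    base = np.floor(raw).astype(int)
    left = total_cells - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:left]] += 1
    return base


def allocate(
    current: LULCMap,
    suitability: Mapping[int, Grid],
    config: ScenarioConfig,
    demand_year: int,
) -> AllocationResult:
    """Allocate one year's class-area demand onto the map.

    Demand (ha) is converted to integer cell targets by largest-remainder
    rounding. Cells whose current class allows no conversion are frozen
    and removed from the balancing arithmetic. Non-convergence within
    ``max_iterations`` is flagged on the result, not raised; the best map
    seen (smallest worst relative deviation) is returned.
    """
    geom = current.grid
    mask = geom.valid_mask
    n = int(mask.sum())
    cell_ha = geom.cell_area_ha
    demand = np.array(
        [config.demand.for_year(demand_year)[c] for c in CLASS_CODES], dtype=float
    )
    total_ha = n * cell_ha
    tol = (
        config.tolerance_ha
        if config.tolerance_ha is not None
        else np.maximum(cell_ha, 0.001 * demand)
    )
    tol = np.broadcast_to(np.asarray(tol, dtype=float), (N_CLASSES,))
    if abs(demand.sum() - total_ha) > max(float(np.max(tol)), cell_ha):
        raise ValueError(
            f"demand total {demand.sum():.2f} ha does not match map area {total_ha:.2f} ha"
        )

    cur = np.asarray(current.values)[mask].astype(int) - 1  # 0-based class index
    S = _suitability_matrix(suitability, geom, mask)
    elas = np.asarray(config.elas, dtype=float)

    # incumbency bonus and conversion mask depend only on the year-start map
    base = S + elas[cur] * (np.arange(N_CLASSES)[:, None] == cur[None, :])
    base = np.where(config.allowed.T[:, cur], base, _NEG)

    # a class is frozen where no conversion away is possible: either its
    # allowed row is self-only, or its elasticity is 1 (fully stable class
    # in the CLUE-S sense — never displaced from occupied cells)
    frozen_classes = np.flatnonzero(config.allowed.sum(axis=1) == 1)
    frozen = np.isin(cur, frozen_classes) | (elas[cur] >= 1.0 - 1e-12)
    free = ~frozen
    n_free = int(free.sum())
    frozen_counts = np.bincount(cur[frozen], minlength=N_CLASSES)

    targets = _largest_remainder_counts(demand, n)
    free_targets = targets - frozen_counts
    if np.any(free_targets < 0):
        raise ValueError(
            "demand for a fully frozen class is below its frozen area; infeasible"
        )

    offsets = np.zeros(N_CLASSES)
    dead = demand <= 0
    offsets[dead] = _NEG / 2  # a class with zero demand must win nowhere
    damping = config.damping
    prev_sign = None
    best = None
    history: list[dict[int, float]] = []
    assigned = cur.copy()
    it = 0
    for it in range(1, config.max_iterations + 1):
        scores = base[:, free] + offsets[:, None]
        assigned_free = np.argmax(scores, axis=0)
        assigned = cur.copy()
        assigned[free] = assigned_free
        counts = np.bincount(assigned, minlength=N_CLASSES)
        alloc_ha = counts * cell_ha
        dev = demand - alloc_ha
        history.append({c: float(dev[i]) for i, c in enumerate(CLASS_CODES)})
        worst = float(np.max(np.abs(dev) / np.maximum(demand, cell_ha)))
        if best is None or worst < best[0]:
            best = (worst, assigned.copy(), offsets.copy(), dict(history[-1]))
        if np.all(np.abs(dev) <= tol):
            break
        sign = np.sign(dev)
        if prev_sign is not None:
            live = (sign != 0) & (prev_sign != 0)
            if live.any() and np.all(sign[live] == -prev_sign[live]):
                damping = max(damping * 0.5, 1e-3)
        prev_sign = sign
        upd = np.where(~dead, damping * dev / np.maximum(demand, cell_ha), 0.0)
        offsets = offsets + upd
    else:
        # keep the best assignment seen rather than the last oscillation
        _, assigned, offsets, _ = best

    if config.exact_finish:
        assigned = _exact_finish(assigned, base, free, free_targets, frozen_counts)

    counts = np.bincount(assigned, minlength=N_CLASSES)
    alloc_ha = counts * cell_ha
    dev = demand - alloc_ha
    converged = bool(np.all(np.abs(dev) <= tol))

    out_vals = np.asarray(current.values).copy()
    out_vals[mask] = assigned + 1
    result_map = LULCMap(geom.copy(values=out_vals))
    return AllocationResult(
        map=result_map,
        iterations_used=it,
        final_offsets={c: float(offsets[i]) for i, c in enumerate(CLASS_CODES)},
        deviation_ha={c: float(dev[i]) for i, c in enumerate(CLASS_CODES)},
        converged=converged,
        history=history,
    )


def _exact_finish(
    assigned: np.ndarray,
    base: np.ndarray,
    free: np.ndarray,
    free_targets: np.ndarray,
    frozen_counts: np.ndarray,
) -> np.ndarray:
    """Swap cheapest cells until class counts hit the integer targets.

    Deterministic greedy: repeatedly move the single cell whose switch
    from an over-allocated to an under-allocated class costs the least
    score, honouring the allowed-conversion mask baked into ``base``.
    """
    assigned = assigned.copy()
    free_idx = np.flatnonzero(free)
    if free_idx.size == 0:
        return assigned
    sub = assigned[free_idx]
    counts = np.bincount(sub, minlength=N_CLASSES)
    guard = 0
    max_moves = 2 * int(np.abs(counts - free_targets).sum()) + free_idx.size
    while guard < max_moves:
        over = np.flatnonzero(counts > free_targets)
        under = np.flatnonzero(counts < free_targets)
        if over.size == 0 or under.size == 0:
            break
        best_gain, best_cell, best_dst = -np.inf, -1, -1
        Bf = base[:, free_idx]
        for o in over:
            cells = np.flatnonzero(sub == o)
            if cells.size == 0:
                continue
            cand = Bf[np.ix_(under, cells)]  # (n_under, n_cells)
            gain = cand - Bf[o, cells][None, :]
            ui, cj = np.unravel_index(np.argmax(gain), gain.shape)
            if gain[ui, cj] > best_gain and cand[ui, cj] > _NEG / 2:
                best_gain = float(gain[ui, cj])
                best_cell = int(cells[cj])
                best_dst = int(under[ui])
        if best_cell < 0:
            break  # no legal move remains
        src = sub[best_cell]
        sub[best_cell] = best_dst
        counts[src] -= 1
        counts[best_dst] += 1
        guard += 1
    assigned[free_idx] = sub
    return assigned


def run_scenario(
    lulc_start: LULCMap,
    suitability: Mapping[int, Grid],
    config: ScenarioConfig,
    years: Sequence[int] | None = None,
) -> tuple[dict[int, LULCMap], list[AllocationResult]]:
    """Allocate year by year; each year's map seeds the next.

    ``years`` defaults to every demand-table year after the first (the
    first row is the start state). Returns the yearly maps and the
    per-year allocation diagnostics; an empty horizon returns the start
    map unchanged.
    """
    table_years = config.demand.years
    if years is None:
        years = table_years[1:]
    missing = [y for y in years if y not in table_years]
    if missing:
        raise ValueError(f"demand table lacks years {missing}")
    maps: dict[int, LULCMap] = {}
    results: list[AllocationResult] = []
    cur = lulc_start
    for y in years:
        cfg = config
        res = allocate(cur, suitability, cfg, y)
        maps[y] = res.map
        results.append(res)
        cur = res.map
    if not years:
        maps[table_years[0] if table_years else 0] = lulc_start
    return maps, results
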