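"""Class-area demand: Markov transition estimation and projection.

The area a land class must occupy in a future year is projected by a
first-order Markov chain: the transition matrix is estimated from a pair
of observed maps by cross-tabulation, reduced to an annual matrix by a
matrix root, optionally bent by scenario rules (multiplicative retention
factors on ruled conversions, with the removed mass returned to the
diagonal so rows stay stochastic), and iterated forward from the initial
class-area vector. The single land-use dynamic degree summarises a
class's annualised rate of change in percent per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rasterkit import CLASS_CODES, CLASS_NAMES, N_CLASSES, LULCMap, cross_tabulate

__all__ = [
    "TransitionMatrix",
    "DemandTable",
    "ChangeReport",
    "estimate_transition",
    "matrix_root",
    "annualize",
    "project_demand",
    "adjust_for_scenario",
    "dynamic_degree",
]

#: Class areas in one year must close on the table total within this (ha).
AREA_CLOSURE_HA = 0.5


@dataclass
class TransitionMatrix:
    """Row-stochastic 6×6 class-transition matrix spanning ``period`` years."""

    matrix: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"transition matrix must be 6×6, got {m.shape}")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition entries must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not self.period > 0:
            raise ValueError("period must be positive")
        self.matrix = np.clip(m, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES[c] for c in CLASS_CODES]
        return pd.DataFrame(self.matrix, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class DemandTable:
    """Per-year class areas (ha); every year closes on ``total_area``.

    ``areas`` is a DataFrame indexed by year with the six class codes as
    columns.
    """

    areas: pd.DataFrame
    total_area: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.areas.copy()
        df.columns = [int(c) for c in df.columns]
        if list(df.columns) != list(CLASS_CODES):
            raise ValueError(f"demand columns must be the class codes, got {list(df.columns)}")
        if (df.values < -1e-9).any():
            raise ValueError("demand areas must be nonnegative")
        df.index = pd.Index([int(y) for y in df.index])
        self.areas = df
        if self.total_area is None:
            self.total_area = float(df.iloc[0].sum())
        sums = df.sum(axis=1)
        off = (sums - self.total_area).abs()
        if (off > AREA_CLOSURE_HA).any():
            year = int(off.idxmax())
            raise ValueError(
                f"demand for year {year} sums to {sums.loc[year]:.2f} ha, "
                f"not the table total {self.total_area:.2f} ± {AREA_CLOSURE_HA}"
            )

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.areas.index]

    def for_year(self, year: int) -> dict[int, float]:
        return {int(c): float(v) for c, v in self.areas.loc[int(year)].items()}

    def to_csv(self, path: str | Path) -> None:
        long = self.areas.reset_index(names="year").melt(
            id_vars="year", var_name="class_code", value_name="area_ha"
        )
        long["class_name"] = long["class_code"].map(CLASS_NAMES)
        long = long.sort_values(["year", "class_code"])
        long.to_csv(path, index=False, columns=["year", "class_code", "class_name", "area_ha"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DemandTable":
        long = pd.read_csv(path)
        wide = long.pivot(index="year", columns="class_code", values="area_ha")
        wide = wide[[c for c in CLASS_CODES]]
        return cls(wide)


@dataclass
class ChangeReport:
    """Per-class signed area change (ha) and dynamic degree (%/yr)."""

    area_change_ha: dict[int, float]
    dynamic_degree_pct: dict[int, float]
    span_years: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_name": {c: CLASS_NAMES[c] for c in CLASS_CODES},
                "area_change_ha": self.area_change_ha,
                "dynamic_degree_pct": {
                    c: round(v, 2) for c, v in self.dynamic_degree_pct.items()
                },
            }
        )


# ---------------------------------------------------------------------------
# Estimation and projection
# ---------------------------------------------------------------------------

def estimate_transition(
    map_t0: LULCMap, map_t1: LULCMap, period_years: float = 1.0
) -> TransitionMatrix:
    """Row-normalised cross-tabulation of a map pair.

    Every class must be present at t0 (its transition row is undefined
    otherwise). ``period_years`` records the elapsed time the matrix spans.
    """
    counts = cross_tabulate(map_t0, map_t1).astype(float)
    row_tot = counts.sum(axis=1)
    absent = [CLASS_CODES[i] for i in range(N_CLASSES) if row_tot[i] == 0]
    if absent:
        raise ValueError(f"classes absent at t0, transition rows undefined: {absent}")
    return TransitionMatrix(counts / row_tot[:, None], period=period_years)


def matrix_root(matrix: np.ndarray, period: float) -> np.ndarray:
    """Raw period-th matrix root by eigendecomposition (no clipping).

    The returned matrix satisfies ``root**period == matrix`` to numerical
    precision but may carry tiny negative entries; :func:`annualize`
    wraps it with the clip-and-renormalise guard. Raises when eigenvalues
    are complex or nonpositive beyond tolerance (no real root exists).
    """
    m = np.asarray(matrix, dtype=float)
    lam, V = np.linalg.eig(m)
    if np.abs(lam.imag).max() > 1e-8 or np.any(lam.real <= 1e-12):
        raise ValueError(
            "matrix has complex or nonpositive eigenvalues; no real annual root "
            "exists — project at the period level instead"
        )
    return np.real((V * (lam.real ** (1.0 / period))) @ np.linalg.inv(V))


def annualize(tm: TransitionMatrix) -> TransitionMatrix:
    """Period-th matrix root via eigendecomposition → a 1-year matrix.

    Requires real positive eigenvalues (the typical case for the strongly
    diagonal matrices land-cover pairs produce). Small negative entries
    from the root are clipped to 0 and rows renormalised.
    """
    T = tm.period
    if T < 1:
        raise ValueError("matrix period must be at least 1 year")
    if T == 1:
        return TransitionMatrix(tm.matrix.copy(), period=1.0)
    root = matrix_root(tm.matrix, T)
    root = np.clip(root, 0.0, None)
    root /= root.sum(axis=1, keepdims=True)
    return TransitionMatrix(root, period=1.0)


def project_demand(
    initial_areas: Mapping[int, float] | Sequence[float],
    annual: TransitionMatrix,
    n_years: int,
    start_year: int = 0,
) -> DemandTable:
    """Propagate the class-area vector year by year: s_{t+1} = s_t · M.

    Row-stochasticity conserves the total area exactly; every yearly row
    (including year 0) is recorded.
    """
    if annual.period != 1.0:
        raise ValueError("projection requires an annual (period = 1) matrix")
    if isinstance(initial_areas, Mapping):
        s = np.array([float(initial_areas[c]) for c in CLASS_CODES])
    else:
        s = np.asarray(initial_areas, dtype=float)
    if s.shape != (N_CLASSES,):
        raise ValueError("initial areas must have one entry per class")
    if np.any(s < 0):
        raise ValueError("initial areas must be nonnegative")
    rows = [s.copy()]
    for _ in range(int(n_years)):
        s = s @ annual.matrix
        rows.append(s.copy())
    years = [start_year + k for k in range(len(rows))]
    df = pd.DataFrame(rows, index=years, columns=list(CLASS_CODES))
    return DemandTable(df)


def adjust_for_scenario(
    tm: TransitionMatrix,
    rules: Iterable[tuple[int, int, float]],
) -> TransitionMatrix:
    """Scale ruled conversions by retention factors; mass returns to stay.

    ``rules`` is an iterable of ``(source_code, dest_code, factor)`` with
    factor in [0, 1]: 0 forbids the conversion outright, 1 leaves it
    unchanged. The probability removed from each ruled off-diagonal entry
    is added to the source class's diagonal, so rows remain stochastic.
    """
    m = tm.matrix.copy()
    for src, dst, factor in rules:
        if not 0.0 <= factor <= 1.0:
            raise ValueError(f"retention factor must be in [0, 1], got {factor}")
        si, di = CLASS_CODES.index(int(src)), CLASS_CODES.index(int(dst))
        if si == di:
            continue
        removed = m[si, di] * (1.0 - factor)
        m[si, di] -= removed
        m[si, si] += removed
    return TransitionMatrix(m, period=tm.period)


def dynamic_degree(area_change_ha: float, start_area_ha: float, span_years: float) -> float:
    """Single land-use dynamic degree, percent per year.

    100 × ΔA / (A_start × T): the annualised rate of change of one
    class's area relative to its starting area.
    """
    if not start_area_ha > 0:
        raise ValueError("start area must be positive")
    if not span_years > 0:
        raise ValueError("span must be positive")
    return 100.0 * area_change_ha / (start_area_ha * span_years)
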