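"""Map-agreement statistics and change accounting.

Agreement between a simulated and an observed categorical map is
summarised by the confusion matrix, the observed proportion correct Po,
per-class producer/user accuracies, and a kappa index in the fixed-chance
form

    kappa = (Po − Pc) / (Pp − Pc),   Pc = 1/n,  Pp = 1,

where n is the number of classes (6 here). Cohen's kappa (marginal-
product chance expectation) is reported alongside under a distinct key.
Quantity agreement irrespective of location is summarised by a
kappa-for-quantity: the total-variation agreement of class proportions
rescaled against the same 1/n chance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .demand import ChangeReport, dynamic_degree
from .rasterkit import CLASS_CODES, CLASS_NAMES, N_CLASSES, Grid, LULCMap, cross_tabulate

__all__ = [
    "ValidationReport",
    "kappa",
    "cohen_kappa",
    "kappa_quantity",
    "accuracy_report",
    "change_report",
]

#: The conventional acceptance bar for simulation agreement.
KAPPA_ACCEPTABLE = 0.75


def kappa(po: float, n: int = N_CLASSES, pp: float = 1.0) -> float:
    """Fixed-chance kappa: (Po − 1/n) / (Pp − 1/n)."""
    if not 0.0 <= po <= 1.0:
        raise ValueError("Po must lie in [0, 1]")
    if n < 2:
        raise ValueError("kappa needs at least 2 classes")
    pc = 1.0 / n
    if pp <= pc:
        raise ValueError("Pp must exceed the chance proportion 1/n")
    return (po - pc) / (pp - pc)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa with the marginal-product chance expectation."""
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / total
    pe = float((c.sum(axis=0) * c.sum(axis=1)).sum()) / total**2
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_quantity(
    actual_areas: Mapping[int, float] | Sequence[float],
    simulated_areas: Mapping[int, float] | Sequence[float],
) -> float:
    """Quantity agreement rescaled against chance 1/n.

    Aq = 1 − ½ Σ|p_u − q_u| over class proportions; Kq = (Aq − 1/n)/(1 − 1/n).
    Symmetric in its arguments; 1 iff the proportions coincide.
    """

    def vec(a) -> np.ndarray:
        if isinstance(a, Mapping):
            return np.array([float(a[c]) for c in CLASS_CODES])
        return np.asarray(a, dtype=float)

    p, q = vec(actual_areas), vec(simulated_areas)
    if p.shape != q.shape:
        raise ValueError("area vectors must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("areas must be nonnegative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("area vectors must have positive totals")
    if abs(p.sum() - q.sum()) > 0.5:
        raise ValueError("area totals differ by more than 0.5 ha")
    n = p.size
    aq = 1.0 - 0.5 * float(np.abs(p / p.sum() - q / q.sum()).sum())
    pc = 1.0 / n
    return (aq - pc) / (1.0 - pc)


@dataclass
class ValidationReport:
    """Agreement summary between an observed and a simulated map.

    ``confusion[u−1, v−1]`` counts cells simulated as u and observed as
    v (rows = simulated). Accuracies are percentages.
    """

    confusion: np.ndarray
    po: float
    pc: float
    pp: float
    n_classes: int
    kappa: float
    kappa_cohen: float
    kquantity: float
    producer_accuracy: dict[int, float]
    user_accuracy: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "po": round(self.po, 4),
            "pc": self.pc,
            "pp": self.pp,
            "n_classes": self.n_classes,
            "kappa": round(self.kappa, 3),
            "kappa_cohen": round(self.kappa_cohen, 3),
            "kquantity": round(self.kquantity, 3),
            "producer_accuracy_pct": {
                str(c): round(v, 2) for c, v in self.producer_accuracy.items()
            },
            "user_accuracy_pct": {
                str(c): round(v, 2) for c, v in self.user_accuracy.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def to_text(self) -> str:
        lines = [
            f"overall proportion correct (Po): {self.po:.4f}",
            f"kappa (Pc = 1/{self.n_classes}): {self.kappa:.3f}"
            f"   [Cohen: {self.kappa_cohen:.3f}]",
            f"kappa for quantity: {self.kquantity:.3f}",
            "class                                  producer%   user%",
        ]
        for c in CLASS_CODES:
            lines.append(
                f"{c} {CLASS_NAMES[c]:<36} {self.producer_accuracy[c]:8.2f}"
                f" {self.user_accuracy[c]:7.2f}"
            )
        return "\n".join(lines)


def accuracy_report(actual: LULCMap, simulated: LULCMap) -> ValidationReport:
    """Full agreement report between an observed and a simulated map.

    Producer accuracy of class u is diag/column total (share of observed
    u simulated correctly); user accuracy is diag/row total (share of
    simulated u that is observed u).
    """
    confusion = cross_tabulate(simulated, actual)  # rows = simulated
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("maps share no jointly valid cells")
    diag = np.diag(confusion).astype(float)
    po = float(diag.sum()) / total
    col = confusion.sum(axis=0).astype(float)
    row = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        producer = np.where(col > 0, 100.0 * diag / np.maximum(col, 1), np.nan)
        user = np.where(row > 0, 100.0 * diag / np.maximum(row, 1), np.nan)
    cell_ha = actual.grid.cell_area_ha
    kq = kappa_quantity(
        {c: col[i] * cell_ha for i, c in enumerate(CLASS_CODES)},
        {c: row[i] * cell_ha for i, c in enumerate(CLASS_CODES)},
    )
    return ValidationReport(
        confusion=confusion,
        po=po,
        pc=1.0 / N_CLASSES,
        pp=1.0,
        n_classes=N_CLASSES,
        kappa=kappa(po, N_CLASSES, 1.0),
        kappa_cohen=cohen_kappa(confusion),
        kquantity=kq,
        producer_accuracy={c: float(producer[i]) for i, c in enumerate(CLASS_CODES)},
        user_accuracy={c: float(user[i]) for i, c in enumerate(CLASS_CODES)},
    )


def change_report(
    map_t0: LULCMap, map_t1: LULCMap, span_years: float
) -> tuple[ChangeReport, Grid]:
    """Per-class area change, dynamic degree, and the from→to change raster.

    The raster codes each jointly valid cell as ``10·from + to`` (so an
    unchanged farmland cell reads 11, farmland→water 15, ...).
    """
    if not map_t0.grid.same_geometry(map_t1.grid):
        raise ValueError("change report requires identical geometry")
    if not span_years > 0:
        raise ValueError("span must be positive")
    a0 = map_t0.class_areas_ha()
    a1 = map_t1.class_areas_ha()
    change = {c: a1[c] - a0[c] for c in CLASS_CODES}
    dyn = {
        c: dynamic_degree(change[c], a0[c], span_years) if a0[c] > 0 else float("nan")
        for c in CLASS_CODES
    }
    joint = map_t0.grid.valid_mask & map_t1.grid.valid_mask
    codes = np.where(
        joint,
        10 * np.asarray(map_t0.values, dtype=np.int32)
        + np.asarray(map_t1.values, dtype=np.int32),
        np.int32(map_t0.grid.nodata_value),
    )
    raster = Grid(
        codes,
        cellsize=map_t0.grid.cellsize,
        xllcorner=map_t0.grid.xllcorner,
        yllcorner=map_t0.grid.yllcorner,
        nodata_value=map_t0.grid.nodata_value,
    )
    return ChangeReport(change, dyn, span_years), raster
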