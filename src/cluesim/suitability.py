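"""Suitability modelling: per-class binary logistic regression on drivers.

The occurrence of each land class u is modelled one-vs-rest with a binary
logistic regression on the standardized driving factors,

    logit P_u(x) = beta0_u + sum_j beta_uj x_j,

so each class carries its own intercept and coefficient vector over an
included subset of the seven drivers. Standardization (zero mean, unit
population standard deviation over valid cells) happens at fit time and
the parameters are stored on the model for prediction-time reuse.
Explanatory power is screened with the rank-statistic area under the ROC
curve (AUC > 0.7 is the conventional adequacy bar), and driver
multicollinearity with tolerance / variance-inflation diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
import statsmodels.api as sm

from .rasterkit import (
    CLASS_CODES,
    DRIVER_NAMES,
    DriverStack,
    Grid,
    LULCMap,
    resample_categorical,
    resample_continuous,
)

__all__ = [
    "StandardizationParams",
    "standardize",
    "apply_standardization",
    "CollinearityReport",
    "collinearity_diagnostics",
    "ClassModel",
    "SuitabilityModel",
    "fit_binary_logistic",
    "fit_suitability_model",
    "predict_probability",
    "predict_all",
    "roc_auc",
    "scale_selection",
]

#: Tolerance below / VIF above which a driver is flagged as collinear.
TOLERANCE_CRITICAL = 0.1
VIF_CRITICAL = 5.0
#: Conventional adequacy bar for the area under the ROC curve.
AUC_ADEQUATE = 0.7

StandardizationParams = dict[str, tuple[float, float]]  # name -> (mean, sd)


def standardize(drivers: DriverStack) -> tuple[DriverStack, StandardizationParams]:
    """Zero-mean, unit-variance transform of every driver layer.

    The population (divide-by-n) standard deviation over valid cells is
    used. Returns the transformed stack and the per-driver (mean, sd)
    parameters for prediction-time reuse.
    """
    params: StandardizationParams = {}
    for name, g in drivers.items():
        vals = np.asarray(g.values, dtype=float)[g.valid_mask]
        if vals.size < 2:
            raise ValueError(f"driver {name!r} has fewer than 2 valid cells")
        mean = float(vals.mean())
        sd = float(vals.std())  # population convention (ddof=0)
        if sd == 0:
            raise ValueError(f"driver {name!r} is constant and cannot be standardized")
        params[name] = (mean, sd)
    return apply_standardization(drivers, params), params


def apply_standardization(
    drivers: DriverStack, params: StandardizationParams
) -> DriverStack:
    """Apply stored (mean, sd) parameters to a raw driver stack."""

    def tf(name: str, g: Grid) -> Grid:
        mean, sd = params[name]
        out = np.asarray(g.values, dtype=float).copy()
        m = g.valid_mask
        out[m] = (out[m] - mean) / sd
        out[~m] = g.nodata_value
        return g.copy(values=out)

    return drivers.map_layers(tf)


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    """Tolerance (1 − R² of each driver on the others) and its reciprocal VIF."""

    tolerance: dict[str, float]
    vif: dict[str, float]
    flagged: tuple[str, ...]

    @property
    def min_tolerance(self) -> float:
        return min(self.tolerance.values())

    @property
    def max_vif(self) -> float:
        return max(self.vif.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tolerance": pd.Series(self.tolerance),
                "vif": pd.Series(self.vif),
                "flagged": pd.Series(
                    {n: n in self.flagged for n in self.tolerance}
                ),
            }
        )


def collinearity_diagnostics(drivers: DriverStack) -> CollinearityReport:
    """Regress each driver on all others; tolerance = 1 − R², VIF = 1/tolerance.

    Drivers with tolerance < 0.1 or VIF > 5 are flagged as collinear (the
    conventional critical values). A driver that is an exact linear
    combination of the others is reported with tolerance floored at 1e-12
    rather than a division-by-zero.
    """
    X = drivers.as_matrix()
    n, p = X.shape
    if p < 2:
        raise ValueError("collinearity diagnostics require at least 2 drivers")
    if n <= p:
        raise ValueError(f"need more valid cells ({n}) than drivers ({p})")
    names = drivers.names
    tol: dict[str, float] = {}
    vif: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, rank, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"driver {name!r} is constant; diagnostics undefined")
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        t = max(1.0 - r2, 1e-12)
        tol[name] = min(t, 1.0)
        vif[name] = 1.0 / tol[name]
    flagged = tuple(
        n for n in names if tol[n] < TOLERANCE_CRITICAL or vif[n] > VIF_CRITICAL
    )
    return CollinearityReport(tol, vif, flagged)


# ---------------------------------------------------------------------------
# Logistic models
# ---------------------------------------------------------------------------

@dataclass
class ClassModel:
    """Fitted one-vs-rest logistic model for one land class."""

    class_code: int
    intercept: float
    coefficients: dict[str, float]  # only the included drivers
    converged: bool = True
    separation: bool = False
    n_obs: int = 0
    log_likelihood: float = float("nan")


@dataclass
class SuitabilityModel:
    """Six per-class logistic models plus the shared standardization params."""

    classes: dict[int, ClassModel]
    standardization: StandardizationParams

    def to_json(self) -> str:
        doc = {
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "classes": {
                str(c): {
                    "intercept": m.intercept,
                    "coefficients": m.coefficients,
                    "converged": m.converged,
                    "separation": m.separation,
                    "n_obs": m.n_obs,
                }
                for c, m in self.classes.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SuitabilityModel":
        doc = json.loads(text)
        classes = {
            int(c): ClassModel(
                class_code=int(c),
                intercept=float(d["intercept"]),
                coefficients={k: float(v) for k, v in d["coefficients"].items()},
                converged=bool(d.get("converged", True)),
                separation=bool(d.get("separation", False)),
                n_obs=int(d.get("n_obs", 0)),
            )
            for c, d in doc["classes"].items()
        }
        std = {k: (float(v[0]), float(v[1])) for k, v in doc["standardization"].items()}
        return cls(classes, std)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SuitabilityModel":
        return cls.from_json(Path(path).read_text())


MIN_CLASS_CELLS = 30


def fit_binary_logistic(
    lulc: LULCMap,
    class_code: int,
    drivers: DriverStack,
    included: Sequence[str] | None = None,
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> ClassModel:
    """Maximum-likelihood one-vs-rest logistic fit for one class.

    ``drivers`` must already be standardized. Complete separation or
    non-convergence is flagged on the returned model, not raised.
    """
    included = tuple(included) if included is not None else DRIVER_NAMES
    unknown = [d for d in included if d not in DRIVER_NAMES]
    if unknown:
        raise ValueError(f"unknown drivers in subset: {unknown}")
    mask = lulc.grid.valid_mask & drivers.valid_mask
    y = (np.asarray(lulc.values)[mask] == class_code).astype(float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0:
        raise ValueError(f"class {class_code} absent from the map")
    if n_pos < MIN_CLASS_CELLS or n_neg < MIN_CLASS_CELLS:
        raise ValueError(
            f"class {class_code}: need ≥ {MIN_CLASS_CELLS} cells present and absent "
            f"(got {n_pos} / {n_neg})"
        )
    cols = [np.asarray(drivers[d].values, dtype=float)[mask] for d in included]
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((y.size, 1))

    converged = True
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=0
            )
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # Newton can fail outright under (near-)separation; fall back
            res = sm.Logit(y, X).fit(method="lbfgs", maxiter=5 * maxiter, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
    params = np.asarray(res.params, dtype=float)
    if np.abs(params).max() > 50:
        separation = True
    return ClassModel(
        class_code=class_code,
        intercept=float(params[0]),
        coefficients={d: float(b) for d, b in zip(included, params[1:])},
        converged=converged,
        separation=separation,
        n_obs=int(y.size),
        log_likelihood=float(res.llf),
    )


def fit_suitability_model(
    lulc: LULCMap,
    drivers: DriverStack,
    included: Mapping[int, Sequence[str]] | None = None,
) -> SuitabilityModel:
    """Standardize the drivers and fit all six one-vs-rest class models.

    ``included`` optionally restricts the driver subset per class (drivers
    absent from the subset are structurally excluded: coefficient 0).
    """
    std, params = standardize(drivers)
    classes = {}
    for c in CLASS_CODES:
        subset = included.get(c, DRIVER_NAMES) if included else DRIVER_NAMES
        classes[c] = fit_binary_logistic(lulc, c, std, subset)
    return SuitabilityModel(classes, params)


def predict_probability(
    model: SuitabilityModel,
    drivers: DriverStack,
    class_code: int,
    *,
    standardized: bool = False,
) -> Grid:
    """Per-cell logistic probability surface P_u = expit(beta0 + beta·x).

    Raw drivers are standardized with the model's stored parameters unless
    ``standardized=True`` says they already are.
    """
    cm = model.classes[class_code]
    if not standardized:
        drivers = apply_standardization(drivers, model.standardization)
    geom = drivers.geometry
    mask = drivers.valid_mask
    eta = np.full(geom.shape, cm.intercept, dtype=float)
    for name, beta in cm.coefficients.items():
        try:
            layer = drivers[name]
        except KeyError:
            raise ValueError(f"driver {name!r} required by the model is missing") from None
        eta += beta * np.asarray(layer.values, dtype=float)
    prob = expit(eta)
    prob[~mask] = geom.nodata_value
    return geom.copy(values=prob)


def predict_all(
    model: SuitabilityModel, drivers: DriverStack, *, standardized: bool = False
) -> dict[int, Grid]:
    """Probability surfaces for all six classes (shared standardization pass)."""
    if not standardized:
        drivers = apply_standardization(drivers, model.standardization)
    return {
        c: predict_probability(model, drivers, c, standardized=True)
        for c in model.classes
    }


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores, truth) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    ``scores`` and ``truth`` may be Grids or arrays; tied scores receive
    averaged ranks. Raises if the truth holds a single outcome class.
    """
    s = np.asarray(scores.values if isinstance(scores, Grid) else scores, dtype=float)
    t = np.asarray(truth.values if isinstance(truth, Grid) else truth)
    if isinstance(scores, Grid) and isinstance(truth, Grid):
        mask = scores.valid_mask & truth.valid_mask
        s, t = s[mask], t[mask]
    s, t = s.ravel(), (t.ravel() != 0)
    n1 = int(t.sum())
    n0 = int(t.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC is undefined when only one outcome class is present")
    ranks = rankdata(s)
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def scale_selection(
    lulc: LULCMap,
    drivers: DriverStack,
    factors: Iterable[int] = (2, 3, 4, 5),
) -> pd.DataFrame:
    """Refit all six models at coarser grids and compare per-class AUC.

    For each aggregation factor the LULC map is majority-resampled, each
    driver block-mean-resampled, the six logistic models refit and their
    in-sample AUC recorded. A class too rare to fit at a coarse scale
    yields NaN rather than failing the whole table. Rows are sorted by
    output cellsize.
    """
    rows = {}
    for factor in sorted(set(int(f) for f in factors)):
        lulc_f = resample_categorical(lulc, factor)
        drivers_f = drivers.map_layers(lambda _n, g: resample_continuous(g, factor))
        std, _ = standardize(drivers_f)
        mask = lulc_f.grid.valid_mask & std.valid_mask
        vals = np.asarray(lulc_f.values)[mask]
        aucs = {}
        for c in CLASS_CODES:
            try:
                cm = fit_binary_logistic(lulc_f, c, std)
            except ValueError:
                aucs[c] = np.nan
                continue
            eta = np.full(vals.shape, cm.intercept)
            for name, beta in cm.coefficients.items():
                eta = eta + beta * np.asarray(std[name].values, dtype=float)[mask]
            aucs[c] = roc_auc(expit(eta), vals == c)
        rows[lulc_f.grid.cellsize] = aucs
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "cellsize_m"
    return out
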