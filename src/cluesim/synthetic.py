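"""Seeded synthetic landscape generator.

Produces a self-contained stand-in for the study-area rasters: a smooth
lowland DEM, rasterised feature networks (roads, rivers, ditches, mines,
residential patches), the derived seven-driver stack, and categorical
land-cover maps sampled from a known multinomial-logistic structure and
evolved by a known Markov transition matrix. Because the generating
parameters are recorded in :class:`SyntheticTruth`, every downstream
stage (regression, demand estimation, allocation, validation) can be
tested as a parameter-recovery problem with no external data.

The default geometry is a 200×200 grid of 60 m cells (14,400 ha), six
classes with area shares near the natural-development budget of the
published mining-area calibration (farmland 0.220, other agricultural
land 0.355, construction 0.056, subsided seeper 0.010, water 0.333,
tidal wetland 0.025).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rasterkit import (
    CLASS_CODES,
    DRIVER_NAMES,
    N_CLASSES,
    DriverStack,
    Grid,
    LULCMap,
    euclidean_distance,
    majority_filter,
    slope_from_dem,
)
from .suitability import standardize

__all__ = [
    "DEFAULT_PROPORTIONS",
    "DEFAULT_TRANSITION",
    "SyntheticTruth",
    "default_true_betas",
    "generate_dem",
    "generate_features",
    "generate_drivers",
    "generate_lulc",
    "evolve_lulc",
    "generate_fixture_set",
]

MIN_DIM = 16

#: Class area shares of the natural-development 2025 budget (row share of
#: the scenario total 117,681.84 ha), rounded to 3 decimals.
DEFAULT_PROPORTIONS = np.array([0.220, 0.355, 0.056, 0.010, 0.333, 0.026])
DEFAULT_PROPORTIONS = DEFAULT_PROPORTIONS / DEFAULT_PROPORTIONS.sum()

#: Default generating transition matrix for an 11-year-style evolution:
#: strongly diagonal, with flows echoing the study area's direction of
#: change (farmland/construction/wetland shrinking toward other
#: agricultural land and water).
DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.05, 0.01, 0.005, 0.030, 0.005],
        [0.04, 0.90, 0.01, 0.005, 0.040, 0.005],
        [0.05, 0.06, 0.86, 0.005, 0.020, 0.005],
        [0.02, 0.03, 0.01, 0.880, 0.060, 0.000],
        [0.01, 0.02, 0.00, 0.000, 0.960, 0.010],
        [0.02, 0.10, 0.00, 0.000, 0.080, 0.800],
    ]
)


@dataclass
class SyntheticTruth:
    """Generating parameters behind a synthetic landscape.

    ``intercepts``/``betas`` are the multinomial-logit scores actually
    used to sample classes (betas shape (6, 7), driver order
    :data:`cluesim.rasterkit.DRIVER_NAMES`); ``transition`` is the
    row-stochastic matrix used by :func:`evolve_lulc` (None until an
    evolution step records it).
    """

    intercepts: np.ndarray
    betas: np.ndarray
    seed: int
    nrows: int
    ncols: int
    cellsize: float
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (N_CLASSES, len(DRIVER_NAMES)):
            raise ValueError(f"betas must be (6, 7), got {self.betas.shape}")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if np.any(t < 0) or np.any(t > 1):
                raise ValueError("transition entries must lie in [0, 1]")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1")
            self.transition = t

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "nrows": self.nrows,
                "ncols": self.ncols,
                "cellsize": self.cellsize,
                "driver_order": list(DRIVER_NAMES),
                "intercepts": self.intercepts.tolist(),
                "betas": self.betas.tolist(),
                "transition": None
                if self.transition is None
                else self.transition.tolist(),
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            intercepts=np.array(d["intercepts"]),
            betas=np.array(d["betas"]),
            seed=int(d["seed"]),
            nrows=int(d["nrows"]),
            ncols=int(d["ncols"]),
            cellsize=float(d["cellsize"]),
            transition=None if d["transition"] is None else np.array(d["transition"]),
        )


def default_true_betas(
    proportions: np.ndarray = DEFAULT_PROPORTIONS,
) -> np.ndarray:
    """Generating coefficient matrix (6 classes × 7 drivers).

    Signs follow the published driver associations for the six classes
    (construction land and farmland hugging residential areas and roads,
    subsided seeper area hugging mines, water pulled to rivers and away
    from ditches, wetland away from ditches, ...), with magnitudes kept
    in a moderate range.

    A multinomial logit is only identified up to adding a common vector
    to every class's coefficients, while downstream fitting is
    one-vs-rest binary. Each driver column is therefore centred by the
    prevalence-weighted mean so that the generative coefficients live on
    the same contrast scale the binary fits estimate.
    """
    B = np.array(
        [
            # res   mines  roads  rivers ditch  elev   slope
            [-0.90, 0.00, 0.80, -0.80, 0.90, -0.20, -0.10],  # farmland
            [0.10, 0.30, -0.10, -0.70, 0.60, 0.00, 0.10],  # other agricultural
            [-1.80, -0.80, -0.20, 0.00, 0.20, 0.00, 0.00],  # construction
            [0.60, -3.00, -0.80, -0.90, 0.40, 0.50, 0.00],  # subsided seeper
            [1.00, -0.30, -1.00, 1.20, -1.40, 0.20, 0.00],  # water
            [0.50, 0.90, -0.50, -0.50, -2.20, 0.20, 0.20],  # tidal wetland
        ]
    )
    w = np.asarray(proportions, dtype=float)
    w = w / w.sum()
    return B - (w[:, None] * B).sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Terrain and feature generation
# ---------------------------------------------------------------------------

def generate_dem(
    nrows: int,
    ncols: int,
    cellsize: float = 60.0,
    seed: int = 0,
    smoothness: float = 8.0,
) -> Grid:
    """Spatially autocorrelated lowland DEM (Gaussian-filtered white noise).

    Values are rescaled to a 30–60 m band, matching a lake-plain county.
    ``smoothness`` is the Gaussian sigma in cells; larger means smoother.
    """
    if nrows < MIN_DIM or ncols < MIN_DIM:
        raise ValueError(f"DEM must be at least {MIN_DIM}×{MIN_DIM}")
    if not smoothness > 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nrows, ncols))
    surf = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    lo, hi = surf.min(), surf.max()
    z = 30.0 + (surf - lo) / (hi - lo) * 28.0
    return Grid(z, cellsize=cellsize)


def _random_polyline(
    rng: np.random.Generator, nrows: int, ncols: int, axis: int
) -> np.ndarray:
    """Random 8-connected walk crossing the grid along ``axis`` (0 = N→S)."""
    steps = nrows if axis == 0 else ncols
    cross = ncols if axis == 0 else nrows
    pos = int(rng.integers(cross // 6, cross - cross // 6))
    cells = []
    for t in range(steps):
        cells.append((t, pos) if axis == 0 else (pos, t))
        pos = int(np.clip(pos + rng.integers(-1, 2), 0, cross - 1))
    return np.array(cells)


def generate_features(
    nrows: int,
    ncols: int,
    cellsize: float = 60.0,
    seed: int = 0,
) -> dict[str, Grid]:
    """Feature masks for the five accessibility drivers.

    Roads (3 east–west lines), rivers (2 north–south meanders), ditches
    (4 shorter segments), mines (scattered points) and residential
    (small square patches). Every mask is non-empty and 0/1 coded.
    """
    if nrows < MIN_DIM or ncols < MIN_DIM:
        raise ValueError(f"feature geometry must be at least {MIN_DIM}×{MIN_DIM}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    masks = {
        name: np.zeros((nrows, ncols), dtype=np.int32)
        for name in ("roads", "rivers", "ditches", "mines", "residential")
    }
    for _ in range(3):
        for r, c in _random_polyline(rng, nrows, ncols, axis=1):
            masks["roads"][r, c] = 1
    for _ in range(2):
        for r, c in _random_polyline(rng, nrows, ncols, axis=0):
            masks["rivers"][r, c] = 1
    for _ in range(4):
        line = _random_polyline(rng, nrows, ncols, axis=int(rng.integers(0, 2)))
        keep = line[: max(4, len(line) // 2)]
        off_r = int(rng.integers(0, nrows // 2))
        off_c = int(rng.integers(0, ncols // 2))
        for r, c in keep:
            rr, cc = min(r + off_r, nrows - 1), min(c + off_c, ncols - 1)
            masks["ditches"][rr, cc] = 1
    for _ in range(max(4, nrows * ncols // 4000)):
        r = int(rng.integers(1, nrows - 2))
        c = int(rng.integers(1, ncols - 2))
        masks["mines"][r : r + 2, c : c + 2] = 1  # mines as small patches
    for _ in range(max(6, nrows * ncols // 4000)):
        r = int(rng.integers(1, nrows - 2))
        c = int(rng.integers(1, ncols - 2))
        size = int(rng.integers(2, 4))
        masks["residential"][r : r + size, c : c + size] = 1
    return {n: Grid(m, cellsize=cellsize) for n, m in masks.items()}


def generate_drivers(
    dem: Grid, features: dict[str, Grid]
) -> DriverStack:
    """Derive the seven-driver stack from a DEM and the feature masks."""
    layers = {
        "dist_residential": euclidean_distance(features["residential"]),
        "dist_mines": euclidean_distance(features["mines"]),
        "dist_roads": euclidean_distance(features["roads"]),
        "dist_rivers": euclidean_distance(features["rivers"]),
        "dist_ditches": euclidean_distance(features["ditches"]),
        "elevation": dem,
        "slope": slope_from_dem(dem),
    }
    return DriverStack(layers)


# ---------------------------------------------------------------------------
# Land-cover sampling and evolution
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def generate_lulc(
    drivers: DriverStack,
    true_betas: np.ndarray | None = None,
    target_proportions: np.ndarray = DEFAULT_PROPORTIONS,
    seed: int = 0,
    smooth_passes: int = 1,
) -> tuple[LULCMap, SyntheticTruth]:
    """Sample a categorical map from a multinomial logit on the drivers.

    Per-class linear scores on the standardized drivers are combined by a
    softmax; intercepts are auto-tuned (iterative log-share adjustment)
    so the expected class shares hit ``target_proportions``, then each
    cell's class is sampled and ``smooth_passes`` majority-filter passes
    give the map its patch structure. Realised shares stay within ±3
    percentage points of the targets.
    """
    targets = np.asarray(target_proportions, dtype=float)
    if targets.shape != (N_CLASSES,):
        raise ValueError("target_proportions must have 6 entries")
    if abs(targets.sum() - 1.0) > 1e-6:
        raise ValueError("target_proportions must sum to 1")
    if np.any(targets <= 0):
        raise ValueError("every class needs a positive target share")
    B = default_true_betas(targets) if true_betas is None else np.asarray(true_betas, float)

    std, _ = standardize(drivers)
    mask = std.valid_mask
    X = std.as_matrix(mask)  # (n, 7)
    scores = B @ X.T  # (6, n)

    geom = std.geometry

    def tune_expected(b0: np.ndarray) -> np.ndarray:
        # inner loop: match the *expected* softmax shares to the targets
        for _ in range(200):
            shares = _softmax(scores + b0[:, None]).mean(axis=1)
            if np.abs(shares - targets).max() < 1e-4:
                break
            b0 = b0 + np.log(targets / np.maximum(shares, 1e-12))
            b0 -= b0.mean()
        else:
            if np.abs(shares - targets).max() > 0.03:
                raise ValueError("intercept tuning failed to reach the target shares")
        return b0

    def realise(b0: np.ndarray, substream: int) -> LULCMap:
        p = _softmax(scores + b0[:, None])
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29, substream]))
        u = rng.random(p.shape[1])
        codes = (u[None, :] < np.cumsum(p, axis=0)).argmax(axis=0) + 1
        vals = np.full(geom.shape, int(geom.nodata_value), dtype=np.int32)
        vals[mask] = codes
        lulc = LULCMap(
            Grid(
                vals,
                cellsize=geom.cellsize,
                xllcorner=geom.xllcorner,
                yllcorner=geom.yllcorner,
                nodata_value=geom.nodata_value,
            )
        )
        return majority_filter(lulc, passes=smooth_passes) if smooth_passes else lulc

    # outer loop: the majority filter erodes rare scattered classes and its
    # share response to the intercepts is steep, so the correction against
    # the smoothed realisation is damped and clamped, keeping the best
    # iterate seen (everything deterministic per seed)
    b0 = tune_expected(np.log(targets))
    n_cells = int(mask.sum())
    best: tuple[float, np.ndarray, int] | None = None
    for outer in range(30):
        lulc = realise(b0, outer)
        counts = lulc.class_counts()
        realised = np.array([counts[c] for c in CLASS_CODES], dtype=float) / n_cells
        err = float(np.abs(realised - targets).max())
        if best is None or err < best[0]:
            best = (err, b0.copy(), outer)
        if err <= 0.005:
            break
        step = 0.5 * np.log(targets / np.maximum(realised, targets / 20.0))
        b0 = b0 + np.clip(step, -1.0, 1.0)
        b0 -= b0.mean()
    else:
        _, b0, outer = best
        lulc = realise(b0, outer)
        counts = lulc.class_counts()
        realised = np.array([counts[c] for c in CLASS_CODES], dtype=float) / n_cells
    if np.abs(realised - targets).max() > 0.03:
        raise ValueError(
            "realised class shares missed the targets by more than 3 percentage points"
        )
    truth = SyntheticTruth(
        intercepts=b0,
        betas=B,
        seed=int(seed),
        nrows=geom.nrows,
        ncols=geom.ncols,
        cellsize=geom.cellsize,
    )
    return lulc, truth


def evolve_lulc(
    lulc: LULCMap,
    transition: np.ndarray,
    suitability: dict[int, Grid],
    seed: int = 0,
) -> LULCMap:
    """Evolve a map one period by a known row-stochastic transition matrix.

    For each source class u the destination counts are the largest-
    remainder rounding of n_u × row_u. Among cells of u slated to become
    v, those with the highest suitability for v convert first; a tiny
    seeded jitter breaks exact score ties deterministically.
    """
    T = np.asarray(transition, dtype=float)
    if T.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("transition must be 6×6")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9) or np.any(T < 0):
        raise ValueError("transition must be row-stochastic")
    geom = lulc.grid
    for c, g in suitability.items():
        if not g.same_geometry(geom):
            raise ValueError(f"suitability layer for class {c} has mismatched geometry")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    vals = np.asarray(lulc.values)
    mask = geom.valid_mask
    flat_idx = np.flatnonzero(mask.ravel())
    codes = vals.ravel()[flat_idx]
    suit = {
        c: np.asarray(g.values, dtype=float).ravel()[flat_idx]
        for c, g in suitability.items()
    }
    out = codes.copy()
    for ui, u in enumerate(CLASS_CODES):
        members = np.flatnonzero(codes == u)
        n_u = members.size
        if n_u == 0:
            continue
        quota = _largest_remainder(T[ui] * n_u, n_u)
        remaining = members
        for vi, v in enumerate(CLASS_CODES):
            if v == u or quota[vi] == 0 or remaining.size == 0:
                continue
            k = min(int(quota[vi]), remaining.size)
            score = suit[v][remaining] + rng.uniform(0, 1e-9, remaining.size)
            take = remaining[np.argsort(-score, kind="stable")[:k]]
            out[take] = v
            remaining = np.setdiff1d(remaining, take, assume_unique=True)
    new_vals = vals.copy().ravel()
    new_vals[flat_idx] = out
    return LULCMap(geom.copy(values=new_vals.reshape(geom.shape)))


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative reals to integers preserving their exact sum."""
    base = np.floor(raw).astype(int)
    short = int(round(total - base.sum()))
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(raw - base, kind="stable")
        for j in order:
            if base[j] > 0 and short < 0:
                base[j] -= 1
                short += 1
    return base


# ---------------------------------------------------------------------------
# Fixture-set convenience
# ---------------------------------------------------------------------------

def generate_fixture_set(
    nrows: int = 200,
    ncols: int = 200,
    cellsize: float = 60.0,
    seed: int = 0,
    transition: np.ndarray | None = None,
    smooth_passes: int = 1,
):
    """One call producing the full synthetic study package.

    Returns ``(lulc_t0, lulc_t1, drivers, truth)`` where t1 is t0 evolved
    by ``transition`` (default :data:`DEFAULT_TRANSITION`) with the
    generating model's own probability surfaces steering the placement of
    conversions.
    """
    T = DEFAULT_TRANSITION if transition is None else np.asarray(transition, float)
    dem = generate_dem(nrows, ncols, cellsize, seed=seed)
    features = generate_features(nrows, ncols, cellsize, seed=seed)
    drivers = generate_drivers(dem, features)
    lulc_t0, truth = generate_lulc(
        drivers, seed=seed, smooth_passes=smooth_passes
    )
    std, _ = standardize(drivers)
    X = std.as_matrix(std.valid_mask)
    scores = _softmax(truth.betas @ X.T + truth.intercepts[:, None])
    geom = std.geometry
    suit = {}
    for ci, c in enumerate(CLASS_CODES):
        layer = np.full(geom.shape, geom.nodata_value, dtype=float)
        layer[std.valid_mask] = scores[ci]
        suit[c] = geom.copy(values=layer)
    lulc_t1 = evolve_lulc(lulc_t0, T, suit, seed=seed)
    truth.transition = T
    return lulc_t0, lulc_t1, drivers, truth
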