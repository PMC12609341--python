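"""Projection-pursuit composite index optimized by a real-coded
accelerated genetic algorithm (RAGA-PPC).

The composite resilience score of sample i is the projection
``Z(i) = sum_j a_j X*_ij`` of the direction-aware min-max normalized
indicator matrix onto a direction ``a`` with ``sum a_j^2 = 1`` and
``a_j in [0, 1]``.  The direction is chosen to maximize the projection
index ``Q(a) = S_z * D_z``, the product of the projection's sample
standard deviation (between-sample spread) and its local density

    D_z = sum_i sum_j (R - r_ij) * u(R - r_ij),    r_ij = |Z(i) - Z(j)|,

with ``u`` the unit step and ``R`` the window radius.  The double sum runs
over all ordered pairs including i = j (each diagonal term contributes R);
a switch excludes the diagonal for sensitivity checks.

The optimizer is a real-coded genetic algorithm with rank-based selection,
arithmetic crossover, uniform mutation and elitism, "accelerated" by
iteratively shrinking the per-coordinate search interval to the span of
the elite set and reinitializing, until the objective stops improving.
Candidates are repaired onto the feasible set by clipping to [0, 1] and
scaling to unit Euclidean norm (which preserves the box constraint, since
the norm of a nonnegative vector is at least its largest component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .indicators import IndicatorSpec, default_indicator_specs
from .panel_ops import OUTCOME, PanelDataset, UNIT, YEAR

__all__ = [
    "NormalizedMatrix",
    "ProjectionDirection",
    "ProjectionIndexValue",
    "GAConfig",
    "ProjectionPursuit",
    "ProjectionPursuitResults",
    "IndexResult",
    "normalize_indicators",
    "project",
    "projection_index",
    "default_window_radius",
    "optimize_direction",
    "compute_resilience_index",
]

_RADIUS_FLOOR = 1e-6


@dataclass
class NormalizedMatrix:
    """Direction-aware min-max normalized indicator grid in [0, 1]."""

    values: np.ndarray
    indicator_names: list[str]
    sample_keys: pd.DataFrame | None = None


@dataclass
class ProjectionDirection:
    """Feasible projection direction: unit Euclidean norm, entries in [0, 1]."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 1 or self.a.size == 0:
            raise ValueError("direction must be a nonempty vector")
        if not np.isclose(np.sum(self.a**2), 1.0, atol=1e-9):
            raise ValueError("direction must have unit sum of squares")
        if (self.a < -1e-12).any() or (self.a > 1 + 1e-12).any():
            raise ValueError("direction components must lie in [0, 1]")


@dataclass
class ProjectionIndexValue:
    """Objective decomposition Q = Sz * Dz at one direction."""

    Q: float
    Sz: float
    Dz: float
    z_mean: float
    R: float


@dataclass
class GAConfig:
    """Hyperparameters of the accelerated genetic algorithm.

    Defaults are sized for reliable convergence on a 360 x 22 panel.
    ``window_radius=None`` recomputes R = 0.1 * Sz per candidate direction;
    a float fixes R globally.  ``include_diagonal`` controls the i = j
    terms of the local-density sum.
    """

    population_size: int = 400
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    elite_count: int = 2
    acceleration_rounds: int = 20
    n_generations: int = 30
    convergence_tol: float = 1e-6
    window_radius: float | None = None
    include_diagonal: bool = True
    weight_convention: str = "squared"  # or "normalized_loadings"
    seed: int = 0

    def validate(self) -> "GAConfig":
        if not (0 <= self.crossover_prob <= 1):
            raise ValueError("GAConfig.crossover_prob must lie in [0, 1]")
        if not (0 <= self.mutation_prob <= 1):
            raise ValueError("GAConfig.mutation_prob must lie in [0, 1]")
        if self.population_size < 10:
            raise ValueError("GAConfig.population_size must be >= 10")
        if self.elite_count < 1 or self.elite_count >= self.population_size:
            raise ValueError("GAConfig.elite_count must be in [1, population_size)")
        if self.weight_convention not in ("squared", "normalized_loadings"):
            raise ValueError(
                "GAConfig.weight_convention must be 'squared' or 'normalized_loadings'"
            )
        return self


def normalize_indicators(
    raw: pd.DataFrame | np.ndarray,
    specs: Sequence[IndicatorSpec],
    sample_keys: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Min-max normalize each indicator over the pooled panel.

    Positive-direction indicators map to (x - min) / (max - min), negative
    ones to (max - x) / (max - min), so larger normalized values always
    mean more resilience.  Min/max are taken over all units and years
    jointly, keeping the index comparable across time.  Constant columns
    map to 0.5.  Missing entries propagate as NaN.
    """
    if isinstance(raw, pd.DataFrame):
        names = [s.name for s in specs]
        missing = [n for n in names if n not in raw.columns]
        if missing:
            raise KeyError(f"indicator columns absent from data: {missing}")
        x = raw[names].to_numpy(dtype=float)
    else:
        x = np.asarray(raw, dtype=float)
        if x.shape[1] != len(specs):
            raise ValueError(
                f"matrix has {x.shape[1]} columns but {len(specs)} indicator specs"
            )
        names = [s.name for s in specs]
    out = np.empty_like(x)
    for j, spec in enumerate(specs):
        col = x[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            raise ValueError(f"indicator {spec.name!r} has no finite values")
        lo, hi = np.nanmin(col), np.nanmax(col)
        if hi == lo:
            out[:, j] = np.where(finite, 0.5, np.nan)
        elif spec.direction == "positive":
            out[:, j] = (col - lo) / (hi - lo)
        else:
            out[:, j] = (hi - col) / (hi - lo)
    return NormalizedMatrix(out, names, sample_keys)


def project(
    direction: ProjectionDirection | np.ndarray,
    normalized: NormalizedMatrix | np.ndarray,
) -> np.ndarray:
    """Per-sample projection values Z(i) = sum_j a_j X*_ij."""
    a = direction.a if isinstance(direction, ProjectionDirection) else np.asarray(direction, float)
    x = normalized.values if isinstance(normalized, NormalizedMatrix) else np.asarray(normalized, float)
    if x.shape[1] != a.size:
        raise ValueError(f"direction length {a.size} != {x.shape[1]} indicators")
    return x @ a


def _local_density(z: np.ndarray, R: float, include_diagonal: bool = True) -> float:
    """Sum of (R - r_ij) over ordered pairs with r_ij <= R, via sorting."""
    n = z.size
    v = np.sort(z)
    s = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    left = np.searchsorted(v, v - R, side="left")
    right = np.searchsorted(v, v + R, side="right") - 1
    cnt = right - left + 1
    below = v * (idx - left + 1) - (s[idx + 1] - s[left])
    above = (s[right + 1] - s[idx + 1]) - v * (right - idx)
    dz = float(np.sum(cnt * R - (below + above)))
    if not include_diagonal:
        dz -= n * R
    return dz


def projection_index(
    z: np.ndarray, R: float, include_diagonal: bool = True
) -> ProjectionIndexValue:
    """Evaluate Q = Sz * Dz for projection values ``z`` and window radius ``R``.

    Sz is the sample standard deviation (n - 1 denominator); Dz sums
    (R - r_ij) over all ordered pairs within the window, including i = j
    unless ``include_diagonal`` is False.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("projection index requires at least 2 samples")
    if R <= 0:
        raise ValueError("window radius R must be > 0")
    sz = float(np.std(z, ddof=1))
    dz = _local_density(z, R, include_diagonal)
    return ProjectionIndexValue(Q=sz * dz, Sz=sz, Dz=dz, z_mean=float(z.mean()), R=R)


def default_window_radius(z: np.ndarray) -> float:
    """Default local-density window radius R = 0.1 * Sz(z).

    Constant projections have Sz = 0; a small positive floor is returned
    with a warning so the density term stays well-defined.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("window radius requires at least 2 samples")
    sz = float(np.std(z, ddof=1))
    r = 0.1 * sz
    if r <= 0:
        warnings.warn(
            "constant projection: window radius floored at 1e-6", RuntimeWarning
        )
        return _RADIUS_FLOOR
    return r


# ---------------------------------------------------------------------------
# genetic algorithm


def _repair(pop: np.ndarray, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Project candidates onto {a in [0,1]^p : ||a|| = 1}."""
    pop = np.clip(pop, 0.0, 1.0)
    norms = np.linalg.norm(pop, axis=1)
    dead = norms == 0
    while dead.any():
        pop[dead] = np.clip(rng.uniform(lo, hi, (int(dead.sum()), pop.shape[1])), 0.0, 1.0)
        norms = np.linalg.norm(pop, axis=1)
        dead = norms == 0
    return pop / norms[:, None]


def _evaluate(pop: np.ndarray, x: np.ndarray, ga: GAConfig) -> np.ndarray:
    """Objective Q for each candidate direction (rows of ``pop``)."""
    z = x @ pop.T  # n x k
    n = z.shape[0]
    mu = z.mean(axis=0)
    sz = np.sqrt(np.sum((z - mu) ** 2, axis=0) / (n - 1))
    q = np.empty(pop.shape[0])
    for k in range(pop.shape[0]):
        r = ga.window_radius if ga.window_radius is not None else max(0.1 * sz[k], _RADIUS_FLOOR)
        q[k] = sz[k] * _local_density(z[:, k], r, ga.include_diagonal)
    return q


def optimize_direction(
    normalized: NormalizedMatrix | np.ndarray,
    ga: GAConfig | None = None,
    sample_keys: pd.DataFrame | None = None,
    indicator_names: list[str] | None = None,
) -> "ProjectionPursuitResults":
    """Run the accelerated GA and return the fitted index.

    Returns the best feasible direction, its objective decomposition,
    per-sample scores and per-indicator weights, plus the best-objective
    trace across generations (non-decreasing by elitism).
    """
    ga = (ga or GAConfig()).validate()
    if isinstance(normalized, NormalizedMatrix):
        x = normalized.values
        names = normalized.indicator_names
        keys = normalized.sample_keys if sample_keys is None else sample_keys
    else:
        x = np.asarray(normalized, dtype=float)
        names = indicator_names or [f"x{j + 1}" for j in range(x.shape[1])]
        keys = sample_keys
    n, p = x.shape
    if p == 0:
        raise ValueError("no indicators to project")
    if n < 2:
        raise ValueError("projection pursuit requires at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError(
            "normalized matrix contains missing values; interpolate before fitting"
        )

    if p == 1:
        a = np.ones(1)
        z = project(a, x)
        r = ga.window_radius if ga.window_radius is not None else max(0.1 * np.std(z, ddof=1), _RADIUS_FLOOR)
        obj = projection_index(z, r, ga.include_diagonal)
        return ProjectionPursuitResults(
            direction=ProjectionDirection(a),
            objective=obj,
            scores=z,
            indicator_names=names,
            weight_convention=ga.weight_convention,
            trace=[obj.Q],
            sample_keys=keys,
        )

    # canonical internal column order (sorted by indicator name) so results
    # are invariant to the order the columns arrive in
    perm = np.argsort(np.asarray(names))
    x_work = x[:, perm]

    rng = np.random.default_rng(ga.seed)
    lo = np.zeros(p)
    hi = np.ones(p)
    best_a: np.ndarray | None = None
    best_q = -np.inf
    trace: list[float] = []
    prev_round_best = -np.inf

    for _ in range(ga.acceleration_rounds):
        pop = _repair(rng.uniform(lo, hi, (ga.population_size, p)), lo, hi, rng)
        if best_a is not None:
            pop[0] = best_a  # carry the incumbent across acceleration rounds
        q = _evaluate(pop, x_work, ga)
        for _gen in range(ga.n_generations):
            order = np.argsort(-q)
            pop, q = pop[order], q[order]
            if q[0] > best_q:
                best_q, best_a = float(q[0]), pop[0].copy()
            trace.append(best_q)
            # rank-based selection: weight linearly decreasing in rank
            m = ga.population_size
            weights = (m - np.arange(m)).astype(float)
            probs = weights / weights.sum()
            n_children = m - ga.elite_count
            pa = pop[rng.choice(m, n_children, p=probs)]
            pb = pop[rng.choice(m, n_children, p=probs)]
            lam = rng.random((n_children, p))
            cross = rng.random(n_children) < ga.crossover_prob
            children = np.where(cross[:, None], lam * pa + (1 - lam) * pb, pa)
            # uniform mutation: one random gene resampled inside the interval
            mutate = rng.random(n_children) < ga.mutation_prob
            genes = rng.integers(0, p, n_children)
            fresh = rng.uniform(lo[genes], hi[genes])
            children = children.copy()
            children[mutate, genes[mutate]] = fresh[mutate]
            children = _repair(children, lo, hi, rng)
            q_children = _evaluate(children, x_work, ga)
            pop = np.vstack([pop[: ga.elite_count], children])
            q = np.concatenate([q[: ga.elite_count], q_children])
        round_best = float(q.max())
        if best_a is not None and round_best - prev_round_best < ga.convergence_tol and len(trace) > ga.n_generations:
            break
        prev_round_best = max(round_best, prev_round_best)
        # acceleration: shrink the search interval to the elite span
        n_elite = max(ga.elite_count, ga.population_size // 20)
        elite = pop[np.argsort(-q)[:n_elite]]
        pad = 0.1 * (hi - lo)
        lo = np.clip(elite.min(axis=0) - pad, 0.0, 1.0)
        hi = np.clip(elite.max(axis=0) + pad, 0.0, 1.0)
        hi = np.maximum(hi, lo + 1e-9)

    assert best_a is not None
    a_full = np.empty(p)
    a_full[perm] = best_a
    z = project(a_full, x)
    r = ga.window_radius if ga.window_radius is not None else max(0.1 * np.std(z, ddof=1), _RADIUS_FLOOR)
    obj = projection_index(z, r, ga.include_diagonal)
    return ProjectionPursuitResults(
        direction=ProjectionDirection(a_full),
        objective=obj,
        scores=z,
        indicator_names=names,
        weight_convention=ga.weight_convention,
        trace=trace,
        sample_keys=keys,
    )


@dataclass
class ProjectionPursuitResults:
    """Fitted projection-pursuit index: direction, objective, scores, weights."""

    direction: ProjectionDirection
    objective: ProjectionIndexValue
    scores: np.ndarray
    indicator_names: list[str]
    weight_convention: str = "squared"
    trace: list[float] = field(default_factory=list)
    sample_keys: pd.DataFrame | None = None

    @property
    def loadings(self) -> np.ndarray:
        return self.direction.a

    @property
    def weights(self) -> np.ndarray:
        """Per-indicator weights; sum to 1 under either convention."""
        a = self.direction.a
        if self.weight_convention == "squared":
            return a**2 / np.sum(a**2)
        return a / np.sum(a)

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.indicator_names, "loading": self.loadings, "weight": self.weights}
        )

    def scores_frame(self) -> pd.DataFrame:
        if self.sample_keys is not None:
            out = self.sample_keys.reset_index(drop=True).copy()
        else:
            out = pd.DataFrame(index=range(len(self.scores)))
        out[OUTCOME] = self.scores
        return out

    def run_log(self) -> dict:
        return {
            "Q": self.objective.Q,
            "Sz": self.objective.Sz,
            "Dz": self.objective.Dz,
            "R": self.objective.R,
            "z_mean": self.objective.z_mean,
            "n_samples": int(len(self.scores)),
            "weight_convention": self.weight_convention,
            "trace": list(self.trace),
        }

    def summary(self) -> str:
        o = self.objective
        lines = [
            "Projection-pursuit composite index (RAGA)",
            "=" * 58,
            f"samples: {len(self.scores):>6d}    indicators: {len(self.indicator_names)}",
            f"Q* = {o.Q:.6f}   Sz = {o.Sz:.6f}   Dz = {o.Dz:.6f}   R = {o.R:.6f}",
            f"weights: {self.weight_convention}",
            "-" * 58,
            f"{'indicator':<28s}{'loading':>12s}{'weight':>12s}",
        ]
        for name, a, w in zip(self.indicator_names, self.loadings, self.weights):
            lines.append(f"{name:<28s}{a:>12.6f}{w:>12.6f}")
        return "\n".join(lines)


IndexResult = ProjectionPursuitResults


class ProjectionPursuit:
    """Projection-pursuit index model over a raw indicator table.

    Parameters
    ----------
    data
        DataFrame of raw indicator columns (plus optional unit/year keys)
        or a plain numeric matrix.
    specs
        Indicator specifications (name, direction, group).  Defaults to
        the standard 22-indicator resilience system when the columns are
        present.
    """

    def __init__(
        self,
        data: pd.DataFrame | np.ndarray,
        specs: Sequence[IndicatorSpec] | None = None,
    ):
        if specs is None:
            specs = default_indicator_specs()
        self.specs = list(specs)
        keys = None
        if isinstance(data, pd.DataFrame) and UNIT in data.columns and YEAR in data.columns:
            keys = data[[UNIT, YEAR]]
        self.normalized = normalize_indicators(data, self.specs, sample_keys=keys)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, specs: Sequence[IndicatorSpec] | None = None
    ) -> "ProjectionPursuit":
        return cls(df, specs)

    def fit(self, ga: GAConfig | None = None) -> ProjectionPursuitResults:
        return optimize_direction(self.normalized, ga)


def compute_resilience_index(
    panel: PanelDataset | pd.DataFrame,
    specs: Sequence[IndicatorSpec] | None = None,
    ga: GAConfig | None = None,
    column: str = OUTCOME,
) -> tuple[pd.DataFrame, ProjectionPursuitResults]:
    """Chain normalize -> optimize -> project and attach the index column.

    Returns the panel with the per-unit-year composite score in
    ``column`` together with the fitted results (direction, objective,
    weights, GA trace).  Indicator columns must be complete; run
    :func:`climres.panel_ops.interpolate_missing` first if needed.
    """
    df = panel.frame if isinstance(panel, PanelDataset) else panel
    model = ProjectionPursuit(df, specs)
    res = model.fit(ga)
    out = df.copy()
    out[column] = res.scores
    return out, res
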