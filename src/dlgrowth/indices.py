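"""Spatial indices that diagnose diffusion-limited growth from colony point sets.

Three dimensionless indices quantify the classic DLG phenomena:

* ``angular_index`` (I_theta) -- non-uniformity of growth about the colony's
  centre of mass; 0 for angularly uniform colonies, larger for branched or
  screened morphologies.
* ``repulsion_index`` (I_c) -- fraction of cells lying between two seed
  colonies; near 0.5 for uniform twin colonies, below 0.5 when nutrient
  depletion opens a gap (repulsion), above 0.5 for growth toward each other.
* ``bias_index`` (I_b) -- fraction of cells on the right-hand half of the
  domain; 0.5 for unbiased growth, near 1 for growth directed at a
  right-hand nutrient source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass
class ColonyPointSet:
    """Cell (or pixel-centre) coordinates with the domain geometry.

    ``bounds`` is ``(x_min, x_max, y_min, y_max)``.  ``seeds`` holds one or
    two seed positions where known; ``scale`` is the physical length of one
    coordinate unit and ``elapsed_time`` the colony age, both optional.
    """

    points: np.ndarray
    bounds: tuple[float, float, float, float]
    seeds: Optional[list[tuple[float, float]]] = None
    scale: Optional[float] = None
    elapsed_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        x_min, x_max, y_min, y_max = self.bounds
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < x_min).any() or (x > x_max).any() or (y < y_min).any() or (y > y_max).any():
                raise ValueError("points fall outside the stated domain bounds")

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def from_lattice_state(cls, state, config, seeds=None) -> "ColonyPointSet":
        """Point set from a lattice state; sites are unit squares so the
        domain bounds are offset by half a site."""
        pts = state.cell_positions().astype(float)
        bounds = (0.5, config.L_x + 0.5, 0.5, config.L_y + 0.5)
        if seeds is None:
            seeds = [tuple(map(float, s)) for s in config.seed_positions()]
        return cls(points=pts, bounds=bounds, seeds=seeds)


@dataclass
class IndexResult:
    """A computed spatial index with its parameters and raw counts."""

    kind: str  # "theta" | "c" | "b"
    value: float
    params: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


def angular_index(points: ColonyPointSet, n_bins: int = 16) -> IndexResult:
    """Angular index of non-uniform growth I_theta.

    The angle of every cell about the centre of mass (unweighted centroid of
    the cell positions) is binned into ``n_bins`` equal arcs; counts are
    scaled by the uniform expectation ``nu / n_bins`` and I_theta is the
    population standard deviation of the scaled counts.  Zero for angularly
    uniform colonies; ``sqrt(n_bins - 1)`` when one bin holds every cell.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pts = points.points
    if len(pts) == 0:
        raise ValueError("cannot compute an angular index of an empty point set")
    centre = pts.mean(axis=0)
    rel = pts - centre
    off_centre = (np.abs(rel) > 1e-12).any(axis=1)
    if not off_centre.any():
        raise ValueError("all points coincide with the centre of mass")
    angles = np.arctan2(rel[off_centre, 1], rel[off_centre, 0]) % (2.0 * np.pi)
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, 2.0 * np.pi))
    scaled = counts / (counts.sum() / n_bins)
    value = float(scaled.std())  # population std
    return IndexResult(
        kind="theta",
        value=value,
        params={"n_bins": n_bins, "centre": tuple(centre)},
        counts={"bin_counts": counts, "nu": int(len(pts))},
    )


def repulsion_index(points: ColonyPointSet) -> IndexResult:
    """Repulsion index I_c: the fraction of cells between the two seeds.

    ``nu_c`` counts cells whose x-coordinate lies strictly inside the open
    vertical strip bounded by the two seeds' x-coordinates, and
    ``I_c = nu_c / nu``.  Values near 0.5 indicate uniform twin colonies,
    values below 0.5 a depleted gap (colonies repelling), values above 0.5
    growth toward each other.
    """
    if points.seeds is None or len(points.seeds) != 2:
        raise ValueError("repulsion index requires exactly two seed positions")
    (x1, _), (x2, _) = points.seeds
    if x1 == x2:
        raise ValueError("seed positions must have distinct x-coordinates")
    lo, hi = min(x1, x2), max(x1, x2)
    if points.n == 0:
        raise ValueError("cannot compute a repulsion index of an empty point set")
    x = points.points[:, 0]
    nu_c = int(((x > lo) & (x < hi)).sum())
    value = nu_c / points.n
    return IndexResult(
        kind="c",
        value=float(value),
        params={"strip": (lo, hi)},
        counts={"nu_c": nu_c, "nu": points.n},
    )


def bias_index(points: ColonyPointSet) -> IndexResult:
    """Directed-growth bias I_b: fraction of cells right of the domain midline.

    Points exactly on the midline contribute half a cell each, so a
    mirror-symmetric colony scores exactly 0.5.  ``I_b > 0.5`` indicates bias
    toward the right-hand side of the domain.
    """
    if points.n == 0:
        raise ValueError("cannot compute a bias index of an empty point set")
    x_min, x_max, _, _ = points.bounds
    if not (np.isfinite(x_min) and np.isfinite(x_max)):
        raise ValueError("bias index requires finite domain bounds")
    mid = 0.5 * (x_min + x_max)
    x = points.points[:, 0]
    n_right = (x > mid).sum() + 0.5 * (x == mid).sum()
    value = float(n_right / points.n)
    return IndexResult(
        kind="b",
        value=value,
        params={"midline": mid},
        counts={"nu_right": float(n_right), "nu": points.n},
    )


_INDEX_FUNCS: dict[str, Callable] = {
    "theta": angular_index,
    "c": repulsion_index,
    "b": bias_index,
}


def compute_index(points: ColonyPointSet, kind: str, **kwargs) -> IndexResult:
    """Dispatch to one of the three index computations by kind."""
    try:
        func = _INDEX_FUNCS[kind]
    except KeyError:
        raise ValueError(f"unknown index kind {kind!r}") from None
    return func(points, **kwargs)


@dataclass
class EnsembleIndex:
    """Mean of an index over independent seeded simulation runs."""

    kind: str
    mean: float
    stderr: float
    values: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.values)


def mean_index_over_realisations(
    config,
    n_reps: int,
    kind: str,
    base_seed: int = 0,
    **index_kwargs,
) -> EnsembleIndex:
    """Run ``n_reps`` independently seeded lattice simulations and average
    one index over them.

    Runs that do not reach the stopping density are excluded from the mean
    and reported via ``n_excluded``.  Replicate ``i`` uses seed
    ``base_seed + i``, so the ensemble is reproducible.
    """
    from . import lattice  # deferred; keeps this module importable standalone

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    values = []
    n_excluded = 0
    for i in range(n_reps):
        res = lattice.run_until_density(lattice.with_seed(config, base_seed + i))
        if not res.converged:
            n_excluded += 1
            continue
        pts = ColonyPointSet.from_lattice_state(res.state, res.config)
        values.append(compute_index(pts, kind, **index_kwargs).value)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise RuntimeError("no simulation reached the stopping density")
    stderr = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return EnsembleIndex(
        kind=kind,
        mean=float(values.mean()),
        stderr=stderr,
        values=values,
        n_excluded=n_excluded,
    )
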