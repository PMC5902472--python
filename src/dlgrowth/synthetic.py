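"""Synthetic colony fixtures with known ground truth.

Generators for point sets, area series and binary masks whose index values,
slopes and areas are known in closed form, so that every analysis stage can
be validated without experimental photographs.  All generators are
deterministic under a fixed seed and return the ground truth alongside the
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .indices import ColonyPointSet
from .rates import AreaSeries

#: default domain mirrors the standard lattice scenarios
DEFAULT_BOUNDS = (0.5, 200.5, 0.5, 200.5)
DEFAULT_SEEDS = [(75.0, 100.0), (125.0, 100.0)]


def _rng(seed):
    return np.random.default_rng(seed)


def uniform_disc(
    n: int,
    radius: float = 50.0,
    centre: tuple[float, float] = (100.5, 100.5),
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
) -> ColonyPointSet:
    """``n`` points uniform by area in a disc: an angularly uniform colony.

    Its angular index decays like ``sqrt(n_bins / n)`` as n grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    pts = np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])
    return ColonyPointSet(points=pts, bounds=bounds, seeds=[centre])


def angular_branches(
    n: int,
    n_branches: int = 4,
    branch_halfwidth: float = np.pi / 32,
    radius: float = 50.0,
    centre: tuple[float, float] = (100.5, 100.5),
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
) -> ColonyPointSet:
    """Points confined to ``n_branches`` equally spaced angular sectors.

    Emulates a branched (screened) colony; with bins aligned to the sectors
    the expected angular index is computable in closed form.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = _rng(seed)
    k = rng.integers(0, n_branches, size=n)
    base = k * 2 * np.pi / n_branches
    th = base + rng.uniform(-branch_halfwidth, branch_halfwidth, size=n)
    r = radius * np.sqrt(rng.random(n))
    pts = np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])
    pts[:, 0] = pts[:, 0].clip(bounds[0], bounds[1])
    pts[:, 1] = pts[:, 1].clip(bounds[2], bounds[3])
    return ColonyPointSet(points=pts, bounds=bounds, seeds=[centre])


def split_right_fraction(
    n: int,
    f: float,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
) -> ColonyPointSet:
    """Point set with exactly ``round(f * n)`` points right of the midline.

    Ground truth for the bias index: ``bias_index == round(f*n)/n`` exactly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    rng = _rng(seed)
    x_min, x_max, y_min, y_max = bounds
    mid = 0.5 * (x_min + x_max)
    n_right = int(round(f * n))
    eps = 1e-6 * (x_max - x_min)
    xr = rng.uniform(mid + eps, x_max, size=n_right)
    xl = rng.uniform(x_min, mid - eps, size=n - n_right)
    x = np.concatenate([xr, xl])
    y = rng.uniform(y_min, y_max, size=n)
    return ColonyPointSet(points=np.column_stack([x, y]), bounds=bounds)


def twin_discs(
    n: int,
    radius: float = 30.0,
    gap_halfwidth: float = 0.0,
    seeds=None,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
) -> ColonyPointSet:
    """Two uniform discs centred on the two-seed positions.

    ``gap_halfwidth`` removes all points within that distance of the domain
    midline, emulating a depleted inter-colony gap.  With no gap the
    repulsion index is close to 0.5; with a gap wide enough to cover the
    inter-seed strip it is 0.
    """
    rng = _rng(seed)
    if seeds is None:
        seeds = DEFAULT_SEEDS
    (s1x, s1y), (s2x, s2y) = seeds
    mid = 0.5 * (bounds[0] + bounds[1])
    pts = []
    while sum(len(p) for p in pts) < n:
        m = n - sum(len(p) for p in pts)
        which = rng.random(m) < 0.5
        r = radius * np.sqrt(rng.random(m))
        th = rng.random(m) * 2 * np.pi
        cx = np.where(which, s1x, s2x)
        cy = np.where(which, s1y, s2y)
        cand = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        keep = np.abs(cand[:, 0] - mid) >= gap_halfwidth
        pts.append(cand[keep])
    pts = np.concatenate(pts)[:n]
    return ColonyPointSet(
        points=pts, bounds=bounds, seeds=[(s1x, s1y), (s2x, s2y)]
    )


def generate_area_series(
    slope: float,
    n: int = 20,
    sigma: float = 0.0,
    t_max: float = 100.0,
    time_units: str = "min",
    area_units: str = "mm2",
    seed: int = 0,
) -> tuple[AreaSeries, float]:
    """Linear area growth ``A(t) = slope * t`` plus Gaussian noise.

    Areas are clipped at zero.  Returns the series and the true slope.
    """
    if slope < 0 or sigma < 0 or n < 2:
        raise ValueError("need slope >= 0, sigma >= 0, n >= 2")
    rng = _rng(seed)
    t = np.linspace(0.0, t_max, n)
    a = slope * t + rng.normal(0.0, sigma, size=n) if sigma > 0 else slope * t
    a = np.clip(a, 0.0, None)
    return AreaSeries(times=t, areas=a, time_units=time_units, area_units=area_units), slope


def render_mask(
    points: ColonyPointSet, pixel_scale: float = 1.0
) -> np.ndarray:
    """Binary mask with one set pixel per point (no dilation).

    Pixel (i, j) covers the square ``[j, j+1) x [i, i+1)`` in units of
    ``pixel_scale``; row 0 is the bottom of the domain.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    x_min, x_max, y_min, y_max = points.bounds
    w = int(np.ceil((x_max - x_min) / pixel_scale))
    h = int(np.ceil((y_max - y_min) / pixel_scale))
    mask = np.zeros((h, w), dtype=np.uint8)
    if points.n:
        j = np.floor((points.points[:, 0] - x_min) / pixel_scale).astype(int)
        i = np.floor((points.points[:, 1] - y_min) / pixel_scale).astype(int)
        mask[i.clip(0, h - 1), j.clip(0, w - 1)] = 1
    return mask


def mask_to_points(
    mask: np.ndarray,
    pixel_scale: float = 1.0,
    origin: tuple[float, float] = (0.5, 0.5),
) -> ColonyPointSet:
    """Pixel-centre coordinates of the set pixels of a binary mask.

    The inverse of :func:`render_mask` for distinct integer-aligned points.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    i, j = np.nonzero(mask)
    x0, y0 = origin
    pts = np.column_stack(
        [x0 + (j + 0.5) * pixel_scale, y0 + (i + 0.5) * pixel_scale]
    )
    h, w = mask.shape
    bounds = (x0, x0 + w * pixel_scale, y0, y0 + h * pixel_scale)
    return ColonyPointSet(points=pts, bounds=bounds)
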