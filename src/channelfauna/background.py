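"""Target-group background sampling via volume density contours.

Presence-only archives are collected where observers go, not where animals
are. Fitting against a uniform background would let the model learn the
observers; the fix is to draw background points with the *same* spatial bias
as the sightings. Here the sightings' kernel density surface is sliced into
nested volume contours — the smallest regions holding 25, 50, 75, 99 and 100%
of the density volume — and an equal share of background points is drawn
uniformly within each contour. Nested contours over-weight high-density areas,
which is exactly the target-group-background intent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_layers import PredictorStack
from .grids import GridSpec, RasterLayer

__all__ = ["ContourSet", "BackgroundSet", "kde_density", "volume_contour_masks",
           "sample_background", "DEFAULT_LEVELS", "DEFAULT_N_BACKGROUND"]

DEFAULT_LEVELS = (25, 50, 75, 99, 100)
DEFAULT_N_BACKGROUND = 10_000


@dataclass
class ContourSet:
    """A density surface plus its nested volume-contour cell masks."""

    density: RasterLayer
    levels: tuple[int, ...]
    masks: dict[int, np.ndarray]


@dataclass
class BackgroundSet:
    """Background points (cell centers) with stratum labels and environment."""

    points: pd.DataFrame  # columns x, y, stratum
    features: pd.DataFrame  # one column per environmental variable
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.concat([self.points.reset_index(drop=True),
                          self.features.reset_index(drop=True)], axis=1)


def _scott_bandwidths(pts: np.ndarray) -> tuple[float, float]:
    """Scott's rule per axis for a 2-D sample: h = sd · n^(-1/6)."""
    n = pts.shape[0]
    factor = n ** (-1.0 / 6.0)
    sx = pts[:, 0].std(ddof=1)
    sy = pts[:, 1].std(ddof=1)
    # degenerate axes fall back to one cell width equivalents upstream
    return max(sx, 1e-12) * factor, max(sy, 1e-12) * factor


def kde_density(
    points_xy: np.ndarray,
    spec: GridSpec,
    bandwidth: float | str = "scott",
    sea: np.ndarray | None = None,
) -> RasterLayer:
    """Gaussian kernel density of sighting locations, normalized over sea cells.

    ``bandwidth`` is either a scalar used on both axes or ``"scott"`` for
    Scott's rule per axis. The surface is nonnegative, zero is allowed, and
    it sums to exactly 1 over sea (non-NaN) cells.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for a density surface")
    if bandwidth == "scott":
        hx, hy = _scott_bandwidths(pts)
    else:
        hx = hy = float(bandwidth)
        if hx <= 0:
            raise ValueError("bandwidth must be positive")
    xs, ys = spec.cell_centers()
    dens = np.zeros(spec.shape)
    for px, py in pts:
        dens += np.exp(
            -((xs - px) ** 2) / (2 * hx**2) - ((ys - py) ** 2) / (2 * hy**2)
        )
    if sea is not None:
        dens = np.where(sea, dens, np.nan)
    total = np.nansum(dens)
    if total <= 0:
        raise ValueError("density surface is zero everywhere")
    dens = dens / total
    return RasterLayer(spec=spec, name="sighting_density", values=dens)


def volume_contour_masks(
    density: RasterLayer, levels: tuple[int, ...] = DEFAULT_LEVELS
) -> ContourSet:
    """Smallest highest-density cell sets holding each volume percentage.

    Cells are sorted by descending density, ties broken by row-major order;
    mask(q) takes the shortest prefix whose cumulative density ≥ q/100.
    mask(100) is every positive-density cell. Masks are nested by
    construction.
    """
    vals = density.values
    flat = np.where(np.isnan(vals), 0.0, vals).ravel()
    total = flat.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("density must be normalized to sum 1")
    if list(levels) != sorted(set(levels)) or not all(0 < q <= 100 for q in levels):
        raise ValueError("levels must be strictly increasing in (0, 100]")
    # stable sort on -density preserves row-major order among ties
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    masks: dict[int, np.ndarray] = {}
    for q in levels:
        if q >= 100:
            chosen = flat > 0
        else:
            k = int(np.searchsorted(csum, q / 100.0 - 1e-12)) + 1
            chosen = np.zeros(flat.size, dtype=bool)
            chosen[order[:k]] = True
        masks[q] = chosen.reshape(density.spec.shape)
    return ContourSet(density=density, levels=tuple(levels), masks=masks)


def sample_background(
    contours: ContourSet,
    n_total: int,
    seed: int,
    env: PredictorStack | None = None,
) -> BackgroundSet:
    """Draw background points uniformly within each contour stratum.

    ``n_total`` is split equally across the levels (integer division), with
    the remainder assigned to the widest (highest-level) stratum. Points are
    placed at cell centers of cells drawn uniformly with replacement from the
    stratum's mask; each point carries its cell's environmental values when a
    predictor stack is supplied.
    """
    levels = contours.levels
    if n_total < len(levels):
        raise ValueError("n_total smaller than number of strata")
    rng = np.random.default_rng(seed)
    spec = contours.density.spec
    per = n_total // len(levels)
    counts = {q: per for q in levels}
    counts[max(levels)] += n_total - per * len(levels)
    frames = []
    feats = []
    for q in levels:
        mask = contours.masks[q]
        r, c = np.nonzero(mask)
        if r.size == 0:
            raise ValueError(f"stratum {q} has an empty mask")
        pick = rng.integers(0, r.size, size=counts[q])
        rr, cc = r[pick], c[pick]
        frames.append(
            pd.DataFrame(
                {
                    "x": spec.origin_x + (cc + 0.5) * spec.cell_size,
                    "y": spec.origin_y - (rr + 0.5) * spec.cell_size,
                    "stratum": q,
                }
            )
        )
        if env is not None:
            feats.append(env.values_at(rr, cc))
    points = pd.concat(frames, ignore_index=True)
    features = (
        pd.concat(feats, ignore_index=True) if env is not None else pd.DataFrame()
    )
    return BackgroundSet(points=points, features=features, seed=seed)
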