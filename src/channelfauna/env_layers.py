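"""Environmental predictor surfaces.

Seasonal climatologies, Horn-method bottom slope, Euclidean distance to the
shelf break (200 m isobath) and to shore, kernel occurrence surfaces for
plankton, and the pairwise-correlation screen that keeps the predictor set
interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .grids import GridSpec, RasterLayer
from .records import SEASON_MONTHS

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorStack",
    "seasonal_mean",
    "slope_degrees",
    "isobath_cells",
    "distance_to_level",
    "distance_to_shore",
    "occurrence_surface",
    "correlation_screen",
]


@dataclass
class PredictorStack:
    """Ordered, grid-aligned set of predictor layers for one season."""

    season: str
    layers: dict[str, RasterLayer] = field(default_factory=dict)

    def add(self, layer: RasterLayer, provenance: str = "") -> None:
        if self.layers:
            first = next(iter(self.layers.values()))
            if layer.spec != first.spec:
                raise ValueError("layer GridSpec mismatch in PredictorStack")
        if layer.name in self.layers:
            raise ValueError(f"duplicate variable {layer.name!r}")
        if provenance:
            layer.provenance = provenance
        self.layers[layer.name] = layer

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    def sea_mask(self) -> np.ndarray:
        """Cells with data in every layer."""
        m = np.ones(self.spec.shape, dtype=bool)
        for layer in self.layers.values():
            m &= layer.mask
        return m

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Per-point table of layer values at the given cells."""
        return pd.DataFrame(
            {name: layer.values[rows, cols] for name, layer in self.layers.items()}
        )

    def table(self) -> pd.DataFrame:
        """All-sea-cell table (row per cell where every layer has data)."""
        m = self.sea_mask()
        r, c = np.nonzero(m)
        return self.values_at(r, c)

    def subset(self, names: list[str]) -> "PredictorStack":
        out = PredictorStack(season=self.season)
        for n in names:
            out.layers[n] = self.layers[n]
        return out


def seasonal_mean(monthly: list[RasterLayer], season: str) -> RasterLayer:
    """Cellwise mean of a season's monthly layers (a 3-month climatology).

    The mean runs over available (non-NaN) months per cell; a cell is NaN only
    where every month is NaN. ``monthly`` must hold the layers of the season's
    months (1 to 3 of them), all on one grid.
    """
    if not monthly:
        raise ValueError("no monthly layers supplied")
    spec = monthly[0].spec
    for layer in monthly:
        if layer.spec != spec:
            raise ValueError("GridSpec mismatch among monthly layers")
    stack = np.stack([l.values for l in monthly])
    all_nan = np.isnan(stack).all(axis=0)
    filled = np.where(np.isnan(stack), 0.0, stack)
    counts = (~np.isnan(stack)).sum(axis=0)
    vals = np.where(all_nan, np.nan, filled.sum(axis=0) / np.maximum(counts, 1))
    return RasterLayer(
        spec=spec,
        name=monthly[0].name,
        values=vals,
        units=monthly[0].units,
        season=season,
        provenance=f"{len(monthly)}-month mean, {season} ({SEASON_MONTHS[season]})",
    )


def slope_degrees(bathymetry: RasterLayer) -> RasterLayer:
    """Seafloor slope in degrees by Horn's 3x3 finite-difference method.

    Horn's estimator weights the 8 neighbours (a,b,c / d,_,f / g,h,i) as
    dz/dx = ((c+2f+i) - (a+2d+g)) / (8·cell), dz/dy likewise across rows;
    slope = arctan(hypot(dz/dx, dz/dy)). Edges use replicate padding; NaN
    cells are filled from their nearest data cell for the stencil and masked
    out again afterwards.
    """
    spec = bathymetry.spec
    if spec.n_rows < 3 or spec.n_cols < 3:
        raise ValueError("grid too small for a 3x3 stencil")
    z = bathymetry.values
    nan = np.isnan(z)
    if nan.any():
        # fill from nearest data cell so coastal stencils stay finite
        idx = distance_transform_edt(nan, return_indices=True)[1]
        z = z[tuple(idx)]
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    cell = spec.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope = np.where(nan, np.nan, slope)
    return RasterLayer(
        spec=spec, name="slope", values=slope, units="deg",
        provenance="Horn 3x3 on bathymetry",
    )


def isobath_cells(bathymetry: RasterLayer, level: float) -> np.ndarray:
    """Boolean mask of cells on the given isobath.

    A cell is on the isobath when its depth ≥ level and a 4-neighbour is
    shallower than level (land/NaN neighbours do not count as shallower).
    """
    z = bathymetry.values
    deep = z >= level
    shallow = z < level  # False on NaN
    pad = np.pad(shallow, 1, mode="constant", constant_values=False)
    near_shallow = pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    return deep & near_shallow


def _distance_to_targets(target: np.ndarray, spec: GridSpec, name: str) -> RasterLayer:
    if not target.any():
        raise ValueError("level not crossed: no target cells")
    dist = distance_transform_edt(~target) * spec.cell_size
    return RasterLayer(spec=spec, name=name, values=dist, units="grid length")


def distance_to_level(bathymetry: RasterLayer, level: float) -> RasterLayer:
    """Euclidean center-to-center distance to the nearest isobath cell."""
    target = isobath_cells(bathymetry, level)
    layer = _distance_to_targets(target, bathymetry.spec, f"dist_{level:g}m")
    layer.provenance = f"Euclidean distance to {level:g} isobath"
    return layer


def distance_to_shore(land: RasterLayer) -> RasterLayer:
    """Euclidean center-to-center distance to the nearest land cell."""
    target = land.values == 1
    if not target.any():
        raise ValueError("no land cells")
    layer = _distance_to_targets(target, land.spec, "dist_shore")
    layer.provenance = "Euclidean distance to land"
    return layer


def occurrence_surface(
    points_xy: np.ndarray, spec: GridSpec, bandwidth: float,
    sea: np.ndarray | None = None, name: str = "occurrence",
) -> RasterLayer:
    """Gaussian-kernel occurrence surface rescaled to a 0-1 maximum.

    A stand-in for interpolated probability-of-occurrence products built from
    presence-only plankton records: kernel intensity at cell centers, divided
    by its maximum.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    xs, ys = spec.cell_centers()
    dens = np.zeros(spec.shape)
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for px, py in pts:
        dens += np.exp(-((xs - px) ** 2 + (ys - py) ** 2) * inv2h2)
    peak = dens.max()
    if peak > 0:
        dens /= peak
    if sea is not None:
        dens = np.where(sea, dens, np.nan)
    return RasterLayer(
        spec=spec, name=name, values=dens, units="relative",
        provenance="kernel intensity rescaled to max 1 (synthetic stand-in for "
        "interpolated probability-of-occurrence surfaces)",
    )


def correlation_screen(
    table: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop predictors until no kept pair has |Pearson r| ≥ threshold.

    Of each offending pair, the variable with the larger mean absolute
    correlation against all other variables is dropped (it is the more
    redundant one). Zero-variance variables are dropped up front with a
    warning, since r is undefined for them. Returns
    ``(kept, dropped, correlation matrix)`` over the original variables.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >=2 variables and >=3 rows")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    dropped: list[str] = []
    table = table.dropna()
    const = [c for c in table.columns if table[c].nunique() <= 1]
    for c in const:
        logger.warning("dropping zero-variance variable %r", c)
        dropped.append(c)
    work = table.drop(columns=const)
    corr = work.corr(method="pearson")
    kept = list(work.columns)
    while True:
        sub = corr.loc[kept, kept].abs()
        np.fill_diagonal(sub.values, 0.0)
        if sub.values.size == 0 or sub.values.max() < threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        # mean |r| against all other kept variables decides who goes
        mean_a = sub.loc[a].sum() / max(len(kept) - 1, 1)
        mean_b = sub.loc[b].sum() / max(len(kept) - 1, 1)
        if mean_b > mean_a or (mean_b == mean_a and list(table.columns).index(b) > list(table.columns).index(a)):
            loser = b
        else:
            loser = a
        logger.info("correlation screen drops %r (|r|=%.3f with %r)", loser,
                    sub.loc[a, b], a if loser == b else b)
        kept.remove(loser)
        dropped.append(loser)
    full_corr = table.corr(method="pearson")
    return kept, dropped, full_corr
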