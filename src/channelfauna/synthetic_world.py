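"""Synthetic study region with known habitat truth.

Real marine-megafauna archives are presence-only, spatially clustered around
survey ports, and ride on smooth, seasonally cycling environmental fields.
This module builds an artificial region with exactly that structure and a
*known* data-generating model, so every downstream step (bias-matched
background sampling, maximum-entropy fitting, evaluation) can be tested
against ground truth:

* environmental fields are smooth Gaussian random fields plus deterministic
  spatial gradients, with a sinusoidal seasonal cycle across the 12 monthly
  layers — this gives controllable inter-variable correlation and seasonality;
* bathymetry deepens away from a contiguous land band and crosses both the
  30 m and 200 m levels, so shelf-break derivatives are well defined;
* the habitat truth is a log-linear (Gibbs) probability surface over sea
  cells — the same model family the fitter estimates;
* observer bias is a single Gaussian bump centred on a "port", reproducing
  the clustered-sampling problem that target-group background corrects;
* strandings are drawn from configured cause/condition/zone/year
  distributions along the coast.

Coordinates live on an abstract equal-area plane; cell centers are the
sampling locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .errors import ConfigurationError, DegenerateInputError
from .grids import GridSpec, RasterLayer
from .records import GUILDS, SEASON_MONTHS

__all__ = [
    "WorldConfig",
    "TruthModel",
    "StrandingParams",
    "make_world",
    "make_bias_field",
    "make_truth_surface",
    "sample_sightings",
    "sample_strandings",
    "degrade_records",
]

#: per-variable (mean level, gradient amplitude, gradient axis, noise
#: amplitude, seasonal amplitude, seasonal phase month); distinct gradient
#: axes keep the fields from being mutually collinear
_VARIABLE_STYLES = {
    "sst": (12.0, 4.0, "x", 1.0, 3.0, 8.0),
    "chlorophyll": (2.0, 1.0, "y", 0.6, 1.2, 5.0),
    "salinity": (34.0, 1.5, "xy", 0.4, 0.5, 2.0),
}


@dataclass(frozen=True)
class WorldConfig:
    """Shape and content of the synthetic region.

    Defaults give a 45x60 grid of 4-length-unit cells (the analysis
    resolution), three dynamic variables over 12 months, and a maximum depth
    of 400 so the 30 and 200 isobaths both exist.
    """

    n_rows: int = 45
    n_cols: int = 60
    cell_size: float = 4.0
    variables: tuple[str, ...] = ("sst", "chlorophyll", "salinity")
    n_months: int = 12
    max_depth: float = 400.0
    land_rows: int = 5
    smoothness: float = 4.0
    planar_bathymetry: bool = False

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ConfigurationError("grid must be at least 10x10")
        if len(self.variables) < 3:
            raise ConfigurationError("need at least 3 dynamic variables")
        if self.n_months != 12:
            raise ConfigurationError("a world spans 12 months")

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            origin_x=0.0,
            origin_y=self.n_rows * self.cell_size,
        )


@dataclass(frozen=True)
class TruthModel:
    """Known data-generating habitat model.

    ``coefficients`` map predictor names to log-linear weights (the
    data-generating analogue of the fitted model's coefficient vector);
    ``bias_center``/``bias_spread`` parametrize the Gaussian observer-bias
    bump in plane coordinates.
    """

    coefficients: dict[str, float]
    bias_center: tuple[float, float]
    bias_spread: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ConfigurationError("truth needs at least one nonzero coefficient")
        if self.bias_spread <= 0:
            raise ConfigurationError("bias_spread must be positive")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_world(
    config: WorldConfig, seed: int
) -> tuple[dict[tuple[str, int], RasterLayer], RasterLayer, RasterLayer]:
    """Generate monthly environmental layers, bathymetry, and a land mask.

    Returns ``(monthly, bathymetry, land)`` where ``monthly`` maps
    ``(variable, month)`` (month 1..12) to a layer, ``bathymetry`` holds
    positive depths on sea cells (NaN on land), and ``land`` is 1 on land /
    0 at sea. Identical ``(config, seed)`` reproduce the world bitwise.
    """
    rng = np.random.default_rng(seed)
    spec = config.grid_spec()
    rows = np.arange(config.n_rows)[:, None] * np.ones((1, config.n_cols))
    cols = np.ones((config.n_rows, 1)) * np.arange(config.n_cols)[None, :]

    # contiguous land band along the top with a gently wandering coastline
    coast_wiggle = 2.0 * np.sin(2 * np.pi * np.arange(config.n_cols) / config.n_cols)
    coast_row = config.land_rows + coast_wiggle
    land = (rows < coast_row[None, :]).astype(float)
    sea = land == 0

    # depth grows with distance from land; crosses 30 and 200 by construction
    dist_from_land = distance_transform_edt(sea)
    max_dist = dist_from_land.max()
    if config.planar_bathymetry:
        depth = config.max_depth * dist_from_land / max_dist
    else:
        depth = config.max_depth * (dist_from_land / max_dist) ** 1.2
        depth = depth * (1.0 + 0.15 * _smooth_field(rng, spec.shape, config.smoothness))
        depth = np.clip(depth, 0.0, None)
        # guarantee both isobaths exist whatever the noise did
        depth[-1, :] = np.maximum(depth[-1, :], 250.0)
    bathy_vals = np.where(sea, depth, np.nan)
    bathymetry = RasterLayer(spec=spec, name="bathymetry", values=bathy_vals, units="m")
    land_layer = RasterLayer(spec=spec, name="land", values=land, units="")

    monthly: dict[tuple[str, int], RasterLayer] = {}
    gx = (cols / max(config.n_cols - 1, 1) - 0.5) * 2.0
    gy = (rows / max(config.n_rows - 1, 1) - 0.5) * 2.0
    gradients = {"x": gx, "y": gy, "xy": (gx + gy) / np.sqrt(2.0)}
    axes = ["x", "y", "xy"]
    for vi, var in enumerate(config.variables):
        mean, grad_amp, axis, noise_amp, seas_amp, phase = _VARIABLE_STYLES.get(
            var, (0.0, 1.0, axes[vi % 3], 0.5, 1.0, 6.0)
        )
        base = (
            mean
            + grad_amp * gradients[axis]
            + noise_amp * _smooth_field(rng, spec.shape, config.smoothness)
        )
        for month in range(1, config.n_months + 1):
            seasonal = seas_amp * math.sin(2 * np.pi * (month - phase) / 12.0)
            wobble = 0.1 * noise_amp * _smooth_field(rng, spec.shape, config.smoothness)
            vals = np.where(sea, base + seasonal + wobble, np.nan)
            monthly[(var, month)] = RasterLayer(
                spec=spec, name=var, values=vals, season=None, units=""
            )
    return monthly, bathymetry, land_layer


def make_bias_field(truth: TruthModel, spec: GridSpec) -> RasterLayer:
    """Gaussian observer-effort bump centred on the truth's port location."""
    xs, ys = spec.cell_centers()
    cx, cy = truth.bias_center
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    vals = np.exp(-d2 / (2.0 * truth.bias_spread**2))
    return RasterLayer(spec=spec, name="observer_bias", values=vals)


def make_truth_surface(
    truth: TruthModel, env_layers: dict[str, RasterLayer]
) -> RasterLayer:
    """Log-linear habitat probability over sea cells.

    ``p(cell) ∝ exp(Σ_v coef_v · env_v(cell))`` normalized to sum 1 over sea
    (non-NaN) cells; land cells stay NaN. Layer values are used as given —
    scale them before building the truth if the coefficients assume it.
    """
    for var in truth.coefficients:
        if var not in env_layers:
            raise ConfigurationError(f"truth variable {var!r} not among layers")
    first = next(iter(env_layers.values()))
    spec = first.spec
    lin = np.zeros(spec.shape)
    sea = np.ones(spec.shape, dtype=bool)
    for var, coef in truth.coefficients.items():
        layer = env_layers[var]
        sea &= layer.mask
        lin = lin + coef * np.where(layer.mask, layer.values, 0.0)
    lin = np.where(sea, lin, -np.inf)
    lin -= lin[sea].max()  # stabilize the exponential
    p = np.exp(lin)
    p[~sea] = 0.0
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError("truth surface has zero total probability")
    p /= total
    vals = np.where(sea, p, np.nan)
    return RasterLayer(spec=spec, name="truth", values=vals)


_SPECIES_POOL = {
    "large pelagic fishes": [("Cetorhinus maximus", "Cetorhinidae")],
    "cetaceans": [("Phocoena phocoena", "Phocoenidae"),
                  ("Delphinus delphis", "Delphinidae")],
    "pelagic seabirds": [("Morus bassanus", "Sulidae"), ("Uria aalge", "Alcidae")],
    "marine turtles": [("Dermochelys coriacea", "Dermochelyidae")],
    "pinnipeds": [("Halichoerus grypus", "Phocidae")],
}


def _random_dates(rng, n, season, years=(2002, 2011)):
    months = rng.choice(SEASON_MONTHS[season], size=n)
    yrs = rng.integers(years[0], years[1] + 1, size=n)
    days = rng.integers(1, 29, size=n)  # day 1..28 avoids month-length logic
    return [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(yrs, months, days)]


def sample_sightings(
    truth_surface: RasterLayer,
    bias: RasterLayer,
    n: int,
    guild: str,
    season: str,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` presence-only sightings with probability ∝ truth × bias.

    Records land at cell centers of sea cells; dates fall inside the season's
    months; sea state is drawn from 0..3 (the post-QC range).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec = truth_surface.spec
    p = np.where(truth_surface.mask, truth_surface.values, 0.0) * np.where(
        bias.mask, bias.values, 0.0
    )
    p = p.ravel()
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError("truth × bias probability is zero everywhere")
    cells = rng.choice(p.size, size=n, p=p / total)
    r, c = np.unravel_index(cells, spec.shape)
    xs = spec.origin_x + (c + 0.5) * spec.cell_size
    ys = spec.origin_y - (r + 0.5) * spec.cell_size
    pool = _SPECIES_POOL.get(guild, [("Genus species", "Familidae")])
    picks = rng.integers(0, len(pool), size=n)
    return pd.DataFrame(
        {
            "species": [pool[i][0] for i in picks],
            "family": [pool[i][1] for i in picks],
            "guild": guild,
            "date": _random_dates(rng, n, season),
            "x": xs,
            "y": ys,
            "record_type": "sighting",
            "condition": "alive",
            "sea_state": rng.integers(0, 4, size=n),
            "cause": "",
            "taxon_rank": "species",
            "zone": "",
        }
    )


@dataclass(frozen=True)
class StrandingParams:
    """Distributions governing synthetic strandings records."""

    n: int = 200
    cause_probs: dict[str, float] = field(
        default_factory=lambda: {
            "bycatch": 0.10,
            "entanglement": 0.05,
            "ship strike": 0.03,
            "direct killing": 0.02,
            "disease": 0.10,
            "starvation": 0.08,
            "physical trauma": 0.07,
            "undetermined": 0.55,
        }
    )
    year_range: tuple[int, int] = (2002, 2011)
    zone_weights: dict[str, float] = field(
        default_factory=lambda: {"west": 0.5, "east": 0.3, "north": 0.2}
    )
    alive_prob: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.cause_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cause probabilities must sum to 1")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError("empty year range")


def sample_strandings(
    params: StrandingParams,
    land: RasterLayer,
    seed: int,
) -> pd.DataFrame:
    """Draw strandings along the coast with configured cause/zone/year mixes.

    Coastal cells are sea cells 4-adjacent to land; zones partition the coast
    into vertical thirds (west / east / north left-to-right) for the zone mix.
    """
    rng = np.random.default_rng(seed)
    spec = land.spec
    is_land = land.values == 1
    sea = ~is_land
    padded = np.pad(is_land, 1, mode="edge")
    near_land = (
        padded[:-2, 1:-1] | padded[2:, 1:-1] | padded[1:-1, :-2] | padded[1:-1, 2:]
    )
    coastal = sea & near_land
    coast_r, coast_c = np.nonzero(coastal)
    if coast_r.size == 0:
        raise DegenerateInputError("no coastal cells")

    zone_labels = list(params.zone_weights)
    zone_p = np.array([params.zone_weights[z] for z in zone_labels], dtype=float)
    zone_p = zone_p / zone_p.sum()
    thirds = np.minimum((coast_c * len(zone_labels)) // spec.n_cols, len(zone_labels) - 1)

    causes = list(params.cause_probs)
    cause_p = np.array([params.cause_probs[c] for c in causes])

    rows = []
    for _ in range(params.n):
        zi = rng.choice(len(zone_labels), p=zone_p)
        candidates = np.nonzero(thirds == zi)[0]
        if candidates.size == 0:
            candidates = np.arange(coast_r.size)
        k = rng.choice(candidates)
        r, c = coast_r[k], coast_c[k]
        guild = GUILDS[rng.integers(0, len(GUILDS))]
        species, family = _SPECIES_POOL[guild][
            rng.integers(0, len(_SPECIES_POOL[guild]))
        ]
        year = int(rng.integers(params.year_range[0], params.year_range[1] + 1))
        month = int(rng.integers(1, 13))
        rows.append(
            {
                "species": species,
                "family": family,
                "guild": guild,
                "date": f"{year:04d}-{month:02d}-{int(rng.integers(1, 29)):02d}",
                "x": spec.origin_x + (c + 0.5) * spec.cell_size,
                "y": spec.origin_y - (r + 0.5) * spec.cell_size,
                "record_type": "stranding",
                "condition": "alive" if rng.random() < params.alive_prob else "dead",
                "sea_state": np.nan,
                "cause": causes[rng.choice(len(causes), p=cause_p)],
                "taxon_rank": "species",
                "zone": zone_labels[zi],
            }
        )
    return pd.DataFrame(rows)


def degrade_records(
    records: pd.DataFrame, rate: float, seed: int, bounds_pad: float = 50.0
) -> pd.DataFrame:
    """Inject archive-style defects for exercising QC.

    A fraction ``rate`` of rows (rounded down, at least 1 if rate>0) gets one
    defect each, cycling through: sea state >3, blank family, out-of-bounds
    location, unparseable date.
    """
    out = records.copy().reset_index(drop=True)
    if rate <= 0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    n_bad = max(1, int(rate * len(out)))
    idx = rng.choice(len(out), size=min(n_bad, len(out)), replace=False)
    out["sea_state"] = out["sea_state"].astype(float)
    out["date"] = out["date"].astype(object)
    for j, i in enumerate(idx):
        kind = j % 4
        if kind == 0:
            out.loc[i, "sea_state"] = float(rng.integers(4, 8))
        elif kind == 1:
            out.loc[i, "family"] = ""
        elif kind == 2:
            out.loc[i, "x"] = float(out["x"].max()) + bounds_pad
        else:
            out.loc[i, "date"] = "not-a-date"
    return out
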