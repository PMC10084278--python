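"""Synthetic deforestation-frontier scene generator.

Every downstream stage of the package — covariate engineering, spatially
decorrelated sampling, logistic conversion modelling, Monte Carlo
projection, map validation and fragmentation metrics — is exercisable on
scenes from this module, with the generative parameters (the true logit
coefficients in particular) recorded so parameter recovery can be checked
against ground truth.

A scene consists of:

* a t0 land-cover map: forest where a spatially autocorrelated field
  exceeds the quantile matching ``forest_fraction_t0``; the remainder is
  agriculture apart from small water / wetland / built / bare-soil blobs;
* a covariate stack covering the standard variable roles of frontier
  land-use-change models (terrain and suitability fields, Euclidean
  distances to roads, rivers, cities, fires, mines, existing agriculture
  and proposed rail, fire density, municipality-level zone proxies, PADDD
  and settlement indicator masks, a protected-area disc with two
  surrounding buffer rings, and the nonforest-neighbourhood share);
* a t1 map in which each forest cell converts to agriculture independently
  with probability ``inverse-logit(beta · x)`` — a Bernoulli conversion
  process whose per-pixel rate defaults to about 5% per epoch.

Continuous covariates are stored in the stack z-scored over valid cells,
with the affine transform frozen in layer provenance so that dynamic layers
recomputed during forward projection stay on the fitted scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .covariates import (
    BUFFER_CODES,
    CovariateStack,
    buffer_zones,
    distance_to,
    neighborhood_nonforest,
    point_density,
    zonal_value,
)
from .grids import (
    DEFAULT_CLASS_LABELS,
    ContinuousSurface,
    GridGeometry,
    LandCoverMap,
    write_landcover,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticScene",
    "correlated_field",
    "scatter_points",
    "make_zones",
    "make_scene",
    "DEFAULT_BETA",
]


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def inv_logit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


#: Default true coefficients (z-scored covariate scale, logit link).  The
#: intercept pins the baseline per-pixel conversion probability near 5% per
#: epoch; both "classical" land-use-change covariates (terrain, roads,
#: neighbourhood) and "frontier-narrative" covariates (distance to
#: agriculture, fire density, unallocated public land) carry signal so the
#: four-model comparison is meaningful on default scenes.
DEFAULT_BETA: dict[str, float] = {
    "intercept": logit(0.05),
    "elevation": -0.4,
    "slope": -0.25,
    "soil_moisture": -0.25,
    "dist_road": -0.3,
    "dist_agriculture": -0.5,
    "fire_density": 0.4,
    "unallocated_land": 0.3,
    "nonforest_neighborhood": 0.4,
    "buffer_10km": 0.3,
}

DEFAULT_FIELD_PARAMS: dict[str, dict] = {
    "elevation": {"mean": 250.0, "sd": 80.0, "range_m": 900.0},
    "slope": {"mean": 5.0, "sd": 3.0, "range_m": 450.0},
    "soil_moisture": {"mean": 12.0, "sd": 3.0, "range_m": 600.0},
    "precipitation": {"mean": 5.5, "sd": 0.8, "range_m": 1200.0},
    "crop_suitability": {"mean": 50.0, "sd": 15.0, "range_m": 750.0},
}

DEFAULT_POINT_INTENSITIES: dict[str, float] = {"fires": 2.0, "mines": 0.2}

#: Target fractions of the landscape for the minor land-cover classes.
MINOR_CLASS_FRACTIONS: dict[str, float] = {
    "water": 0.01,
    "wetland": 0.01,
    "built": 0.005,
    "bare_soil": 0.02,
}


@dataclass
class GeneratorConfig:
    """Everything needed to regenerate a scene deterministically."""

    geometry: GridGeometry = dc_field(
        default_factory=lambda: GridGeometry(n_rows=200, n_cols=200, cell_size=30.0,
                                             origin_y=200 * 30.0)
    )
    seed: int = 0
    beta: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_BETA))
    field_params: dict[str, dict] = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIELD_PARAMS.items()}
    )
    point_intensities: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_POINT_INTENSITIES)
    )
    n_zones: int = 3
    pa_fraction: float = 0.25
    forest_fraction_t0: float = 0.7
    #: Buffer-ring distances around the protected area, metres.  Desk-scale
    #: scenes are a few kilometres across, so the rings default to a scaled
    #: analogue of the 10-km / 20-km field design.
    ring_distances: tuple[float, float] = (1_000.0, 2_000.0)
    density_radius_km: float = 1.0
    neighborhood_radius: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.forest_fraction_t0 <= 1.0):
            raise ValueError("forest_fraction_t0 must lie in (0, 1]")
        if any(v < 0 for v in self.point_intensities.values()):
            raise ValueError("point intensities must be non-negative")

    def to_json_dict(self) -> dict:
        g = self.geometry
        return {
            "geometry": {
                "n_rows": g.n_rows, "n_cols": g.n_cols, "cell_size": g.cell_size,
                "origin_x": g.origin_x, "origin_y": g.origin_y,
                "nodata_code": g.nodata_code,
            },
            "seed": self.seed,
            "beta": self.beta,
            "field_params": self.field_params,
            "point_intensities": self.point_intensities,
            "n_zones": self.n_zones,
            "pa_fraction": self.pa_fraction,
            "forest_fraction_t0": self.forest_fraction_t0,
            "ring_distances": list(self.ring_distances),
            "density_radius_km": self.density_radius_km,
            "neighborhood_radius": self.neighborhood_radius,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = GridGeometry(**d["geometry"])
        if "ring_distances" in d:
            d["ring_distances"] = tuple(d["ring_distances"])
        return cls(**d)


@dataclass
class SyntheticScene:
    """A generated two-epoch landscape with known conversion process."""

    map_t0: LandCoverMap
    map_t1: LandCoverMap
    stack: CovariateStack
    truth: GeneratorConfig
    conversion_probabilities: ContinuousSurface
    points: dict[str, np.ndarray] = dc_field(default_factory=dict)
    zone_map: np.ndarray | None = None
    zone_attributes: pd.DataFrame | None = None
    pa_mask: np.ndarray | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_landcover(self.map_t0, directory / "landcover_t0.asc")
        write_landcover(self.map_t1, directory / "landcover_t1.asc")
        self.stack.save(directory / "stack")
        (directory / "truth.json").write_text(
            json.dumps(self.truth.to_json_dict(), indent=2)
        )
        features = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {"set": name},
                }
                for name, pts in self.points.items()
                for x, y in np.atleast_2d(pts)
            ],
        }
        (directory / "points.geojson").write_text(json.dumps(features))
        if self.zone_attributes is not None:
            self.zone_attributes.to_csv(directory / "zone_attributes.csv")


def correlated_field(
    geometry: GridGeometry, range_m: float, seed: int, name: str = "field"
) -> ContinuousSurface:
    """Spatially autocorrelated standard-normal surface.

    Seeded white noise is smoothed with an isotropic Gaussian kernel whose
    bandwidth is ``range_m`` (in cell units) and the result is re-standardised
    to exactly zero mean / unit variance, so the empirical autocorrelation
    decays on the order of ``range_m``.
    """
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(geometry.shape)
    sigma_cells = range_m / geometry.cell_size
    smooth = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return ContinuousSurface(geometry, smooth, name=name, units="z")


def scatter_points(geometry: GridGeometry, intensity: float, seed: int) -> np.ndarray:
    """Homogeneous Poisson point process over the landscape extent.

    *intensity* is the expected number of points per km²; the count is
    Poisson(intensity × landscape area) and locations are uniform.
    Returns an ``(n, 2)`` array of planar ``(x, y)`` coordinates.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * geometry.extent_km2)
    width = geometry.n_cols * geometry.cell_size
    height = geometry.n_rows * geometry.cell_size
    x = geometry.origin_x + rng.uniform(0.0, width, n)
    y = geometry.origin_y - rng.uniform(0.0, height, n)
    return np.column_stack([x, y]) if n else np.empty((0, 2))


def make_zones(
    geometry: GridGeometry, n_zones: int, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Nearest-seed-point partition of the grid into contiguous zones.

    Emulates municipality-scale proxies: each zone carries draws for the
    share of unallocated public land, cattle density, population density
    and a poverty rate, returned as a DataFrame indexed by zone id.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    rng = np.random.default_rng(seed)
    width = geometry.n_cols * geometry.cell_size
    height = geometry.n_rows * geometry.cell_size
    seeds_xy = np.column_stack(
        [
            geometry.origin_x + rng.uniform(0, width, n_zones),
            geometry.origin_y - rng.uniform(0, height, n_zones),
        ]
    )
    x, y = geometry.cell_centers()
    _, zone = cKDTree(seeds_xy).query(np.column_stack([x.ravel(), y.ravel()]))
    zone_map = zone.reshape(geometry.shape).astype(np.int32)
    attrs = pd.DataFrame(
        {
            "unallocated_land": rng.uniform(0.0, 1.0, n_zones),
            "cattle_density": rng.lognormal(2.5, 0.6, n_zones),
            "population_density": rng.lognormal(2.0, 0.8, n_zones),
            "poverty_rate": rng.uniform(0.1, 0.6, n_zones),
        },
        index=pd.RangeIndex(n_zones, name="zone"),
    )
    return zone_map, attrs


def _transect_points(geometry: GridGeometry, rng: np.random.Generator) -> np.ndarray:
    """Points sampled densely along a random straight transect of the map."""
    width = geometry.n_cols * geometry.cell_size
    height = geometry.n_rows * geometry.cell_size
    x0, y0 = geometry.origin_x, geometry.origin_y
    if rng.uniform() < 0.5:  # left-right crossing
        a = np.array([x0, y0 - rng.uniform(0, height)])
        b = np.array([x0 + width, y0 - rng.uniform(0, height)])
    else:  # top-bottom crossing
        a = np.array([x0 + rng.uniform(0, width), y0])
        b = np.array([x0 + rng.uniform(0, width), y0 - height])
    n = int(np.ceil(np.linalg.norm(b - a) / (geometry.cell_size / 2.0))) + 1
    t = np.linspace(0.0, 1.0, n)[:, None]
    return a + t * (b - a)


def _blob_mask(
    geometry: GridGeometry, fraction: float, range_m: float, seed: int
) -> np.ndarray:
    """Contiguous blobs covering about *fraction* of the landscape."""
    f = correlated_field(geometry, range_m, seed).values
    thr = np.quantile(f, 1.0 - fraction)
    return f > thr


def _zscore(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(values[valid].mean())
    sd = float(values[valid].std())
    if sd == 0:
        sd = 1.0
    return (values - mean) / sd, mean, sd


def make_scene(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticScene:
    """Generate a full synthetic scene; deterministic under (config, seed)."""
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config.seed = seed
    geom = config.geometry
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(24)]
    forest_code = 1
    ag_code = 2
    labels = dict(DEFAULT_CLASS_LABELS)
    code_of = {v: k for k, v in labels.items()}

    # --- t0 land cover ------------------------------------------------
    forest_field = correlated_field(geom, 12 * geom.cell_size, seeds[0]).values
    thr = np.quantile(forest_field, 1.0 - config.forest_fraction_t0)
    forest0 = forest_field > thr
    cells0 = np.where(forest0, forest_code, ag_code).astype(np.int32)
    minor_field = correlated_field(geom, 4 * geom.cell_size, seeds[1]).values
    nonforest = ~forest0
    if nonforest.any():
        # carve minor-class blobs out of the nonforest matrix by quantile
        # bands of a smooth field, so each class forms contiguous patches
        mf = minor_field[nonforest]
        lo = 0.0
        nonforest_share = nonforest.mean()
        for cls, frac in MINOR_CLASS_FRACTIONS.items():
            band = min(frac / nonforest_share, 1.0 - lo)
            if band <= 0:
                break
            q0, q1 = np.quantile(mf, [lo, min(lo + band, 1.0)])
            sel = nonforest & (minor_field >= q0) & (minor_field < q1)
            cells0[sel] = code_of[cls]
            lo += band
    map_t0 = LandCoverMap(geom, cells0, labels)

    # --- feature sets -------------------------------------------------
    rng_lines = np.random.default_rng(seeds[2])
    roads = np.vstack([_transect_points(geom, rng_lines) for _ in range(2)])
    railroad = _transect_points(geom, rng_lines)
    river = _transect_points(geom, rng_lines)
    def at_least_one(pts: np.ndarray, seed: int) -> np.ndarray:
        # distance covariates need a nonempty feature set even on tiny scenes
        if len(pts):
            return pts
        r = np.random.default_rng(seed)
        return np.array(
            [[geom.origin_x + r.uniform(0, geom.n_cols * geom.cell_size),
              geom.origin_y - r.uniform(0, geom.n_rows * geom.cell_size)]]
        )

    cities = at_least_one(scatter_points(geom, 0.1, seeds[3]), seeds[3])
    fires = at_least_one(
        scatter_points(geom, config.point_intensities.get("fires", 0.0), seeds[4]),
        seeds[4],
    )
    mines = at_least_one(
        scatter_points(geom, config.point_intensities.get("mines", 0.0), seeds[5]),
        seeds[5],
    )

    zone_map, zone_attrs = make_zones(geom, config.n_zones, seeds[6])

    # protected area: central disc covering pa_fraction of the landscape
    x, y = geom.cell_centers()
    cx = geom.origin_x + geom.n_cols * geom.cell_size / 2.0
    cy = geom.origin_y - geom.n_rows * geom.cell_size / 2.0
    pa_radius = np.sqrt(config.pa_fraction * geom.extent_km2 / np.pi) * 1000.0
    pa_mask = (x - cx) ** 2 + (y - cy) ** 2 <= pa_radius**2
    zones = buffer_zones(pa_mask, geom, config.ring_distances)

    paddd = _blob_mask(geom, 0.10, 8 * geom.cell_size, seeds[7])
    settlement = _blob_mask(geom, 0.08, 8 * geom.cell_size, seeds[8])

    # --- covariate stack ---------------------------------------------
    valid = map_t0.valid_mask
    stack = CovariateStack(geom)

    def add_z(name: str, values: np.ndarray, role: str, dynamic: bool = False, **params):
        z, mean, sd = _zscore(np.asarray(values, dtype=float), valid)
        stack.add(name, z, dynamic=dynamic, role=role,
                  transform={"mean": mean, "sd": sd}, **params)

    for fname, fp in config.field_params.items():
        raw = fp["mean"] + fp["sd"] * correlated_field(
            geom, fp["range_m"], seeds[9 + list(config.field_params).index(fname)]
        ).values
        add_z(fname, raw, role="LUC", kind="field", range_m=fp["range_m"])

    add_z("dist_road", distance_to(roads, geom).values, role="LUC", kind="distance")
    add_z("dist_river", distance_to(river, geom).values, role="LUC", kind="distance")
    add_z("dist_city", distance_to(cities, geom).values, role="LUC", kind="distance")
    add_z(
        "population_density",
        zonal_value(zone_map, zone_attrs, "population_density", geom).values,
        role="LUC",
        kind="zonal",
    )
    add_z(
        "nonforest_neighborhood",
        neighborhood_nonforest(map_t0, config.neighborhood_radius).values,
        role="LUC",
        dynamic=True,
        op="neighborhood_nonforest",
        window_radius=config.neighborhood_radius,
    )
    add_z(
        "dist_agriculture",
        distance_to(map_t0.class_mask("agriculture"), geom).values,
        role="DA",
        dynamic=True,
        op="distance_to_class",
        target_class="agriculture",
    )
    add_z("dist_fires", distance_to(fires, geom).values, role="DA", kind="distance")
    add_z(
        "fire_density",
        point_density(fires, geom, config.density_radius_km).values,
        role="DA",
        kind="density",
        radius_km=config.density_radius_km,
    )
    add_z("dist_mines", distance_to(mines, geom).values, role="DA", kind="distance")
    add_z("dist_railroad", distance_to(railroad, geom).values, role="DA", kind="distance")
    add_z(
        "unallocated_land",
        zonal_value(zone_map, zone_attrs, "unallocated_land", geom).values,
        role="DA",
        kind="zonal",
    )
    add_z(
        "cattle_density",
        zonal_value(zone_map, zone_attrs, "cattle_density", geom).values,
        role="DA",
        kind="zonal",
    )
    stack.add("paddd", paddd.astype(float), role="DA", kind="indicator")
    stack.add("settlement", settlement.astype(float), role="DA", kind="indicator")
    for ring in ("buffer_10km", "buffer_20km", "outside"):
        stack.add(
            ring,
            (zones == BUFFER_CODES[ring]).astype(float),
            role="both",
            kind="indicator",
        )

    # --- conversion process ------------------------------------------
    missing = [t for t in config.beta if t != "intercept" and t not in stack]
    if missing:
        raise ValueError(f"beta references ungenerated covariates: {missing}")
    eta = np.full(geom.shape, config.beta.get("intercept", 0.0))
    for term, b in config.beta.items():
        if term == "intercept":
            continue
        eta = eta + b * stack[term]
    p = inv_logit(eta)
    rng_conv = np.random.default_rng(seeds[20])
    u = rng_conv.uniform(size=geom.shape)
    convert = forest0 & (u < p)
    cells1 = cells0.copy()
    cells1[convert] = ag_code
    map_t1 = LandCoverMap(geom, cells1, labels)

    prob = np.where(forest0, p, np.nan)
    return SyntheticScene(
        map_t0=map_t0,
        map_t1=map_t1,
        stack=stack,
        truth=config,
        conversion_probabilities=ContinuousSurface(geom, prob, name="p_conversion"),
        points={"roads": roads, "railroad": railroad, "river": river,
                "cities": cities, "fires": fires, "mines": mines},
        zone_map=zone_map,
        zone_attributes=zone_attrs,
        pa_mask=pa_mask,
    )
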