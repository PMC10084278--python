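"""Spatial covariate engineering.

Builds the proxy surfaces a frontier land-use-change model consumes:
Euclidean distance to features (roads, rivers, agriculture, fires, mines,
proposed infrastructure), disc-count point densities (fires per km²),
neighbourhood land-cover composition, zone-level attribute rasters
(municipality proxies such as the share of unallocated public land), and the
protected-area / 10-km / 20-km buffer-ring surface.

All distances are planar Euclidean between cell centres (or cell centre and
point) in projected metres; no geodesy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import (
    ContinuousSurface,
    GridAlignmentError,
    GridGeometry,
    LandCoverMap,
    _require_aligned,
)

__all__ = [
    "CovariateStack",
    "BUFFER_CODES",
    "distance_to",
    "point_density",
    "neighborhood_nonforest",
    "zonal_value",
    "buffer_zones",
    "assemble_stack",
]

#: Codes of the protected-area buffer-zone surface.
BUFFER_CODES = {"inside_pa": 0, "buffer_10km": 1, "buffer_20km": 2, "outside": 3}


class EmptyTargetError(ValueError):
    """Distance to an empty target set is undefined."""


def distance_to(
    target: np.ndarray | "tuple | list | np.ndarray",
    geometry: GridGeometry,
    name: str = "distance",
) -> ContinuousSurface:
    """Minimum Euclidean distance (m) from each cell centre to a target.

    *target* is either a boolean cell mask (distance measured centre to
    centre, exact via the sampled Euclidean distance transform) or an
    ``(n, 2)`` array of planar ``(x, y)`` points.  Cells on the target have
    distance 0.
    """
    if isinstance(target, np.ndarray) and target.dtype == bool:
        if target.shape != geometry.shape:
            raise GridAlignmentError("target mask shape does not match geometry")
        if not target.any():
            raise EmptyTargetError("distance to an empty cell mask is undefined")
        dist = ndimage.distance_transform_edt(
            ~target, sampling=(geometry.cell_size, geometry.cell_size)
        )
        return ContinuousSurface(geometry, dist, name=name, units="m")
    pts = np.atleast_2d(np.asarray(target, dtype=float))
    if pts.size == 0:
        raise EmptyTargetError("distance to an empty point set is undefined")
    if pts.shape[1] != 2:
        raise ValueError("point target must be an (n, 2) array of x, y")
    x, y = geometry.cell_centers()
    tree = cKDTree(pts)
    dist, _ = tree.query(np.column_stack([x.ravel(), y.ravel()]))
    return ContinuousSurface(geometry, dist.reshape(geometry.shape), name=name, units="m")


def point_density(
    points: np.ndarray,
    geometry: GridGeometry,
    radius_km: float = 5.0,
    name: str = "density",
) -> ContinuousSurface:
    """Disc-count point density (points per km²) around each cell centre.

    Counts points within ``radius_km`` of the cell centre and divides by the
    disc area ``pi * radius_km**2``.  An empty point set yields an all-zero
    surface.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    x, y = geometry.cell_centers()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        vals = np.zeros(geometry.shape)
    else:
        tree = cKDTree(pts)
        counts = tree.query_ball_point(
            np.column_stack([x.ravel(), y.ravel()]),
            r=radius_km * 1000.0,
            return_length=True,
        )
        vals = counts.reshape(geometry.shape) / (np.pi * radius_km**2)
    return ContinuousSurface(geometry, vals, name=name, units="per km2")


def neighborhood_nonforest(
    lc_map: LandCoverMap, window_radius: int = 1, forest_label: str = "forest"
) -> ContinuousSurface:
    """Percentage of surrounding cells carrying a nonforest class.

    For each cell the square window of half-width ``window_radius`` (the
    8-neighbourhood at radius 1), excluding the centre cell, is inspected;
    the value is ``100 * nonforest / valid`` neighbours.  Cells at the map
    border use their reduced neighbour count; nodata neighbours are ignored.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * window_radius + 1
    valid = lc_map.valid_mask
    nonforest = valid & ~lc_map.class_mask(forest_label)
    # integer box sums keep neighbour counts exact (no float filter round-off)
    kernel = np.ones((size, size), dtype=np.int64)
    box = lambda a: ndimage.convolve(
        a.astype(np.int64), kernel, mode="constant", cval=0
    )
    n_valid = box(valid) - valid.astype(np.int64)
    n_nonforest = box(nonforest) - nonforest.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_valid > 0, 100.0 * n_nonforest / n_valid, 0.0)
    return ContinuousSurface(lc_map.geometry, pct, name="nonforest_neighborhood", units="%")


def zonal_value(
    zone_map: np.ndarray,
    attributes: "dict | object",
    attribute: str,
    geometry: GridGeometry,
) -> ContinuousSurface:
    """Broadcast a per-zone attribute onto the grid (municipality proxies).

    *attributes* is a mapping ``zone id -> {attribute name -> value}`` or a
    pandas DataFrame indexed by zone id.  Every zone id present in
    *zone_map* must carry the attribute.
    """
    zone_map = np.asarray(zone_map)
    if zone_map.shape != geometry.shape:
        raise GridAlignmentError("zone map shape does not match geometry")
    zones = np.unique(zone_map)
    lut = {}
    for z in zones:
        try:
            if hasattr(attributes, "loc"):
                lut[int(z)] = float(attributes.loc[int(z), attribute])
            else:
                lut[int(z)] = float(attributes[int(z)][attribute])
        except (KeyError, IndexError) as exc:
            raise KeyError(
                f"zone {int(z)} has no attribute {attribute!r}"
            ) from exc
    vals = np.vectorize(lut.__getitem__, otypes=[float])(zone_map)
    return ContinuousSurface(geometry, vals, name=attribute)


def buffer_zones(
    pa_mask: np.ndarray,
    geometry: GridGeometry,
    ring_distances: tuple[float, ...] = (10_000.0, 20_000.0),
) -> np.ndarray:
    """Partition the landscape into protected area, buffer rings, and outside.

    Returns an integer surface with :data:`BUFFER_CODES`: 0 on the protected
    area itself, ring *k* on cells whose distance to the PA lies in
    ``(d_{k-1}, d_k]``, and the final code beyond the last ring.
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    if not pa_mask.any():
        raise EmptyTargetError("protected-area mask is empty")
    if list(ring_distances) != sorted(ring_distances) or len(set(ring_distances)) != len(
        ring_distances
    ):
        raise ValueError("ring_distances must be strictly increasing")
    dist = distance_to(pa_mask, geometry).values
    zones = np.full(geometry.shape, len(ring_distances) + 1, dtype=np.int32)
    for k in range(len(ring_distances) - 1, -1, -1):
        zones[dist <= ring_distances[k]] = k + 1
    zones[pa_mask] = 0
    return zones


@dataclass
class CovariateStack:
    """Named, co-registered covariate surfaces plus per-layer provenance.

    ``provenance[name]`` records how the layer was built; two keys matter
    downstream: ``dynamic`` (recomputed from the evolving land-cover map
    between projection steps — distance to agriculture and the nonforest
    neighbourhood share) and ``transform`` (a frozen ``(mean, sd)`` z-score
    applied after any raw recompute, so projected epochs stay on the scale
    the model was fitted on).
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def add(
        self,
        name: str,
        surface: ContinuousSurface | np.ndarray,
        dynamic: bool = False,
        role: str = "",
        **params,
    ) -> "CovariateStack":
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        values = surface.values if isinstance(surface, ContinuousSurface) else np.asarray(
            surface, dtype=float
        )
        if values.shape != self.geometry.shape:
            raise GridAlignmentError(f"layer {name!r} shape does not match stack geometry")
        if isinstance(surface, ContinuousSurface) and not surface.geometry.same_grid(
            self.geometry
        ):
            raise GridAlignmentError(f"layer {name!r} geometry does not match stack")
        self.layers[name] = values
        self.provenance[name] = {"dynamic": dynamic, "role": role, **params}
        return self

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def dynamic_names(self) -> list[str]:
        return [n for n, p in self.provenance.items() if p.get("dynamic")]

    def save(self, directory: str | Path) -> None:
        """Export every layer as an ASCII grid plus a JSON manifest."""
        from .grids import write_surface

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, values in self.layers.items():
            fname = f"{name}.asc"
            write_surface(
                ContinuousSurface(self.geometry, values, name=name), directory / fname
            )
            manifest[name] = {"file": fname, **self.provenance[name]}
        (directory / "stack_manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CovariateStack":
        from .grids import read_surface

        directory = Path(directory)
        manifest = json.loads((directory / "stack_manifest.json").read_text())
        stack = None
        for name, meta in manifest.items():
            surf = read_surface(directory / meta["file"], name=name)
            if stack is None:
                stack = cls(surf.geometry)
            params = {k: v for k, v in meta.items() if k not in {"file", "dynamic", "role"}}
            stack.add(name, surf, dynamic=meta.get("dynamic", False), role=meta.get("role", ""), **params)
        if stack is None:
            raise ValueError(f"empty stack manifest in {directory}")
        return stack


def assemble_stack(
    geometry: GridGeometry, **named_surfaces: ContinuousSurface | np.ndarray
) -> CovariateStack:
    """Bundle aligned surfaces into a :class:`CovariateStack`."""
    stack = CovariateStack(geometry)
    for name, surf in named_surfaces.items():
        stack.add(name, surf)
    return stack
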