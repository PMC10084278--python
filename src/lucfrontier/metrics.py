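"""Class-level fragmentation and connectivity metrics.

Patches are maximal 8-connected components of one land-cover class.  Per
patch, area is cell count × cell area; perimeter counts cell faces adjacent
to a different class or to the map border, times the cell size; a core cell
is one whose full 8-neighbourhood (edge depth of one cell) is same-class
and inside the map.  From these the class-level metric suite is computed:
patch count, mean patch area, class area, core-area index, core area as a
share of the landscape, landscape division, fractal dimension index,
perimeter-area fractal dimension (PAFRAC), perimeter:area ratio, percent of
landscape occupied, total core area and total edge.  The landscape area
denominator is all non-nodata cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LandCoverMap

__all__ = ["PatchSet", "MetricsReport", "label_patches", "class_metrics"]

EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class PatchSet:
    """Per-patch geometry for one class of one landscape."""

    class_label: str
    labels: np.ndarray  # 0 = background, 1..n = patch id
    n_patches: int
    cell_counts: np.ndarray  # cells per patch
    perimeters_m: np.ndarray  # metres per patch
    core_cells: np.ndarray  # core cells per patch
    cell_size: float
    landscape_cells: int  # non-nodata cells in the landscape

    @property
    def areas_ha(self) -> np.ndarray:
        return self.cell_counts * self.cell_size**2 / 10_000.0

    @property
    def core_areas_ha(self) -> np.ndarray:
        return self.core_cells * self.cell_size**2 / 10_000.0

    @property
    def landscape_area_ha(self) -> float:
        return self.landscape_cells * self.cell_size**2 / 10_000.0


def label_patches(lc_map: LandCoverMap, class_label: str = "forest") -> PatchSet:
    """Label maximal 8-connected patches of *class_label* with geometry.

    Diagonal adjacency joins patches (8-cell neighbour rule).  An absent
    class yields an empty PatchSet; downstream ratio metrics are then
    flagged undefined rather than computed.
    """
    mask = lc_map.class_mask(class_label)
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n == 0:
        return PatchSet(
            class_label=class_label,
            labels=labels,
            n_patches=0,
            cell_counts=np.empty(0, dtype=np.int64),
            perimeters_m=np.empty(0),
            core_cells=np.empty(0, dtype=np.int64),
            cell_size=lc_map.geometry.cell_size,
            landscape_cells=int(lc_map.valid_mask.sum()),
        )
    cell_counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    # perimeter: faces against a different class or the map border
    face_count = np.zeros(n + 1, dtype=np.int64)
    padded = np.pad(mask, 1, constant_values=False)
    lab_padded = np.pad(labels, 1, constant_values=0)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        exposed = mask & ~neigh
        face_count += np.bincount(labels[exposed], minlength=n + 1)
    perimeters = face_count[1:] * lc_map.geometry.cell_size
    # core: full 8-neighbourhood same class and inside the map
    core_mask = ndimage.binary_erosion(mask, structure=EIGHT, border_value=0)
    core_cells = np.bincount(labels[core_mask], minlength=n + 1)[1:]
    return PatchSet(
        class_label=class_label,
        labels=labels,
        n_patches=int(n),
        cell_counts=cell_counts.astype(np.int64),
        perimeters_m=perimeters.astype(float),
        core_cells=core_cells.astype(np.int64),
        cell_size=lc_map.geometry.cell_size,
        landscape_cells=int(lc_map.valid_mask.sum()),
    )


@dataclass
class MetricsReport:
    """The class-level metric suite for one landscape (NaN = undefined)."""

    class_label: str
    n_patches: int
    class_area_ha: float
    mean_patch_area_ha: float
    sd_patch_area_ha: float
    mean_core_area_index_pct: float
    sd_core_area_index_pct: float
    mean_core_area_ha: float
    sd_core_area_ha: float
    core_area_pct_landscape: float
    landscape_division_index: float
    mean_fractal_dimension: float
    sd_fractal_dimension: float
    perimeter_area_fractal_dimension: float
    mean_perimeter_area_ratio: float
    sd_perimeter_area_ratio: float
    pct_landscape_forested: float
    total_core_area_ha: float
    total_edge_m: float
    undefined_reasons: str = ""

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d

    @staticmethod
    def table(reports: dict[str, "MetricsReport"]) -> pd.DataFrame:
        """Stack reports (keyed by landscape name) into one table."""
        return pd.DataFrame({name: r.to_row() for name, r in reports.items()})


def class_metrics(patches: PatchSet) -> MetricsReport:
    """Compute the class-level metric suite from labelled patches."""
    n = patches.n_patches
    cs = patches.cell_size
    land_ha = patches.landscape_area_ha
    if n == 0:
        nanr = float("nan")
        return MetricsReport(
            class_label=patches.class_label,
            n_patches=0,
            class_area_ha=0.0,
            mean_patch_area_ha=nanr, sd_patch_area_ha=nanr,
            mean_core_area_index_pct=nanr, sd_core_area_index_pct=nanr,
            mean_core_area_ha=nanr, sd_core_area_ha=nanr,
            core_area_pct_landscape=0.0,
            landscape_division_index=1.0,
            mean_fractal_dimension=nanr, sd_fractal_dimension=nanr,
            perimeter_area_fractal_dimension=nanr,
            mean_perimeter_area_ratio=nanr, sd_perimeter_area_ratio=nanr,
            pct_landscape_forested=0.0,
            total_core_area_ha=0.0,
            total_edge_m=0.0,
            undefined_reasons="class absent: per-patch means undefined",
        )
    areas_ha = patches.areas_ha
    areas_m2 = patches.cell_counts.astype(float) * cs**2
    perims = patches.perimeters_m
    core_ha = patches.core_areas_ha
    class_area = float(areas_ha.sum())
    cai = 100.0 * core_ha / areas_ha
    # fractal dimension index per patch; exactly 1 for squares, and defined
    # as 1 when the log ratio degenerates (single 1 m² patch)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 2.0 * np.log(0.25 * perims) / np.log(areas_m2)
    frac = np.where(areas_m2 == 1.0, 1.0, frac)
    pa_ratio = perims / areas_m2
    reasons = []
    if n >= 2 and np.std(np.log(perims)) > 0:
        slope = np.polyfit(np.log(perims), np.log(areas_m2), 1)[0]
        pafrac = 2.0 / slope
    else:
        pafrac = float("nan")
        reasons.append(
            "PAFRAC undefined: needs >= 2 patches with distinct perimeters"
        )
    division = 1.0 - float(((areas_ha / land_ha) ** 2).sum())
    return MetricsReport(
        class_label=patches.class_label,
        n_patches=n,
        class_area_ha=class_area,
        mean_patch_area_ha=float(areas_ha.mean()),
        sd_patch_area_ha=float(areas_ha.std()),
        mean_core_area_index_pct=float(cai.mean()),
        sd_core_area_index_pct=float(cai.std()),
        mean_core_area_ha=float(core_ha.mean()),
        sd_core_area_ha=float(core_ha.std()),
        core_area_pct_landscape=100.0 * float(core_ha.sum()) / land_ha,
        landscape_division_index=division,
        mean_fractal_dimension=float(frac.mean()),
        sd_fractal_dimension=float(frac.std()),
        perimeter_area_fractal_dimension=float(pafrac),
        mean_perimeter_area_ratio=float(pa_ratio.mean()),
        sd_perimeter_area_ratio=float(pa_ratio.std()),
        pct_landscape_forested=100.0 * class_area / land_ha,
        total_core_area_ha=float(core_ha.sum()),
        total_edge_m=float(perims.sum()),
        undefined_reasons="; ".join(reasons),
    )
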