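"""Monte Carlo landscape projection and quota-constrained allocation.

Given a per-forest-cell conversion-probability surface, an ensemble of
landscapes is simulated by independent Bernoulli draws per forest cell; the
per-cell conversion counts across the ensemble rank cells for allocation.
A predicted map converts exactly the predetermined forest-loss area: forest
cells are ranked by (ensemble count desc, fitted probability desc,
row-major index) and the top cells become agriculture, all nonforest cells
persisting unchanged.  Forward projection recomputes the dynamic covariates
(distance to agriculture and the nonforest-neighbourhood share) from the
current map — on the frozen fitted scale — and repeats
predict → simulate → allocate with frozen coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .covariates import CovariateStack, distance_to, neighborhood_nonforest
from .grids import GridGeometry, LandCoverMap

__all__ = [
    "ProbabilitySurface",
    "EnsembleCounts",
    "AllocationResult",
    "simulate_ensemble",
    "allocate_quota",
    "update_dynamic_layers",
    "project_step",
]


@dataclass
class ProbabilitySurface:
    """Conversion probabilities on a forest mask; NaN elsewhere."""

    geometry: GridGeometry
    values: np.ndarray
    forest_mask: np.ndarray
    model_name: str = ""
    epoch: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.forest_mask = np.asarray(self.forest_mask, dtype=bool)
        on = self.values[self.forest_mask]
        if on.size and ((on < 0).any() or (on > 1).any() or np.isnan(on).any()):
            raise ValueError("probabilities on forest cells must lie in [0, 1]")

    @property
    def forest_probabilities(self) -> np.ndarray:
        return self.values[self.forest_mask]

    def expected_loss_area_ha(self) -> float:
        return float(self.forest_probabilities.sum()) * self.geometry.cell_area_ha


@dataclass
class EnsembleCounts:
    """Per-forest-cell conversion counts over a Monte Carlo ensemble."""

    geometry: GridGeometry
    counts: np.ndarray  # 2-D int array, 0 outside the forest mask
    forest_mask: np.ndarray
    S: int
    seed: int
    mean_loss_area_ha: float
    sd_loss_area_ha: float

    def run_record(self) -> dict:
        return {
            "S": self.S,
            "seed": self.seed,
            "mean_loss_area_ha": self.mean_loss_area_ha,
            "sd_loss_area_ha": self.sd_loss_area_ha,
        }


def simulate_ensemble(
    prob: ProbabilitySurface, S: int = 1000, seed: int = 0, chunk: int = 128
) -> EnsembleCounts:
    """Simulate *S* landscapes; each forest cell converts independently.

    Counts accumulate per cell; the loss area of each simulated landscape
    feeds the ensemble mean/sd deforestation rate.  Deterministic under
    ``(seed, S)``.
    """
    if S < 1:
        raise ValueError("ensemble size S must be >= 1")
    p = prob.forest_probabilities
    rng = np.random.default_rng(seed)
    counts = np.zeros(p.size, dtype=np.int64)
    losses = np.empty(S, dtype=np.int64)
    done = 0
    while done < S:
        m = min(chunk, S - done)
        draws = rng.random((m, p.size)) < p
        counts += draws.sum(axis=0)
        losses[done : done + m] = draws.sum(axis=1)
        done += m
    cell_area = prob.geometry.cell_area_ha
    grid_counts = np.zeros(prob.geometry.shape, dtype=np.int64)
    grid_counts[prob.forest_mask] = counts
    return EnsembleCounts(
        geometry=prob.geometry,
        counts=grid_counts,
        forest_mask=prob.forest_mask,
        S=S,
        seed=seed,
        mean_loss_area_ha=float(losses.mean()) * cell_area,
        sd_loss_area_ha=float(losses.std()) * cell_area,
    )


@dataclass
class AllocationResult:
    """A single predicted landscape from quota-constrained allocation."""

    predicted: LandCoverMap
    quota_cells: int
    tie_break_trace: str


def allocate_quota(
    counts: EnsembleCounts,
    prob: ProbabilitySurface,
    map_t: LandCoverMap,
    quota_area_ha: float,
) -> AllocationResult:
    """Convert exactly the quota area of forest, highest ensemble count first.

    ``quota_cells = round(quota_area / cell_area)`` (half-up).  Ties in the
    ensemble count are broken by descending fitted probability, then by
    row-major cell index; the rule applied at the quota boundary is recorded
    in ``tie_break_trace``.  Cells nonforest at *t* are never modified.
    """
    geom = map_t.geometry
    cell_area = geom.cell_area_ha
    quota_cells = int(np.floor(quota_area_ha / cell_area + 0.5))
    forest_idx = np.flatnonzero(counts.forest_mask.ravel())
    if quota_cells > forest_idx.size:
        raise ValueError(
            f"quota of {quota_cells} cells exceeds the {forest_idx.size} "
            "forest cells available"
        )
    c = counts.counts.ravel()[forest_idx]
    p = prob.values.ravel()[forest_idx]
    order = np.lexsort((forest_idx, -p, -c))
    chosen = forest_idx[order[:quota_cells]]
    predicted = map_t.copy()
    ag_code = map_t.code_of("agriculture")
    flat = predicted.cells.ravel()
    flat[chosen] = ag_code
    if quota_cells == 0:
        trace = "quota 0: no cells converted"
    else:
        boundary_count = int(c[order[quota_cells - 1]])
        n_tied = int((c == boundary_count).sum())
        n_taken = int((c[order[:quota_cells]] == boundary_count).sum())
        trace = (
            f"boundary ensemble count {boundary_count}: {n_taken} of {n_tied} "
            "tied cells taken, ranked by fitted probability then row-major index"
        )
    return AllocationResult(predicted=predicted, quota_cells=quota_cells, tie_break_trace=trace)


def update_dynamic_layers(stack: CovariateStack, lc_map: LandCoverMap) -> CovariateStack:
    """Recompute dynamic covariates from *lc_map* on the frozen fitted scale.

    Layers whose provenance marks them dynamic are rebuilt from the current
    land-cover map — ``distance_to_class`` (e.g. distance to existing
    agriculture) and ``neighborhood_nonforest`` — then re-standardised with
    the ``transform`` (mean, sd) recorded when the stack was assembled, so
    the model's coefficients keep their meaning across epochs.  Static
    layers are reused as-is.
    """
    new = CovariateStack(stack.geometry)
    for name in stack.names:
        prov = dict(stack.provenance[name])
        if not prov.get("dynamic"):
            new.layers[name] = stack.layers[name]
            new.provenance[name] = prov
            continue
        op = prov.get("op")
        if op == "distance_to_class":
            raw = distance_to(lc_map.class_mask(prov["target_class"]), stack.geometry).values
        elif op == "neighborhood_nonforest":
            raw = neighborhood_nonforest(lc_map, prov.get("window_radius", 1)).values
        else:
            raise ValueError(f"dynamic layer {name!r} has unknown recompute op {op!r}")
        tr = prov.get("transform")
        if tr:
            raw = (raw - tr["mean"]) / tr["sd"]
        new.layers[name] = raw
        new.provenance[name] = prov
    return new


def project_step(
    map_t: LandCoverMap,
    model,
    stack: CovariateStack,
    quota_area_ha: float,
    S: int = 1000,
    seed: int = 0,
    epoch: str = "t+1",
) -> tuple[LandCoverMap, "ProbabilitySurface", EnsembleCounts]:
    """One forward projection epoch with frozen coefficients.

    Dynamic covariates are updated from *map_t*, conversion probabilities
    predicted on the current forest mask, an ensemble simulated, and the
    quota allocated.  Composable: chaining steps projects multiple epochs.
    """
    from .models import predict_probability

    stack_t = update_dynamic_layers(stack, map_t)
    forest = map_t.class_mask("forest")
    prob = predict_probability(model, stack_t, forest, epoch=epoch)
    counts = simulate_ensemble(prob, S=S, seed=seed)
    alloc = allocate_quota(counts, prob, map_t, quota_area_ha)
    return alloc.predicted, prob, counts


def save_run_record(path: str | Path, **record) -> None:
    """Write a JSON run record (seed, S, quota, model, tie-break rule)."""
    Path(path).write_text(json.dumps(record, indent=2, default=str))
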