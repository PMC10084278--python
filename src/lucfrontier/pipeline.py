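"""End-to-end study pipeline.

One configuration drives the whole design: synthesise (or load) a
two-epoch scene, build the covariate sample, screen correlated covariates,
fit the four conversion-model presets (classical land-use-change variables,
frontier-narrative variables, their union, and a refined union), validate
each model's quota-allocated prediction against the observed second epoch,
project one epoch ahead with dynamic covariate updating, and compute the
fragmentation metric suite for every observed and predicted landscape.

Outputs are plain CSV / JSON / ASCII-grid files plus a manifest with a
SHA-256 digest per file; two runs from the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import crosstab, disagreement
from .covariates import CovariateStack
from .grids import GridGeometry, LandCoverMap, read_landcover, transition_matrix, write_landcover
from .metrics import MetricsReport, class_metrics, label_patches
from .models import (
    FittedModel,
    SampleTable,
    XY_NAMES,
    compare_models,
    correlation_screen,
    fit_logistic,
    grid_sample,
    mcfadden_adjusted,
)
from .project import project_step, simulate_ensemble, allocate_quota
from .synth import GeneratorConfig, make_scene

__all__ = ["RunConfig", "RunManifest", "default_presets", "refined_terms", "run_pipeline"]

#: Terms usually treated as the "important narrative" subset when refining
#: the combined model.
DEFAULT_DA_IMPORTANT = [
    "dist_agriculture",
    "dist_fires",
    "fire_density",
    "dist_railroad",
    "paddd",
    "settlement",
]

LUC_TERMS = [
    "elevation",
    "slope",
    "soil_moisture",
    "precipitation",
    "crop_suitability",
    "dist_road",
    "dist_river",
    "dist_city",
    "population_density",
    "nonforest_neighborhood",
    "buffer_10km",
    "buffer_20km",
    "outside",
]

DA_TERMS = [
    "dist_agriculture",
    "dist_fires",
    "fire_density",
    "dist_mines",
    "dist_railroad",
    "unallocated_land",
    "cattle_density",
    "paddd",
    "settlement",
    "buffer_10km",
    "buffer_20km",
    "outside",
]


def default_presets() -> dict[str, list[str] | str]:
    both = LUC_TERMS + [t for t in DA_TERMS if t not in LUC_TERMS]
    return {
        "LUC": list(LUC_TERMS),
        "DA": list(DA_TERMS),
        "LUC_DA": both,
        "refined_LUC_DA": "auto",
    }


def refined_terms(
    luc_model: FittedModel,
    da_important: list[str] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Refined combined preset: significant classical terms + key narrative terms."""
    da_important = list(DEFAULT_DA_IMPORTANT if da_important is None else da_important)
    tab = luc_model.coefficient_table()
    sig = [
        t for t, p in zip(tab["term"], tab["p"])
        if t != "intercept" and t not in XY_NAMES and p < alpha
    ]
    return sig + [t for t in da_important if t not in sig]


@dataclass
class RunConfig:
    """Declarative configuration for :func:`run_pipeline`."""

    scene: GeneratorConfig | dict | None = None  # synthetic scene recipe
    scene_paths: dict | None = None  # or: paths to t0/t1 maps + stack dir
    spacing_m: float = 300.0
    screen_threshold: float = 0.66
    screen_alpha: float = 0.05
    screen_priority: list[str] | None = None
    include_xy: bool = True
    presets: dict = field(default_factory=default_presets)
    da_important: list[str] = field(default_factory=lambda: list(DEFAULT_DA_IMPORTANT))
    S: int = 1000
    seed: int = 0
    quota_policy: str = "area"  # "area": prior observed converted area;
    # "rate": prior forest→agriculture rate applied to the current forest area

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scene" in raw and raw["scene"] is not None:
            raw["scene"] = GeneratorConfig.from_json_dict(raw["scene"])
        return cls(**raw)

    def to_json_dict(self) -> dict:
        d = dict(self.__dict__)
        if isinstance(self.scene, GeneratorConfig):
            d["scene"] = self.scene.to_json_dict()
        return d


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str]
    stage_seconds: dict[str, float]
    version: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "outputs": self.outputs,
                    "warnings": self.warnings,
                    "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
                },
                indent=2,
            )
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_scene_from_paths(paths: dict):
    map_t0 = read_landcover(paths["t0"])
    map_t1 = read_landcover(paths["t1"])
    stack = CovariateStack.load(paths["stack"])
    return map_t0, map_t1, stack


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Run the full study design; returns the manifest of written outputs."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []
    timings: dict[str, float] = {}
    files: list[Path] = []

    def stage(name):
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # ---- scene -------------------------------------------------------
    stage("scene")
    if config.scene_paths:
        map_t0, map_t1, stack = _load_scene_from_paths(config.scene_paths)
    else:
        scfg = config.scene
        if scfg is None:
            scfg = GeneratorConfig(seed=config.seed)
        elif isinstance(scfg, dict):
            scfg = GeneratorConfig.from_json_dict(scfg)
        scene = make_scene(scfg)
        map_t0, map_t1, stack = scene.map_t0, scene.map_t1, scene.stack
        scene.save(out / "scene")
        files += sorted((out / "scene").rglob("*"))
    done("scene")

    # ---- observed change --------------------------------------------
    stage("observed")
    tm = transition_matrix(map_t0, map_t1)
    tm.to_csv(out / "transition_matrix.csv")
    files.append(out / "transition_matrix.csv")
    forest0 = map_t0.class_mask("forest")
    ag1 = map_t1.class_mask("agriculture")
    converted_cells = int((forest0 & ag1).sum())
    cell_area = map_t0.geometry.cell_area_ha
    observed_quota_ha = converted_cells * cell_area
    done("observed")

    # ---- sample and screen ------------------------------------------
    stage("sample")
    sample = grid_sample(map_t0, map_t1, stack, config.spacing_m)
    sample.to_csv(out / "sample.csv")
    files.append(out / "sample.csv")
    continuous = [
        n for n in stack.names
        if stack.provenance[n].get("kind") != "indicator"
    ]
    names = continuous + ([*XY_NAMES] if config.include_xy else [])
    priority = config.screen_priority or names
    screen = correlation_screen(
        sample, names, config.screen_threshold, config.screen_alpha, priority
    )
    pd.DataFrame(
        screen.dropped, columns=["dropped", "retained", "r", "p"]
    ).to_csv(out / "screen_report.csv", index=False)
    files.append(out / "screen_report.csv")
    kept = set(screen.kept)
    indicators = [n for n in stack.names if stack.provenance[n].get("kind") == "indicator"]
    done("sample")

    def usable(term: str) -> bool:
        if term in indicators:
            col = sample.data[term].to_numpy()
            if col.std() == 0:
                notes.append(f"term {term} constant in sample; dropped from fits")
                return False
            return True
        if term in XY_NAMES:
            return term in kept
        return term in kept

    # ---- fit presets -------------------------------------------------
    stage("fit")
    presets = dict(config.presets)
    models: dict[str, FittedModel] = {}
    order = [k for k in presets if presets[k] != "auto"] + [
        k for k in presets if presets[k] == "auto"
    ]
    for mname in order:
        spec_terms = presets[mname]
        if spec_terms == "auto":
            base = models.get("LUC")
            if base is None:
                raise ValueError("'auto' refined preset requires a LUC preset fit")
            spec_terms = refined_terms(base, config.da_important)
        terms = [t for t in spec_terms if usable(t)]
        skipped = [t for t in spec_terms if t not in terms]
        if skipped:
            notes.append(f"model {mname}: screened/constant terms omitted: {skipped}")
        # coordinate covariates ride along only when they survived screening
        if config.include_xy:
            terms += [n for n in XY_NAMES if n in kept and n not in terms]
        model = fit_logistic(sample, terms, include_xy=False, name=mname)
        models[mname] = model
        model.save(out / f"model_{mname}.json")
        model.coefficient_table().to_csv(out / f"coefficients_{mname}.csv", index=False)
        files += [out / f"model_{mname}.json", out / f"coefficients_{mname}.csv"]
    done("fit")

    # ---- model comparison -------------------------------------------
    stage("comparison")
    rows = []
    mnames = list(models)
    for i, a in enumerate(mnames):
        for b in mnames[i + 1 :]:
            first, second = models[a], models[b]
            if set(second.terms) <= set(first.terms):
                first, second = second, first
            cr = compare_models(first, second)
            rows.append(
                {
                    "model_a": cr.model_a,
                    "model_b": cr.model_b,
                    "nested": cr.nested,
                    "lr_statistic": cr.statistic,
                    "df": cr.df,
                    "p_value": cr.p_value,
                    "pseudo_r2_a": cr.pseudo_r2_a,
                    "pseudo_r2_b": cr.pseudo_r2_b,
                }
            )
    pd.DataFrame(rows).to_csv(out / "model_comparison.csv", index=False)
    pd.DataFrame(
        {
            "model": mnames,
            "mcfadden_adjusted": [mcfadden_adjusted(models[m]) for m in mnames],
            "loglik": [models[m].loglik for m in mnames],
            "K": [models[m].K for m in mnames],
            "n": [models[m].n for m in mnames],
        }
    ).to_csv(out / "model_fit.csv", index=False)
    files += [out / "model_comparison.csv", out / "model_fit.csv"]
    done("comparison")

    # ---- validation against the observed second epoch ---------------
    stage("validate")
    from .models import predict_probability

    disagreement_rows = []
    predicted_t1: dict[str, LandCoverMap] = {}
    for i, mname in enumerate(mnames):
        prob = predict_probability(models[mname], stack, forest0, epoch="t0")
        counts = simulate_ensemble(prob, S=config.S, seed=config.seed + 1000 + i)
        alloc = allocate_quota(counts, prob, map_t0, observed_quota_ha)
        predicted_t1[mname] = alloc.predicted
        write_landcover(alloc.predicted, out / f"predicted_t1_{mname}.asc")
        files.append(out / f"predicted_t1_{mname}.asc")
        rep = disagreement(crosstab(alloc.predicted, map_t1))
        rep.save(out / f"disagreement_{mname}.json")
        files.append(out / f"disagreement_{mname}.json")
        disagreement_rows.append(
            {
                "model": mname,
                "quantity": rep.quantity,
                "allocation": rep.allocation,
                "total": rep.total,
                "mean_loss_area_ha": counts.mean_loss_area_ha,
                "sd_loss_area_ha": counts.sd_loss_area_ha,
            }
        )
    pd.DataFrame(disagreement_rows).to_csv(out / "disagreement.csv", index=False)
    files.append(out / "disagreement.csv")
    done("validate")

    # ---- forward projection -----------------------------------------
    stage("project")
    if config.quota_policy == "rate":
        rate = tm.prob("forest", "agriculture")
        quota_t2 = rate * float(map_t1.class_mask("forest").sum()) * cell_area
    else:
        quota_t2 = observed_quota_ha
    projected_t2: dict[str, LandCoverMap] = {}
    for i, mname in enumerate(mnames):
        map_t2, _, _ = project_step(
            map_t1,
            models[mname],
            stack,
            quota_area_ha=quota_t2,
            S=config.S,
            seed=config.seed + 2000 + i,
            epoch="t2",
        )
        projected_t2[mname] = map_t2
        write_landcover(map_t2, out / f"projected_t2_{mname}.asc")
        files.append(out / f"projected_t2_{mname}.asc")
    done("project")

    # ---- fragmentation metrics --------------------------------------
    stage("metrics")
    landscapes = {"observed_t0": map_t0, "observed_t1": map_t1}
    landscapes.update({f"predicted_t1_{m}": predicted_t1[m] for m in mnames})
    landscapes.update({f"projected_t2_{m}": projected_t2[m] for m in mnames})
    reports = {
        name: class_metrics(label_patches(lc, "forest"))
        for name, lc in landscapes.items()
    }
    MetricsReport.table(reports).to_csv(out / "landscape_metrics.csv")
    files.append(out / "landscape_metrics.csv")
    done("metrics")

    manifest = RunManifest(
        config=config.to_json_dict(),
        outputs={
            str(f.relative_to(out)): _digest(f) for f in sorted(set(files)) if f.is_file()
        },
        warnings=notes,
        stage_seconds=timings,
        version=__version__,
    )
    manifest.save(out / "manifest.json")
    return manifest
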