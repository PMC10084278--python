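"""Spatially decorrelated sampling, covariate screening, and logistic
conversion models.

The estimation sample is drawn along a coarse regular grid (300 m by
default) so adjacent, spatially autocorrelated pixels do not enter the
model together.  Candidate covariates are screened pairwise by Pearson
correlation (|r| > 0.66, p < 0.05 by default) with a user-declared priority
order deciding which member of an offending pair survives.  Conversion
models are maximum-likelihood binomial GLMs with a logit link; model
quality is summarised by McFadden's adjusted pseudo-R² and nested models
are compared with likelihood-ratio tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .covariates import CovariateStack
from .grids import GridGeometry, LandCoverMap

__all__ = [
    "SampleTable",
    "FittedModel",
    "ScreenReport",
    "ComparisonResult",
    "grid_sample",
    "correlation_screen",
    "fit_logistic",
    "mcfadden_adjusted",
    "compare_models",
    "predict_probability",
    "SeparationError",
]

XY_NAMES = ("x_coord", "y_coord")


class SeparationError(RuntimeError):
    """The likelihood is unbounded because a term separates the outcomes."""


@dataclass
class SampleTable:
    """Forest-at-t0 sample rows with outcome and covariate values.

    ``data`` holds one row per sampled cell: grid indices, planar
    coordinates, the centred/extent-scaled coordinate covariates, the
    binary forest→agriculture outcome, and every stack layer.
    """

    data: pd.DataFrame
    spacing_m: float
    geometry: GridGeometry

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, spacing_m: float, geometry: GridGeometry):
        return cls(pd.read_csv(path), spacing_m, geometry)


def scaled_xy(geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate covariates: cell-centre x/y, centred and scaled by extent."""
    x, y = geometry.cell_centers()
    width = geometry.n_cols * geometry.cell_size
    height = geometry.n_rows * geometry.cell_size
    xs = (x - (geometry.origin_x + width / 2.0)) / width
    ys = (y - (geometry.origin_y - height / 2.0)) / height
    return xs, ys


def grid_sample(
    map_t0: LandCoverMap,
    map_t1: LandCoverMap,
    stack: CovariateStack,
    spacing_m: float = 300.0,
) -> SampleTable:
    """Extract forest-at-t0 cells along a regular grid of pitch *spacing_m*.

    The outcome is 1 only for forest→agriculture transitions; forest cells
    converting to any other class remain in the sample with outcome 0.
    The spacing must be an integer multiple of the cell size (no
    resampling); candidates start at cell (0, 0).
    """
    geom = map_t0.geometry
    step_f = spacing_m / geom.cell_size
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError(
            f"spacing {spacing_m} m is not an integer multiple of the "
            f"{geom.cell_size} m cell size"
        )
    if not geom.same_grid(map_t1.geometry) or not geom.same_grid(stack.geometry):
        raise ValueError("maps and stack must share one grid geometry")
    rows = np.arange(0, geom.n_rows, step)
    cols = np.arange(0, geom.n_cols, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    forest = map_t0.class_mask("forest")[rr, cc] & map_t1.valid_mask[rr, cc]
    rr, cc = rr[forest], cc[forest]
    if len(rr) == 0:
        warnings.warn("no forest cells on the sampling grid; sample is empty")
    ag_code = map_t0.code_of("agriculture")
    outcome = (map_t1.cells[rr, cc] == ag_code).astype(int)
    x, y = geom.cell_centers()
    xs, ys = scaled_xy(geom)
    table = {
        "row": rr,
        "col": cc,
        "x": x[rr, cc],
        "y": y[rr, cc],
        XY_NAMES[0]: xs[rr, cc],
        XY_NAMES[1]: ys[rr, cc],
        "outcome": outcome,
    }
    for name in stack.names:
        table[name] = stack[name][rr, cc]
    return SampleTable(pd.DataFrame(table), spacing_m, geom)


@dataclass
class ScreenReport:
    """Result of the pairwise Pearson correlation screen."""

    kept: list[str]
    dropped: list[tuple[str, str, float, float]]  # (dropped, retained, r, p)
    threshold: float
    alpha: float

    def __repr__(self) -> str:
        lines = [f"ScreenReport(kept={len(self.kept)}, dropped={len(self.dropped)})"]
        for d, k, r, p in self.dropped:
            lines.append(f"  dropped {d} (kept {k}; r={r:+.3f}, p={p:.2g})")
        return "\n".join(lines)


def correlation_screen(
    table: SampleTable,
    names: list[str],
    threshold: float = 0.66,
    alpha: float = 0.05,
    priority: list[str] | None = None,
) -> ScreenReport:
    """Iteratively drop the lower-priority member of each offending pair.

    A pair offends when |Pearson r| exceeds *threshold* with two-sided
    p < *alpha*.  At each step the highest-|r| offending pair is resolved by
    dropping whichever member ranks lower in *priority* (default: the given
    order of *names*, so earlier names are preferred).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    priority = list(priority if priority is not None else names)
    missing = [n for n in names if n not in priority]
    if missing:
        raise ValueError(f"priority omits screened names: {missing}")
    rank = {n: i for i, n in enumerate(priority)}
    kept = list(names)
    dropped: list[tuple[str, str, float, float]] = []
    while True:
        worst = None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                va = table.data[a].to_numpy()
                vb = table.data[b].to_numpy()
                if np.std(va) == 0 or np.std(vb) == 0:
                    continue
                r, p = stats.pearsonr(va, vb)
                if abs(r) > threshold and p < alpha:
                    if worst is None or abs(r) > abs(worst[2]):
                        worst = (a, b, r, p)
        if worst is None:
            break
        a, b, r, p = worst
        loser, winner = (b, a) if rank[a] <= rank[b] else (a, b)
        kept.remove(loser)
        dropped.append((loser, winner, float(r), float(p)))
    return ScreenReport(kept=kept, dropped=dropped, threshold=threshold, alpha=alpha)


@dataclass
class FittedModel:
    """One fitted logistic conversion model.

    ``terms`` excludes the intercept, which is always present; ``beta`` and
    ``se`` are aligned with ``["intercept", *terms]``.
    """

    name: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    pvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def K(self) -> int:
        """Number of non-intercept terms."""
        return len(self.terms)

    @property
    def term_names(self) -> list[str]:
        return ["intercept", *self.terms]

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.term_names.index(term)])

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "terms": self.terms,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "K": self.K,
            "n": self.n,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            terms=d["terms"],
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            loglik=d["loglik"],
            loglik_null=d["loglik_null"],
            n=d["n"],
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Human-readable coefficient table with significance stars."""
        if self.pvalues is None:
            z = self.beta / self.se
            pvals = 2 * stats.norm.sf(np.abs(z))
        else:
            pvals = self.pvalues
        stars = ["***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
                 for p in pvals]
        return pd.DataFrame(
            {"term": self.term_names, "estimate": self.beta, "se": self.se,
             "p": pvals, "sig": stars}
        )


def _null_loglik(y: np.ndarray) -> float:
    n, n1 = len(y), int(y.sum())
    n0 = n - n1
    p = n1 / n
    ll = 0.0
    if n1:
        ll += n1 * np.log(p)
    if n0:
        ll += n0 * np.log(1 - p)
    return float(ll)


def fit_logistic(
    table: SampleTable,
    terms: list[str],
    include_xy: bool = False,
    name: str = "model",
) -> FittedModel:
    """Maximum-likelihood logit fit of the forest→agriculture outcome.

    Covariates enter on the scale they carry in the sample table.  With
    ``include_xy`` the centred/extent-scaled coordinates are appended as
    spatial-trend covariates.  Complete or quasi-complete separation is
    surfaced as :class:`SeparationError`.
    """
    y = table.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is all 0 or all 1; the model is undefined")
    use_terms = list(terms)
    if include_xy:
        use_terms += [n for n in XY_NAMES if n not in use_terms]
    missing = [t for t in use_terms if t not in table.data.columns]
    if missing:
        raise KeyError(f"sample table lacks covariates: {missing}")
    X = sm.add_constant(table.data[use_terms].to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            if "erfect" in type(exc).__name__ or "separ" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise
    for w in caught:
        if "separ" in str(w.message).lower():
            bad = [t for t, s in zip(["intercept", *use_terms], res.bse) if not np.isfinite(s) or s > 1e4]
            raise SeparationError(
                f"separation detected while fitting {name!r}; suspect terms: {bad}"
            )
    return FittedModel(
        name=name,
        terms=use_terms,
        beta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        loglik=float(res.llf),
        loglik_null=_null_loglik(y),
        n=len(y),
        pvalues=np.asarray(res.pvalues, dtype=float),
    )


def mcfadden_adjusted(model: FittedModel) -> float:
    """McFadden's adjusted pseudo-R²: ``1 - (lnL - K) / lnL_null``.

    Penalises the likelihood by the number of non-intercept terms, so adding
    an uninformative covariate can lower the value.
    """
    if model.loglik_null == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R² undefined")
    return 1.0 - (model.loglik - model.K) / model.loglik_null


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    nested: bool
    pseudo_r2_a: float
    pseudo_r2_b: float
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None


def compare_models(model_a: FittedModel, model_b: FittedModel) -> ComparisonResult:
    """Likelihood-ratio comparison for nested fits; descriptive otherwise.

    If the terms of *model_a* are a subset of *model_b*'s (both fitted on
    the same sample), the deviance difference ``2(lnL_b - lnL_a)`` is
    referred to chi-square with ``K_b - K_a`` degrees of freedom.  Models
    with non-nested term sets are compared only by adjusted pseudo-R².
    """
    if model_a.n != model_b.n:
        raise ValueError("models were fitted on different sample sizes")
    out = ComparisonResult(
        model_a=model_a.name,
        model_b=model_b.name,
        nested=False,
        pseudo_r2_a=mcfadden_adjusted(model_a),
        pseudo_r2_b=mcfadden_adjusted(model_b),
    )
    if set(model_a.terms) <= set(model_b.terms):
        stat = max(0.0, 2.0 * (model_b.loglik - model_a.loglik))
        df = model_b.K - model_a.K
        out.nested = True
        out.statistic = stat
        out.df = df
        out.p_value = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return out


def predict_probability(
    model: FittedModel,
    stack: CovariateStack,
    forest_mask: np.ndarray,
    epoch: str = "t0",
):
    """Per-forest-cell conversion probability surface for a fitted model.

    Coordinate covariates are synthesised from the grid geometry when the
    model uses them; every other term must be a stack layer.
    """
    from .project import ProbabilitySurface

    geom = stack.geometry
    eta = np.full(geom.shape, model.beta[0], dtype=float)
    xs, ys = scaled_xy(geom)
    synth = {XY_NAMES[0]: xs, XY_NAMES[1]: ys}
    for term, b in zip(model.terms, model.beta[1:]):
        if term in stack:
            layer = stack[term]
        elif term in synth:
            layer = synth[term]
        else:
            raise KeyError(f"model term {term!r} not present in covariate stack")
        eta += b * layer
    from scipy.special import expit

    values = np.where(forest_mask, expit(eta), np.nan)
    return ProbabilitySurface(
        geometry=geom,
        values=values,
        forest_mask=np.asarray(forest_mask, dtype=bool),
        model_name=model.name,
        epoch=epoch,
    )
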