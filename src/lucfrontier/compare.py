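"""Map validation: quantity and allocation disagreement.

A predicted categorical map is validated against an observed one through
their cross-tabulation.  With proportions ``p[i, j]`` (predicted class i,
observed class j), each class g contributes

* quantity component ``q_g = |p_{g.} - p_{.g}|`` — mismatch in how much of
  the map each class occupies, and
* allocation component ``a_g = 2 * min(p_{g.} - p_{gg}, p_{.g} - p_{gg})``
  — mismatch in where the class sits, given its quantity.

Overall quantity disagreement is ``0.5 * sum(q_g)``, allocation
disagreement ``0.5 * sum(a_g)``, and their sum equals the total
disagreement ``1 - trace(p)`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import GridAlignmentError, LandCoverMap

__all__ = ["CrossTab", "DisagreementReport", "crosstab", "disagreement"]


@dataclass
class CrossTab:
    """Square predicted × observed contingency table."""

    classes: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def crosstab(
    predicted: LandCoverMap,
    observed: LandCoverMap,
    restrict_mask: np.ndarray | None = None,
) -> CrossTab:
    """Cross-tabulate predicted against observed classes cell by cell.

    Cells nodata in either map are excluded; *restrict_mask* optionally
    confines the comparison (e.g. to the prior epoch's forest extent).
    """
    if not predicted.geometry.same_grid(observed.geometry):
        raise GridAlignmentError("predicted and observed maps are not aligned")
    if predicted.class_labels != observed.class_labels:
        raise GridAlignmentError("maps carry different class rosters")
    codes = sorted(predicted.class_labels)
    labels = [predicted.class_labels[c] for c in codes]
    k = len(codes)
    lut = {c: i for i, c in enumerate(codes)}
    valid = predicted.valid_mask & observed.valid_mask
    if restrict_mask is not None:
        valid &= np.asarray(restrict_mask, dtype=bool)
    a = np.vectorize(lut.__getitem__, otypes=[np.int64])(predicted.cells[valid])
    b = np.vectorize(lut.__getitem__, otypes=[np.int64])(observed.cells[valid])
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return CrossTab(classes=labels, counts=counts)


@dataclass
class DisagreementReport:
    quantity: float
    allocation: float
    total: float
    per_class_quantity: dict[str, float]
    per_class_allocation: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "allocation": self.allocation,
            "total": self.total,
            "per_class_quantity": self.per_class_quantity,
            "per_class_allocation": self.per_class_allocation,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def disagreement(ct: CrossTab) -> DisagreementReport:
    """Decompose total map disagreement into quantity and allocation parts."""
    if ct.total == 0:
        raise ValueError("empty cross-tabulation; disagreement undefined")
    p = ct.proportions
    row = p.sum(axis=1)  # predicted marginals
    col = p.sum(axis=0)  # observed marginals
    diag = np.diag(p)
    q = np.abs(row - col)
    a = 2.0 * np.minimum(row - diag, col - diag)
    quantity = 0.5 * float(q.sum())
    allocation = 0.5 * float(a.sum())
    total = 1.0 - float(diag.sum())
    return DisagreementReport(
        quantity=quantity,
        allocation=allocation,
        total=total,
        per_class_quantity={c: float(v) for c, v in zip(ct.classes, q)},
        per_class_allocation={c: float(v) for c, v in zip(ct.classes, a)},
    )
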