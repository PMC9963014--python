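"""Accuracy evaluation for fractional-cover extraction.

Three ingredients:

* a reference cover fraction from a classified map — the share of vegetation
  pixels among all classified pixels (vegetation, bare ground, road,
  sedimentation pond, building, or any other class set with one designated
  vegetation class);
* the extraction error EC = |FI - FV| / FI x 100, the relative deviation of
  a model's mean cover FV from the reference FI, in percent;
* classification agreement between two label maps: confusion matrix, overall
  accuracy (trace / total) and Cohen's kappa, the chance-corrected agreement
  (p_o - p_e) / (1 - p_e) with p_e from the marginal products.

EC uses the absolute difference so the error is a magnitude regardless of
whether the model over- or under-estimates cover.  All stored values keep
full precision; rounding to two decimals is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError
from .indices import INDEX_NAMES
from .raster import LabelMap

__all__ = [
    "ClassCounts",
    "EvaluationReport",
    "fvc_from_counts",
    "counts_from_labels",
    "extraction_error",
    "agreement",
    "compare_models",
]

#: Default name of the vegetation class in label maps.
VEGETATION = "vegetation"


@dataclass(frozen=True)
class ClassCounts:
    """Pixel tallies per land-cover class, with one designated vegetation class."""

    counts: Mapping[str, int]
    vegetation: str = VEGETATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))
        if self.vegetation not in self.counts:
            raise ContractError(f"no {self.vegetation!r} class in counts")
        if any(c < 0 for c in self.counts.values()):
            raise ContractError("negative class count")

    @classmethod
    def from_five(cls, n_veg: int, n_land: int, n_road: int, n_pool: int,
                  n_building: int) -> "ClassCounts":
        """The canonical five-class tally (vegetation, bare ground, road,
        sedimentation pond, building)."""
        return cls({"vegetation": n_veg, "bare_ground": n_land, "road": n_road,
                    "pond": n_pool, "building": n_building})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_veg(self) -> int:
        return self.counts[self.vegetation]


def fvc_from_counts(counts: ClassCounts) -> float:
    """Reference cover fraction: vegetation pixels over all classified pixels."""
    total = counts.total
    if total == 0:
        raise ContractError("zero total pixel count")
    return counts.n_veg / total


def counts_from_labels(labels: LabelMap, vegetation: str = VEGETATION) -> ClassCounts:
    """Tally valid pixels per class name from a label map."""
    names = set(labels.class_names.values())
    if vegetation not in names:
        raise ContractError(f"label map has no {vegetation!r} class")
    tallies = {name: 0 for name in labels.class_names.values()}
    valid = labels.labels[labels.valid_mask]
    codes, n = np.unique(valid, return_counts=True)
    for code, count in zip(codes, n):
        tallies[labels.class_names[int(code)]] += int(count)
    return ClassCounts(tallies, vegetation=vegetation)


@dataclass
class EvaluationReport:
    """Accuracy figures for one model (or one pair of classifications)."""

    fi: float | None = None       #: reference (classified-map) cover fraction
    fv: float | None = None       #: model cover fraction
    difference: float | None = None
    ec: float | None = None       #: extraction error, percent
    confusion: pd.DataFrame | None = None
    overall_accuracy: float | None = None
    kappa: float | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        for key in ("fi", "fv", "difference", "ec", "overall_accuracy", "kappa"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
        return out


def extraction_error(fi: float, fv: float) -> EvaluationReport:
    """Extraction error of a model cover fraction against the reference.

    ``ec`` is |fi - fv| / fi in percent; ``difference`` the absolute
    deviation on the fraction scale.
    """
    if fi <= 0:
        raise ContractError("reference cover fraction must be positive")
    difference = abs(fi - fv)
    return EvaluationReport(fi=fi, fv=fv, difference=difference,
                            ec=difference / fi * 100.0)


def agreement(reference: LabelMap, predicted: LabelMap) -> EvaluationReport:
    """Confusion matrix, overall accuracy and Cohen's kappa of two label maps.

    Computed over jointly valid pixels.  A sparse validation sample (e.g.
    hand-marked points) is just a label map that is invalid everywhere except
    the sample pixels.  Kappa is undefined (None) when the expected agreement
    p_e equals 1, i.e. both maps are single-class.
    """
    if reference.shape != predicted.shape:
        raise ContractError("label map dimensions differ")
    joint = reference.valid_mask & predicted.valid_mask
    if not joint.any():
        raise ContractError("no jointly valid pixels")
    ref = reference.labels[joint]
    pred = predicted.labels[joint]
    codes = np.union1d(np.unique(ref), np.unique(pred))
    names = {**predicted.class_names, **reference.class_names}
    k = codes.size
    pos = {int(c): i for i, c in enumerate(codes)}
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (np.searchsorted(codes, ref), np.searchsorted(codes, pred)), 1)
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) / total) @ (cm.sum(axis=0) / total))
    kappa = None if p_e == 1.0 else float((p_o - p_e) / (1.0 - p_e))
    index = [names.get(int(c), str(int(c))) for c in codes]
    confusion = pd.DataFrame(cm, index=pd.Index(index, name="reference"),
                             columns=pd.Index(index, name="predicted"))
    return EvaluationReport(confusion=confusion, overall_accuracy=float(p_o),
                            kappa=kappa)


def compare_models(reference_fvc: float, model_fvcs: Mapping[str, float]) -> pd.DataFrame:
    """Rank cover-extraction models by extraction error, ascending.

    Ties are broken by the canonical index order (then by insertion order
    for names outside the canonical set).  Columns mirror the usual
    comparison table: model, dichotomy FVC, reference FVC, difference, EC %.
    """
    if not model_fvcs:
        raise ContractError("empty model mapping")
    order = {name: i for i, name in enumerate(INDEX_NAMES)}
    rows = []
    for pos, (name, fv) in enumerate(model_fvcs.items()):
        rep = extraction_error(reference_fvc, fv)
        rows.append({
            "model": name,
            "fvc_dichotomy": fv,
            "fvc_reference": reference_fvc,
            "difference": rep.difference,
            "extraction_error_pct": rep.ec,
            "_tie": order.get(name.upper(), len(order) + pos),
        })
    table = pd.DataFrame(rows).sort_values(
        ["extraction_error_pct", "_tie"], kind="stable"
    ).drop(columns="_tie").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
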