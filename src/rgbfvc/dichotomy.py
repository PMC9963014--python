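"""The dimidiate (pixel dichotomy) fractional-cover model.

Each pixel's index value VI is treated as a linear mixture of a pure-soil
endmember VI_soil and a pure-vegetation endmember VI_veg, so

    FVC = (VI - VI_soil) / (VI_veg - VI_soil),   clipped to [0, 1].

Endmembers are estimated from the image's own index histogram: at a
confidence level c (default 0.02), the value at cumulative fraction c of the
valid-pixel distribution is the soil endpoint and the value at 1 - c the
vegetation endpoint, swapped for indices that decrease with greenness
(CIVE).  Percentiles use the nearest-rank rule on the sorted valid pixels:
the ceil(q * n)-th order statistic, giving exact, reproducible integer-rank
semantics rather than interpolated values.

Clipping implements the noise rule: pixels beyond the soil endpoint are
fully bare (0) and pixels beyond the vegetation endpoint fully covered (1).

Fractional cover is discretized by two grading schemes:

* five_level — [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0], codes 1-5
* six_level  — a dedicated code 0 for exactly-zero cover, then (0,0.2),
  [0.2,0.4), ... as above, codes 0-5

Intervals are lower-inclusive / upper-exclusive except the top, which
includes 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .errors import ContractError, DegenerateDistributionError
from .indices import IndexDefinition, IndexImage, get_index

__all__ = [
    "EndpointPair",
    "FVCMap",
    "GradeScheme",
    "GradeMap",
    "estimate_endpoints",
    "compute_fvc",
    "mean_fvc",
    "grade_map",
    "grade_area_fractions",
]

#: Minimum number of valid pixels for a meaningful tail estimate.
MIN_PIXELS = 100


@dataclass(frozen=True)
class EndpointPair:
    """Pure-soil and pure-vegetation index values with their confidence cut."""

    vi_soil: float
    vi_veg: float
    confidence: float
    index: IndexDefinition

    def __post_init__(self) -> None:
        if self.vi_soil == self.vi_veg:
            raise DegenerateDistributionError("vi_soil equals vi_veg")
        if not 0.0 < self.confidence < 0.5:
            raise ContractError("confidence must lie in (0, 0.5)")
        lo, hi = sorted((self.vi_soil, self.vi_veg))
        expected_soil = lo if self.index.polarity == "increasing" else hi
        if self.vi_soil != expected_soil:
            raise ContractError(
                f"endpoint order inconsistent with {self.index.name} polarity "
                f"({self.index.polarity}): vi_soil={self.vi_soil}, vi_veg={self.vi_veg}"
            )


@dataclass
class FVCMap:
    """Per-pixel fractional vegetation cover in [0, 1]."""

    values: np.ndarray
    endpoints: EndpointPair | None
    valid_mask: np.ndarray
    georeference: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ContractError("values and valid_mask shapes differ")
        valid = self.values[self.valid_mask]
        if valid.size and (valid.min() < 0.0 or valid.max() > 1.0):
            raise ContractError("FVC values outside [0, 1] on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th order statistic of pre-sorted values (1-based)."""
    n = sorted_values.size
    rank = min(max(math.ceil(q * n), 1), n)
    return float(sorted_values[rank - 1])


def estimate_endpoints(index_image: IndexImage, confidence: float = 0.02) -> EndpointPair:
    """Estimate pure-pixel endpoints from the index histogram tails.

    For an increasing index the soil endpoint is the value at cumulative
    fraction ``confidence`` and the vegetation endpoint at ``1 - confidence``;
    for a decreasing index (CIVE) the assignments swap.
    """
    if not 0.0 < confidence < 0.5:
        raise ContractError("confidence must lie in (0, 0.5)")
    values = index_image.values[index_image.valid_mask]
    if values.size < MIN_PIXELS:
        raise ContractError(f"need at least {MIN_PIXELS} valid pixels, got {values.size}")
    s = np.sort(values)
    lo = nearest_rank(s, confidence)
    hi = nearest_rank(s, 1.0 - confidence)
    if lo == hi:
        raise DegenerateDistributionError(
            f"degenerate {index_image.index.name} distribution: both tails at {lo}"
        )
    if index_image.index.polarity == "increasing":
        vi_soil, vi_veg = lo, hi
    else:
        vi_soil, vi_veg = hi, lo
    return EndpointPair(vi_soil=vi_soil, vi_veg=vi_veg,
                        confidence=confidence, index=index_image.index)


def make_endpoints(vi_soil: float, vi_veg: float, index: IndexDefinition | str,
                   confidence: float = 0.02) -> EndpointPair:
    """Wrap externally supplied endpoint values (e.g. published tables)."""
    if isinstance(index, str):
        index = get_index(index)
    return EndpointPair(vi_soil=float(vi_soil), vi_veg=float(vi_veg),
                        confidence=confidence, index=index)


def compute_fvc(index_image: IndexImage, endpoints: EndpointPair) -> FVCMap:
    """Apply the dimidiate model with clipping to [0, 1]."""
    if endpoints.index.name != index_image.index.name:
        raise ContractError(
            f"endpoint index {endpoints.index.name} does not match "
            f"image index {index_image.index.name}"
        )
    span = endpoints.vi_veg - endpoints.vi_soil
    f = (index_image.values - endpoints.vi_soil) / span
    f = np.clip(f, 0.0, 1.0)
    f = np.where(index_image.valid_mask, f, np.nan)
    return FVCMap(values=f, endpoints=endpoints, valid_mask=index_image.valid_mask,
                  georeference=index_image.georeference)


def mean_fvc(fvc: FVCMap) -> float:
    """Arithmetic mean fractional cover over valid pixels."""
    valid = fvc.values[fvc.valid_mask]
    if valid.size == 0:
        raise ContractError("no valid pixels")
    return float(valid.mean())


@dataclass(frozen=True)
class GradeScheme:
    """A partition of [0, 1] into cover grades.

    ``boundaries`` are the interior breakpoints; ``codes`` the grade code per
    interval in ascending cover order.  ``zero_class`` reserves the first
    code for exactly-zero cover.
    """

    name: str
    boundaries: tuple[float, ...]
    codes: tuple[int, ...]
    zero_class: bool = False
    labels: tuple[str, ...] = ()

    @classmethod
    def five_level(cls) -> "GradeScheme":
        return cls(name="five_level", boundaries=(0.2, 0.4, 0.6, 0.8),
                   codes=(1, 2, 3, 4, 5),
                   labels=("0-20%", "20-40%", "40-60%", "60-80%", "80-100%"))

    @classmethod
    def six_level(cls) -> "GradeScheme":
        return cls(name="six_level", boundaries=(0.2, 0.4, 0.6, 0.8),
                   codes=(0, 1, 2, 3, 4, 5), zero_class=True,
                   labels=("0", "1-20%", "20-40%", "40-60%", "60-80%", "80-100%"))

    @classmethod
    def by_name(cls, name: str) -> "GradeScheme":
        schemes = {"five_level": cls.five_level, "six_level": cls.six_level,
                   "five": cls.five_level, "six": cls.six_level}
        if name not in schemes:
            raise ContractError(f"unknown grade scheme {name!r}")
        return schemes[name]()

    def assign(self, f: np.ndarray) -> np.ndarray:
        """Vectorized grade assignment for cover fractions in [0, 1]."""
        f = np.asarray(f, dtype=np.float64)
        # interval index: lower-inclusive, upper-exclusive, top includes 1.0
        idx = np.searchsorted(self.boundaries, f, side="right")
        offset = 1 if self.zero_class else 0
        codes = np.asarray(self.codes)
        grades = codes[np.clip(idx + offset, 0, len(codes) - 1)]
        if self.zero_class:
            grades = np.where(f == 0.0, codes[0], grades)
        return grades.astype(np.int32)


@dataclass
class GradeMap:
    """Per-pixel integer cover grade under a :class:`GradeScheme`."""

    grades: np.ndarray
    scheme: GradeScheme
    valid_mask: np.ndarray
    georeference: tuple | None = None

    def __post_init__(self) -> None:
        self.grades = np.asarray(self.grades)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grades.shape != self.valid_mask.shape:
            raise ContractError("grades and valid_mask shapes differ")
        present = set(np.unique(self.grades[self.valid_mask]).tolist())
        if not present <= set(self.scheme.codes):
            raise ContractError("grade codes outside the scheme")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grades.shape


def grade_map(fvc: FVCMap, scheme: GradeScheme | str = "five_level") -> GradeMap:
    """Discretize an FVC map into cover grades."""
    if isinstance(scheme, str):
        scheme = GradeScheme.by_name(scheme)
    f = np.where(fvc.valid_mask, fvc.values, 0.0)
    grades = scheme.assign(f)
    return GradeMap(grades=grades, scheme=scheme, valid_mask=fvc.valid_mask,
                    georeference=fvc.georeference)


def grade_area_fractions(grades: GradeMap) -> dict[int, float]:
    """Share of valid pixels per grade code; includes zero-share grades."""
    valid = grades.grades[grades.valid_mask]
    if valid.size == 0:
        raise ContractError("no valid pixels")
    return {int(code): float(np.count_nonzero(valid == code) / valid.size)
            for code in grades.scheme.codes}
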