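"""Visible-band (RGB) vegetation indices.

Seven greenness indices computable from red/green/blue channels alone:

========  ==============================================  =========
name      formula (8-bit channel values)                  polarity
========  ==============================================  =========
EXG       2G - R - B                                      increasing
GRVI      (G - R) / (G + R)                               increasing
EXGR      EXG - (1.4R - G) = 3G - 2.4R - B                increasing
NGBDI     (G - B) / (G + B)                               increasing
CIVE      0.441R - 0.811G + 0.385B + 18.78745             decreasing
RGBVI     (G^2 - RB) / (G^2 + RB)                         increasing
VDVI      (G - (R+B)/2) / (G + (R+B)/2)                   increasing
========  ==============================================  =========

Polarity records whether the index rises or falls with vegetation greenness;
CIVE is the one index that *decreases* over vegetation, which downstream
endpoint estimation must respect when deciding which histogram tail is soil.

CIVE ships with two coefficient presets.  ``"literature"`` (the default) is
the standard formulation above.  ``"paper"`` is an alternative printed in
some sources with a positive green coefficient (0.44R + 0.88G + 0.39B +
18.79); it is kept selectable for comparison but makes CIVE an increasing
brightness-like quantity, inconsistent with published pure-vegetation CIVE
endpoints being negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ContractError
from .raster import RGBImage

__all__ = [
    "IndexDefinition",
    "IndexImage",
    "INDEX_NAMES",
    "list_indices",
    "get_index",
    "compute_index",
]

Polarity = Literal["increasing", "decreasing"]

#: Canonical index order used for stable iteration and tie-breaking.
INDEX_NAMES = ("EXG", "GRVI", "EXGR", "NGBDI", "CIVE", "RGBVI", "VDVI")

_CIVE_COEFFS = {
    "literature": (0.441, -0.811, 0.385, 18.78745),
    "paper": (0.44, 0.88, 0.39, 18.79),
}


@dataclass(frozen=True)
class IndexDefinition:
    """A named vegetation index: its formula, polarity, and CIVE preset."""

    name: str
    polarity: Polarity
    cive_preset: str | None = None

    def __call__(self, r: np.ndarray, g: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Apply the formula; return ``(values, defined)``.

        ``defined`` is False where the formula is undefined (zero denominator
        of a normalized index); such pixels must be dropped, not zero-filled,
        or they would bias endpoint percentiles.
        """
        r = np.asarray(r, dtype=np.float64)
        g = np.asarray(g, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        ok = np.ones(np.broadcast(r, g, b).shape, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.name == "EXG":
                v = 2.0 * g - r - b
            elif self.name == "GRVI":
                den = g + r
                ok = den != 0
                v = np.where(ok, (g - r) / np.where(ok, den, 1.0), np.nan)
            elif self.name == "EXGR":
                v = (2.0 * g - r - b) - (1.4 * r - g)
            elif self.name == "NGBDI":
                den = g + b
                ok = den != 0
                v = np.where(ok, (g - b) / np.where(ok, den, 1.0), np.nan)
            elif self.name == "CIVE":
                cr, cg, cb, c0 = _CIVE_COEFFS[self.cive_preset or "literature"]
                v = cr * r + cg * g + cb * b + c0
            elif self.name == "RGBVI":
                den = g * g + r * b
                ok = den != 0
                v = np.where(ok, (g * g - r * b) / np.where(ok, den, 1.0), np.nan)
            elif self.name == "VDVI":
                den = g + (r + b) / 2.0
                ok = den != 0
                v = np.where(ok, (g - (r + b) / 2.0) / np.where(ok, den, 1.0), np.nan)
            else:  # pragma: no cover - constructor guards the name set
                raise ContractError(f"unknown index {self.name!r}")
        return v, ok


@dataclass
class IndexImage:
    """A single-band vegetation-index grid tagged with its definition."""

    values: np.ndarray
    index: IndexDefinition
    valid_mask: np.ndarray
    georeference: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ContractError("values and valid_mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def get_index(name: str, cive_preset: str = "literature") -> IndexDefinition:
    """Look up an index definition by (case-insensitive) name."""
    key = name.upper()
    if key not in INDEX_NAMES:
        raise ContractError(f"unknown index {name!r}; choose from {INDEX_NAMES}")
    if key == "CIVE":
        if cive_preset not in _CIVE_COEFFS:
            raise ContractError(f"unknown CIVE preset {cive_preset!r}")
        return IndexDefinition(name=key, polarity="decreasing", cive_preset=cive_preset)
    return IndexDefinition(name=key, polarity="increasing")


def list_indices(cive_preset: str = "literature") -> list[IndexDefinition]:
    """The seven index definitions in canonical order."""
    return [get_index(name, cive_preset) for name in INDEX_NAMES]


def compute_index(image: RGBImage, index: IndexDefinition | str) -> IndexImage:
    """Compute a vegetation index over an RGB image.

    Pixels where a normalized index's denominator vanishes are marked
    invalid in the output mask; input-invalid pixels stay invalid.
    """
    if isinstance(index, str):
        index = get_index(index)
    values, defined = index(image.red, image.green, image.blue)
    mask = image.valid_mask & defined
    values = np.where(mask, values, np.nan)
    return IndexImage(values=values, index=index, valid_mask=mask,
                      georeference=image.georeference)
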