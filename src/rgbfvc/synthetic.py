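"""Seeded synthetic multi-class RGB scenes with ground truth.

A scene emulates a restored-mining-area land cover mosaic: five classes
(vegetation, bare ground, road, sedimentation pond, building) laid out as
contiguous patches, each with its own mean color and Gaussian color spread,
plus additive per-channel sensor noise.  A configurable share of pixels on
the vegetation side are two-endmember mixtures — convex blends of the
vegetation and bare-ground colors with a uniform blend weight — mirroring
the linear-mixing assumption behind the dimidiate cover model.

Patch layout comes from thresholding a Gaussian-smoothed random field at the
rank quantiles of the requested class fractions, so realized class shares
match the specification to rounding and the patches have the blobby spatial
structure real cover maps show.  Every scene carries exact ground truth:
per-pixel class labels and the true fractional cover (1 on pure vegetation,
the blend weight on mixed pixels, 0 elsewhere).

Given the same seed, generation is bit-reproducible.  The color and noise
fields are drawn independently of the class layout, so scenes generated with
the same seed but different vegetation fractions share their non-vegetation
structure — a requirement for meaningful multi-date trend experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .dichotomy import FVCMap
from .errors import ContractError
from .raster import LabelMap, RGBImage

__all__ = ["ClassColor", "SceneSpec", "SyntheticScene", "generate_scene", "trend_scenes"]

#: Class layout order; vegetation and bare ground are adjacent in the rank
#: partition so their patches share borders, where mixed pixels are natural.
CLASS_ORDER = ("vegetation", "bare_ground", "road", "pond", "building")

#: Integer codes written to label rasters.
CLASS_CODES = {name: i + 1 for i, name in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class ClassColor:
    """Mean RGB of a class and the per-channel Gaussian spread around it."""

    mean: tuple[float, float, float]
    spread: float = 15.0


#: Default class colors: strongly green vegetation against gray/brown
#: non-vegetation, with building the brightest and bluest class.
DEFAULT_COLORS: dict[str, ClassColor] = {
    "vegetation": ClassColor((40.0, 120.0, 50.0)),
    "bare_ground": ClassColor((150.0, 130.0, 110.0)),
    "road": ClassColor((170.0, 170.0, 170.0)),
    "pond": ClassColor((120.0, 130.0, 125.0)),
    "building": ClassColor((180.0, 190.0, 210.0)),
}

#: Default class shares, matching a high-cover restored scene
#: (vegetation ~74%, the remainder split among bare ground, roads,
#: a small pond and buildings).
DEFAULT_FRACTIONS: dict[str, float] = {
    "vegetation": 0.737,
    "bare_ground": 0.071,
    "road": 0.103,
    "pond": 0.018,
    "building": 0.071,
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    width: int = 256
    height: int = 256
    class_fractions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    class_colors: Mapping[str, ClassColor] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    mixed_pixel_fraction: float = 0.05
    noise_sd: float = 5.0
    blob_sigma: float = 8.0
    seed: int = 0

    def validated(self) -> "SceneSpec":
        if self.width <= 0 or self.height <= 0:
            raise ContractError("degenerate scene dimensions")
        fractions = dict(self.class_fractions)
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ContractError("class fractions must sum to 1")
        if any(f < 0 for f in fractions.values()):
            raise ContractError("negative class fraction")
        unknown = set(fractions) - set(self.class_colors)
        if unknown:
            raise ContractError(f"classes without colors: {sorted(unknown)}")
        for cc in self.class_colors.values():
            if any(not 0 <= v <= 255 for v in cc.mean):
                raise ContractError("class mean color outside 0-255")
        if not 0.0 <= self.mixed_pixel_fraction < 1.0:
            raise ContractError("mixed_pixel_fraction must lie in [0, 1)")
        return self

    def with_vegetation_fraction(self, veg: float) -> "SceneSpec":
        """Rescale non-vegetation shares proportionally so vegetation = veg."""
        if not 0.0 <= veg <= 1.0:
            raise ContractError("vegetation fraction must lie in [0, 1]")
        fractions = dict(self.class_fractions)
        rest = 1.0 - fractions.get("vegetation", 0.0)
        out = {}
        for name, f in fractions.items():
            if name == "vegetation":
                out[name] = veg
            else:
                out[name] = (f / rest if rest > 0 else 1.0 / (len(fractions) - 1)) * (1.0 - veg)
        return replace(self, class_fractions=out)


@dataclass
class SyntheticScene:
    """A generated image plus its exact ground truth."""

    image: RGBImage
    truth_labels: LabelMap
    truth_fvc: FVCMap
    spec: SceneSpec


def _class_layout(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Assign classes by rank-thresholding a smoothed random field."""
    h, w = spec.height, spec.width
    fld = gaussian_filter(rng.standard_normal((h, w)), sigma=spec.blob_sigma)
    order = np.argsort(fld, axis=None, kind="stable")
    n = h * w
    fractions = spec.class_fractions
    counts = {name: int(round(fractions.get(name, 0.0) * n)) for name in CLASS_ORDER}
    # distribute rounding remainder to the largest class
    drift = n - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    labels = np.empty(n, dtype=np.int32)
    start = 0
    for name in CLASS_ORDER:
        stop = start + counts[name]
        labels[order[start:stop]] = CLASS_CODES[name]
        start = stop
    return labels.reshape(h, w)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene deterministically from its specification."""
    spec = spec.validated()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    labels = _class_layout(spec, rng)

    # color-variation and sensor-noise fields drawn independently of the
    # layout so same-seed scenes with different fractions stay comparable
    z_spread = rng.standard_normal((h, w, 3))
    z_noise = rng.standard_normal((h, w, 3))
    blend = rng.uniform(0.0, 1.0, size=(h, w))
    mix_order = rng.permutation(h * w)

    img = np.zeros((h, w, 3))
    for name in CLASS_ORDER:
        cc = spec.class_colors[name]
        sel = labels == CLASS_CODES[name]
        img[sel] = np.asarray(cc.mean) + cc.spread * z_spread[sel]

    truth = (labels == CLASS_CODES["vegetation"]).astype(np.float64)

    n_mixed = int(round(spec.mixed_pixel_fraction * h * w))
    veg_or_soil = np.isin(labels.ravel(), [CLASS_CODES["vegetation"], CLASS_CODES["bare_ground"]])
    has_both = (labels == CLASS_CODES["vegetation"]).any() and (labels == CLASS_CODES["bare_ground"]).any()
    if n_mixed > 0 and has_both:
        candidates = mix_order[veg_or_soil[mix_order]][:n_mixed]
        rows, cols = np.unravel_index(candidates, (h, w))
        wgt = blend[rows, cols]
        veg_c = spec.class_colors["vegetation"]
        soil_c = spec.class_colors["bare_ground"]
        veg_draw = np.asarray(veg_c.mean) + veg_c.spread * z_spread[rows, cols]
        soil_draw = np.asarray(soil_c.mean) + soil_c.spread * z_spread[rows, cols][:, ::-1]
        img[rows, cols] = wgt[:, None] * veg_draw + (1.0 - wgt[:, None]) * soil_draw
        truth[rows, cols] = wgt

    img += spec.noise_sd * z_noise
    np.clip(img, 0.0, 255.0, out=img)

    image = RGBImage(red=img[..., 0], green=img[..., 1], blue=img[..., 2])
    class_names = {CLASS_CODES[name]: name for name in CLASS_ORDER}
    truth_labels = LabelMap(labels=labels, class_names=class_names)
    truth_fvc = FVCMap(values=truth, endpoints=None,
                       valid_mask=np.ones((h, w), dtype=bool))
    return SyntheticScene(image=image, truth_labels=truth_labels,
                          truth_fvc=truth_fvc, spec=spec)


def trend_scenes(base: SceneSpec, veg_fractions: Sequence[float]) -> list[SyntheticScene]:
    """One scene per vegetation fraction, sharing the base seed stream.

    The underlying random field, color variation and noise are identical
    across the list, so only the class partition moves — the synthetic
    analogue of one site revisited on several dates.
    """
    if len(veg_fractions) == 0:
        raise ContractError("empty vegetation-fraction list")
    return [generate_scene(base.with_vegetation_fraction(f)) for f in veg_fractions]
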