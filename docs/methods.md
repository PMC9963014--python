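# Methods

## Model

`rgbfvc` estimates fractional vegetation cover (FVC) from true-color
imagery with the dimidiate pixel model. The model assumes each pixel's
vegetation-index value VI is an area-weighted linear mixture of exactly two
endmembers — pure vegetation (VI_veg) and pure soil/non-vegetation
(VI_soil) — so the cover fraction is the affine position of VI between

    FVC = (VI − VI_soil) / (VI_veg − VI_soil)

clipped to [0, 1]. The assumptions this inherits: (i) two endmembers
suffice (water, shadow, built surfaces are lumped into "soil"); (ii) the
index responds linearly to sub-pixel cover; (iii) the endmembers are
spatially constant across the scene. None of these is exactly true of real
scenes; the model's appeal is that it needs no training data and no bands
beyond R, G, B.

Seven visible-band indices drive the model. Six increase with greenness;
CIVE decreases, which matters wherever a "high" tail must be interpreted:
for CIVE the soil endmember is the *upper* histogram tail. Each index's
polarity is part of its definition and is consulted by the endpoint
estimator, so no caller ever hard-codes a direction.

CIVE ships with two coefficient presets. The default, `literature`, is
0.441R − 0.811G + 0.385B + 18.78745 — the standard form, whose negative
green coefficient is what makes CIVE decrease over vegetation and is the
only form consistent with published negative pure-vegetation CIVE
endpoints. The alternative `paper` preset (0.44R + 0.88G + 0.39B + 18.79),
printed in some sources, is kept selectable for comparison; with every
coefficient positive it behaves as a brightness index, and its polarity is
then genuinely increasing-with-brightness rather than tied to greenness, so
results under this preset are not comparable with published CIVE endpoint
tables.

## Endpoint estimation

Pure-pixel endmembers are estimated from the index histogram of the scene
itself at a confidence level c (default 0.02, i.e. 2%): the soil endpoint
is the value at cumulative valid-pixel fraction c and the vegetation
endpoint at 1 − c, with the two assignments swapped for decreasing-polarity
indices. Percentiles use the **nearest-rank rule**: on the n sorted valid
pixels, the ceil(q·n)-th order statistic (1-based). This gives exact
integer-rank semantics — an independent sort-and-count loop reproduces the
estimator bit-for-bit — instead of the interpolation most percentile
routines default to.

One boundary consequence is documented rather than hidden: negating an
index image and flipping its declared polarity reproduces the FVC map
exactly whenever c·n is not an integer (the generic case for continuous
data); when c·n lands exactly on a rank boundary, the mirrored estimate
sits one order statistic away, because ceil(c·n) + ceil((1−c)·n) = n rather
than n + 1 there. The estimator follows the cumulative-fraction reading
consistently in both directions; tests assert the generic symmetry and the
boundary off-by-one explicitly.

Estimation requires at least 100 valid pixels and a non-degenerate
distribution (distinct tails); published endpoint values can be supplied
directly in place of estimation, e.g. to reproduce worked examples or to
hold endpoints fixed across dates.

Pixels where a normalized index's denominator vanishes (e.g. G + R = 0 for
GRVI on a pure-black pixel) are marked invalid rather than zero-filled; a
zero there is not a measurement and would bias the tail percentiles.

## Clipping and grading

Values beyond the endpoints are clamped: below the soil endpoint → 0 (fully
bare), beyond the vegetation endpoint → 1 (full cover). By construction
roughly a c-share of pixels pins to each extreme.

Cover maps are discretized by two schemes: `five_level` — [0, 0.2),
[0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0], codes 1–5 — and
`six_level`, which prepends a dedicated code 0 for exactly-zero cover
(useful when the zero class is a clamped "no vegetation" statement rather
than a low measurement). Intervals are lower-inclusive / upper-exclusive
except the top, which includes 1.0; exact boundary values therefore grade
deterministically upward.

## Evaluation

The reference cover fraction of a classified map is the vegetation share of
all classified pixels — invariant to how the non-vegetation classes are
split or merged. A model's extraction error is

    EC = |FI − FV| / FI × 100   (percent)

with FI the reference and FV the model mean cover. The absolute value makes
EC a magnitude; the signed information is preserved separately in the
report's fraction-scale difference. Agreement between two label maps is
summarized by the confusion matrix over jointly valid pixels, overall
accuracy (trace/total), and Cohen's kappa (p_o − p_e)/(1 − p_e) with p_e
from the marginal products; kappa is reported as undefined, not an error,
when both maps are single-class (p_e = 1). Stored values keep full
precision; two-decimal rounding happens only at presentation.

Model comparison tables rank by EC ascending with ties broken by the
canonical index order (EXG, GRVI, EXGR, NGBDI, CIVE, RGBVI, VDVI).

## Multi-date analysis

Scenes are assumed co-registered; mismatched dimensions are an error, never
silently resampled. The series summary reports per-date mean FVC and
six-level grade-area shares; the change map is simply later − earlier on
jointly valid pixels. Endpoints are re-estimated per date by default — each
scene's illumination and phenology set its own endmembers — with an option
to estimate once and hold fixed, which trades per-date adaptivity for a
common scale. No trend fitting or significance testing is performed.

## Synthetic scenes

The generator emulates a restored-mining-area land-cover mosaic: five
classes (vegetation, bare ground, road, sedimentation pond, building) laid
out as contiguous patches by thresholding a Gaussian-smoothed random field
(smoothing sigma 8 px at the default 256×256 size) at the rank quantiles of
the requested class fractions, so realized shares match the request to
rounding. Default composition is a high-cover scene — vegetation 0.737,
bare ground 0.071, road 0.103, pond 0.018, building 0.071, the class
proportions of a real restored-area reference classification. Each class
draws pixel colors from a Gaussian around its mean color (default spread 15
channel units; vegetation (40, 120, 50) strongly green against gray/brown
non-vegetation), plus additive sensor noise (default sd 5). A 5% share of
pixels on the vegetation/bare-ground side are convex blends of the two
endmember colors with uniform blend weight — exactly the mixture the
dichotomy model assumes. Ground truth (labels, per-pixel true cover) is
exact by construction, and generation is bit-reproducible from the seed;
same-seed scenes with different vegetation fractions share their random
fields, giving comparable multi-date sequences with nested vegetation
patches.

What the generator does **not** emulate: shadows, atmospheric and seasonal
effects, compression artifacts, spatially varying illumination, and
three-way mixtures. Passing tests on these scenes therefore demonstrate the
pipeline's internal correctness and its statistical behaviour under the
two-endmember assumption — not accuracy on arbitrary real imagery.

## Known limitations

**Attenuation bias of tail endpoints.** With endpoints taken at the 2%/98%
histogram tails, each endpoint lies roughly two standard deviations inside
its class's color-noise distribution, so typical vegetation pixels score
below 1 and typical soil pixels above 0: mean cover is attenuated toward
the interior. On the default high-cover synthetic scene this is a
substantial *underestimate* (the acceptance script reports the measured
per-index recovery errors; the worked example in the README shows CIVE
recovering 0.589 against a true 0.716), the bias crossing zero near 50%
cover and reversing sign below it. This mirrors the published experience
with this model family, where six of seven visible-index models deviated by
0.11–0.30 absolute from their supervised reference. The bias shrinks as
within-class color spread shrinks relative to the vegetation–soil
separation; it is a property of percentile endpoint selection, not of any
particular index. Consequently the pipeline's mean-cover *trends* (monotone
in true cover, reproducible across seeds) are more trustworthy than its
absolute levels, and applications needing unbiased absolute cover should
supply externally calibrated endpoints instead of histogram tails.

**Other numerical choices.** Channel values are carried as float64 in the
native 8-bit domain (0–255) by default; unit scaling is available but
published endpoint tables assume 8-bit. Nodata is an explicit mask
end-to-end — never a sentinel inside arithmetic — and no downstream
operation revalidates an invalid pixel. Rasters are written float32 (NaN
nodata) for continuous grids and int32 (−1 nodata) for grades and labels,
with GeoTIFF georeference tags passed through opaquely.
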