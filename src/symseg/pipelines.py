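"""The two symmetry pipelines and the plain Chan-Vese baseline.

HASA (hybrid algorithm using symmetry and active contour):
  optional morphology → reflect → difference D = O - R → localize the
  components where high rectified-difference intensities aggregate → seed a
  level set there → evolve the active contour *on the rectified difference
  image* → final mask = {φ > 0}.

EHASA (enhanced HASA):
  same front half, then binarize the rectified difference at
  T = 0.25 · max(O), map the binary mask back onto the original by
  elementwise product, seed from the mask's components, and evolve the
  contour *on the masked original image*. The hard threshold discards
  sub-threshold asymmetry residuals before the contour ever sees them,
  which is what suppresses the spurious extra regions HASA can segment.

Baseline: checkerboard-initialized Chan-Vese on the raw image with no
symmetry stage — the comparison arm that also segments every bright
non-tumor structure (skull, lobes).

All three are pure functions of (image, config): no randomness, no user
interaction, bit-identical masks on identical inputs. Because every stage
commutes exactly with left-right mirroring, the two symmetry pipelines are
exactly laterality-equivariant: run(mirror(I)) == mirror(run(I)) pixel for
pixel — the method cannot prefer a hemisphere. A lesion centered on the
midline, however, cancels in D and is invisible to both pipelines; this is
the method's documented failure mode, flagged by the metrics report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chanvese import evolve, init_level_set, region_means
from .config import PipelineConfig
from .errors import ParameterError
from .io import validate_gray_image
from .preprocess import morphological_clean
from .symmetry import DifferenceImage, difference_image, estimate_midline_shift, recenter, reflect

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structure


@dataclass(frozen=True)
class SeedRegion:
    """A connected aggregate of high rectified-difference intensity.

    mass is the summed rectified intensity over the component; the
    equivalent radius (of the disk with the same area, floored at 2 px)
    sizes the level-set seed disk.
    """

    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    mass: float
    area_px: int

    @property
    def radius(self) -> float:
        return max(2.0, math.sqrt(self.area_px / math.pi))


@dataclass(frozen=True)
class RegionRecord:
    """Per-component record of a final segmentation."""

    area_px: int
    centroid: tuple[float, float]
    mean_intensity: float
    touches_border: bool


@dataclass
class SegmentationResult:
    """Final mask plus per-component bookkeeping for one pipeline run."""

    mask: np.ndarray
    regions: list[RegionRecord]
    n_regions: int
    method: str
    params_used: dict
    intermediates: dict = field(default_factory=dict)


def _component_stats(mask: np.ndarray, intensity: np.ndarray) -> list[RegionRecord]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    records = []
    rows, cols = mask.shape
    for k in range(1, n + 1):
        comp = labels == k
        rr, cc = np.nonzero(comp)
        area = int(rr.size)
        # integer index sums are exact in float64, keeping centroids
        # bit-identical under mirroring
        centroid = (float(rr.sum()) / area, float(cc.sum()) / area)
        touches = bool(
            (rr == 0).any() or (rr == rows - 1).any() or (cc == 0).any() or (cc == cols - 1).any()
        )
        records.append(
            RegionRecord(
                area_px=area,
                centroid=centroid,
                mean_intensity=float(intensity[comp].mean()),
                touches_border=touches,
            )
        )
    records.sort(key=lambda r: (-r.area_px, r.centroid))
    return records


def _make_result(
    mask: np.ndarray,
    intensity: np.ndarray,
    method: str,
    config: PipelineConfig,
    intermediates: dict,
) -> SegmentationResult:
    if config.drop_border_regions:
        labels, _n = ndimage.label(mask, structure=_EIGHT)
        border_labels = (
            set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
        ) - {0}
        if border_labels:
            mask = mask & ~np.isin(labels, sorted(border_labels))
    regions = _component_stats(mask, intensity)
    return SegmentationResult(
        mask=mask,
        regions=regions,
        n_regions=len(regions),
        method=method,
        params_used=config.to_dict(),
        intermediates=intermediates,
    )


def localize_high_intensity(
    diff: DifferenceImage,
    frac: float = 0.5,
    min_area: int = 10,
    noise_floor: float = 0.05,
) -> list[SeedRegion]:
    """Components of the rectified difference above frac of its maximum.

    Thresholds the rectified field at frac·max, labels 8-connected
    components, drops those smaller than min_area, and returns the rest as
    SeedRegions sorted by mass descending. An empty list — returned outright
    when the rectified maximum sits below the noise floor — is the no-tumor
    signal, not an error.
    """
    if not 0 < frac < 1:
        raise ParameterError(f"frac must be in (0, 1), got {frac}")
    rect = diff.rectified
    peak = float(rect.max())
    if peak < noise_floor:
        return []
    labels, n = ndimage.label(rect > frac * peak, structure=_EIGHT)
    seeds = []
    for k in range(1, n + 1):
        comp = labels == k
        rr, cc = np.nonzero(comp)
        area = int(rr.size)
        if area < int(min_area):
            continue
        seeds.append(
            SeedRegion(
                centroid=(float(rr.sum()) / area, float(cc.sum()) / area),
                bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
                mass=float(math.fsum(rect[comp])),
                area_px=area,
            )
        )
    seeds.sort(key=lambda s: (-s.mass, s.centroid))
    return seeds


def _seeds_from_mask(mask: np.ndarray, intensity: np.ndarray, min_area: int) -> list[SeedRegion]:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    seeds = []
    for k in range(1, n + 1):
        comp = labels == k
        rr, cc = np.nonzero(comp)
        area = int(rr.size)
        if area < int(min_area):
            continue
        seeds.append(
            SeedRegion(
                centroid=(float(rr.sum()) / area, float(cc.sum()) / area),
                bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
                mass=float(math.fsum(intensity[comp])),
                area_px=area,
            )
        )
    seeds.sort(key=lambda s: (-s.mass, s.centroid))
    return seeds


def ehasa_threshold(image: np.ndarray, fraction: float = 0.25) -> float:
    """Binarization threshold T = fraction · max(O): about 25% of the
    original image's maximum intensity by default."""
    arr = validate_gray_image(image)
    return float(fraction) * float(arr.max())


def ehasa_mask(diff: DifferenceImage, threshold: float) -> np.ndarray:
    """Binary mask of the rectified difference: True where it exceeds T."""
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    return diff.rectified > threshold


def map_mask(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Elementwise product of mask and original: outside pixels become 0."""
    arr = validate_gray_image(image)
    m = np.asarray(mask)
    if m.shape != arr.shape:
        raise ParameterError(f"shape mismatch: mask {m.shape} vs image {arr.shape}")
    return arr * m


def _front_half(image: np.ndarray, config: PipelineConfig):
    """Shared stages: optional morphology, optional recentering, reflection,
    difference. Returns (working image, reflection, DifferenceImage)."""
    work = validate_gray_image(image)
    if config.preprocess_enabled:
        work = morphological_clean(work, config.preprocess_radius, config.preprocess_mode)
    if config.shift_search:
        work = recenter(work, estimate_midline_shift(work))
    refl = reflect(work)
    return work, refl, difference_image(work, refl)


def _empty_result(image, method, config, intermediates):
    mask = np.zeros(np.asarray(image).shape, dtype=bool)
    return _make_result(mask, np.asarray(image, dtype=float), method, config, intermediates)


def run_hasa(image: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """HASA: seed where asymmetry aggregates, contour the difference image."""
    config = config or PipelineConfig()
    work, refl, diff = _front_half(image, config)
    intermediates = {
        "preprocessed": work,
        "reflection": refl,
        "difference_signed": diff.signed,
        "difference_rectified": diff.rectified,
    }
    seeds = localize_high_intensity(
        diff, config.seed_frac, config.seed_min_area, config.noise_floor
    )
    if not seeds:
        return _empty_result(work, "hasa", config, intermediates)
    phi0 = init_level_set(work.shape, [(s.centroid[0], s.centroid[1], s.radius) for s in seeds])
    phi = evolve(diff.rectified, phi0, config.chanvese)
    mask = phi > 0
    intermediates["final_mask"] = mask
    return _make_result(mask, diff.rectified, "hasa", config, intermediates)


def run_ehasa(image: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """EHASA: binarize the difference at T, map onto the original, contour."""
    config = config or PipelineConfig()
    work, refl, diff = _front_half(image, config)
    if config.ehasa_use_mean:
        threshold = float(np.mean(diff.rectified))
    else:
        threshold = ehasa_threshold(work, config.ehasa_fraction)
    bmask = ehasa_mask(diff, threshold)
    mapped = map_mask(bmask, work)
    intermediates = {
        "preprocessed": work,
        "reflection": refl,
        "difference_signed": diff.signed,
        "difference_rectified": diff.rectified,
        "binary_mask": bmask,
        "mapped": mapped,
    }
    seeds = _seeds_from_mask(bmask, mapped, config.seed_min_area)
    if not seeds:
        return _empty_result(work, "ehasa", config, intermediates)
    phi0 = init_level_set(work.shape, [(s.centroid[0], s.centroid[1], s.radius) for s in seeds])
    phi = evolve(mapped, phi0, config.chanvese)
    mask = phi > 0
    intermediates["final_mask"] = mask
    return _make_result(mask, mapped, "ehasa", config, intermediates)


def run_chanvese_baseline(
    image: np.ndarray, config: PipelineConfig | None = None
) -> SegmentationResult:
    """Plain Chan-Vese on the raw image, checkerboard-initialized.

    No symmetry stage and no seeding: every bright structure is fair game,
    which on head slices yields extra non-tumor regions. Images with no
    usable contrast (peak-to-peak below the noise floor) return an empty
    result, since the two-phase split is then meaningless.
    """
    config = config or PipelineConfig()
    work = validate_gray_image(image)
    intermediates: dict = {}
    if float(work.max() - work.min()) < config.noise_floor:
        return _empty_result(work, "chanvese-baseline", config, intermediates)
    phi0 = init_level_set(work.shape, None)
    phi = evolve(work, phi0, config.chanvese)
    mask = phi > 0
    c1, c2 = region_means(work, phi, config.chanvese.eps)
    if c1 < c2:  # report the brighter phase as the object
        mask = ~mask
    intermediates["final_mask"] = mask
    return _make_result(mask, work, "chanvese-baseline", config, intermediates)
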