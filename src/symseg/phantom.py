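"""Synthetic axial brain-slice phantoms with ground truth.

A phantom emulates the features the symmetry pipelines care about in a real
T2-style slice: a bright elliptical brain on a dark background, a bilaterally
symmetric bright skull/scalp rim separated from the brain by a dark CSF gap,
a mirrored pair of dark ventricles, one or more hyperintense lesions at
arbitrary lateral positions, mild natural hemispheric asymmetry (per-pixel
multiplicative jitter on one hemisphere), and additive Gaussian noise
(truncated at ±3σ so a noise outlier can never masquerade as a lesion).
Optional bright *artifacts* — non-tumor hyperintense streaks excluded from
the ground truth — exercise the false-positive behavior that separates the
two pipelines.

Everything symmetric is rendered about the exact mirror axis (column
(cols-1)/2), so a spec with no lesions, no jitter and no noise is exactly
left-right symmetric and its difference image is identically zero. The
ground-truth mask is the union of the lesions' ideal ellipses, rendered
before jitter and noise, so truth is independent of the noise realization.
All randomness flows from ``rng_seed``; the same spec renders bit-identical
images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError

BACKGROUND = 0.05


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-by-default ellipse: center (row, col), semi-axes
    (rows, cols), rotation angle in degrees, and an intensity value whose
    meaning depends on context (absolute level for anatomy, positive delta
    over local tissue for lesions/artifacts)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    intensity: float
    angle_deg: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic slice.

    shape             (rows, cols) of the rendered image.
    head              bright brain ellipse (absolute intensity).
    skull             optional symmetric bright rim: an Ellipse giving the
                      *outer* boundary plus ``skull_thickness`` (px).
    ventricles        optional pair of dark ellipses; rendered as given, so
                      a symmetric phantom must list a mirrored pair.
    lesions           hyperintense lesions; ``intensity`` is the positive
                      delta added on top of the local tissue. These define
                      the ground-truth mask.
    artifacts         bright non-tumor ellipses (same delta semantics),
                      excluded from ground truth.
    asymmetry_jitter  max fractional per-pixel multiplicative perturbation
                      applied to the right hemisphere (mild natural
                      asymmetry).
    noise_sigma       std of additive zero-mean Gaussian noise, truncated
                      at ±3σ; must be < 0.2.
    rng_seed          seed for jitter and noise.
    mirrored          render, then flip image and truth left-right (used to
                      build an exact mirror fixture).
    """

    shape: tuple[int, int] = (128, 128)
    head: Ellipse = Ellipse((63.5, 63.5), (44.0, 36.0), 0.55)
    skull: Ellipse | None = Ellipse((63.5, 63.5), (54.0, 46.0), 0.80)
    skull_thickness: float = 4.0
    ventricles: tuple[Ellipse, ...] = (
        Ellipse((66.0, 53.5), (9.0, 3.5), 0.25),
        Ellipse((66.0, 73.5), (9.0, 3.5), 0.25),
    )
    lesions: tuple[Ellipse, ...] = ()
    artifacts: tuple[Ellipse, ...] = ()
    asymmetry_jitter: float = 0.0
    noise_sigma: float = 0.0
    rng_seed: int = 0
    mirrored: bool = False

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ParameterError(f"phantom shape must be at least 8x8, got {self.shape}")
        if self.noise_sigma < 0 or self.noise_sigma >= 0.2:
            raise ParameterError(
                f"noise_sigma must be in [0, 0.2), got {self.noise_sigma}"
            )
        if self.asymmetry_jitter < 0:
            raise ParameterError("asymmetry_jitter must be >= 0")
        for les in self.lesions + self.artifacts:
            if les.intensity <= 0:
                raise ParameterError("lesion/artifact intensity delta must be > 0")


def _rho(shape, ellipse: Ellipse) -> np.ndarray:
    """Normalized elliptical radius: 1 on the boundary, < 1 inside."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - ellipse.center[0]
    dc = cc - ellipse.center[1]
    if ellipse.angle_deg:
        t = np.deg2rad(ellipse.angle_deg)
        u = np.cos(t) * dr + np.sin(t) * dc
        v = -np.sin(t) * dr + np.cos(t) * dc
    else:
        u, v = dr, dc
    a, b = ellipse.semi_axes
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _coverage(shape, ellipse: Ellipse) -> np.ndarray:
    """Anti-aliased ellipse indicator: ~1 px soft edge, 0.5 on the boundary."""
    rho = _rho(shape, ellipse)
    softness = min(ellipse.semi_axes)  # d(rho)/d(px) ~ 1/min(axes) near the edge
    return np.clip(0.5 + (1.0 - rho) * softness, 0.0, 1.0)


def _paint(img: np.ndarray, cover: np.ndarray, level: float) -> np.ndarray:
    return img * (1.0 - cover) + level * cover


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a spec into (image, ground-truth lesion mask).

    The image is float64 in [0, 1]; the truth mask is boolean (pixels whose
    center lies inside a lesion's ideal ellipse). Fully reproducible from
    ``rng_seed``; the truth does not depend on jitter or noise.
    """
    shape = spec.shape
    img = np.full(shape, BACKGROUND, dtype=float)

    if spec.skull is not None:
        outer = _coverage(shape, spec.skull)
        inner_axes = (
            spec.skull.semi_axes[0] - spec.skull_thickness,
            spec.skull.semi_axes[1] - spec.skull_thickness,
        )
        if min(inner_axes) <= 0:
            raise ParameterError("skull thickness exceeds its semi-axes")
        inner = _coverage(shape, replace(spec.skull, semi_axes=inner_axes))
        ring = np.clip(outer - inner, 0.0, 1.0)
        img = _paint(img, ring, spec.skull.intensity)

    head_cover = _coverage(shape, spec.head)
    img = _paint(img, head_cover, spec.head.intensity)
    head_inside = _rho(shape, spec.head) <= 1.0

    for vent in spec.ventricles:
        img = _paint(img, _coverage(shape, vent), vent.intensity)

    truth = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        cover = _coverage(shape, les)
        if ((cover > 0) & ~head_inside).any():
            raise ParameterError(f"lesion {les} extends outside the head ellipse")
        img = img + les.intensity * cover
        truth |= _rho(shape, les) <= 1.0

    for art in spec.artifacts:
        img = img + art.intensity * _coverage(shape, art)

    if (img > 1.0 + 1e-9).any():
        raise ParameterError("intensity deltas push pixels above 1.0")
    img = np.clip(img, 0.0, 1.0)

    rng = np.random.default_rng(spec.rng_seed)
    if spec.asymmetry_jitter > 0:
        half = shape[1] // 2
        jitter = rng.uniform(
            -spec.asymmetry_jitter, spec.asymmetry_jitter, size=(shape[0], shape[1] - half)
        )
        img[:, half:] *= 1.0 + jitter
    if spec.noise_sigma > 0:
        s = spec.noise_sigma
        noise = np.clip(rng.normal(0.0, s, size=shape), -3 * s, 3 * s)
        img = img + noise
    img = np.clip(img, 0.0, 1.0)

    if spec.mirrored:
        img = img[:, ::-1].copy()
        truth = truth[:, ::-1].copy()
    return img, truth


# --- the standard fixture suite -------------------------------------------

_LEFT_LESION = Ellipse((56.0, 40.0), (8.0, 6.0), 0.40)
_RIGHT_SMALL = Ellipse((78.0, 86.0), (7.0, 5.0), 0.40)
_MIDLINE = Ellipse((46.0, 63.5), (8.0, 6.0), 0.40)
_ARTIFACT = Ellipse((46.0, 82.0), (12.0, 3.0), 0.18, angle_deg=30.0)

_SUITE_NOISE = 0.02
_SUITE_JITTER = 0.02


def standard_suite(base_seed: int = 7) -> list[tuple[str, PhantomSpec]]:
    """The six named study fixtures, all 128x128 with fixed seeds.

    "symmetric"            no lesion: the null slice.
    "left-lesion"          one hyperintense lesion, left hemisphere.
    "right-lesion"         the exact left-right mirror of "left-lesion"
                           (same seed, mirrored render).
    "bilateral-two-lesions" one lesion per hemisphere at non-mirroring
                           positions.
    "midline-lesion"       lesion centered on the symmetry axis — the
                           documented failure mode.
    "lesion-plus-artifact" left lesion plus a milder bright non-tumor
                           streak on the right, excluded from truth.
    """
    base = dict(asymmetry_jitter=_SUITE_JITTER, noise_sigma=_SUITE_NOISE)
    left = PhantomSpec(lesions=(_LEFT_LESION,), rng_seed=base_seed + 1, **base)
    return [
        ("symmetric", PhantomSpec(rng_seed=base_seed, **base)),
        ("left-lesion", left),
        ("right-lesion", replace(left, mirrored=True)),
        (
            "bilateral-two-lesions",
            PhantomSpec(lesions=(_LEFT_LESION, _RIGHT_SMALL), rng_seed=base_seed + 2, **base),
        ),
        ("midline-lesion", PhantomSpec(lesions=(_MIDLINE,), rng_seed=base_seed + 3, **base)),
        (
            "lesion-plus-artifact",
            PhantomSpec(
                lesions=(_LEFT_LESION,), artifacts=(_ARTIFACT,), rng_seed=base_seed + 4, **base
            ),
        ),
    ]


def large_case_spec(rng_seed: int = 11) -> PhantomSpec:
    """A 512x512 single-lesion case mirroring the geometry of a 512-row
    clinical acquisition (everything scaled x4 from the 128 default)."""
    return PhantomSpec(
        shape=(512, 512),
        head=Ellipse((255.5, 255.5), (176.0, 144.0), 0.55),
        skull=Ellipse((255.5, 255.5), (216.0, 184.0), 0.80),
        skull_thickness=16.0,
        ventricles=(
            Ellipse((264.0, 215.5), (36.0, 14.0), 0.25),
            Ellipse((264.0, 295.5), (36.0, 14.0), 0.25),
        ),
        lesions=(Ellipse((224.0, 160.0), (32.0, 24.0), 0.40),),
        asymmetry_jitter=_SUITE_JITTER,
        noise_sigma=_SUITE_NOISE,
        rng_seed=rng_seed,
    )


def export_dicom(image: np.ndarray, path) -> None:
    """Write a [0, 1] grayscale array as a minimal synthetic 8-bit
    MONOCHROME2 secondary-capture DICOM, exercising the DICOM reader
    end-to-end. The file carries WindowCenter=127.5 / WindowWidth=255 so
    the read-back reproduces the source intensities to 8-bit precision."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    arr = np.round(np.clip(np.asarray(image, dtype=float), 0.0, 1.0) * 255).astype(np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.WindowCenter = 127.5
    ds.WindowWidth = 255
    ds.PixelData = arr.tobytes()
    ds.save_as(str(Path(path)), enforce_file_format=True)
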