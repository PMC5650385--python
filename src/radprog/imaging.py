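"""Image variants for radiomics: LoG band-pass filtering, undecimated wavelet
decomposition, and gray-level discretization of the tumor ROI.

Each patient sequence is expanded into an indexed set of 13 image variants —
the original image, four Laplacian-of-Gaussian responses emphasising fine to
coarse texture (sigma 1.0, 1.5, 2.0, 2.5 pixels), and the eight subbands of a
single-level undecimated 3-D wavelet decomposition (coif1) — from which the
texture matrices are computed.  Variant indices are fixed by
:func:`build_variant_set` and never depend on the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "ROIMask",
    "VariantImage",
    "DiscretizedROI",
    "DEFAULT_LOG_SIGMAS",
    "WAVELET_SUBBANDS",
    "log_kernel_2d",
    "apply_log_filter",
    "wavelet_decompositions",
    "build_variant_set",
    "discretize",
]

#: LoG filter widths (pixels): 0 = no filtration (the original image is kept
#: separately), 1.0 = fine texture, 1.5/2.0 = medium, 2.5 = coarse.
DEFAULT_LOG_SIGMAS: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)

#: Subband order: low/high per axis (x, y, z), lexicographic with L < H.
WAVELET_SUBBANDS: tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)


@dataclass
class ImageVolume:
    """A 3-D scalar image with physical voxel spacing.

    Axes are (x, y, z); the axial plane is (x, y) and z indexes slices.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sequence_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class ROIMask:
    """A binary tumor mask aligned voxel-for-voxel with its image volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.values.ndim}")
        if not self.values.any():
            raise ValueError("mask is empty")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class VariantImage:
    """One filtered variant of a patient sequence, with its catalog index."""

    image: ImageVolume
    variant_index: int
    descriptor: str


@dataclass
class DiscretizedROI:
    """Gray levels 1..n_bins inside the mask, 0 outside."""

    levels: np.ndarray
    n_bins: int
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inside = self.levels > 0
        if not inside.any():
            raise ValueError("discretized ROI is empty")
        if self.levels.max() > self.n_bins:
            raise ValueError("level exceeds n_bins")

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def log_kernel_2d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discretized 2-D negated-Laplacian-of-Gaussian kernel.

    K(x, y) = -(1 / (pi sigma^4)) (1 - r^2 / (2 sigma^2)) exp(-r^2 / (2 sigma^2))

    sampled on an odd square grid of half-width ``ceil(truncate * sigma)`` and
    shifted to be exactly zero-sum, so a constant image yields a zero response.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive for a LoG kernel")
    radius = int(math.ceil(truncate * sigma))
    coords = np.arange(-radius, radius + 1, dtype=float)
    x, y = np.meshgrid(coords, coords, indexing="ij")
    r2 = x * x + y * y
    kernel = -(1.0 / (math.pi * sigma**4)) * (1.0 - r2 / (2.0 * sigma**2)) * np.exp(
        -r2 / (2.0 * sigma**2)
    )
    kernel -= kernel.mean()
    return kernel


def apply_log_filter(image: ImageVolume, sigma: float) -> ImageVolume:
    """Slice-wise 2-D LoG band-pass filter in the axial (x, y) plane.

    ``sigma`` is in pixels; ``sigma = 0`` means no filtration and returns the
    input values unchanged.  Boundaries use symmetric (reflect) extension.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return ImageVolume(image.values.copy(), image.spacing_mm, image.sequence_label)
    kernel = log_kernel_2d(sigma)
    out = ndimage.convolve(image.values, kernel[:, :, None], mode="reflect")
    return ImageVolume(out, image.spacing_mm, image.sequence_label)


def _filter_axis(values: np.ndarray, weights: np.ndarray, axis: int, mode: str) -> np.ndarray:
    # convolve1d flips the weights (true convolution), matching the wavelet
    # analysis convention y[n] = sum_k h[k] x[n - k] up to the centering shift.
    return ndimage.convolve1d(values, weights, axis=axis, mode=mode)


def wavelet_decompositions(
    image: ImageVolume,
    wavelet: str = "coif1",
    mode: str = "reflect",
    first_index: int = 6,
) -> list[VariantImage]:
    """Single-level undecimated 3-D wavelet decomposition into 8 subbands.

    Applies the analysis low-pass (L) / high-pass (H) filter of ``wavelet``
    along each of x, y, z without downsampling, so every subband has the shape
    of the input and the transform is shift-consistent.  Subbands are returned
    in the fixed order ``LLL, LLH, ..., HHH`` with catalog indices starting at
    ``first_index``.
    """
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo, dtype=float)
    hi = np.asarray(wav.dec_hi, dtype=float)
    flen = len(lo)
    for axis, n in enumerate(image.shape):
        if n < 2:
            raise ValueError(f"axis {axis} has length {n}; cannot decompose a degenerate axis")
        if n < flen:
            raise ValueError(
                f"axis {axis} has length {n} < filter length {flen} of {wavelet}"
            )
    out: list[VariantImage] = []
    for idx, name in enumerate(WAVELET_SUBBANDS):
        band = image.values
        for axis, letter in enumerate(name):
            band = _filter_axis(band, lo if letter == "L" else hi, axis, mode)
        out.append(
            VariantImage(
                ImageVolume(band, image.spacing_mm, image.sequence_label),
                variant_index=first_index + idx,
                descriptor=f"wavelet-{name}",
            )
        )
    return out


def build_variant_set(
    image: ImageVolume,
    log_sigmas: tuple[float, ...] = DEFAULT_LOG_SIGMAS,
    wavelet: str = "coif1",
) -> list[VariantImage]:
    """The full ordered variant set for one sequence.

    Index 1 is the original image, indices 2..(1+len(log_sigmas)) the LoG
    responses by ascending sigma, and the remaining 8 the wavelet subbands.
    With the default sigmas this yields 13 variants per sequence.
    """
    sigmas = tuple(float(s) for s in log_sigmas)
    if len(set(sigmas)) != len(sigmas):
        raise ValueError(f"duplicate LoG sigmas: {sigmas}")
    if any(s <= 0 for s in sigmas):
        raise ValueError("LoG sigmas must be positive (the original image is variant 1)")
    variants = [VariantImage(image, 1, "original")]
    for k, sigma in enumerate(sorted(sigmas)):
        variants.append(
            VariantImage(apply_log_filter(image, sigma), 2 + k, f"LoG-{sigma:g}")
        )
    variants.extend(
        wavelet_decompositions(image, wavelet=wavelet, first_index=2 + len(sigmas))
    )
    return variants


def discretize(image: ImageVolume, mask: ROIMask, n_bins: int = 32) -> DiscretizedROI:
    """Equal-width gray-level binning of in-mask intensities into 1..n_bins.

    Bin edges span the in-mask min..max; a constant region maps wholly to
    level 1.  Voxels outside the mask are assigned level 0.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    inside = mask.values
    vals = image.values[inside]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities inside the mask")
    vmin = vals.min()
    vmax = vals.max()
    levels = np.zeros(image.shape, dtype=np.int64)
    if vmax == vmin:
        levels[inside] = 1
    else:
        scaled = (image.values[inside] - vmin) / (vmax - vmin)
        levels[inside] = np.minimum(np.floor(scaled * n_bins).astype(np.int64) + 1, n_bins)
    return DiscretizedROI(levels, n_bins, image.spacing_mm)
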