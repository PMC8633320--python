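"""Tomato / calyx-stem segmentation from spectral-derivative significance maps.

The two tissue classes differ in *where* along the spectrum their reflectance
varies: tomato (fruit) pixels vary mostly below 1150 nm, sepal and stem pixels
mostly above it.  After per-spectrum SNV normalization, every pixel's spectrum
is filtered with the first derivative of a 1-D Gaussian in its local-difference
form

    r(i,j,n) = sum_{s=-L..L} ( m(i,j,n) - m(i,j,n+s) ) * g'(s),   L = ceil(3*sigma_g)

and two significance maps are formed by summing |r| over the bands at or below
the 1150 nm split (tomato map ``t``) and at or above it (calyx-stem map ``s``;
the split band contributes to both).  Each map is percentile-rescaled,
Otsu-thresholded, and overlaps are resolved toward the larger normalized
significance, yielding disjoint binary masks.  Dice overlap against reference
masks evaluates the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io import HyperCube

__all__ = [
    "DoGKernel",
    "SignificanceMaps",
    "RegionMasks",
    "snv_transform",
    "build_dog_kernel",
    "spectral_response",
    "significance_maps",
    "rescale_and_threshold",
    "segment_regions",
    "dice_score",
]

SPLIT_WAVELENGTH_NM = 1150.0


@dataclass(frozen=True)
class DoGKernel:
    """Sampled first derivative of a Gaussian, taps at integer band offsets -L..L."""

    sigma_g: float
    half_length: int
    taps: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_length, self.half_length + 1)


@dataclass
class SignificanceMaps:
    """Per-pixel evidence for each tissue class: tomato map ``t``, calyx-stem map ``s``."""

    t: np.ndarray
    s: np.ndarray


@dataclass
class RegionMasks:
    """Disjoint binary masks for the two tissue classes plus the parameters used."""

    tomato: np.ndarray
    calyxstem: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        if self.tomato.shape != self.calyxstem.shape:
            raise ValueError("region masks must share a shape")
        if np.any(self.tomato & self.calyxstem):
            raise ValueError("region masks must be disjoint")


def snv_transform(cube: HyperCube, min_sd: float = 0.0) -> HyperCube:
    """Standard normal variate: center and scale each pixel's spectrum.

    Uses the population standard deviation.  Spectrally constant pixels
    (sd <= ``min_sd``; exactly constant by default) are set to all-zero rather
    than aborting — flat background pixels are expected.  A positive
    ``min_sd`` extends the same policy to pixels whose spectral variation sits
    below the sensor noise floor: normalizing pure noise to unit variance
    would manufacture signal where there is none.
    """
    mean = cube.data.mean(axis=2, keepdims=True)
    sd = cube.data.std(axis=2, keepdims=True)
    flat = sd[:, :, 0] <= min_sd
    safe_sd = np.where(sd <= min_sd, 1.0, sd)
    out = (cube.data - mean) / safe_sd
    if flat.any():
        out[flat] = 0.0
    return HyperCube(out, cube.wavelengths, kind=cube.kind)


def build_dog_kernel(sigma_g: float = 2.5) -> DoGKernel:
    """Sample g'(x) = -(x / sigma_g^2) g(x) at integer offsets in [-L, L], L = ceil(3 sigma_g)."""
    if sigma_g <= 0:
        raise ValueError(f"sigma_g must be positive, got {sigma_g}")
    half_length = int(np.ceil(3.0 * sigma_g))
    x = np.arange(-half_length, half_length + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma_g**2)) / (np.sqrt(2.0 * np.pi) * sigma_g)
    taps = -(x / sigma_g**2) * g
    return DoGKernel(sigma_g=float(sigma_g), half_length=half_length, taps=taps)


def spectral_response(cube: HyperCube, kernel: DoGKernel) -> np.ndarray:
    """Local-difference derivative response r(i,j,n) at every band n.

    Implements the sum over the window centered at band n of
    ``(m(n) - m(n+s)) * g'(s)`` — not a plain convolution: the centered-
    difference term makes the response exactly zero for spectrally constant
    pixels.  Spectral edges are handled by reflection.
    """
    L = kernel.half_length
    if 2 * L + 1 > cube.n_bands:
        raise ValueError(
            f"kernel support {2 * L + 1} exceeds spectrum length {cube.n_bands}"
        )
    data = cube.data
    padded = np.pad(data, ((0, 0), (0, 0), (L, L)), mode="reflect")
    n_bands = cube.n_bands
    r = np.zeros_like(data, dtype=np.float64)
    # sum_s m(n) g'(s) vanishes only up to float rounding; keep the exact form.
    for idx, s in enumerate(range(-L, L + 1)):
        tap = kernel.taps[idx]
        if tap == 0.0:
            continue
        r += (data - padded[:, :, idx : idx + n_bands]) * tap
    return r


def significance_maps(
    r: np.ndarray, wavelengths: np.ndarray, lambda_d: float = SPLIT_WAVELENGTH_NM
) -> SignificanceMaps:
    """Sum |r| below and above the split wavelength; the split band feeds both maps."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if r.shape[2] != wavelengths.size:
        raise ValueError("response tensor and wavelengths must align")
    if not (wavelengths[0] < lambda_d < wavelengths[-1]):
        raise ValueError(
            f"split wavelength {lambda_d} nm outside range "
            f"[{wavelengths[0]:.1f}, {wavelengths[-1]:.1f}]"
        )
    d = int(np.argmin(np.abs(wavelengths - lambda_d)))
    abs_r = np.abs(r)
    t = abs_r[:, :, : d + 1].sum(axis=2)
    s = abs_r[:, :, d:].sum(axis=2)
    return SignificanceMaps(t=t, s=s)


def rescale_and_threshold(
    significance: np.ndarray,
    p_low: float = 1.0,
    p_high: float = 99.0,
    return_rescaled: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Percentile-clip, min-max normalize to [0, 1], binarize at the Otsu threshold.

    The Otsu level maximizes between-class variance over a 256-level histogram.
    Errors on a constant map (no threshold separates one value).
    """
    significance = np.asarray(significance, dtype=float)
    if np.ptp(significance) == 0:
        raise ValueError("significance map is constant; Otsu threshold undefined")
    lo, hi = np.percentile(significance, [p_low, p_high])
    if hi == lo:  # pathologically heavy ties; fall back to the full range
        lo, hi = significance.min(), significance.max()
    clipped = np.clip(significance, lo, hi)
    rescaled = (clipped - lo) / (hi - lo)
    mask = rescaled > threshold_otsu(rescaled, nbins=256)
    if return_rescaled:
        return mask, rescaled
    return mask


def segment_regions(
    cube: HyperCube,
    sigma_g: float = 2.5,
    lambda_d: float = SPLIT_WAVELENGTH_NM,
    p_low: float = 1.0,
    p_high: float = 99.0,
    snv_min_sd: float = 0.01,
) -> RegionMasks:
    """Full segmentation: SNV -> derivative response -> significance -> Otsu masks.

    A pixel is assigned to a class when that class's Otsu mask claims it *and*
    its raw significance for that class dominates the other's (ties go to
    tomato), so the output masks are disjoint by construction; pixels claimed
    by neither are background.  Dominance is compared on the raw maps, not the
    percentile-rescaled ones: per-map rescaling stretches a near-empty map to
    [0, 1] and would inflate its claims when one tissue class is absent.
    ``snv_min_sd`` is the reflectance-scale noise floor below which a pixel's
    spectrum counts as constant (background).
    """
    snv = snv_transform(cube, min_sd=snv_min_sd)
    kernel = build_dog_kernel(sigma_g)
    r = spectral_response(snv, kernel)
    maps = significance_maps(r, cube.wavelengths, lambda_d=lambda_d)
    t_mask = rescale_and_threshold(maps.t, p_low, p_high)
    s_mask = rescale_and_threshold(maps.s, p_low, p_high)

    tomato = t_mask & (maps.t >= maps.s)
    calyx = s_mask & (maps.s > maps.t)
    return RegionMasks(
        tomato=tomato,
        calyxstem=calyx,
        provenance={
            "sigma_g": sigma_g,
            "lambda_d_nm": lambda_d,
            "p_low": p_low,
            "p_high": p_high,
            "snv_min_sd": snv_min_sd,
            "kernel_half_length": kernel.half_length,
        },
    )


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Sorensen-Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
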