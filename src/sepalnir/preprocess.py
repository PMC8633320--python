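"""Radiometric correction, noisy-band rejection and denoising.

Raw intensity cubes are converted to reflectance with the standard flat-field
rule ``(raw - black) / (white - black)``.  Per-band sensor noise is then
estimated from the median absolute deviation of the finest-level 2-D wavelet
detail coefficients (sigma = MAD / 0.6745); bands noisier than 1.5x the
minimum sigma are discarded, but only from the leading and trailing runs of
the spectrum, so the kept range stays contiguous.  Bands over threshold that
fall in a configurable long-wavelength "retain" window are kept anyway —
they carry spatial information the sepal segmentation needs.  Denoising is
per-band 2-D wavelet soft thresholding (BayesShrink) followed, where asked,
by a per-pixel 1-D spectral median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.restoration import denoise_wavelet, estimate_sigma

from .io import HyperCube, ReferenceSpectra

__all__ = [
    "BandQuality",
    "flat_field_correct",
    "estimate_band_noise",
    "select_bands",
    "denoise_soft_threshold",
    "spectral_median_filter",
    "DEFAULT_RETAIN_WINDOW_NM",
]

# Reflectance clip bounds after flat-field correction: specular highlights can
# exceed the white panel, deep shadow can dip below black.
REFLECTANCE_CLIP = (-0.1, 1.5)

# Long-wavelength window whose bands are retained for segmentation even when
# their noise exceeds the rejection threshold.
DEFAULT_RETAIN_WINDOW_NM = (1580.0, 1660.0)

_WAVELET = "db2"


@dataclass
class BandQuality:
    """Per-band noise estimate and keep/retain/discard status.

    ``keep`` marks bands used downstream (features and segmentation);
    ``retained_for_segmentation`` flags the subset of kept bands that exceeded
    the noise threshold but fall inside the retain window.  Discarded bands
    are exactly ``~keep``; the three statuses partition the spectrum.
    """

    wavelengths: np.ndarray
    sigma: np.ndarray
    keep: np.ndarray
    retained_for_segmentation: np.ndarray

    def __post_init__(self) -> None:
        n = self.wavelengths.size
        if not (self.sigma.size == self.keep.size == self.retained_for_segmentation.size == n):
            raise ValueError("BandQuality arrays must share one length")
        if np.any(self.retained_for_segmentation & ~self.keep):
            raise ValueError("retained bands must be a subset of kept bands")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def kept_range_nm(self) -> tuple[float, float]:
        kept = self.wavelengths[self.keep]
        return float(kept[0]), float(kept[-1])

    def to_frame(self) -> pd.DataFrame:
        """Report table: wavelength, sigma, status in {kept, retained, discarded}."""
        status = np.where(
            self.retained_for_segmentation, "retained", np.where(self.keep, "kept", "discarded")
        )
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "sigma": self.sigma, "status": status}
        )


def flat_field_correct(
    raw: HyperCube,
    refs: ReferenceSpectra,
    clip: tuple[float, float] | None = REFLECTANCE_CLIP,
) -> HyperCube:
    """Convert raw intensity to reflectance: (raw - black) / (white - black).

    Values are clipped to ``clip`` to bound specular outliers; pass
    ``clip=None`` to disable.  Errors if any band's white and black references
    coincide (the correction is undefined there).
    """
    if raw.kind != "raw":
        raise ValueError(f"expected a raw cube, got kind={raw.kind!r}")
    if refs.n_bands != raw.n_bands:
        raise ValueError(
            f"references have {refs.n_bands} bands but cube has {raw.n_bands}"
        )
    denom = refs.white - refs.black
    degenerate = np.nonzero(denom == 0)[0]
    if degenerate.size:
        wl = raw.wavelengths[degenerate[0]]
        raise ValueError(
            f"white equals black at band {degenerate[0]} ({wl:.1f} nm); "
            "flat-field correction undefined"
        )
    refl = (raw.data - refs.black[None, None, :]) / denom[None, None, :]
    if clip is not None:
        refl = np.clip(refl, *clip)
    return HyperCube(refl, raw.wavelengths, kind="corrected")


def estimate_band_noise(cube: HyperCube) -> np.ndarray:
    """Per-band noise sd from the MAD of the finest-level wavelet detail coefficients.

    Each band is treated as an independent 2-D image; sigma is the robust
    Donoho estimate median(|d|) / 0.6745 over the diagonal detail subband
    (as implemented by ``skimage.restoration.estimate_sigma``).
    """
    rows, cols = cube.spatial_shape
    if rows < 16 or cols < 16:
        raise ValueError(f"bands must be at least 16x16 pixels, got {rows}x{cols}")
    sigma = np.array(
        [
            estimate_sigma(cube.data[:, :, b], average_sigmas=True)
            for b in range(cube.n_bands)
        ],
        dtype=float,
    )
    return np.nan_to_num(sigma, nan=0.0)  # constant band has no detail coeffs


def select_bands(
    wavelengths: np.ndarray,
    sigma: np.ndarray,
    factor: float = 1.5,
    retain_window_nm: tuple[float, float] | None = DEFAULT_RETAIN_WINDOW_NM,
) -> BandQuality:
    """Flag bands as kept / retained-for-segmentation / discarded.

    A band is over threshold when sigma > factor * min(sigma).  Only the
    leading and trailing over-threshold runs are discarded (the kept range
    stays contiguous); over-threshold bands inside ``retain_window_nm`` are
    kept anyway and flagged ``retained_for_segmentation``, as are interior
    over-threshold bands.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if wavelengths.size != sigma.size:
        raise ValueError("wavelengths and sigma must align")
    noisy = sigma > factor * sigma.min()
    in_retain = (
        np.zeros_like(noisy)
        if retain_window_nm is None
        else (wavelengths >= retain_window_nm[0]) & (wavelengths <= retain_window_nm[1])
    )

    candidate = noisy & ~in_retain  # bands that may be discarded at all
    ok = np.nonzero(~candidate)[0]
    if ok.size == 0:
        raise ValueError("all bands rejected; check the noise estimates")
    keep = np.zeros_like(noisy)
    keep[ok[0] : ok[-1] + 1] = True  # interior over-threshold bands stay kept
    keep |= in_retain
    retained = keep & noisy
    return BandQuality(
        wavelengths=wavelengths, sigma=sigma, keep=keep, retained_for_segmentation=retained
    )


def denoise_soft_threshold(cube: HyperCube) -> HyperCube:
    """Per-band 2-D wavelet soft thresholding (BayesShrink, db2).

    Each band is denoised independently with a threshold derived from its own
    estimated sigma; spatial shape is unchanged.
    """
    out = np.empty_like(cube.data, dtype=np.float64)
    for b in range(cube.n_bands):
        band = cube.data[:, :, b]
        if np.ptp(band) == 0:  # constant band: nothing to threshold
            out[:, :, b] = band
            continue
        out[:, :, b] = denoise_wavelet(
            band,
            method="BayesShrink",
            mode="soft",
            wavelet=_WAVELET,
            rescale_sigma=True,
        )
    return HyperCube(out, cube.wavelengths, kind=cube.kind)


def spectral_median_filter(cube: HyperCube, window: int = 5) -> HyperCube:
    """Per-pixel 1-D median filter along the spectral axis; reflected edges."""
    if window % 2 == 0:
        raise ValueError(f"median window must be odd, got {window}")
    if window < 3 or window > cube.n_bands:
        raise ValueError(f"median window must be in [3, {cube.n_bands}], got {window}")
    out = median_filter(cube.data, size=(1, 1, window), mode="reflect")
    return HyperCube(out, cube.wavelengths, kind=cube.kind)
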