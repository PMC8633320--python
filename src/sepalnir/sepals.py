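"""Per-sepal pixel extraction and spectral feature vectors.

The calyx-stem ROI from the automatic segmentation is intersected with the
(manually drawn, here synthetic) sepal identification mask; each surviving
label is one sepal.  A sepal's features are the per-band mean and population
standard deviation of its pixels' reflectance — two vectors of length equal
to the number of kept bands.  Features are computed on the corrected,
band-selected cube *without* spatial denoising: sepal tips are tiny and
spatial smoothing would bleed background reflectance into them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HyperCube

__all__ = ["SepalRecord", "extract_sepal_masks", "sepal_features", "records_to_frame"]

logger = logging.getLogger(__name__)

MIN_SEPAL_AREA_PX = 10


@dataclass
class SepalRecord:
    """One sepal: 4-digit id (batch, truss, tomato, sepal), its spectra and severity."""

    sepal_id: str
    label: int
    pixel_count: int
    mean_spectrum: np.ndarray
    std_spectrum: np.ndarray
    severity: float | None = None
    flagged: bool = False  # single-pixel sepal: std undefined, reported as 0

    def __post_init__(self) -> None:
        if self.mean_spectrum.shape != self.std_spectrum.shape:
            raise ValueError("mean and std spectra must share a length")
        if np.any(self.std_spectrum < 0):
            raise ValueError("std spectrum must be nonnegative")

    @property
    def batch(self) -> int:
        return int(self.sepal_id[0])

    @property
    def tomato_id(self) -> str:
        """Batch + truss + tomato digits: the tomato this sepal belongs to."""
        return self.sepal_id[:3]


def extract_sepal_masks(
    roi: np.ndarray, id_mask: np.ndarray, min_area: int = MIN_SEPAL_AREA_PX
) -> np.ndarray:
    """Intersect the calyx-stem ROI with the sepal identification mask.

    A pixel keeps label L iff the ROI is true there and the identification
    mask says L.  Labels whose surviving area falls below ``min_area`` are
    dropped (slivers from imperfect registration) and logged.  Errors if no
    label survives at all — that pattern suggests the ROI and the mask do not
    belong to the same scene.
    """
    roi = np.asarray(roi, dtype=bool)
    id_mask = np.asarray(id_mask)
    if roi.shape != id_mask.shape:
        raise ValueError(f"ROI shape {roi.shape} != id mask shape {id_mask.shape}")
    out = np.where(roi, id_mask, 0).astype(id_mask.dtype)
    labels, counts = np.unique(out[out > 0], return_counts=True)
    # An all-false ROI legitimately yields no sepals; a non-empty ROI that
    # misses every label suggests the two rasters are from different scenes.
    if labels.size == 0 and id_mask.max() > 0 and roi.any():
        raise ValueError(
            "no sepal label survives the ROI intersection; "
            "the ROI and identification mask are likely misregistered"
        )
    for lab, cnt in zip(labels, counts):
        if cnt < min_area:
            logger.warning("dropping sepal label %d: only %d px survive (< %d)", lab, cnt, min_area)
            out[out == lab] = 0
    return out


def sepal_features(
    cube: HyperCube,
    sepal_mask: np.ndarray,
    id_by_label: dict[int, str] | None = None,
) -> list[SepalRecord]:
    """Per-band mean and population sd of each labeled sepal's pixels.

    ``id_by_label`` maps raster labels to 4-digit sepal identifiers; absent a
    mapping, the label number itself (zero-padded) is used.  A single-pixel
    sepal has no spread: its std is reported as zero and the record flagged.
    """
    sepal_mask = np.asarray(sepal_mask)
    if sepal_mask.shape != cube.spatial_shape:
        raise ValueError(
            f"sepal mask shape {sepal_mask.shape} != cube spatial shape {cube.spatial_shape}"
        )
    records: list[SepalRecord] = []
    for lab in np.unique(sepal_mask[sepal_mask > 0]):
        pixels = cube.data[sepal_mask == lab]  # (n_px, bands)
        flagged = pixels.shape[0] == 1
        if flagged:
            logger.warning("sepal label %d has a single pixel; std set to 0", lab)
        sepal_id = id_by_label.get(int(lab)) if id_by_label else None
        records.append(
            SepalRecord(
                sepal_id=sepal_id if sepal_id is not None else f"{int(lab):04d}",
                label=int(lab),
                pixel_count=int(pixels.shape[0]),
                mean_spectrum=pixels.mean(axis=0),
                std_spectrum=np.zeros(pixels.shape[1]) if flagged else pixels.std(axis=0),
                flagged=flagged,
            )
        )
    return records


def records_to_frame(records: list[SepalRecord], wavelengths: np.ndarray) -> pd.DataFrame:
    """Flatten records to the features CSV schema: sepal_id, mean_*, std_*, severity."""
    wavelengths = np.asarray(wavelengths)
    if records and wavelengths.size != records[0].mean_spectrum.size:
        raise ValueError("wavelength vector does not match feature length")
    cols = {"sepal_id": [r.sepal_id for r in records]}
    for i, wl in enumerate(wavelengths):
        cols[f"mean_{wl:.0f}"] = [r.mean_spectrum[i] for r in records]
    for i, wl in enumerate(wavelengths):
        cols[f"std_{wl:.0f}"] = [r.std_spectrum[i] for r in records]
    cols["severity"] = [r.severity for r in records]
    return pd.DataFrame(cols)
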