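"""End-to-end orchestration: raw cube in, severity-labeled sepal records out.

Two spectral products are kept deliberately distinct: the *segmentation* cube
(band-selected, spatially denoised, spectrally median-filtered — smoothing
helps the significance maps) and the *feature* cube (band-selected only —
sepal tips are small and spatial smoothing would contaminate them with
background reflectance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ground_truth import FusedSeverity
from .io import HyperCube, ReferenceSpectra
from .preprocess import (
    BandQuality,
    denoise_soft_threshold,
    estimate_band_noise,
    flat_field_correct,
    select_bands,
    spectral_median_filter,
)
from .segment import RegionMasks, segment_regions
from .sepals import SepalRecord, extract_sepal_masks, sepal_features

__all__ = ["SceneResult", "process_scene", "process_study", "attach_severities"]


@dataclass
class SceneResult:
    """Everything one scene's processing produced."""

    band_quality: BandQuality
    masks: RegionMasks
    sepal_mask: np.ndarray
    records: list[SepalRecord]
    feature_wavelengths: np.ndarray


def process_scene(
    raw: HyperCube,
    refs: ReferenceSpectra,
    id_mask: np.ndarray,
    id_by_label: dict[int, str] | None = None,
    noise_factor: float = 1.5,
    sigma_g: float = 2.5,
    median_window: int = 5,
    denoise: bool = True,
    band_quality: BandQuality | None = None,
) -> SceneResult:
    """Run correction, band selection, segmentation and feature extraction.

    ``id_mask`` is the per-truss sepal identification raster (0 background).
    Features come from the corrected band-selected cube without spatial or
    spectral smoothing.  Pass a precomputed ``band_quality`` to reuse one band
    selection across the scenes of a study (feature vectors must align).
    """
    corrected = flat_field_correct(raw, refs)
    if band_quality is None:
        sigma = estimate_band_noise(corrected)
        quality = select_bands(corrected.wavelengths, sigma, factor=noise_factor)
    else:
        quality = band_quality
    kept = corrected.select(quality.keep)

    seg_cube = denoise_soft_threshold(kept) if denoise else kept
    seg_cube = spectral_median_filter(seg_cube, window=median_window)
    masks = segment_regions(seg_cube, sigma_g=sigma_g)

    sepal_mask = extract_sepal_masks(masks.calyxstem, id_mask)
    records = sepal_features(kept, sepal_mask, id_by_label=id_by_label)
    return SceneResult(
        band_quality=quality,
        masks=masks,
        sepal_mask=sepal_mask,
        records=records,
        feature_wavelengths=kept.wavelengths,
    )


def process_study(
    scenes: list,
    **kwargs,
) -> tuple[list[SceneResult], np.ndarray]:
    """Process every (cfg, cube, refs, truth) scene of a study with one shared band selection.

    The band set is estimated on the first scene and reused, so the feature
    vectors of all batches align.  Returns the per-scene results and the
    shared kept-band wavelengths.
    """
    results: list[SceneResult] = []
    quality: BandQuality | None = None
    for _, cube, refs, truth in scenes:
        id_by_label = dict(
            zip(truth.sepal_table["label"].astype(int), truth.sepal_table["sepal_id"])
        )
        res = process_scene(
            cube, refs, truth.sepal_labels, id_by_label=id_by_label,
            band_quality=quality, **kwargs,
        )
        quality = res.band_quality
        results.append(res)
    return results, results[0].feature_wavelengths


def attach_severities(records: list[SepalRecord], fused: FusedSeverity) -> list[SepalRecord]:
    """Fill each record's severity from the fused panel scores (matched by sepal id).

    Records without a fused score are dropped — a sepal invisible to the
    graders has no target.
    """
    by_id = dict(zip((str(s) for s in fused.sepal_ids), fused.severity))
    out = []
    for rec in records:
        if rec.sepal_id in by_id:
            rec.severity = float(by_id[rec.sepal_id])
            out.append(rec)
    return out
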