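"""Synthetic NIR scenes of tomato trusses with known ground truth.

No public dataset exists for the sepal-severity problem, so this module
generates scenes with the statistical structure the processing pipeline
relies on:

* a ~224-band cube on a 900 nm + k*3.46 nm grid, stored as raw intensity
  built from reflectance via ``raw = black + refl * (white - black) + noise``,
  so flat-field correction inverts the construction exactly at zero noise;
* sensor noise elevated at both spectral extremes (the first 13 and last 16
  bands by default), giving band rejection something to reject;
* tomato tissue whose across-pixel reflectance variance is concentrated
  below 1150 nm and sepal tissue whose variance is concentrated above it —
  the contrast the derivative-significance segmentation exploits;
* a water-absorption dip near 1400 nm whose depth grows with a latent
  per-sepal hydration variable h in [0, 1]; dry sepals (low h, shallow dip,
  high reflectance) carry high latent severity, so mean reflectance in the
  1390-1420 nm window is positively informative about severity by
  construction;
* a second water dip near 1200 nm of severity-independent depth, planted so
  interpretation checks can confirm the model ignores it;
* an 11-grader panel whose grades are latent severity plus grader bias and
  noise, clipped to [0, 5], with strongly correlated columns.

Spectra are smooth parametric curves (logistic ramps plus Gaussian dips),
not radiative-transfer simulations: only the variance ordering and the dip
geometry matter to the downstream method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import HyperCube, ReferenceSpectra

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "generate_panel",
    "generate_study",
    "INFORMATIVE_WINDOW_NM",
]

# Wavelength window (nm) in which sepal reflectance is informative about
# latent severity: the hydration-driven dip at 1400 nm, +/- 2.5 sigma.
_DIP_CENTER_NM = 1400.0
_DIP_SIGMA_NM = 25.0
INFORMATIVE_WINDOW_NM = (
    _DIP_CENTER_NM - 2.5 * _DIP_SIGMA_NM,
    _DIP_CENTER_NM + 2.5 * _DIP_SIGMA_NM,
)

_SECONDARY_DIP_CENTER_NM = 1200.0
_SECONDARY_DIP_SIGMA_NM = 20.0
_SECONDARY_DIP_DEPTH = 0.08


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, spectral grid and noise regime of one synthetic scene (= one batch)."""

    rows: int = 112
    cols: int = 168
    n_bands: int = 224
    wl_start: float = 900.0
    wl_step: float = 3.46
    n_trusses: int = 2
    tomatoes_per_truss: int = 3
    sepals_per_tomato: int = 5
    noise_floor: float = 0.01
    edge_noise_boost: float = 3.0
    n_edge_low: int = 13
    n_edge_high: int = 16
    hydration_range: tuple[float, float] = (0.05, 0.95)
    batch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_step <= 0:
            raise ValueError("wl_step must be positive")
        if self.n_bands < 32:
            raise ValueError("need at least 32 bands")
        if self.edge_noise_boost <= 1:
            raise ValueError("edge_noise_boost must exceed 1 so edge bands are rejectable")
        lo, hi = self.hydration_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("hydration_range must be a sub-interval of [0, 1]")
        if not (1 <= self.batch <= 9):
            raise ValueError("batch must be a single digit 1-9 (4-digit sepal ids)")
        if self.n_trusses > 9 or self.tomatoes_per_truss > 9 or self.sepals_per_tomato > 9:
            raise ValueError("trusses/tomatoes/sepals counts must each fit one digit")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wl_start + self.wl_step * np.arange(self.n_bands)

    @property
    def boosted_bands(self) -> np.ndarray:
        """Boolean mask of bands whose sensor noise is multiplied by edge_noise_boost."""
        mask = np.zeros(self.n_bands, dtype=bool)
        mask[: self.n_edge_low] = True
        if self.n_edge_high:
            mask[-self.n_edge_high :] = True
        return mask


@dataclass
class SceneTruth:
    """Ground truth for one scene: region masks, sepal labels and the latent table."""

    tomato_mask: np.ndarray
    calyxstem_mask: np.ndarray
    sepal_labels: np.ndarray
    sepal_table: pd.DataFrame  # columns: sepal_id, label, hydration, severity, batch

    def __post_init__(self) -> None:
        if np.any(self.tomato_mask & self.calyxstem_mask):
            raise ValueError("tomato and calyx-stem masks must be disjoint")
        if np.any((self.sepal_labels > 0) & ~self.calyxstem_mask):
            raise ValueError("every sepal label must lie inside the calyx-stem mask")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def severity_from_hydration(h: np.ndarray | float) -> np.ndarray | float:
    """Latent fungal-susceptibility grade on the 0-5 scale; strictly decreasing in h."""
    return 5.0 * (1.0 - np.asarray(h, dtype=float))


def _tomato_reflectance(wl: np.ndarray, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel tomato (fruit) spectra: steep ramp below 1150 nm, flat above.

    ``scale`` is a per-pixel latent in N(0,1); it modulates the sub-1150 nm
    shoulder so across-pixel variance concentrates below the split wavelength.
    """
    base = 0.62 - 0.28 * _logistic((wl - 1030.0) / 35.0)
    low_mode = _gauss(wl, 1000.0, 60.0)  # support essentially < 1150 nm
    spectra = base[None, :] + 0.10 * scale[:, None] * low_mode[None, :]
    spectra += 0.004 * rng.standard_normal(spectra.shape)  # tissue micro-texture
    return spectra


def _sepal_reflectance(
    wl: np.ndarray, hydration: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel sepal spectra: hydration-scaled 1400 nm dip, fixed 1200 nm dip."""
    base = 0.42 + 0.10 * _logistic((wl - 1250.0) / 60.0)
    dip_main = _gauss(wl, _DIP_CENTER_NM, _DIP_SIGMA_NM)
    dip_secondary = _gauss(wl, _SECONDARY_DIP_CENTER_NM, _SECONDARY_DIP_SIGMA_NM)
    depth = 0.10 + 0.30 * hydration  # wetter tissue absorbs more near 1400 nm
    spectra = (
        base[None, :]
        - depth[:, None] * dip_main[None, :]
        - _SECONDARY_DIP_DEPTH * dip_secondary[None, :]
    )
    spectra += 0.004 * rng.standard_normal(spectra.shape)
    return spectra


def _background_reflectance(wl: np.ndarray, n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    """Matte dark background: flat, low, featureless."""
    return 0.06 + 0.002 * rng.standard_normal((n_pixels, wl.size))


def _place_geometry(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[dict]]:
    """Lay out trusses on a grid: one tomato disk per cell with a sepal fan above it.

    Returns (tomato_mask, calyxstem_mask, sepal_labels, sepal_meta).
    """
    cell_r = cfg.rows // cfg.n_trusses
    cell_c = cfg.cols // cfg.tomatoes_per_truss
    min_cell = 30  # disk + fan need ~30 px; below this the wedges collapse
    if cell_r < min_cell or cell_c < min_cell:
        raise ValueError(
            f"scene {cfg.rows}x{cfg.cols} too small for {cfg.n_trusses} trusses of "
            f"{cfg.tomatoes_per_truss} tomatoes; need at least "
            f"{cfg.n_trusses * min_cell}x{cfg.tomatoes_per_truss * min_cell} pixels"
        )

    rr, cc = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
    tomato = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    calyx = np.zeros((cfg.rows, cfg.cols), dtype=bool)
    labels = np.zeros((cfg.rows, cfg.cols), dtype=np.int32)
    meta: list[dict] = []

    disk_radius = int(0.30 * min(cell_r, cell_c))
    fan_outer = int(0.42 * min(cell_r, cell_c))
    label = 0
    for truss in range(cfg.n_trusses):
        for tom in range(cfg.tomatoes_per_truss):
            # Tomato disk sits in the lower half of its cell; calyx fan above it.
            center_r = truss * cell_r + int(0.62 * cell_r)
            center_c = tom * cell_c + cell_c // 2
            d2 = (rr - center_r) ** 2 + (cc - center_c) ** 2
            tomato |= d2 <= disk_radius**2

            fan_center_r = truss * cell_r + int(0.28 * cell_r)
            dr = rr - fan_center_r
            dc = cc - center_c
            dist = np.sqrt(dr**2 + dc**2)
            ring = (dist > 2) & (dist <= fan_outer) & (dr <= 2)  # upward-facing fan
            angle = np.arctan2(-dr, dc)  # 0..pi across the fan
            angle = np.clip(angle, 0.0, np.pi - 1e-9)
            for sep in range(cfg.sepals_per_tomato):
                label += 1
                a0 = sep * np.pi / cfg.sepals_per_tomato
                a1 = (sep + 1) * np.pi / cfg.sepals_per_tomato
                # Thin gap between wedges so sepals are distinct instances.
                wedge = ring & (angle >= a0 + 0.03) & (angle < a1 - 0.03)
                labels[wedge] = label
                sepal_id = f"{cfg.batch}{truss + 1}{tom + 1}{sep + 1}"
                meta.append({"sepal_id": sepal_id, "label": label})
    calyx = labels > 0
    tomato &= ~calyx  # fans win ties; keeps the masks disjoint
    return tomato, calyx, labels, meta


def generate_scene(
    cfg: SceneConfig,
) -> tuple[HyperCube, ReferenceSpectra, SceneTruth]:
    """Generate one raw scene: intensity cube, references and ground truth.

    The raw cube is ``black + reflectance * (white - black) + noise`` with
    per-band Gaussian sensor noise of sd ``noise_floor * (white - black)``,
    multiplied by ``edge_noise_boost`` on the edge bands.
    """
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths

    tomato_mask, calyx_mask, sepal_labels, meta = _place_geometry(cfg)
    rows, cols = tomato_mask.shape

    # Latent hydration per sepal; severity strictly decreasing in hydration.
    lo, hi = cfg.hydration_range
    for m in meta:
        m["hydration"] = rng.uniform(lo, hi)
        m["severity"] = float(severity_from_hydration(m["hydration"]))
        m["batch"] = cfg.batch
    table = pd.DataFrame(meta, columns=["sepal_id", "label", "hydration", "severity", "batch"])

    reflectance = np.empty((rows, cols, cfg.n_bands), dtype=np.float64)
    bg = ~(tomato_mask | calyx_mask)
    reflectance[bg] = _background_reflectance(wl, int(bg.sum()), rng)
    reflectance[tomato_mask] = _tomato_reflectance(
        wl, rng.standard_normal(int(tomato_mask.sum())), rng
    )
    # Sepal pixels take their sepal's hydration plus a little pixel-level jitter.
    pixel_h = np.zeros(int(calyx_mask.sum()))
    flat_labels = sepal_labels[calyx_mask]
    h_by_label = dict(zip(table["label"], table["hydration"]))
    for lab, h in h_by_label.items():
        sel = flat_labels == lab
        pixel_h[sel] = np.clip(h + 0.02 * rng.standard_normal(int(sel.sum())), 0.0, 1.0)
    reflectance[calyx_mask] = _sepal_reflectance(wl, pixel_h, rng)

    white = 3000.0 + 500.0 * _logistic((wl - 1100.0) / 150.0)  # broad halogen curve
    black = np.full_like(white, 120.0)
    refs = ReferenceSpectra(white=white, black=black)

    sigma = cfg.noise_floor * (white - black)
    sigma = np.where(cfg.boosted_bands, sigma * cfg.edge_noise_boost, sigma)
    raw = black + reflectance * (white - black)
    if cfg.noise_floor > 0:
        raw = raw + sigma * rng.standard_normal(raw.shape)

    cube = HyperCube(raw, wl, kind="raw")
    truth = SceneTruth(
        tomato_mask=tomato_mask,
        calyxstem_mask=calyx_mask,
        sepal_labels=sepal_labels,
        sepal_table=table,
    )
    return cube, refs, truth


def generate_panel(
    truth: SceneTruth | pd.DataFrame,
    n_graders: int = 11,
    grader_noise: float = 0.25,
    bias_sd: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a grading panel: latent severity + per-grader bias + noise, clipped to [0, 5].

    With the defaults the grader columns are strongly correlated and the first
    principal component of the panel explains well over 90% of the variance.
    Returns a DataFrame indexed by sepal_id with columns grader_1..grader_n.
    """
    if n_graders < 2:
        raise ValueError("need at least 2 graders for PCA fusion")
    if grader_noise < 0:
        raise ValueError("grader_noise must be nonnegative")
    table = truth.sepal_table if isinstance(truth, SceneTruth) else truth
    rng = np.random.default_rng(seed)
    severity = table["severity"].to_numpy(dtype=float)
    bias = bias_sd * rng.standard_normal(n_graders)
    noise = grader_noise * rng.standard_normal((severity.size, n_graders))
    grades = np.clip(severity[:, None] + bias[None, :] + noise, 0.0, 5.0)
    return pd.DataFrame(
        grades,
        index=pd.Index(table["sepal_id"].astype(str), name="sepal_id"),
        columns=[f"grader_{g + 1}" for g in range(n_graders)],
    )


def generate_study(
    n_batches: int = 6,
    base_cfg: SceneConfig | None = None,
    seed: int = 0,
) -> list[tuple[SceneConfig, HyperCube, ReferenceSpectra, SceneTruth]]:
    """Generate a multi-batch study: one scene per batch with derived seeds."""
    if not (1 <= n_batches <= 9):
        raise ValueError("n_batches must be 1-9")
    base_cfg = base_cfg or SceneConfig()
    out = []
    for b in range(n_batches):
        cfg = replace(base_cfg, batch=b + 1, seed=(seed * 1000 + b) % (2**31 - 1))
        out.append((cfg, *generate_scene(cfg)))
    return out
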