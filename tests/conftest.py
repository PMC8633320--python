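import numpy as np
import pandas as pd
import pytest

import sepalnir as sn


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene (batch 1, seed 7), shared across tests."""
    cfg = sn.SceneConfig(seed=7)
    cube, refs, truth = sn.generate_scene(cfg)
    return cfg, cube, refs, truth


@pytest.fixture(scope="session")
def corrected_scene(default_scene):
    """Flat-field-corrected, band-selected view of the default scene."""
    cfg, cube, refs, truth = default_scene
    corrected = sn.flat_field_correct(cube, refs)
    sigma = sn.estimate_band_noise(corrected)
    quality = sn.select_bands(corrected.wavelengths, sigma)
    return cfg, corrected.select(quality.keep), quality, truth


@pytest.fixture(scope="session")
def small_study():
    """A 3-batch study processed end to end: labeled records + feature wavelengths.

    Session-scoped because the pipeline run is the expensive part shared by
    the model-level tests.
    """
    study = sn.generate_study(3, seed=11)
    results, wl = sn.process_study(study)
    records = [r for res in results for r in res.records]
    combined = pd.concat([t.sepal_table for _, _, _, t in study], ignore_index=True)
    panel = sn.generate_panel(combined, seed=11)
    fused = sn.fuse_grades_pca(sn.GradePanel.from_frame(panel))
    records = sn.attach_severities(records, fused)
    feats = sn.FeatureMatrix.from_records(records, wl)
    return study, results, fused, feats


def random_cube(rows=8, cols=8, bands=10, seed=0, kind="raw"):
    rng = np.random.default_rng(seed)
    wl = 900.0 + 3.46 * np.arange(bands)
    return sn.HyperCube(rng.uniform(0.0, 1.0, size=(rows, cols, bands)), wl, kind=kind)
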