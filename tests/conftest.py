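"""Shared fixtures: small phantom cohorts and a desk-scale pipeline run.

Everything is generated programmatically at test time; no stored images.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpmbreast import phantom
from mpmbreast.pipeline import PipelineConfig, run_full


@pytest.fixture(scope="session")
def reference_phantom():
    """One full-size cancer phantom with ground truth (seed-fixed)."""
    spec = phantom.PhantomSpec(
        tissue_class="cancer_with_normal_regions",
        structure_counts={
            "ducts": 1,
            "adipose": 3,
            "collagen": 4,
            "dcis": 2,
            "invasive": 2,
            "immune": 3,
        },
        seed=7,
    )
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def normal_phantom():
    """One full-size normal phantom (no cancer structures)."""
    return phantom.generate_phantom(phantom.PhantomSpec(tissue_class="normal", seed=3))


@pytest.fixture(scope="session")
def small_pipeline_report():
    """A reduced-geometry end-to-end run (512 px images, 16 tiles each)."""
    config = PipelineConfig(
        n_patients=6,
        images_per_patient=2,
        width_px=512,
        height_px=512,
        epochs=8,
        seed=11,
    )
    return config, run_full(config)


def separable_tiles(n_per_class: int, seed: int = 0, side: int = 128):
    """Two-class synthetic standardized tiles with disjoint signatures."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, (2 * n_per_class, 3, side, side))
    x[:n_per_class, 1] += 1.5  # "cancer": bright channel 2
    y = np.array([1] * n_per_class + [0] * n_per_class, dtype=float)
    return x, y
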