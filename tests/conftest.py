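"""Shared fixtures: scenes, photographs and the default experiment run.

Expensive artefacts (the full 153-photograph study, the misclassification
grid) are computed once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from canopyhp import (
    CameraConfig,
    CanopySpec,
    ExperimentConfig,
    binarize,
    greyness_histogram,
    misclassification_map,
    render_canopy,
    run_experiment,
    simulate_photograph,
)
from canopyhp.camera import mixed_pixel_labels
from canopyhp.etm import matched_threshold, threshold_for_stop
from canopyhp.model_canopy import SceneRaster


@pytest.fixture(scope="session")
def fig6_spec() -> CanopySpec:
    """The demonstration canopy: gap fraction 0.25, opening side 2.5 mm."""
    return CanopySpec.from_gap_fraction(0.25, 2.5)


@pytest.fixture(scope="session")
def fig6_scene(fig6_spec) -> "SceneRaster":
    return render_canopy(fig6_spec, pixel_scale=0.0507, max_extent=75.0)


@pytest.fixture(scope="session")
def reference_photo(fig6_scene):
    """The demonstration canopy photographed at the reference exposure."""
    return simulate_photograph(fig6_scene, 0.0, CameraConfig())


@pytest.fixture(scope="session")
def step_scene() -> SceneRaster:
    """A single vertical sky/canopy edge for sharpness measurements."""
    occupancy = np.zeros((64, 400))
    occupancy[:, 200:] = 1.0
    return SceneRaster(occupancy=occupancy, pixel_scale=0.05)


@pytest.fixture(scope="session")
def experiment_result():
    """The default study: 17 canopies x 9 exposures x 9 thresholding stops."""
    return run_experiment(ExperimentConfig())


@pytest.fixture(scope="session")
def misclassification_grid(fig6_scene):
    """Misclassification audits over exposure x thresholding combinations.

    Exposure manipulations {-2, 0, +2, +4} crossed with thresholding
    manipulations {-5, -3, -1, +1, +3, +5}; each cell records the ETM
    extent, the misclassified fraction, whether every misclassified pixel
    lies in the photographic mixed-pixel zone, and whether the binary map
    is all-canopy or all-sky.
    """
    from canopyhp.model_canopy import LABEL_GREY

    cells = []
    for exposure in (-2.0, 0.0, 2.0, 4.0):
        photo = simulate_photograph(fig6_scene, exposure, CameraConfig())
        hist = greyness_histogram(photo)
        anchor = matched_threshold(photo, hist)
        reference = binarize(photo, anchor)
        labels = mixed_pixel_labels(photo)
        for stop in (-5.0, -3.0, -1.0, 1.0, 3.0, 5.0):
            threshold = threshold_for_stop(photo, stop, hist, anchor=anchor)
            raw = anchor * 2.0 ** ((stop - exposure) / photo.config.gamma)
            bmap = binarize(photo, threshold)
            audit = misclassification_map(bmap, labels, reference)
            wrong = np.isin(
                audit.categories,
                [2, 3],  # false sky / false canopy
            ) & audit.mask
            cells.append(
                {
                    "exposure": exposure,
                    "threshold_stops": stop,
                    "etm": exposure - stop,
                    "threshold_dn": threshold,
                    "threshold_clipped": raw > 255.0 or raw < 1.0,
                    "misclassified_fraction": audit.misclassified_fraction,
                    "grey_only": bool((labels[wrong] == LABEL_GREY).all())
                    if wrong.any()
                    else True,
                    "all_canopy": not bool((bmap.sky & bmap.mask).any()),
                    "all_sky": bool((bmap.sky | ~bmap.mask).all()),
                }
            )
    return cells
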