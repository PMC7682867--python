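"""Shared fixtures: phantoms at the study conditions, analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import tubemorph as tm
from tubemorph.phantom import epithelial_preset, mesenchymal_preset
from tubemorph.pipeline import AnalysisParams, analyze_phantom


@pytest.fixture(scope="session")
def frame() -> tm.EmbryoFrame:
    return tm.EmbryoFrame()


@pytest.fixture(scope="session")
def clean_phantom() -> tm.TissuePhantom:
    """Ten well-separated nuclei, no blur / noise / debris: masks are exact."""
    cfg = tm.PhantomConfig(
        state="epithelial",
        n_nuclei=10,
        volume_um=(70.0, 70.0, 45.0),
        min_separation_um=12.0,
        marker_probs={"edu": 0.5},
        blur_sigma_um=0.0,
        noise_sd=0.0,
        n_debris=0,
        seed=5,
    )
    return tm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_epithelial() -> tm.TissuePhantom:
    """A fast, realistic epithelial phantom (blur + noise + debris)."""
    cfg = tm.PhantomConfig(
        state="epithelial",
        n_nuclei=30,
        volume_um=(60.0, 60.0, 40.0),
        noise_sd=2.0,
        n_debris=8,
        marker_probs={"edu": 0.75},
        seed=1,
    )
    return tm.generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_epithelial_analysis(small_epithelial):
    return analyze_phantom(small_epithelial, AnalysisParams())


@pytest.fixture(scope="session")
def epithelial_200() -> tm.TissuePhantom:
    """The control condition: n = 200 elongated nuclei, 5 deg jitter."""
    return tm.generate_phantom(epithelial_preset(seed=11))


@pytest.fixture(scope="session")
def epithelial_200_analysis(epithelial_200):
    return analyze_phantom(epithelial_200, AnalysisParams())


@pytest.fixture(scope="session")
def mesenchymal_500() -> tm.TissuePhantom:
    """The transformed condition: n = 500, 20% emigration, seeded clusters."""
    return tm.generate_phantom(mesenchymal_preset(seed=7))


@pytest.fixture(scope="session")
def mesenchymal_500_analysis(mesenchymal_500):
    return analyze_phantom(mesenchymal_500, AnalysisParams())


def match_to_truth(nuclei, truth, max_dist_um: float = 2.0) -> np.ndarray:
    """Index of the nearest ground-truth nucleus per measured nucleus.

    Raises if any measured centre is farther than `max_dist_um` from every
    truth centre (a spurious detection).
    """
    measured = nuclei[["x_um", "y_um", "z_um"]].to_numpy()
    gt = truth[["x_um", "y_um", "z_um"]].to_numpy()
    d = np.linalg.norm(measured[:, None, :] - gt[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    worst = d[np.arange(len(measured)), idx].max() if len(measured) else 0.0
    if worst > max_dist_um:
        raise AssertionError(f"a measured nucleus is {worst:.2f} um from every truth centre")
    return idx
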