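"""Shared fixtures: compact phantom configurations and the reference model.

Most tests run on a 32 x 32 phantom with proportionally shrunken
ventricles and a lower count target — the same generative structure as
the default 64 x 64 acquisition at a fraction of the cost.
"""

from dataclasses import replace

import numpy as np
import pytest

import fadsync as fs


def small_regions(phase_deg=130.0, dispersion_deg=8.0, amp_scale=1.0,
                  delay_deg=0.0):
    """LV/RV ellipses sized for a 32 x 32 grid."""
    return {
        "LV": fs.RegionSpec(center=(19.0, 21.0), radii=(4.0, 4.5),
                            baseline=1.0, amplitude=0.35 * amp_scale,
                            phase_deg=(phase_deg + delay_deg) % 360.0,
                            dispersion_deg=dispersion_deg, label=fs.LV),
        "RV": fs.RegionSpec(center=(18.0, 9.0), radii=(3.5, 3.5),
                            baseline=0.95, amplitude=0.30 * amp_scale,
                            phase_deg=phase_deg % 360.0,
                            dispersion_deg=dispersion_deg, label=fs.RV),
    }


def small_config(seed=0, poisson=True, dispersion_deg=8.0, **kwargs):
    regions = kwargs.pop("regions", None) or small_regions(
        dispersion_deg=dispersion_deg)
    return fs.PhantomConfig(grid=32, frames=16, counts_per_frame=60_000.0,
                            regions=regions, seed=seed, poisson=poisson,
                            **kwargs)


def small_cohort_spec(preset, n, seed, **jitter):
    spec = fs.CohortSpec(preset=preset, n=n, seed=seed,
                         base_config=small_config(), jitter=jitter)
    return spec


@pytest.fixture(scope="session")
def reference_model():
    return fs.load_reference_model()


@pytest.fixture(scope="session")
def reference_sample(reference_model):
    """5,000 draws from the shipped reference mixture."""
    return fs.sample(reference_model, 5000, seed=2024)


@pytest.fixture()
def small_subject():
    return fs.generate_subject(small_config(seed=7))


@pytest.fixture()
def noiseless_subject():
    return fs.generate_subject(small_config(seed=7, poisson=False,
                                            dispersion_deg=0.0))
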