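"""Synthetic gated ERNA subjects with controllable dyssynchrony.

Emulates the acquisition the method targets: 16 EKG-gated frames of
64 x 64 counts at roughly 300 Kcounts per frame, with two elliptical
ventricular blood pools over a flat background. Each ventricular pixel
follows a raised-cosine time-activity curve

    x(k) = b + a * cos(2 pi k / K - phi),    k = 0..K-1,

where the per-pixel phase ``phi`` is drawn wrapped-normally around the
region's phase with dispersion ``sigma_phi`` (intra-region dyssynchrony),
and region phases can be offset against each other (inter-ventricular
dyssynchrony). The noiseless series is scaled so the mean expected frame
total equals the configured counts per frame, then Poisson counting noise
is applied per pixel and frame.

Three cohort presets sketch the populations the method discriminates:

* ``normal`` — coincident LV/RV phases, small dispersion;
* ``lbbb_like`` — an interventricular phase offset of 30-50 degrees
  (well above the 25.5-degree clinical dyssynchrony cut-off), moderate
  dispersion, emulating left bundle branch block;
* ``dcm_like`` — dilated ventricles (radii scaled up), large phase
  dispersion and reduced pulsation amplitude, emulating dilated
  cardiomyopathy with depressed ejection fraction.

No published generative model exists for these populations; the preset
ranges are this package's own calibration, chosen to reproduce the
qualitative contrasts reported clinically (phase-SD ordering, interventricular
offsets) rather than any specific patient data. Photon transport,
collimator blur, attenuation and gating errors are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .io import BACKGROUND, LV, RV, GatedSeries, RoiMask

__all__ = [
    "RegionSpec",
    "PhantomConfig",
    "CohortSpec",
    "PhantomError",
    "PRESETS",
    "generate_subject",
    "generate_cohort",
]


class PhantomError(ValueError):
    """Invalid phantom configuration."""


@dataclass
class RegionSpec:
    """One elliptical ventricular region.

    ``center`` and ``radii`` are in pixels (0-based array coordinates);
    ``baseline`` and ``amplitude`` are relative intensities (the whole
    image is rescaled to the count target); ``phase_deg`` is the cosine
    phase of the count curve and ``dispersion_deg`` the wrapped-normal
    spread of per-pixel phases inside the region.
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    baseline: float = 1.0
    amplitude: float = 0.35
    phase_deg: float = 130.0
    dispersion_deg: float = 8.0
    label: int = LV


@dataclass
class PhantomConfig:
    grid: int = 64
    frames: int = 16
    counts_per_frame: float = 300_000.0
    background: float = 0.1          # fraction of the brightest region peak
    regions: dict = field(default_factory=dict)
    dilation: float = 1.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = default_regions()

    def validate(self) -> None:
        if self.grid < 8:
            raise PhantomError("grid must be at least 8")
        if self.frames < 4:
            raise PhantomError("need at least 4 frames")
        if self.counts_per_frame <= 0:
            raise PhantomError("counts_per_frame must be positive")
        if not 0 <= self.background < 1:
            raise PhantomError("background must be a fraction in [0, 1)")
        if self.dilation <= 0:
            raise PhantomError("dilation must be positive")
        for name, reg in self.regions.items():
            if reg.amplitude < 0 or reg.baseline <= 0:
                raise PhantomError(f"region {name}: bad baseline/amplitude")
            if reg.dispersion_deg < 0:
                raise PhantomError(f"region {name}: negative dispersion")
            if not 0 <= reg.phase_deg % 360 < 360:
                raise PhantomError(f"region {name}: bad phase")


def default_regions() -> dict:
    """Left and right ventricular blood pools in an LAO-style layout."""
    return {
        "LV": RegionSpec(center=(38.0, 42.0), radii=(7.0, 8.0), baseline=1.0,
                         amplitude=0.35, phase_deg=130.0, dispersion_deg=8.0,
                         label=LV),
        "RV": RegionSpec(center=(36.0, 20.0), radii=(6.0, 7.0), baseline=0.95,
                         amplitude=0.30, phase_deg=130.0, dispersion_deg=8.0,
                         label=RV),
    }


def _ellipse_mask(grid: int, center, radii) -> np.ndarray:
    ii, jj = np.mgrid[0:grid, 0:grid]
    return (((ii - center[0]) / radii[0]) ** 2
            + ((jj - center[1]) / radii[1]) ** 2) <= 1.0


def generate_subject(config: PhantomConfig) -> tuple[GatedSeries, RoiMask]:
    """Simulate one gated subject; returns the series and its ground-truth mask.

    Per-pixel phases are drawn once (they are anatomy, not noise) from the
    wrapped-normal dispersion of each region; Poisson counting noise is then
    applied independently per pixel and frame when ``config.poisson``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m, k = config.grid, config.frames

    labels = np.zeros((m, m), dtype=int)
    phase_map = np.zeros((m, m))
    baseline = np.zeros((m, m))
    amplitude = np.zeros((m, m))

    occupied = np.zeros((m, m), dtype=bool)
    for name, reg in config.regions.items():
        radii = (reg.radii[0] * config.dilation, reg.radii[1] * config.dilation)
        if (reg.center[0] - radii[0] < 0 or reg.center[0] + radii[0] > m - 1
                or reg.center[1] - radii[1] < 0
                or reg.center[1] + radii[1] > m - 1):
            raise PhantomError(f"region {name} does not fit inside the grid")
        sel = _ellipse_mask(m, reg.center, radii)
        if (sel & occupied).any():
            raise PhantomError(f"region {name} overlaps another region")
        occupied |= sel
        labels[sel] = reg.label
        baseline[sel] = reg.baseline
        amplitude[sel] = reg.amplitude
        # wrapped-normal per-pixel phases around the region phase
        phases = rng.normal(np.deg2rad(reg.phase_deg),
                            np.deg2rad(reg.dispersion_deg), size=int(sel.sum()))
        phase_map[sel] = phases

    peak = max(reg.baseline + reg.amplitude for reg in config.regions.values())
    baseline[~occupied] = config.background * peak

    theta = 2.0 * np.pi * np.arange(k) / k
    # (K, M, M) noiseless intensities
    series = baseline[None] + amplitude[None] * np.cos(
        theta[:, None, None] - phase_map[None])
    # scale so the mean expected frame total hits the count target
    scale = config.counts_per_frame * k / series.sum()
    series = series * scale
    if config.poisson:
        series = rng.poisson(series).astype(float)

    meta = {
        "frames": k, "grid": m, "counts_per_frame": config.counts_per_frame,
        "poisson": config.poisson, "seed": config.seed,
        "dilation": config.dilation,
        "regions": {
            name: {"phase_deg": reg.phase_deg,
                   "dispersion_deg": reg.dispersion_deg,
                   "amplitude": reg.amplitude, "baseline": reg.baseline}
            for name, reg in config.regions.items()
        },
    }
    return GatedSeries(series, meta=meta), RoiMask(labels)


# ---------------------------------------------------------------------------
# cohorts

#: preset parameter ranges (uniform jitter bounds per subject)
PRESETS = {
    "normal": {
        "base_phase": (120.0, 140.0),
        "delay": (0.0, 0.0),            # LV phase - RV phase, degrees
        "dispersion": (5.0, 10.0),
        "amplitude_scale": (0.9, 1.1),
        "dilation": (1.0, 1.0),
    },
    "lbbb_like": {
        "base_phase": (120.0, 140.0),
        "delay": (30.0, 50.0),          # >= the 25.5 deg clinical cut-off
        "dispersion": (8.0, 15.0),
        "amplitude_scale": (0.9, 1.1),
        "dilation": (1.0, 1.0),
    },
    "dcm_like": {
        "base_phase": (120.0, 140.0),
        "delay": (10.0, 30.0),
        "dispersion": (35.0, 55.0),
        "amplitude_scale": (0.25, 0.45),  # depressed ejection fraction
        "dilation": (1.15, 1.35),
    },
}


@dataclass
class CohortSpec:
    """A class preset plus per-subject jitter, fully seeded."""

    preset: str = "normal"
    n: int = 1
    seed: int = 0
    jitter: dict = field(default_factory=dict)  # overrides of PRESETS ranges
    base_config: PhantomConfig = field(default_factory=PhantomConfig)

    def ranges(self) -> dict:
        if self.preset not in PRESETS:
            raise PhantomError(f"unknown preset {self.preset!r}")
        merged = dict(PRESETS[self.preset])
        merged.update(self.jitter)
        return merged


def subject_config(spec: CohortSpec, draw: dict, seed: int) -> PhantomConfig:
    """Materialize one subject's PhantomConfig from drawn jitter values."""
    regions = {}
    for name, reg in spec.base_config.regions.items():
        phase = draw["base_phase"] + (draw["delay"] if reg.label == LV else 0.0)
        regions[name] = replace(
            reg,
            amplitude=reg.amplitude * draw["amplitude_scale"],
            phase_deg=phase % 360.0,
            dispersion_deg=draw["dispersion"],
        )
    return replace(spec.base_config, regions=regions,
                   dilation=draw["dilation"], seed=seed)


def generate_cohort(spec: CohortSpec) -> list[tuple[GatedSeries, RoiMask]]:
    """Simulate ``spec.n`` subjects; bit-reproducible for a fixed seed."""
    if spec.n < 1:
        raise PhantomError("cohort size must be at least 1")
    ranges = spec.ranges()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for _ in range(spec.n):
        draw = {key: float(rng.uniform(lo, hi))
                for key, (lo, hi) in ranges.items()}
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        subjects.append(generate_subject(subject_config(spec, draw, sub_seed)))
    return subjects
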