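"""Fourier first-harmonic phase analysis — the clinical baseline.

Each pixel's time-activity curve is fitted by the first harmonic of its
discrete Fourier transform, ``x(k) ~ b + a cos(2 pi k / K - phi)``; the
per-pixel phase ``phi`` (degrees in [0, 360), zero-referenced to frame 1)
and amplitude ``a`` form the parametric phase and amplitude images. The
clinical indices derive from the within-ROI phase distributions:

* intraventricular dyssynchrony — standard deviation of the phases
  inside one ventricular ROI;
* interventricular dyssynchrony — absolute difference of the two
  ventricular mean phases;
* the histogram mode (default 1-degree bins) as the dominant phase.

Mean and SD are linear statistics computed after unwrapping each ROI's
phases around its circular mean, so distributions straddling the 0/360
seam are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GatedSeries, RoiMask

__all__ = [
    "PhaseMap",
    "RoiPhaseStats",
    "PhaseIndices",
    "PhaseError",
    "pixel_phase",
    "phase_image",
    "phase_indices",
]


class PhaseError(ValueError):
    """Invalid input to phase analysis."""


@dataclass
class PhaseMap:
    """Per-pixel phase (degrees, NaN where undefined) and amplitude images."""

    phase: np.ndarray
    amplitude: np.ndarray
    mask: RoiMask
    bin_width: float = 1.0
    histograms: dict = field(default_factory=dict)  # label -> (counts, edges)

    def roi_phases(self, region) -> np.ndarray:
        """Defined phase values of one ROI, flattened."""
        label = self.mask.label_for(region)
        sel = self.mask.labels == label
        values = self.phase[sel]
        return values[np.isfinite(values)]


@dataclass
class RoiPhaseStats:
    mean: float
    sd: float
    mode: float
    n: int


@dataclass
class PhaseIndices:
    """Clinical per-ROI summaries plus the interventricular difference."""

    per_roi: dict
    interventricular_difference: float


def pixel_phase(tac) -> tuple[float, float]:
    """First-harmonic (phase degrees, amplitude) of one time-activity curve.

    For ``tac_k = b + a cos(2 pi k / K - phi)`` with ``a > 0`` this returns
    ``(phi mod 360, a)`` exactly (up to rounding). A vanishing first
    harmonic yields amplitude 0 and an undefined (NaN) phase.
    """
    tac = np.asarray(tac, dtype=float).ravel()
    k = tac.size
    if k < 4:
        raise PhaseError(f"need at least 4 frames, got {k}")
    if not np.isfinite(tac).all():
        raise PhaseError("non-finite value in TAC")
    harmonic = np.fft.fft(tac)[1]
    amplitude = 2.0 * np.abs(harmonic) / k
    if amplitude < 1e-12 * max(1.0, float(np.abs(tac).max())):
        return float("nan"), 0.0
    phase = float(np.degrees(-np.angle(harmonic)) % 360.0)
    return phase, float(amplitude)


def phase_image(series: GatedSeries, mask: RoiMask,
                bin_width: float = 1.0) -> PhaseMap:
    """Phase/amplitude images over the masked pixels, with ROI histograms."""
    if mask.grid != series.grid:
        raise PhaseError(
            f"mask grid {mask.grid} does not match series grid {series.grid}")
    if bin_width <= 0:
        raise PhaseError("bin width must be positive")
    selected = mask.labels != 0
    if not selected.any():
        raise PhaseError("empty mask: no ventricular pixels")

    m, k = series.grid, series.frames
    phase = np.full((m, m), np.nan)
    amplitude = np.zeros((m, m))
    # vectorized first harmonic over all masked pixels at once
    rows, cols = np.nonzero(selected)
    tacs = series.counts[:, rows, cols]  # (K, P)
    harmonic = np.fft.fft(tacs, axis=0)[1]
    amp = 2.0 * np.abs(harmonic) / k
    defined = amp >= 1e-12 * np.maximum(1.0, np.abs(tacs).max(axis=0))
    ph = np.degrees(-np.angle(harmonic)) % 360.0
    amplitude[rows, cols] = np.where(defined, amp, 0.0)
    phase[rows, cols] = np.where(defined, ph, np.nan)

    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    histograms = {}
    for label in np.unique(mask.labels[selected]):
        values = phase[(mask.labels == label) & np.isfinite(phase)]
        histograms[int(label)] = (np.histogram(values, bins=edges)[0], edges)
    return PhaseMap(phase=phase, amplitude=amplitude, mask=mask,
                    bin_width=bin_width, histograms=histograms)


def _unwrap_about_circular_mean(phases: np.ndarray) -> np.ndarray:
    """Map phases into a 360-degree window centered on their circular mean."""
    rad = np.deg2rad(phases)
    center = np.degrees(np.angle(np.exp(1j * rad).mean()))
    return (phases - center + 180.0) % 360.0 - 180.0 + center


def _roi_stats(pmap: PhaseMap, region) -> RoiPhaseStats:
    values = pmap.roi_phases(region)
    if values.size == 0:
        raise PhaseError(f"ROI {region!r} has no defined-phase pixels")
    unwrapped = _unwrap_about_circular_mean(values)
    mean = float(unwrapped.mean())
    sd = float(unwrapped.std(ddof=1)) if values.size > 1 else 0.0
    label = pmap.mask.label_for(region)
    counts, edges = pmap.histograms[label]
    top = int(np.argmax(counts))  # argmax takes the lowest bin on ties
    mode = float(0.5 * (edges[top] + edges[top + 1]))
    return RoiPhaseStats(mean=mean % 360.0, sd=sd, mode=mode, n=int(values.size))


def phase_indices(pmap: PhaseMap, lv="LV", rv="RV") -> PhaseIndices:
    """Mean/SD/mode per ventricle and the interventricular mean difference.

    The interventricular difference is the absolute circular difference of
    the two mean phases, in [0, 180].
    """
    stats = {"LV": _roi_stats(pmap, lv), "RV": _roi_stats(pmap, rv)}
    delta = (stats["RV"].mean - stats["LV"].mean + 180.0) % 360.0 - 180.0
    return PhaseIndices(per_roi=stats,
                        interventricular_difference=abs(float(delta)))
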