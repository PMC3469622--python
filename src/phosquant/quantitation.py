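"""Selected-ion-chromatogram peak integration and abundance ratios.

The peak integrator is a documented approximation of the vendor ICIS
algorithm, driven by the four parameters the original analysis printed
(multiple resolution, noise tolerance, noise window, scans in baseline):

* the trace is smoothed with a moving average whose width is
  ``multiple_resolution`` scans and the apex is the smoothed maximum;
* the baseline is the mean of the ``scans_in_baseline`` lowest-intensity
  scans within ``noise_window`` scans of the apex;
* peak boundaries are where the smoothed trace falls to
  ``baseline + noise_tolerance * (apex - baseline)`` walking outward;
* the area is the trapezoidal integral of the raw, baseline-subtracted
  trace between the boundaries.

A minimum peak area of 500 counts — the typical spectral noise level — is
required before any area enters quantitation (inclusive at the boundary).
SILAC heavy/light ratios are formed on raw areas within a run (the two
channels are co-injected, so injection differences cancel); spike-in
normalization applies only to the label-free track across timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MIN_AREA_DEFAULT = 500.0


@dataclass(frozen=True)
class IntegrationParams:
    multiple_resolution: int = 8
    noise_tolerance: float = 0.1
    noise_window: int = 40
    scans_in_baseline: int = 5
    min_area: float = MIN_AREA_DEFAULT

    def __post_init__(self) -> None:
        if min(self.multiple_resolution, self.noise_window, self.scans_in_baseline) <= 0:
            raise ValueError("integration parameters must be positive")
        if self.noise_tolerance <= 0 or self.min_area <= 0:
            raise ValueError("integration parameters must be positive")


@dataclass(frozen=True)
class Chromatogram:
    """Intensity trace over scan time at a fixed precursor m/z."""

    times: np.ndarray
    intensities: np.ndarray
    mz: float = 0.0
    tolerance_ppm: float = 10.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", inten)
        if times.shape != inten.shape or times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("scan times must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = max(1, min(window, len(y)))
    kernel = np.ones(window) / window
    # reflect-pad so the apex is not biased toward the interior
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="same")[pad : pad + len(y)]


def integrate_peak(
    chrom: Chromatogram, params: IntegrationParams = IntegrationParams()
) -> tuple[float, tuple[int, int]] | None:
    """Integrate the dominant elution peak; ``None`` if no peak is defined.

    Returns ``(area, (left_index, right_index))`` with the area in
    intensity*time units above baseline between the boundary scans.
    """
    y = chrom.intensities
    t = chrom.times
    if len(y) < 3:
        raise ValueError("chromatogram must have at least 3 scans")

    smooth = _smooth(y, params.multiple_resolution)
    apex = int(np.argmax(smooth))
    apex_height = smooth[apex]

    lo = max(0, apex - params.noise_window)
    hi = min(len(y), apex + params.noise_window + 1)
    window_vals = np.sort(y[lo:hi])
    baseline = float(np.mean(window_vals[: params.scans_in_baseline]))

    prominence = apex_height - baseline
    if prominence <= 0 or apex_height <= 0:
        return None

    level = baseline + params.noise_tolerance * prominence
    left = apex
    while left > 0 and smooth[left - 1] > level:
        left -= 1
    right = apex
    while right < len(y) - 1 and smooth[right + 1] > level:
        right += 1
    # extend down the monotone descent toward baseline so slow tails are not
    # clipped at the noise-tolerance level
    while left > 0 and baseline < smooth[left - 1] <= smooth[left]:
        left -= 1
    while right < len(y) - 1 and baseline < smooth[right + 1] <= smooth[right]:
        right += 1
    if right - left < 1:
        return None

    segment = np.clip(y[left : right + 1] - baseline, 0.0, None)
    area = float(np.trapezoid(segment, t[left : right + 1]))
    if area <= 0:
        return None
    return area, (left, right)


def apply_area_floor(area: float | None, params: IntegrationParams = IntegrationParams()) -> bool:
    """True iff the area clears the spectral-noise floor (inclusive at 500)."""
    if area is None or (isinstance(area, float) and math.isnan(area)):
        return False
    return area >= params.min_area


def normalize_to_spike(raw_area: float | None, spike_area: float | None) -> float | None:
    """Label-free normalization: peptide area over the co-purified spike area.

    The 10-pmol synthetic spike peptide (LIEDAEpYTAK) is constant per
    timepoint, so dividing by its area cancels injection-scale differences:
    multiplying every area of a run by a constant leaves the result unchanged.
    """
    if raw_area is None or spike_area is None:
        return None
    if spike_area <= 0:
        raise ValueError(f"spike area must be > 0, got {spike_area}")
    return raw_area / spike_area


def silac_ratio(heavy_area: float | None, light_area: float | None) -> float | None:
    """Heavy/light abundance ratio (deficient relative to reconstituted).

    Blank (``None``) if either channel lacks a defined, floor-clearing peak.
    """
    if heavy_area is None or light_area is None:
        return None
    if light_area <= 0:
        return None
    return heavy_area / light_area


def gaussian_chromatogram(
    area: float,
    apex_time: float = 30.0,
    sigma: float = 3.0,
    t_start: float = 0.0,
    t_end: float = 60.0,
    dt: float = 1.0,
    baseline: np.ndarray | float = 0.0,
    mz: float = 0.0,
) -> Chromatogram:
    """Construct a Gaussian elution peak of given integrated area.

    Used by the synthetic generator and by tests; the analytic area of the
    noiseless peak is ``area`` (up to truncation of the Gaussian tails).
    """
    t = np.arange(t_start, t_end + dt / 2, dt)
    apex_intensity = area / (sigma * math.sqrt(2.0 * math.pi))
    y = apex_intensity * np.exp(-0.5 * ((t - apex_time) / sigma) ** 2)
    y = np.clip(y + baseline, 0.0, None)
    return Chromatogram(t, y, mz=mz)
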