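"""Spectral estimation of ALFF and fractional ALFF from BOLD voxel time series.

The amplitude of low-frequency fluctuations (ALFF) of a voxel is the mean
amplitude (square root of the periodogram) of its detrended BOLD series over a
low-frequency band, classically 0.01–0.08 Hz.  Fractional ALFF (fALFF)
expresses that amplitude as a fraction of the total amplitude over the entire
detectable spectrum (0 to Nyquist), which suppresses broadband contributions
such as CSF pulsation and large-vessel signal.

Conventions
-----------
* One-sided periodogram on the ``floor(N/2)`` positive-frequency DFT bins;
  the DC bin is excluded everywhere (linear detrending drives it to ~0).
* Band membership is half-open on bin centres, ``f_low < f <= f_high``, with
  a tiny absolute tolerance so that abutting bands partition the axis without
  double counting.  Disjoint bands covering (0, Nyquist] therefore have
  fALFF values that sum to exactly 1.
* Band-pass filtering is an ideal frequency-domain mask (no FIR/IIR design):
  filtering then computing the spectrum is identical to masking the spectrum.
* fALFF is computed as a ratio of amplitude *sums* over bins.  Because the
  number of bins is fixed, the ratio of sums equals the ratio of
  bin-count-weighted means, so this coincides with the "mean amplitude in
  band over mean amplitude over the full range" phrasing up to the constant
  (band bin count)/(total bin count); the sum form is unambiguous when
  out-of-band bins have been zeroed by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .errors import DataError, EmptyBandError, ParameterError

__all__ = [
    "BROAD",
    "NARROW",
    "AmplitudeMap",
    "BandSpec",
    "PowerSpectrum",
    "TimeSeriesGrid",
    "alff",
    "bandpass",
    "detrend_linear",
    "falff",
    "full_band",
    "n_timepoints_for_duration",
    "nyquist",
    "periodogram",
]

#: Absolute tolerance on band-edge comparisons.  Shared by every band mask so
#: that abutting bands assign each bin to exactly one side of the edge.
FREQ_TOL = 1e-9


def nyquist(tr: float) -> float:
    """Highest resolvable frequency in Hz for a sampling interval ``tr`` (s).

    For the 0.735 s repetition time of a multiband rsfMRI acquisition this is
    1/(2*0.735) = 0.680 Hz.
    """
    if not np.isfinite(tr) or tr <= 0:
        raise ParameterError(f"repetition time must be positive, got {tr!r}")
    return 1.0 / (2.0 * tr)


def n_timepoints_for_duration(duration_s: float, tr: float) -> int:
    """Number of volumes acquired in ``duration_s`` seconds at repetition time ``tr``.

    A 6-minute run at TR = 0.735 s yields round(360/0.735) = 490 volumes.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    nyquist(tr)  # validates tr
    return int(round(duration_s / tr))


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``(f_low, f_high]`` in Hz on the periodogram bin grid."""

    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 <= self.f_low < self.f_high):
            raise ParameterError(
                f"require 0 <= f_low < f_high, got ({self.f_low}, {self.f_high})"
            )

    def validate_for(self, tr: float) -> None:
        nyq = nyquist(tr)
        if self.f_high > nyq + FREQ_TOL:
            raise ParameterError(
                f"band upper edge {self.f_high} Hz exceeds Nyquist {nyq:.4g} Hz"
            )

    def mask(self, frequencies: np.ndarray) -> np.ndarray:
        """Boolean membership of bin centres: ``f_low + tol < f <= f_high + tol``.

        The same tolerance appears on both edges, so for abutting bands
        ``(a, b]`` and ``(b, c]`` a bin within tolerance of ``b`` belongs to
        the lower band only.
        """
        f = np.asarray(frequencies, dtype=float)
        return (f > self.f_low + FREQ_TOL) & (f <= self.f_high + FREQ_TOL)


#: Broad low-pass band used for CVR-oriented analyses.
BROAD = BandSpec(0.0, 0.1164)
#: Classical ALFF band dominated by spontaneous neuronal fluctuations.
NARROW = BandSpec(0.01, 0.08)


def full_band(tr: float) -> BandSpec:
    """The entire detectable range (0, Nyquist] for sampling interval ``tr``."""
    return BandSpec(0.0, nyquist(tr))


@dataclass
class TimeSeriesGrid:
    """Voxel-by-timepoint BOLD values with their repetition time.

    ``values`` has shape (n_voxels, n_timepoints); units are arbitrary scanner
    units.  Rows must be finite and at least 4 timepoints long.
    """

    values: np.ndarray
    tr: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        nyquist(self.tr)  # validates tr
        if self.values.shape[1] < 4:
            raise DataError(
                f"need at least 4 timepoints, got {self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("time series contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class PowerSpectrum:
    """One-sided per-voxel periodogram.

    ``frequencies`` are the positive DFT bin centres k/(N*tr) for
    k = 1..floor(N/2) (DC excluded, Nyquist included when N is even);
    ``power`` is the squared DFT magnitude |X_k|^2, shape
    (n_voxels, n_frequencies).
    """

    frequencies: np.ndarray
    power: np.ndarray
    tr: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < 0):
            raise DataError("power spectrum has negative entries")

    @property
    def n_voxels(self) -> int:
        return self.power.shape[0]


@dataclass
class AmplitudeMap:
    """Per-voxel ALFF or fALFF values for a band.

    fALFF values lie in [0, 1]; voxels whose full-spectrum amplitude is zero
    are undefined and carried as NaN, never as 0.
    """

    values: np.ndarray
    band: BandSpec
    kind: Literal["ALFF", "fALFF"]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise DataError("amplitude values must be nonnegative")


def detrend_linear(ts: TimeSeriesGrid) -> TimeSeriesGrid:
    """Remove the per-voxel least-squares line (intercept + slope * t).

    Residuals are orthogonal to the constant and linear regressors; applying
    the operation twice is a no-op up to floating point.
    """
    out = _signal.detrend(ts.values, axis=-1, type="linear")
    return TimeSeriesGrid(out, ts.tr)


def bandpass(ts: TimeSeriesGrid, band: BandSpec) -> TimeSeriesGrid:
    """Ideal frequency-domain band-pass.

    DFT coefficients at bin frequencies f with ``f_low < f <= f_high`` are
    retained (with their conjugates); all others, including DC, are zeroed.
    """
    band.validate_for(ts.tr)
    n = ts.n_timepoints
    spec = np.fft.rfft(ts.values, axis=-1)
    freqs = np.fft.rfftfreq(n, d=ts.tr)
    spec[:, ~band.mask(freqs)] = 0.0
    return TimeSeriesGrid(np.fft.irfft(spec, n=n, axis=-1), ts.tr)


def periodogram(ts: TimeSeriesGrid) -> PowerSpectrum:
    """One-sided squared-magnitude DFT spectrum per voxel.

    Returns |X_k|^2 on the floor(N/2) positive-frequency bins, DC excluded.
    Parseval's relation holds for the zero-DC signal:
    ``sum_t x_t^2 = (1/N) * sum_k w_k |X_k|^2`` with two-sided weight
    ``w_k = 2`` for interior bins and ``w_k = 1`` for the Nyquist bin at
    even N.
    """
    n = ts.n_timepoints
    spec = np.fft.rfft(ts.values, axis=-1)
    freqs = np.fft.rfftfreq(n, d=ts.tr)
    # drop the DC bin; rfft keeps exactly floor(N/2) positive bins after it
    return PowerSpectrum(freqs[1:], np.abs(spec[:, 1:]) ** 2, ts.tr)


def _band_mask(ps: PowerSpectrum, band: BandSpec) -> np.ndarray:
    mask = band.mask(ps.frequencies)
    if not mask.any():
        raise EmptyBandError(
            f"band ({band.f_low}, {band.f_high}] Hz contains no spectral bins"
        )
    return mask


def alff(
    ps: PowerSpectrum,
    band: BandSpec,
    mean_over: Literal["band", "all"] = "band",
) -> AmplitudeMap:
    """Mean amplitude (sqrt of power) over the band's bins, per voxel.

    ``mean_over`` selects the divisor of the amplitude sum: the number of
    in-band bins (default) or the total number of bins.  The two differ by a
    constant factor that cancels in fALFF; "all" matches pipelines that
    average a band-pass-filtered spectrum over its full length.
    """
    mask = _band_mask(ps, band)
    amplitude = np.sqrt(ps.power)
    if mean_over == "band":
        values = amplitude[:, mask].mean(axis=1)
    elif mean_over == "all":
        values = amplitude[:, mask].sum(axis=1) / ps.power.shape[1]
    else:
        raise ParameterError(f"mean_over must be 'band' or 'all', got {mean_over!r}")
    return AmplitudeMap(values, band, "ALFF")


def falff(ps: PowerSpectrum, band: BandSpec) -> AmplitudeMap:
    """Fractional ALFF: band amplitude sum over full-spectrum amplitude sum.

    Scale-invariant in the input series and bounded by [0, 1].  Voxels whose
    total amplitude is zero are undefined and returned as NaN.
    """
    mask = _band_mask(ps, band)
    amplitude = np.sqrt(ps.power)
    numerator = amplitude[:, mask].sum(axis=1)
    denominator = amplitude.sum(axis=1)
    values = np.full(ps.n_voxels, np.nan)
    ok = denominator > 0
    values[ok] = numerator[ok] / denominator[ok]
    out = AmplitudeMap(values, band, "fALFF")
    return out
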