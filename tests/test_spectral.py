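"""Spectral estimation: periodogram, band masks, ALFF and fALFF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from falff.errors import DataError, EmptyBandError, ParameterError
from falff.spectral import (
    BROAD,
    NARROW,
    BandSpec,
    TimeSeriesGrid,
    alff,
    bandpass,
    detrend_linear,
    falff,
    full_band,
    n_timepoints_for_duration,
    nyquist,
    periodogram,
)

TR = 0.735
N = 490


def sinusoid(k, n=N, tr=TR, amp=1.0, n_voxels=1):
    """Unit sinusoid at exact DFT bin k."""
    t = np.arange(n)
    x = amp * np.sin(2 * np.pi * k * t / n)
    return TimeSeriesGrid(np.tile(x, (n_voxels, 1)), tr)


# --------------------------------------------------------------------------
# nyquist / duration arithmetic
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tr, expected", [(0.735, 0.680), (0.5, 1.0), (2.0, 0.25)]
)
def test_nyquist(tr, expected):
    assert nyquist(tr) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
def test_nyquist_rejects_bad_tr(bad):
    with pytest.raises(ParameterError):
        nyquist(bad)


def test_six_minute_run_has_490_volumes():
    assert n_timepoints_for_duration(360.0, 0.735) == 490


# --------------------------------------------------------------------------
# detrending
# --------------------------------------------------------------------------

def test_detrend_annihilates_lines(grid_factory):
    t = np.arange(N)
    for series in (np.full(N, 7.3), 2.5 + 0.01 * t, -4.0 - 3.0 * t):
        out = detrend_linear(grid_factory(series))
        assert np.max(np.abs(out.values)) < 1e-8


def test_detrend_matches_normal_equations_oracle(grid_factory, rng):
    """Sinusoid + ramp: residual equals an explicit least-squares fit."""
    t = np.arange(N, dtype=float)
    x = np.sin(2 * np.pi * 7 * t / N) + 0.03 * t + 1.5
    design = np.column_stack([np.ones(N), t])
    beta = np.linalg.solve(design.T @ design, design.T @ x)
    expected = x - design @ beta
    out = detrend_linear(grid_factory(x))
    assert np.max(np.abs(out.values[0] - expected)) <= 1e-8
    # residuals orthogonal to both regressors
    assert abs(out.values[0].sum()) < 1e-6
    assert abs(out.values[0] @ t) < 1e-3


def test_detrend_idempotent(rng):
    ts = TimeSeriesGrid(rng.standard_normal((5, N)), TR)
    once = detrend_linear(ts)
    twice = detrend_linear(once)
    assert np.max(np.abs(twice.values - once.values)) < 1e-10


def test_nonfinite_input_rejected():
    bad = np.ones((1, N))
    bad[0, 3] = np.nan
    with pytest.raises(DataError):
        TimeSeriesGrid(bad, TR)


# --------------------------------------------------------------------------
# bandpass
# --------------------------------------------------------------------------

def test_bandpass_passband_identity():
    k = 20  # bin freq 20/(N*TR) = 0.0555 Hz, inside NARROW
    ts = sinusoid(k)
    out = bandpass(ts, NARROW)
    assert np.max(np.abs(out.values - ts.values)) <= 1e-8


def test_bandpass_stopband_annihilation():
    k = 60  # 0.1666 Hz, outside NARROW
    out = bandpass(sinusoid(k), NARROW)
    assert np.max(np.abs(out.values)) <= 1e-8


def test_bandpass_rejects_band_above_nyquist():
    with pytest.raises(ParameterError):
        bandpass(sinusoid(3), BandSpec(0.01, 0.7))


def test_bandpass_white_noise_variance_fraction(rng):
    """Parseval bin counting: retained variance ~ fraction of retained bins."""
    n_rep = 1000
    ts = TimeSeriesGrid(rng.standard_normal((n_rep, N)), TR)
    out = bandpass(ts, NARROW)
    freqs = np.fft.rfftfreq(N, TR)
    frac_bins = NARROW.mask(freqs).sum() / (N / 2)  # two-sided weight cancels
    ratio = out.values.var(axis=1, ddof=0) / ts.values.var(axis=1, ddof=0)
    se = ratio.std(ddof=1) / np.sqrt(n_rep)
    assert abs(ratio.mean() - frac_bins) < 4 * se + 1e-3


# --------------------------------------------------------------------------
# periodogram
# --------------------------------------------------------------------------

def test_periodogram_sinusoid_single_bin():
    k = 11
    ps = periodogram(sinusoid(k))
    peak = np.argmax(ps.power[0])
    assert ps.frequencies[peak] == pytest.approx(k / (N * TR))
    others = np.delete(ps.power[0], peak)
    assert np.max(others) < 1e-12 * ps.power[0, peak]


def test_periodogram_zero_series():
    ps = periodogram(TimeSeriesGrid(np.zeros((2, N)), TR))
    assert np.all(ps.power == 0)


def test_periodogram_axis_matches_bin_grid():
    ps = periodogram(TimeSeriesGrid(np.zeros((1, N)), TR))
    assert len(ps.frequencies) == N // 2
    spacing = np.diff(ps.frequencies)
    assert np.allclose(spacing, 1.0 / (N * TR))
    assert ps.frequencies[0] > 0


def test_periodogram_matches_direct_dft_oracle(rng):
    """Fixed 16-point vector against brute-force DFT summation."""
    x = rng.standard_normal(16)
    ps = periodogram(TimeSeriesGrid(x, tr=1.0))
    for j, freq in enumerate(ps.frequencies):
        k = int(round(freq * 16))
        re = sum(x[t] * np.cos(-2 * np.pi * k * t / 16) for t in range(16))
        im = sum(x[t] * np.sin(-2 * np.pi * k * t / 16) for t in range(16))
        assert ps.power[0, j] == pytest.approx(re**2 + im**2, abs=1e-10)


@pytest.mark.parametrize("n", [16, 17, 490, 489])
def test_periodogram_parseval(rng, n):
    """Two-sided-equivalent power equals time-domain energy of the 0-DC signal."""
    x = rng.standard_normal((3, n))
    x = x - x.mean(axis=1, keepdims=True)
    ps = periodogram(TimeSeriesGrid(x, TR))
    weights = np.full(n // 2, 2.0)
    if n % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin appears once in the two-sided DFT
    lhs = (x**2).sum(axis=1)
    rhs = (ps.power * weights).sum(axis=1) / n
    assert np.allclose(lhs, rhs, rtol=1e-6)


def test_too_short_series_rejected():
    with pytest.raises(DataError):
        TimeSeriesGrid(np.ones((1, 3)), TR)


# --------------------------------------------------------------------------
# ALFF
# --------------------------------------------------------------------------

def test_alff_single_bin_definition():
    """All power p in one in-band bin with B in-band bins -> sqrt(p)/B."""
    ps = periodogram(sinusoid(10, amp=2.0))
    band = NARROW
    mask = band.mask(ps.frequencies)
    b = int(mask.sum())
    p = ps.power[0].max()
    assert alff(ps, band).values[0] == pytest.approx(np.sqrt(p) / b)


def test_alff_homogeneous_in_scale(rng):
    x = rng.standard_normal((4, N))
    a1 = alff(periodogram(TimeSeriesGrid(x, TR)), NARROW).values
    a3 = alff(periodogram(TimeSeriesGrid(3.0 * x, TR)), NARROW).values
    assert np.allclose(a3, 3.0 * a1, rtol=1e-10)


def test_alff_white_noise_matches_bin_enumeration(rng):
    """Brute-force sqrt-then-mean over enumerated bins; theory expectation."""
    n_vox = 1000
    x = rng.standard_normal((n_vox, N))
    ps = periodogram(TimeSeriesGrid(x, TR))
    got = alff(ps, BROAD).values
    mask = BROAD.mask(ps.frequencies)
    brute = np.array(
        [np.mean([np.sqrt(ps.power[v, j]) for j in np.flatnonzero(mask)])
         for v in range(20)]
    )
    assert np.allclose(got[:20], brute, rtol=1e-12)
    # |X_k| of unit white noise is Rayleigh(sqrt(N/2)): mean sqrt(pi*N/4)/sqrt...
    expected = np.sqrt(np.pi * N / 4)
    se = got.std(ddof=1) / np.sqrt(n_vox)
    assert abs(got.mean() - expected) < 4 * se


def test_alff_mean_over_all_is_constant_rescale(rng):
    ps = periodogram(TimeSeriesGrid(rng.standard_normal((3, N)), TR))
    in_band = alff(ps, NARROW, mean_over="band").values
    over_all = alff(ps, NARROW, mean_over="all").values
    b = NARROW.mask(ps.frequencies).sum()
    assert np.allclose(over_all, in_band * b / ps.power.shape[1], rtol=1e-12)


def test_alff_empty_band_raises(rng):
    ps = periodogram(TimeSeriesGrid(rng.standard_normal((1, N)), TR))
    with pytest.raises(EmptyBandError):
        alff(ps, BandSpec(1e-5, 1e-4))


# --------------------------------------------------------------------------
# fALFF
# --------------------------------------------------------------------------

def test_falff_full_band_is_one(rng):
    ps = periodogram(TimeSeriesGrid(rng.standard_normal((5, N)), TR))
    values = falff(ps, full_band(TR)).values
    assert np.allclose(values, 1.0, atol=1e-12)


def test_falff_pure_sinusoid_in_and_out_of_band():
    ps_in = periodogram(sinusoid(10))  # 0.0278 Hz, in NARROW
    assert falff(ps_in, NARROW).values[0] == pytest.approx(1.0, abs=1e-9)
    ps_out = periodogram(sinusoid(60))  # 0.167 Hz, out of NARROW
    assert falff(ps_out, NARROW).values[0] == pytest.approx(0.0, abs=1e-9)


def test_falff_white_noise_band_fraction(rng):
    n_vox = 1000
    ps = periodogram(TimeSeriesGrid(rng.standard_normal((n_vox, N)), TR))
    values = falff(ps, NARROW).values
    frac = NARROW.mask(ps.frequencies).mean()
    se = values.std(ddof=1) / np.sqrt(n_vox)
    assert abs(values.mean() - frac) < 4 * se


def test_falff_scale_invariance(rng):
    x = rng.standard_normal((4, N))
    f1 = falff(periodogram(TimeSeriesGrid(x, TR)), NARROW).values
    fc = falff(periodogram(TimeSeriesGrid(17.0 * x, TR)), NARROW).values
    assert np.max(np.abs(fc - f1)) < 1e-10


def test_falff_band_additivity(rng):
    """Disjoint bands covering (0, Nyquist] sum voxelwise to 1."""
    ps = periodogram(TimeSeriesGrid(rng.standard_normal((6, N)), TR))
    edges = [0.0, 0.01, 0.08, 0.1164, 0.3, nyquist(TR)]
    total = sum(
        falff(ps, BandSpec(lo, hi)).values
        for lo, hi in zip(edges[:-1], edges[1:])
    )
    assert np.max(np.abs(total - 1.0)) < 1e-10


def test_falff_zero_voxel_is_nan_not_zero():
    x = np.vstack([np.zeros(N), np.random.default_rng(0).standard_normal(N)])
    values = falff(periodogram(TimeSeriesGrid(x, TR)), NARROW).values
    assert np.isnan(values[0]) and np.isfinite(values[1])


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.01, max_value=1e4))
def test_falff_scale_invariance_property(seed, c):
    x = np.random.default_rng(seed).standard_normal((2, 64))
    f1 = falff(periodogram(TimeSeriesGrid(x, TR)), NARROW).values
    fc = falff(periodogram(TimeSeriesGrid(c * x, TR)), NARROW).values
    assert np.max(np.abs(fc - f1)) < 1e-9


def test_csf_suppression_on_constructed_spectra():
    """A flat, uniformly stronger spectrum has higher ALFF but lower fALFF
    than a weaker band-concentrated one."""
    from falff.spectral import PowerSpectrum

    freqs = np.fft.rfftfreq(N, TR)[1:]
    band_mask = NARROW.mask(freqs)
    brainstem = np.where(band_mask, 1.0, 0.05)
    csf = np.full_like(freqs, 2.0)  # higher at every frequency, flat
    ps = PowerSpectrum(freqs, np.vstack([csf, brainstem]), TR)
    a = alff(ps, NARROW).values
    f = falff(ps, NARROW).values
    assert a[0] > a[1]
    assert f[0] < f[1]
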