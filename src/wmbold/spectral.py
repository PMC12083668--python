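"""Power spectra and fractional ALFF for BOLD time series.

The fractional amplitude of low-frequency fluctuations (fALFF) of a BOLD
series is the mean spectral amplitude inside a low-frequency band divided
by the mean amplitude over a reference range.  Spectra are estimated with
the Welch averaged-periodogram method and "amplitude" means the square
root of the Welch power density (the canonical fALFF convention; raw
power is available via ``use_power=True``).

Bundle-wise fALFF uses a repeated unbiased-sampling scheme: a fixed number
of voxels is drawn without replacement from the bundle, their series are
averaged, fALFF is computed, and the procedure is repeated; the bundle
value is the mean over repeats.  This controls for bundle-volume effects
on the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "BoldSeries",
    "PowerSpectrum",
    "FalffResult",
    "PeakResult",
    "welch_spectrum",
    "falff",
    "bundle_falff",
    "find_peak",
]

#: default low-frequency band (Hz) for fALFF numerators
DEFAULT_BAND = (0.01, 0.1)
#: default lower bound (Hz) of the fALFF denominator range
DEFAULT_DENOM_LO = 0.01
#: Welch defaults: segment length (samples) and fractional overlap
DEFAULT_SEGMENT_LEN = 256
DEFAULT_OVERLAP_FRAC = 0.5


@dataclass
class BoldSeries:
    """A sampled BOLD time course.

    Parameters
    ----------
    values : array
        Signal S(t), arbitrary units.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    te_s : float
        Echo time in seconds (needed to convert signal to relaxation-rate
        units).
    baseline : float, optional
        Baseline signal level S̄.  Defaults to the series mean when not
        provided.
    """

    values: np.ndarray
    tr_s: float
    te_s: float = 0.0331
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("BoldSeries values must be one-dimensional")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.te_s <= 0:
            raise ValueError("te_s must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.tr_s

    @property
    def duration_s(self) -> float:
        return self.values.size * self.tr_s

    def baseline_value(self) -> float:
        """Stored baseline S̄, falling back to the series mean."""
        if self.baseline is not None:
            return float(self.baseline)
        return float(self.values.mean())


@dataclass
class PowerSpectrum:
    """Amplitude spectrum: sqrt of the Welch power density per frequency."""

    freqs_hz: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freqs_hz.shape != self.amplitude.shape:
            raise ValueError("freqs and amplitude must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.freqs_hz[0] < 0:
            raise ValueError("frequencies must be non-negative")

    @property
    def df_hz(self) -> float:
        """Frequency bin width."""
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)


@dataclass
class FalffResult:
    """Bundle-wise fALFF from repeated voxel sampling."""

    falff: float
    n_repeats: int
    per_repeat: np.ndarray
    band_lo_hz: float
    band_hi_hz: float
    denom_lo_hz: float
    n_sample: int = 0

    @property
    def falff_sd(self) -> float:
        # np.std of n identical floats can round to ~ulp; report exactly 0
        if self.per_repeat.size < 2 or np.ptp(self.per_repeat) == 0:
            return 0.0
        return float(np.std(self.per_repeat, ddof=1))


class PeakResult(NamedTuple):
    """Location of the dominant low-frequency spectral peak."""

    freq_hz: float
    height: float
    is_local_max: bool


def welch_spectrum(
    series: BoldSeries,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> PowerSpectrum:
    """Welch amplitude spectrum of a BOLD series.

    Hann-windowed, mean-removed Welch estimate; the returned amplitude is
    the square root of the power spectral density.  Frequency resolution
    is 1/(segment_len * tr_s).

    Raises
    ------
    ValueError
        If the segment exceeds the series length or the overlap fraction
        is outside [0, 1).
    """
    n = len(series)
    if n < 64:
        raise ValueError(f"series too short for spectral estimation ({n} < 64)")
    if segment_len > n:
        raise ValueError(f"segment_len {segment_len} exceeds series length {n}")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    freqs, pxx = _signal.welch(
        series.values,
        fs=series.fs_hz,
        window="hann",
        nperseg=segment_len,
        noverlap=int(round(segment_len * overlap_frac)),
        detrend="constant",
        scaling="density",
    )
    if np.allclose(pxx, 0.0):
        warnings.warn("constant series: spectrum is identically zero", stacklevel=2)
    return PowerSpectrum(freqs, np.sqrt(np.maximum(pxx, 0.0)))


def falff(
    spectrum: PowerSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    denom_lo: float = DEFAULT_DENOM_LO,
) -> float:
    """Fractional ALFF of an amplitude spectrum.

    Mean amplitude over frequency bins in ``band`` divided by the mean
    amplitude over bins from ``denom_lo`` up to the Nyquist frequency.
    The default denominator starts at the band's lower edge (full range
    above 0.01 Hz); pass ``denom_lo=band[1]`` for the strictly
    above-band variant.
    """
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError("band must satisfy 0 <= lo < hi")
    if denom_lo > lo:
        raise ValueError("denom_lo must not exceed the band lower edge")
    num_mask = spectrum.band_mask(lo, hi)
    den_mask = spectrum.freqs_hz >= denom_lo
    if not num_mask.any() or not den_mask.any():
        raise ValueError("no frequency bins in the requested band")
    denom = float(spectrum.amplitude[den_mask].mean())
    if denom <= 0:
        raise ValueError("zero denominator: constant or band-empty signal")
    return float(spectrum.amplitude[num_mask].mean()) / denom


def bundle_falff(
    voxel_values: np.ndarray | Sequence[BoldSeries],
    tr_s: float | None = None,
    n_sample: int = 500,
    n_repeat: int = 50,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    denom_lo: float = DEFAULT_DENOM_LO,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> FalffResult:
    """Bundle-wise fALFF by repeated unbiased voxel sampling.

    Each repeat draws ``n_sample`` voxels without replacement, averages
    their time series and computes fALFF of the average; the reported
    value is the mean over repeats.  Deterministic given ``seed``.

    Parameters
    ----------
    voxel_values : (n_voxels, n_timepoints) array or sequence of BoldSeries
        One time series per voxel of the bundle.
    tr_s : float
        Sampling interval; required when ``voxel_values`` is an array.
    """
    if tr_s is None:
        if not isinstance(voxel_values, np.ndarray) and len(voxel_values) > 0:
            first = voxel_values[0]
            if isinstance(first, BoldSeries):
                tr_s = first.tr_s
        if tr_s is None:
            raise ValueError("tr_s is required for array input")
    if not isinstance(voxel_values, np.ndarray):
        voxel_values = np.vstack([np.asarray(s.values if isinstance(s, BoldSeries) else s) for s in voxel_values])
    voxel_values = np.asarray(voxel_values, dtype=float)
    n_vox = voxel_values.shape[0]
    if n_vox < n_sample:
        raise ValueError(
            f"bundle has {n_vox} voxels, fewer than n_sample={n_sample}; "
            "it should have been filtered upstream"
        )
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(n_repeat)
    for k in range(n_repeat):
        # sorted so the same voxel set always averages in the same order
        idx = np.sort(rng.choice(n_vox, size=n_sample, replace=False))
        mean_series = BoldSeries(voxel_values[idx].mean(axis=0), tr_s=tr_s)
        spec = welch_spectrum(mean_series, segment_len, overlap_frac)
        per_repeat[k] = falff(spec, band=band, denom_lo=denom_lo)
    return FalffResult(
        falff=float(per_repeat.mean()),
        n_repeats=n_repeat,
        per_repeat=per_repeat,
        band_lo_hz=band[0],
        band_hi_hz=band[1],
        denom_lo_hz=denom_lo,
        n_sample=n_sample,
    )


def find_peak(
    spectrum: PowerSpectrum,
    search_band: tuple[float, float] = (0.02, 0.15),
) -> PeakResult:
    """Dominant local maximum of the spectrum within a band.

    A local maximum is a bin strictly greater than both neighbours; the
    highest one inside ``search_band`` is returned.  When no interior
    local maximum exists (e.g. a monotone spectrum) the band maximum is
    returned with ``is_local_max=False``.
    """
    mask = spectrum.band_mask(*search_band)
    if mask.sum() < 3:
        raise ValueError("need at least 3 frequency bins in the search band")
    amp = spectrum.amplitude
    idx = np.flatnonzero(mask)
    local: list[int] = []
    for i in idx:
        if 0 < i < amp.size - 1 and amp[i] > amp[i - 1] and amp[i] > amp[i + 1]:
            local.append(i)
    if local:
        best = max(local, key=lambda i: amp[i])
        return PeakResult(float(spectrum.freqs_hz[best]), float(amp[best]), True)
    best = idx[np.argmax(amp[idx])]
    return PeakResult(float(spectrum.freqs_hz[best]), float(amp[best]), False)
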