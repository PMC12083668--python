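"""Resting-state hemodynamic response estimation and the initial dip.

Prominent peaks of a resting BOLD series are taken to mark major
spontaneous neural events; epochs time-locked to those events are
averaged (after per-epoch percent-change normalization against the
pre-event window) to yield an empirical HRF.  This event-triggered
average is a deliberately simple estimator of the response shape — it
does not deconvolve overlapping responses the way blind-deconvolution
toolboxes do — but it preserves the feature of interest here: the
*initial dip*, the negative deflection preceding the main positive peak,
whose magnitude is extracted per estimate.

Detected peaks lag the underlying neural events by roughly the HRF peak
time; pass ``onset_shift_s`` to ``estimate_hrf`` to place the epoch
origin at the presumed event onset rather than at the detected peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import BoldSeries

__all__ = ["HrfEstimate", "detect_events", "estimate_hrf", "dip_height"]


@dataclass
class HrfEstimate:
    """Event-triggered average response in percent of the pre-event baseline."""

    time_grid_s: np.ndarray
    curve: np.ndarray
    n_events: int
    dip_height: float
    peak_height: float
    peak_time_s: float
    n_dropped: int = 0
    peak_at_positive_lag: bool = True


def detect_events(
    series: BoldSeries, k_sd: float = 1.0, min_sep_s: float = 4.0
) -> np.ndarray:
    """Indices of prominent signal peaks (putative spontaneous events).

    Local maxima of the standardized series exceeding ``k_sd`` standard
    deviations, thinned so that retained events are at least
    ``min_sep_s`` apart; when two candidates conflict the larger peak is
    kept.
    """
    v = series.values
    if v.size < 64:
        raise ValueError("series too short for event detection")
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance series: no events detectable")
    z = (v - v.mean()) / sd
    cand = [
        i
        for i in range(1, z.size - 1)
        if z[i] > z[i - 1] and z[i] > z[i + 1] and z[i] > k_sd
    ]
    min_sep = int(np.ceil(min_sep_s / series.tr_s))
    kept: list[int] = []
    for i in sorted(cand, key=lambda i: -z[i]):
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def estimate_hrf(
    series: BoldSeries,
    events: np.ndarray,
    pre_window_s: float = 4.0,
    post_window_s: float = 24.0,
    onset_shift_s: float = 0.0,
) -> HrfEstimate:
    """Event-triggered average HRF around the given event indices.

    Each epoch runs from ``pre_window_s`` before to ``post_window_s``
    after the epoch origin (the event index shifted back by
    ``onset_shift_s``) and is expressed as percent change from its own
    pre-window mean, which rejects slow drifts.  Events whose full window
    does not fit inside the series are dropped and counted.

    Raises
    ------
    ValueError
        If fewer than 5 usable events remain.
    """
    v = series.values
    tr = series.tr_s
    pre_n = int(round(pre_window_s / tr))
    post_n = int(round(post_window_s / tr))
    shift_n = int(round(onset_shift_s / tr))
    if pre_n < 1:
        raise ValueError("pre-window must cover at least one sample")
    epochs = []
    n_dropped = 0
    for ev in np.asarray(events, dtype=int):
        origin = ev - shift_n
        if origin - pre_n < 0 or origin + post_n >= v.size:
            n_dropped += 1
            continue
        base = v[origin - pre_n : origin].mean()
        if base <= 0:
            n_dropped += 1
            continue
        seg = v[origin - pre_n : origin + post_n + 1]
        epochs.append(100.0 * (seg - base) / base)
    if len(epochs) < 5:
        raise ValueError(
            f"only {len(epochs)} usable events (need >= 5); {n_dropped} dropped"
        )
    curve = np.mean(epochs, axis=0)
    t = np.arange(-pre_n, post_n + 1) * tr
    peak_idx = int(np.argmax(curve))
    positive = t[peak_idx] > 0
    # main response peak restricted to positive lags
    pos = t > 0
    pos_peak_idx = int(np.flatnonzero(pos)[np.argmax(curve[pos])])
    peak_time = float(t[pos_peak_idx])
    peak_height = float(curve[pos_peak_idx])
    dip_mask = (t > 0) & (t < peak_time)
    dip = float(max(0.0, -curve[dip_mask].min())) if dip_mask.any() else 0.0
    return HrfEstimate(
        time_grid_s=t,
        curve=curve,
        n_events=len(epochs),
        dip_height=dip,
        peak_height=peak_height,
        peak_time_s=peak_time,
        n_dropped=n_dropped,
        peak_at_positive_lag=positive,
    )


def dip_height(est: HrfEstimate) -> float:
    """Magnitude of the initial dip: the most negative value of the curve
    on (0, peak_time), floored at 0 when the curve never goes negative
    there.

    Raises
    ------
    ValueError
        If the estimate's global maximum is not at a positive lag (no
        identifiable main response peak).
    """
    if not est.peak_at_positive_lag:
        raise ValueError("no positive-lag peak: dip height undefined")
    return float(est.dip_height)
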