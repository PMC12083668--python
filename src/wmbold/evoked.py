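"""Block-design evoked-response analysis.

Implements the percent-signal-change analysis used for the optic-nerve
visual task: a paradigm of eight 32-s stimulus blocks (each ending in a
4-s blank) separated by 16-s rests at the start and end of the run and a
12-s rest in the middle, at TR = 1 s (300 time points).  Percent change
is computed against the pooled rest baseline and responses are averaged
time-locked across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import BoldSeries

__all__ = [
    "Paradigm",
    "TimingError",
    "paper_paradigm",
    "percent_change",
    "block_average",
    "block_means",
]


class TimingError(ValueError):
    """Paradigm timing does not match the series it describes."""


@dataclass
class Paradigm:
    """Timing of a block-design run.

    ``block_starts_s``/``block_durs_s`` give the stimulus blocks (a block
    may include a blank tail of ``blank_tail_s`` seconds at its end);
    ``rest_intervals_s`` are (start, end) rest periods used for the
    baseline.  Blocks and rests must be disjoint and tile
    ``[0, n_timepoints * tr_s]`` exactly.
    """

    block_starts_s: np.ndarray
    block_durs_s: np.ndarray
    rest_intervals_s: list[tuple[float, float]]
    tr_s: float = 1.0
    n_timepoints: int = 300
    blank_tail_s: float = 0.0

    def __post_init__(self) -> None:
        self.block_starts_s = np.asarray(self.block_starts_s, dtype=float)
        self.block_durs_s = np.asarray(self.block_durs_s, dtype=float)
        if self.block_starts_s.shape != self.block_durs_s.shape:
            raise TimingError("block starts and durations differ in length")
        if self.tr_s <= 0:
            raise TimingError("tr_s must be positive")
        total = self.n_timepoints * self.tr_s
        intervals = [
            (s, s + d) for s, d in zip(self.block_starts_s, self.block_durs_s)
        ] + [(a, b) for a, b in self.rest_intervals_s]
        for a, b in intervals:
            if a < 0 or b > total + 1e-9:
                raise TimingError(
                    f"interval ({a}, {b}) outside run [0, {total}]"
                )
        ordered = sorted(intervals)
        for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
            if a1 < b0 - 1e-9:
                raise TimingError(
                    f"overlapping intervals ({a0}, {b0}) and ({a1}, {b1})"
                )
        covered = sum(b - a for a, b in intervals)
        if abs(covered - total) > 1e-6:
            raise TimingError(
                f"paradigm covers {covered} s but the run lasts {total} s"
            )

    @property
    def n_blocks(self) -> int:
        return self.block_starts_s.size

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.tr_s

    def _times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_s

    def stimulus_mask(self) -> np.ndarray:
        """True while the stimulus is on (block minus its blank tail)."""
        t = self._times()
        mask = np.zeros(self.n_timepoints, dtype=bool)
        for s, d in zip(self.block_starts_s, self.block_durs_s):
            mask |= (t >= s) & (t < s + d - self.blank_tail_s)
        return mask

    def block_mask(self) -> np.ndarray:
        """True during stimulus blocks, blank tails included."""
        t = self._times()
        mask = np.zeros(self.n_timepoints, dtype=bool)
        for s, d in zip(self.block_starts_s, self.block_durs_s):
            mask |= (t >= s) & (t < s + d)
        return mask

    def rest_mask(self) -> np.ndarray:
        t = self._times()
        mask = np.zeros(self.n_timepoints, dtype=bool)
        for a, b in self.rest_intervals_s:
            mask |= (t >= a) & (t < b)
        return mask


def paper_paradigm() -> Paradigm:
    """The eight-direction bar paradigm: 16 s rest, 4 blocks of 32 s,
    12 s rest, 4 blocks of 32 s, 16 s rest — 300 s total at TR = 1 s.

    Each 32-s block ends with a 4-s blank tail.
    """
    starts = [16.0 + 32.0 * i for i in range(4)]
    starts += [156.0 + 32.0 * i for i in range(4)]
    return Paradigm(
        block_starts_s=np.array(starts),
        block_durs_s=np.full(8, 32.0),
        rest_intervals_s=[(0.0, 16.0), (144.0, 156.0), (284.0, 300.0)],
        tr_s=1.0,
        n_timepoints=300,
        blank_tail_s=4.0,
    )


def percent_change(series: BoldSeries, paradigm: Paradigm) -> np.ndarray:
    """Percent BOLD signal change against the pooled rest baseline.

    S_rest is the mean of the signal over all rest intervals; the result
    is ``100 * (S(t) - S_rest) / S_rest``.
    """
    if len(series) != paradigm.n_timepoints:
        raise TimingError(
            f"series has {len(series)} time points, paradigm expects "
            f"{paradigm.n_timepoints}"
        )
    rest = paradigm.rest_mask()
    if rest.sum() < 5:
        raise TimingError("rest intervals contain fewer than 5 time points")
    s_rest = float(series.values[rest].mean())
    if s_rest <= 0:
        raise ValueError("non-positive rest baseline")
    return 100.0 * (series.values - s_rest) / s_rest


def block_average(
    percent: np.ndarray | list[np.ndarray],
    paradigm: Paradigm,
    window_s: float | None = None,
    include_blank_tail: bool = True,
) -> np.ndarray:
    """Time-locked mean response across stimulus blocks (and runs).

    Extracts a ``window_s``-long epoch from each block onset and averages
    pointwise across the blocks; when a list of percent series is given
    (multiple runs or subjects) the average also pools across them.
    """
    runs = percent if isinstance(percent, list) else [percent]
    runs = [np.asarray(p, dtype=float) for p in runs]
    if window_s is None:
        window_s = float(paradigm.block_durs_s.min())
        if not include_blank_tail:
            window_s -= paradigm.blank_tail_s
    starts = np.sort(paradigm.block_starts_s)
    if starts.size > 1:
        min_gap = float(np.diff(starts).min())
        if window_s > min_gap + 1e-9:
            raise TimingError(
                f"window of {window_s} s exceeds the {min_gap} s inter-block spacing"
            )
    n_w = int(round(window_s / paradigm.tr_s))
    epochs = []
    for run in runs:
        for s in paradigm.block_starts_s:
            i0 = int(round(s / paradigm.tr_s))
            if i0 + n_w > run.size:
                raise TimingError("block window extends past the end of the series")
            epochs.append(run[i0 : i0 + n_w])
    return np.mean(epochs, axis=0)


def block_means(
    percent: np.ndarray,
    paradigm: Paradigm,
    include_blank_tail: bool = True,
) -> np.ndarray:
    """Mean percent change within each stimulus block (one value per block)."""
    p = np.asarray(percent, dtype=float)
    t = np.arange(paradigm.n_timepoints) * paradigm.tr_s
    out = []
    tail = 0.0 if include_blank_tail else paradigm.blank_tail_s
    for s, d in zip(paradigm.block_starts_s, paradigm.block_durs_s):
        m = (t >= s) & (t < s + d - tail)
        out.append(float(p[m].mean()))
    return np.array(out)
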