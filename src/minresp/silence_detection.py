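"""Amplitude-range silence detection with histogram-calibrated cut-off.

Speech produces a highly variable signal; its absence does not.  The
detector computes the signal range (max - min) in small non-overlapping
windows of 0.01 s, builds a histogram of those ranges with Scott's-rule
bin width, and picks a cut-off from the histogram: the range
distribution is strongly right-skewed because silent windows pile up in
the leftmost bins, so the upper edge of the last silence-peak bin (the
lower edge of the valley that follows it) separates silence from
speech.  The cut-off is then applied to
larger non-overlapping windows of 0.1 s, and runs of silent windows are
merged into timestamped pause episodes.

The original procedure selected the histogram bin by listening to
auditory probes; here the valley selection is automated for
reproducibility and a manual ``index:k`` override is kept for parity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._types import PauseEpisode, Waveform

SMALL_WINDOW = 0.01
EVAL_WINDOW = 0.1


@dataclass
class SilenceCalibration:
    small_window: float
    eval_window: float
    bin_width: float
    cutoff: float
    cutoff_bin_index: int  # 1-based
    strategy: str
    histogram_counts: np.ndarray = field(repr=False, default=None)
    histogram_edges: np.ndarray = field(repr=False, default=None)

    def report(self) -> dict:
        return {
            "small_window": self.small_window,
            "eval_window": self.eval_window,
            "bin_width": self.bin_width,
            "cutoff": self.cutoff,
            "cutoff_bin_index": self.cutoff_bin_index,
            "strategy": self.strategy,
            "histogram_counts": [int(c) for c in self.histogram_counts],
            "histogram_edges": [float(e) for e in self.histogram_edges],
        }


def compute_range_series(w: Waveform, window: float = SMALL_WINDOW) -> np.ndarray:
    """max - min of the samples in each non-overlapping window; the final
    partial window is dropped."""
    if w.samples.size == 0:
        raise ValueError("empty waveform")
    n = int(round(window * w.sample_rate))
    if n < 1 or w.samples.size < n:
        raise ValueError(f"waveform shorter than one {window}s window")
    m = w.samples.size // n
    blocks = w.samples[: m * n].reshape(m, n)
    return blocks.max(axis=1) - blocks.min(axis=1)


def scott_bin_width(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    return 3.49 * values.std(ddof=1) * values.size ** (-1.0 / 3.0)


def calibrate_cutoff(ranges: np.ndarray, strategy: str = "valley",
                     smooth: int = 3) -> SilenceCalibration:
    """Histogram-based cut-off in amplitude-range units.

    ``valley`` finds the leftmost valley after the leftmost mode (the
    silence peak) on the raw counts — falling back to a 3-bin
    moving-average smoothed histogram when the raw counts show no
    valley — and cuts at that valley's lower edge; ``index:k`` takes the
    right edge of 1-based bin k.
    """
    ranges = np.asarray(ranges, float)
    if ranges.size < 100:
        raise ValueError("need at least 100 range values to calibrate")
    bw = scott_bin_width(ranges)
    if bw <= 0:
        raise ValueError("no speech detected: zero-variance range series")
    lo = ranges.min()
    n_bins = max(int(np.ceil((ranges.max() - lo) / bw)), 1)
    edges = lo + bw * np.arange(n_bins + 1)
    counts, _ = np.histogram(ranges, bins=edges)

    def _make(idx1: int) -> SilenceCalibration:  # idx1 is 1-based
        return SilenceCalibration(
            small_window=SMALL_WINDOW,
            eval_window=EVAL_WINDOW,
            bin_width=bw,
            cutoff=float(edges[idx1]),
            cutoff_bin_index=idx1,
            strategy=strategy,
            histogram_counts=counts,
            histogram_edges=edges,
        )

    if strategy.startswith("index:"):
        k = int(strategy.split(":", 1)[1])
        if not 1 <= k <= n_bins:
            raise ValueError(f"bin index {k} outside 1..{n_bins}")
        return _make(k)
    if strategy != "valley":
        raise ValueError(f"unknown strategy {strategy!r}")

    def _find_valley(c):
        # leftmost mode: end of the initial non-decreasing run
        mode = 0
        while mode + 1 < len(c) and c[mode + 1] >= c[mode]:
            mode += 1
        # valley: first bin after the mode where the decline bottoms out
        for j in range(mode + 1, len(c) - 1):
            if c[j] <= c[j + 1]:
                return j
        return None

    j = _find_valley(counts.astype(float))
    if j is None and n_bins >= smooth:
        # fall back to a smoothed histogram when the raw one is too ragged
        padded = np.concatenate([counts[:1].repeat(smooth // 2), counts,
                                 counts[-1:].repeat(smooth // 2)]).astype(float)
        sm = np.convolve(padded, np.ones(smooth) / smooth, mode="valid")
        j = _find_valley(sm)
    if j is not None:
        # cut at the lower edge of the valley bin, i.e. the upper edge of
        # the last silence-peak bin (1-based bin index j)
        return _make(j)
    warnings.warn("no valley found in range histogram; falling back to bin 1")
    return _make(1)


def classify_silence(w: Waveform, cal: SilenceCalibration) -> np.ndarray:
    """Boolean flag per non-overlapping 0.1-s window: silent iff the
    amplitude range does not exceed the calibrated cut-off."""
    ranges = compute_range_series(w, window=cal.eval_window)
    return ranges <= cal.cutoff


def merge_to_episodes(flags: np.ndarray, eval_window: float = EVAL_WINDOW,
                      min_duration: float = EVAL_WINDOW) -> list:
    """Maximal runs of silent windows become pause episodes on the window
    grid; runs shorter than ``min_duration`` are dropped."""
    flags = np.asarray(flags, bool)
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    out = []
    for i0, i1 in zip(starts, ends):
        dur = (i1 - i0) * eval_window
        if dur >= min_duration - 1e-12:
            out.append(PauseEpisode(i0 * eval_window, i1 * eval_window))
    return out


def apply_min_duration_filter(episodes, threshold: float = 3.0) -> list:
    """Keep only episodes at least ``threshold`` seconds long (inclusive
    at exactly the threshold) — the conventional 'silence' variant of the
    pause track."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [e for e in episodes if e.duration >= threshold - 1e-12]


def detect_pauses(w: Waveform, strategy: str = "valley",
                  min_duration: float = EVAL_WINDOW):
    """End-to-end detection: range series, calibration, classification,
    episode merging.  Returns (episodes, calibration)."""
    ranges = compute_range_series(w)
    cal = calibrate_cutoff(ranges, strategy=strategy)
    flags = classify_silence(w, cal)
    return merge_to_episodes(flags, min_duration=min_duration), cal


def pause_iou(detected, truth) -> float:
    """Duration-weighted intersection-over-union of two episode sets."""
    def merge(eps):
        ivs = sorted((e.start, e.end) for e in eps)
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return out

    a, b = merge(detected), merge(truth)
    inter = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            inter += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    union = sum(e - s for s, e in a) + sum(e - s for s, e in b) - inter
    return inter / union if union > 0 else 1.0
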