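"""10-second window table and lagged feature matrix.

The session timeline is divided into fixed non-overlapping windows
(default 10 s, trailing partial window dropped).  Pause time is
apportioned *exactly* to windows by overlap — a pause spanning several
windows contributes to each in proportion to the overlap — so summed
window pause time conserves the pause-track total.  Each window is
flagged as rupture when a rupture episode covers more than half of it,
and carries that episode's dominant type and minimal-response marker.

The classifier's feature matrix is built from the four switching-pattern
percentages, z-scored per dyad over *all* of the dyad's windows, then
lagged and led by 1-5 windows (44 features: 4 patterns x 11 offsets).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._types import BOUNDARY, PATTERNS

PATTERN_COLS = [f"pct_{p}" for p in PATTERNS]


def _cumulative_overlap(starts, ends, boundaries):
    """F(t) = total time covered by the intervals within [0, t), evaluated
    at each boundary; intervals must be sorted and disjoint."""
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    durs = ends - starts
    cum = np.concatenate([[0.0], np.cumsum(durs)])
    idx = np.searchsorted(ends, boundaries, side="left")
    full = cum[idx]
    partial = np.where(
        idx < starts.size,
        np.clip(boundaries - starts[np.minimum(idx, starts.size - 1)], 0.0,
                durs[np.minimum(idx, starts.size - 1)] if starts.size else 0.0),
        0.0,
    )
    return full + partial


def window_session(session_length, pauses, ruptures, window: float = 10.0,
                   rupture_overlap: float = 0.5) -> pd.DataFrame:
    """Build the per-window table for one session.

    ``pauses`` must carry switching-pattern labels; ``ruptures`` is a list
    of rupture episodes.  A window counts as rupture when the overlap
    covers at least ``rupture_overlap`` of it (exactly half counts as
    rupture).
    """
    n_win = int(np.floor(session_length / window + 1e-9))
    bounds = np.arange(n_win + 1) * window
    out = pd.DataFrame({"window_index": np.arange(n_win)})
    out["start"] = bounds[:-1]

    total = np.zeros(n_win)
    for pat in PATTERNS + (BOUNDARY,):
        sub = sorted((p for p in pauses if p.pattern == pat), key=lambda p: p.start)
        if any(p.pattern is None for p in pauses):
            raise ValueError("pauses must be pattern-labelled before windowing")
        if sub:
            F = _cumulative_overlap([p.start for p in sub], [p.end for p in sub], bounds)
            sec = np.diff(F)
        else:
            sec = np.zeros(n_win)
        out[f"pct_{pat}"] = 100.0 * sec / window
        total += sec
    out["pause_pct"] = 100.0 * total / window

    # rupture flags: episode with the largest overlap wins the window
    best = np.zeros(n_win)
    best_idx = np.full(n_win, -1)
    ruptures = sorted(ruptures, key=lambda r: r.start)
    for i, a in enumerate(ruptures):
        for j, b in enumerate(ruptures[i + 1:], start=i + 1):
            if a.end > b.start and b.end > a.start and a.dominant_type != b.dominant_type:
                raise ValueError(
                    "overlapping ruptures of different types are an input defect"
                )
    for i, r in enumerate(ruptures):
        ov = np.clip(np.minimum(r.end, bounds[1:]) - np.maximum(r.start, bounds[:-1]),
                     0.0, window)
        take = ov > best
        best[take] = ov[take]
        best_idx[take] = i
    flagged = best >= rupture_overlap * window - 1e-9
    out["in_rupture"] = flagged
    out["dominant_type"] = [
        ruptures[i].dominant_type if (f and i >= 0) else None
        for f, i in zip(flagged, best_idx)
    ]
    out["minimal_response"] = [
        bool(ruptures[i].minimal_response) if (f and i >= 0) else False
        for f, i in zip(flagged, best_idx)
    ]
    out["rupture_id"] = [
        f"r{i}" if (f and i >= 0) else None for f, i in zip(flagged, best_idx)
    ]
    return out


def zscore_by_dyad(rows: pd.DataFrame, cols=None) -> pd.DataFrame:
    """Standardise the pattern columns per dyad (mean 0, SD 1 over all of
    that dyad's windows, rupture and non-rupture alike).  Zero-variance
    columns are set to 0 with a warning.  Scaling happens *before* any
    subsetting to rupture windows."""
    cols = list(cols) if cols is not None else PATTERN_COLS
    out = rows.copy()
    for dyad, idx in out.groupby("dyad_id").groups.items():
        block = out.loc[idx, cols]
        mu = block.mean()
        sd = block.std(ddof=1)
        dead = sd <= 0
        if dead.any():
            warnings.warn(
                f"dyad {dyad}: zero variance in {list(sd.index[dead])}; features set to 0"
            )
            sd = sd.mask(dead, 1.0)
        z = (block - mu) / sd
        z.loc[:, list(sd.index[dead])] = 0.0
        out.loc[idx, cols] = z
    return out


def add_lags(rows: pd.DataFrame, max_lag: int = 5, cols=None):
    """44-column lag/lead feature matrix plus QC report.

    Feature ``<pat>_lag<k>`` at window t holds the (z-scored) pattern
    percentage at window t+k of the same session; offsets reaching
    outside the session are imputed with 0 (the per-dyad z-mean) and
    counted in the QC report.
    """
    cols = list(cols) if cols is not None else PATTERN_COLS
    rows = rows.sort_values(["dyad_id", "session_id", "window_index"])
    pieces, imputed = [], 0
    for _, sess in rows.groupby(["dyad_id", "session_id"], sort=False):
        block = {}
        for c in cols:
            base = sess[c].to_numpy()
            for k in range(-max_lag, max_lag + 1):
                name = f"{c.removeprefix('pct_')}_lag{k}"
                shifted = np.full(base.size, 0.0)
                if k >= 0:
                    shifted[: base.size - k] = base[k:]
                else:
                    shifted[-k:] = base[:k]
                imputed += min(abs(k), base.size)
                block[name] = shifted
        feat = pd.DataFrame(block, index=sess.index)
        keep = sess[[c for c in ("dyad_id", "session_id", "window_index", "in_rupture",
                                 "dominant_type", "minimal_response", "rupture_id",
                                 "pause_pct") if c in sess.columns]]
        pieces.append(pd.concat([keep, feat], axis=1))
    out = pd.concat(pieces, axis=0)
    qc = {"imputed_cells": int(imputed), "n_rows": int(len(out)),
          "n_features": len(cols) * (2 * max_lag + 1)}
    return out, qc


def feature_columns(max_lag: int = 5, cols=None):
    cols = list(cols) if cols is not None else PATTERN_COLS
    return [
        f"{c.removeprefix('pct_')}_lag{k}"
        for c in cols
        for k in range(-max_lag, max_lag + 1)
    ]
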