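"""Supervised speaker diarisation over short-window acoustic features.

Each non-overlapping 0.2-s window of the session is described by 35
acoustic features (13 MFCC means, 13 MFCC standard deviations over the
window's 20-ms sub-frames, mean fundamental frequency, frame energy,
zero-crossing rate, spectral centroid, rolloff, flux, flatness,
bandwidth and harmonic ratio) and classified as patient or therapist
speech by a random forest trained on a small labelled learning set
(nominally at least five minutes of speech per speaker).  Detected
speech utterances — maximal speech runs between pauses — are then
attributed to a speaker by majority vote over their windows.

The exact feature list of the original feature library is not
recoverable; the 35-feature default here is fixed and documented, and
the set is configurable.  Fundamental frequency in unvoiced windows is
encoded as 0 (no indicator column, keeping 35 columns).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from sklearn.ensemble import RandomForestClassifier

from ._types import PATIENT, SPEAKERS, THERAPIST, SpeakerTurn, Waveform

WINDOW = 0.2
N_MFCC = 13
N_MEL = 26
FRAME = 0.020
HOP = 0.010

FEATURE_COLUMNS = (
    [f"mfcc{i}_mean" for i in range(N_MFCC)]
    + [f"mfcc{i}_sd" for i in range(N_MFCC)]
    + ["f0_mean", "energy", "zcr", "centroid", "rolloff",
       "flux", "flatness", "bandwidth", "harmonic_ratio"]
)


@dataclass
class LearningSet:
    """Labelled (start, end, speaker) segments used to train the diariser."""

    segments: list  # of (start, end, speaker)
    source_sessions: list = field(default_factory=list)

    def speech_seconds(self) -> dict:
        out = {s: 0.0 for s in SPEAKERS}
        for s, e, spk in self.segments:
            if spk not in SPEAKERS:
                raise ValueError(f"unknown speaker label {spk!r}")
            out[spk] += e - s
        return out

    def validate(self, minimum: float = 300.0, warn_only: bool = False) -> None:
        secs = self.speech_seconds()
        short = [s for s, v in secs.items() if v < minimum]
        if short:
            msg = (f"learning set below the {minimum / 60:.0f}-min minimum for "
                   f"{short}: {secs}")
            if warn_only:
                warnings.warn(msg)
            else:
                raise ValueError(msg)


def read_learning_set(path) -> LearningSet:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            s, e, lab = line.rstrip("\n").split("\t")
            segs.append((float(s), float(e), lab))
    return LearningSet(segs, source_sessions=[str(path)])


def write_learning_set(ls: LearningSet, path) -> None:
    with open(path, "w") as fh:
        for s, e, spk in ls.segments:
            fh.write(f"{s:.6f}\t{e:.6f}\t{spk}\n")


# ---------------------------------------------------------------------------
# feature extraction

def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def _mel_filterbank(sr: int, n_fft: int, n_mel: int) -> np.ndarray:
    freqs = np.linspace(0.0, sr / 2.0, n_fft // 2 + 1)
    pts = _mel_inv(np.linspace(_mel(0.0), _mel(sr / 2.0), n_mel + 2))
    fb = np.zeros((n_mel, freqs.size))
    for i in range(n_mel):
        lo, mid, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (freqs - lo) / max(mid - lo, 1e-9)
        down = (hi - freqs) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def extract_features(w: Waveform, window: float = WINDOW) -> pd.DataFrame:
    """35 acoustic features per non-overlapping 0.2-s window.

    Deterministic; returns floor(duration / window) rows with a
    ``t_start`` column plus the 35 ``FEATURE_COLUMNS``.
    """
    sr = w.sample_rate
    if sr < 8000:
        raise ValueError("sample_rate too low for the MFCC band (need >= 8000)")
    win_n = int(round(window * sr))
    if w.samples.size < win_n:
        raise ValueError("waveform shorter than one feature window")
    n_win = w.samples.size // win_n
    frame_n, hop_n = int(FRAME * sr), int(HOP * sr)
    n_fft = 1 << (frame_n - 1).bit_length()
    fb = _mel_filterbank(sr, n_fft, N_MEL)
    hann = np.hanning(frame_n)
    frames_per_win = (win_n - frame_n) // hop_n + 1
    freqs = np.linspace(0.0, sr / 2.0, n_fft // 2 + 1)
    lag_lo, lag_hi = int(sr / 400.0), int(sr / 50.0)

    rows = np.empty((n_win, len(FEATURE_COLUMNS)), dtype=np.float64)
    chunk = max(1, int(2e6 // win_n))
    for c0 in range(0, n_win, chunk):
        c1 = min(c0 + chunk, n_win)
        seg = w.samples[c0 * win_n: c1 * win_n].reshape(c1 - c0, win_n)
        # sub-frame power spectra
        idx = (np.arange(frames_per_win) * hop_n)[:, None] + np.arange(frame_n)
        frames = seg[:, idx] * hann  # (win, frame, n)
        spec = np.abs(rfft(frames, n=n_fft, axis=2)) ** 2  # (win, frame, bin)
        mel_e = spec @ fb.T  # (win, frame, n_mel)
        silent = mel_e.sum(axis=2) <= 1e-12  # dead sub-frames
        logmel = np.log(mel_e + 1e-10)
        mfcc = dct(logmel, type=2, norm="ortho", axis=2)[:, :, :N_MFCC]
        mfcc[silent] = 0.0
        block = rows[c0:c1]
        block[:, :N_MFCC] = mfcc.mean(axis=1)
        block[:, N_MFCC:2 * N_MFCC] = mfcc.std(axis=1)

        # window-level spectral shape from the mean power spectrum
        mean_spec = spec.mean(axis=1)  # (win, bin)
        tot = mean_spec.sum(axis=1)
        ok = tot > 1e-12
        centroid = np.zeros(c1 - c0)
        centroid[ok] = (mean_spec[ok] * freqs).sum(axis=1) / tot[ok]
        bw = np.zeros(c1 - c0)
        bw[ok] = np.sqrt(
            (mean_spec[ok] * (freqs - centroid[ok, None]) ** 2).sum(axis=1) / tot[ok]
        )
        cum = np.cumsum(mean_spec, axis=1)
        roll = np.zeros(c1 - c0)
        if ok.any():
            ridx = np.argmax(cum[ok] >= 0.85 * tot[ok, None], axis=1)
            roll[ok] = freqs[ridx]
        flat = np.zeros(c1 - c0)
        flat[ok] = np.exp(np.log(mean_spec[ok] + 1e-12).mean(axis=1)) / (
            mean_spec[ok].mean(axis=1) + 1e-12
        )
        flux = np.sqrt((np.diff(np.sqrt(spec), axis=1) ** 2).sum(axis=2)).mean(axis=1)

        # fundamental frequency and harmonic ratio via autocorrelation
        x = seg - seg.mean(axis=1, keepdims=True)
        n_ac = 1 << (2 * win_n - 1).bit_length()
        X = rfft(x, n=n_ac, axis=1)
        ac = np.fft.irfft(np.abs(X) ** 2, n=n_ac, axis=1)[:, :win_n]
        r0 = ac[:, 0]
        voiced_band = ac[:, lag_lo:lag_hi]
        peak_lag = np.argmax(voiced_band, axis=1) + lag_lo
        peak_val = np.take_along_axis(ac, peak_lag[:, None], axis=1)[:, 0]
        hr = np.where(r0 > 1e-12, peak_val / np.maximum(r0, 1e-12), 0.0)
        f0 = np.where(hr > 0.3, sr / peak_lag, 0.0)

        block[:, 2 * N_MFCC + 0] = f0
        block[:, 2 * N_MFCC + 1] = (seg ** 2).mean(axis=1)
        sgn = np.signbit(seg)
        block[:, 2 * N_MFCC + 2] = (sgn[:, 1:] != sgn[:, :-1]).mean(axis=1)
        block[:, 2 * N_MFCC + 3] = centroid
        block[:, 2 * N_MFCC + 4] = roll
        block[:, 2 * N_MFCC + 5] = flux
        block[:, 2 * N_MFCC + 6] = flat
        block[:, 2 * N_MFCC + 7] = bw
        block[:, 2 * N_MFCC + 8] = hr

    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.insert(0, "t_start", np.arange(n_win) * window)
    return df


# ---------------------------------------------------------------------------
# classifier

@dataclass
class DiariserModel:
    clf: RandomForestClassifier
    feature_names: list
    metadata: dict

    def save_metadata(self, path) -> None:
        json.dump(self.metadata, open(path, "w"), indent=2)


def train_diariser(features: pd.DataFrame, learning: LearningSet, seed: int,
                   n_trees: int = 500, window: float = WINDOW,
                   enforce_minimum: bool = True) -> DiariserModel:
    """Fit the speaker classifier on windows lying fully inside labelled
    learning-set segments."""
    learning.validate(warn_only=not enforce_minimum)
    t0 = features["t_start"].to_numpy()
    t1 = t0 + window
    y = np.full(len(features), "", dtype=object)
    for s, e, spk in learning.segments:
        inside = (t0 >= s - 1e-9) & (t1 <= e + 1e-9)
        y[inside] = spk
    mask = y != ""
    classes = set(y[mask])
    if len(classes) < 2:
        raise ValueError(f"learning set covers a single class: {classes}")
    X = features.loc[mask, FEATURE_COLUMNS].to_numpy()
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    clf.fit(X, y[mask].astype(str))
    counts = pd.Series(y[mask]).value_counts().to_dict()
    return DiariserModel(
        clf=clf,
        feature_names=list(FEATURE_COLUMNS),
        metadata={"seed": seed, "n_trees": n_trees, "class_counts": counts,
                  "n_windows": int(mask.sum())},
    )


def classify_windows(model: DiariserModel, features: pd.DataFrame) -> np.ndarray:
    """One speaker label per 0.2-s window."""
    if list(features.columns[1:1 + len(model.feature_names)]) != model.feature_names:
        missing = [c for c in model.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature spec mismatch: missing {missing}")
    return model.clf.predict(features[model.feature_names].to_numpy())


def segment_turns(labels: np.ndarray, pauses, window: float = WINDOW,
                  duration: float = None) -> list:
    """Attribute each detected speech utterance to a speaker.

    Utterances are the maximal speech intervals between detected pauses;
    each becomes one turn labelled by majority vote over the 0.2-s
    windows whose centre falls inside it.  Ties go to the previous
    turn's speaker, and failing that to the therapist (who opens the
    session).
    """
    labels = np.asarray(labels)
    if duration is None:
        duration = labels.size * window
    centers = (np.arange(labels.size) + 0.5) * window
    # maximal speech runs between pauses
    edges = [0.0]
    for p in sorted(pauses, key=lambda p: p.start):
        edges += [p.start, p.end]
    edges.append(duration)
    turns = []
    prev_speaker = None
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s <= 1e-9:
            continue
        inside = (centers >= s) & (centers < e)
        n_p = int((labels[inside] == PATIENT).sum())
        n_t = int((labels[inside] == THERAPIST).sum())
        if n_p > n_t:
            spk = PATIENT
        elif n_t > n_p:
            spk = THERAPIST
        else:
            spk = prev_speaker if prev_speaker is not None else THERAPIST
        turns.append(SpeakerTurn(s, e, spk))
        prev_speaker = spk
    return turns


def read_turn_track(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            s, e, spk = line.rstrip("\n").split("\t")
            out.append(SpeakerTurn(float(s), float(e), spk))
    return out


def write_turn_track(turns, path) -> None:
    with open(path, "w") as fh:
        for t in turns:
            fh.write(f"{t.start:.6f}\t{t.end:.6f}\t{t.speaker}\n")
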