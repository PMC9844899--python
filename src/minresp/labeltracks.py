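"""File interchange: WAV audio and Audacity-dialect label tracks.

Label tracks are plain TSV lines ``start<TAB>end<TAB>label``.  Three
tracks describe a session: speakers (``patient``/``therapist``), pauses
(pattern or empty), and ruptures
(``withdrawal|confrontation[,minimal_response]``).  Audio is mono PCM-16
WAV.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from ._types import (
    GroundTruth,
    PauseEpisode,
    RuptureEpisode,
    SpeakerTurn,
    Waveform,
)


def write_wav(w: Waveform, path) -> None:
    pcm = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate, (pcm * 32767.0).astype(np.int16))


def read_wav(path) -> Waveform:
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return Waveform(samples, int(sr))


def _write_track(rows, path) -> None:
    with open(path, "w") as fh:
        for start, end, label in rows:
            fh.write(f"{start:.6f}\t{end:.6f}\t{label}\n")


def _read_track(path):
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                parts.append("")
            rows.append((float(parts[0]), float(parts[1]), parts[2]))
    return rows


def rupture_label(r: RuptureEpisode) -> str:
    return r.dominant_type + (",minimal_response" if r.minimal_response else "")


def parse_rupture_label(label: str):
    parts = [p.strip() for p in label.split(",") if p.strip()]
    rtype = parts[0]
    markers = set(parts[1:])
    return rtype, "minimal_response" in markers, markers - {"minimal_response"}


def write_session_tracks(truth: GroundTruth, outdir) -> dict:
    """Write the three ground-truth label tracks of one session; returns
    the file map for the corpus manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = truth.session_id
    files = {
        "speakers": outdir / f"{base}.speakers.tsv",
        "pauses": outdir / f"{base}.pauses.tsv",
        "ruptures": outdir / f"{base}.ruptures.tsv",
    }
    _write_track([(t.start, t.end, t.speaker) for t in truth.turns], files["speakers"])
    _write_track([(p.start, p.end, p.pattern or "") for p in truth.pauses], files["pauses"])
    _write_track(
        [(r.start, r.end, rupture_label(r)) for r in truth.ruptures], files["ruptures"]
    )
    return {k: str(v) for k, v in files.items()}


def read_session_tracks(outdir, session_id: str, dyad_id: str,
                        session_length: float) -> GroundTruth:
    outdir = Path(outdir)
    turns = [
        SpeakerTurn(s, e, lab)
        for s, e, lab in _read_track(outdir / f"{session_id}.speakers.tsv")
    ]
    pauses = [
        PauseEpisode(s, e, lab or None)
        for s, e, lab in _read_track(outdir / f"{session_id}.pauses.tsv")
    ]
    ruptures = []
    for s, e, lab in _read_track(outdir / f"{session_id}.ruptures.tsv"):
        rtype, mr, other = parse_rupture_label(lab)
        ruptures.append(RuptureEpisode(s, e, rtype, mr, frozenset(other)))
    return GroundTruth(
        dyad_id=dyad_id,
        session_id=session_id,
        session_length=session_length,
        turns=turns,
        pauses=pauses,
        ruptures=ruptures,
    )
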