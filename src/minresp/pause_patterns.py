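"""Speaker-switching pattern labelling for pauses.

Every pause is classified by the speakers of its neighbouring
utterances: P_P (patient resumes), P_T (patient hands over to the
therapist), T_P (therapist hands over to the patient) and T_T (the
therapist speaks again after the pause).  Pauses at a session edge with
no utterance on one side are labelled BOUNDARY and excluded from the
four pattern features.
"""
from __future__ import annotations

import bisect

from ._types import BOUNDARY, PATTERNS, PauseEpisode


def _check_disjoint(intervals, what: str) -> None:
    prev_end = None
    for iv in intervals:
        if prev_end is not None and iv.start < prev_end - 1e-9:
            raise ValueError(f"overlapping {what} at t={iv.start:.3f}")
        prev_end = iv.end


def label_patterns(pauses, turns) -> list:
    """Assign each pause its switching pattern from the nearest turns.

    ``pauses`` and ``turns`` must live on a common timeline and be
    individually non-overlapping; both are sorted internally.
    """
    pauses = sorted(pauses, key=lambda p: p.start)
    turns = sorted(turns, key=lambda t: t.start)
    _check_disjoint(pauses, "pauses")
    _check_disjoint(turns, "turns")
    starts = [t.start for t in turns]
    ends = [t.end for t in turns]
    out = []
    for p in pauses:
        i_prev = bisect.bisect_right(ends, p.start + 1e-9) - 1
        i_next = bisect.bisect_left(starts, p.end - 1e-9)
        prev = turns[i_prev] if 0 <= i_prev < len(turns) else None
        nxt = turns[i_next] if i_next < len(turns) else None
        if prev is None or nxt is None:
            out.append(p.with_pattern(BOUNDARY))
        else:
            code = ("P" if prev.speaker == "patient" else "T") + "_" + (
                "P" if nxt.speaker == "patient" else "T"
            )
            out.append(p.with_pattern(code))
    return out


def pattern_summary(pauses, total_time: float) -> dict:
    """Percent of session time spent in pauses of each pattern.

    Returns the four pattern percentages plus ``BOUNDARY`` and ``total``;
    the five categories sum exactly to the total pause percentage.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    acc = {k: 0.0 for k in PATTERNS + (BOUNDARY,)}
    for p in pauses:
        if p.pattern is None:
            raise ValueError("pauses must be labelled before summarising")
        acc[p.pattern] += p.duration
    out = {k: 100.0 * v / total_time for k, v in acc.items()}
    out["total"] = sum(out.values())
    return out


def write_pattern_track(pauses, path) -> None:
    """Labelled pause track in Audacity label-track TSV dialect."""
    with open(path, "w") as fh:
        for p in pauses:
            fh.write(f"{p.start:.6f}\t{p.end:.6f}\t{p.pattern}\n")


def read_pattern_track(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            s, e, lab = line.rstrip("\n").split("\t")
            out.append(PauseEpisode(float(s), float(e), lab))
    return out
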