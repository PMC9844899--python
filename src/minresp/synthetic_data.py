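"""Synthetic dyadic-session generator.

Emulates two-speaker psychotherapy sessions recorded on a single boundary
microphone: alternating patient/therapist turns separated by silent gaps,
with rupture episodes planted so that the window-level pause statistics
match configured targets.  The generator produces exact ground-truth
tracks (turns, pauses with their speaker-switching pattern, ruptures) and
can optionally render a stylised waveform, so every downstream stage —
silence detection, diarisation, windowing, classification, mixed models —
is testable without clinical recordings.

Model
-----
Speech is an alternating renewal process: turns and inter-turn gaps with
lognormal durations.  The speaker of consecutive turns follows a two-state
chain with per-speaker continuation probabilities (a speaker may keep the
floor across a pause, which is what creates P_P and T_T pauses).  For a
regime with target pause fraction ``p`` the mean gap is solved in closed
form from the renewal-reward identity ``p = E[gap] / (E[turn] + E[gap])``.

Rupture episodes switch the gap regime to the configured cell target
(rupture type x minimal-response marker).  Withdrawal ruptures are
preceded by a linear ramp of the pause target starting ``ramp_lead``
seconds before onset.  In minimal-response ruptures the therapist's
continuation probability is raised so that a configurable share of the
*added* pause time falls into the T_T pattern (therapist speaks - pause -
therapist speaks again: the patient is skipping speaking turns).
"""
from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._types import (
    BOUNDARY,
    CONFRONTATION,
    PATIENT,
    RUPTURE_TYPES,
    THERAPIST,
    WITHDRAWAL,
    GroundTruth,
    PauseEpisode,
    RuptureEpisode,
    SpeakerTurn,
    Waveform,
)


def _default_effect_table() -> dict:
    # Additive cell targets: intercept 32.39, +3.22 withdrawal, +11.67
    # minimal response (model-based effects; the marginal per-cell means
    # observed on real data differ slightly through dyad composition).
    return {
        (CONFRONTATION, False): 32.39,
        (WITHDRAWAL, False): 35.61,
        (CONFRONTATION, True): 44.06,
        (WITHDRAWAL, True): 47.28,
    }


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus.

    Percentages are in 0-100, durations in seconds, rates per session.
    The defaults encode the published summary statistics of the clinical
    corpus the generator emulates: a 30.6% baseline pause share, the
    per-cell rupture pause targets, withdrawal/confrontation mixture
    295/516, minimal-response marker probabilities 159/295 and 27/221,
    mean rupture lengths 116.1 s (withdrawal) and 133.4 s
    (confrontation), and a 25 s anticipatory pause ramp before
    withdrawal onsets.
    """

    n_dyads: int = 6
    sessions_per_dyad: int = 10
    session_length: float = 600.0
    sample_rate: int = 16000
    seed: int = 0
    base_pause_target: float = 30.6
    effect_table: dict = field(default_factory=_default_effect_table)
    ramp_lead: float = 25.0
    mr_prob_given_withdrawal: float = 159 / 295
    mr_prob_given_confrontation: float = 27 / 221
    withdrawal_frac: float = 295 / 516
    rupture_duration: dict = field(
        default_factory=lambda: {WITHDRAWAL: (116.1, 189.9), CONFRONTATION: (133.4, 215.8)}
    )
    #: minimal-response ruptures are longer on average; ratio of mean
    #: windows per MR rupture to mean windows per non-MR rupture.
    mr_duration_factor: float = 1.913
    ruptures_per_session: float = 2.0
    turn_duration_means: dict = field(
        default_factory=lambda: {PATIENT: 4.0, THERAPIST: 3.0}
    )
    turn_log_sd: float = 0.6
    gap_log_sd: float = 0.6
    #: probability that a speaker keeps the floor across a gap (creates
    #: the within-speaker P_P / T_T pauses of ordinary conversation)
    continuation_prob: float = 0.25
    #: share of *added* pause time in minimal-response ruptures realised
    #: as therapist-turn / pause / therapist-turn triples
    tt_concentration: float = 0.7
    #: between-dyad SD of the pause level (percent points); together with
    #: the window-level residual this reproduces a dyad ICC of ~0.08
    dyad_sd: float = 6.68
    session_jitter_sd: float = 2.0
    min_turn: float = 0.3
    min_gap: float = 0.15
    # audio rendering
    speech_level: float = 0.3
    noise_floor: float = 0.004
    f0: dict = field(default_factory=lambda: {THERAPIST: 110.0, PATIENT: 220.0})

    def validate(self) -> None:
        probs = [
            self.mr_prob_given_withdrawal,
            self.mr_prob_given_confrontation,
            self.withdrawal_frac,
            self.continuation_prob,
            self.tt_concentration,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.session_length <= 0 or self.ramp_lead < 0:
            raise ValueError("durations must be positive")
        if any(m <= 0 for m in self.turn_duration_means.values()):
            raise ValueError("turn duration means must be positive")
        for v in self.effect_table.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError("effect_table values must be percentages in [0, 100]")
        if not 0.0 <= self.base_pause_target <= 100.0:
            raise ValueError("base_pause_target must be a percentage")
        if self.n_dyads < 1 or self.sessions_per_dyad < 1:
            raise ValueError("corpus must contain at least one dyad and session")


# ---------------------------------------------------------------------------
# seeding

def _session_rng(config: GeneratorConfig, dyad: int, session: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(dyad, session))
    )


def dyad_effects(config: GeneratorConfig) -> np.ndarray:
    """Per-dyad pause-level shifts (percent points), centred over the corpus
    so that planted corpus-level means equal the configured targets."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1 << 20,)))
    eff = rng.normal(0.0, config.dyad_sd, size=config.n_dyads)
    if config.n_dyads > 1:
        eff -= eff.mean()
    else:
        eff[:] = 0.0
    return eff


# ---------------------------------------------------------------------------
# renewal-chain machinery

def _stationary_therapist_share(r_p: float, r_t: float) -> float:
    return (1.0 - r_p) / ((1.0 - r_p) + (1.0 - r_t))


def _solve_therapist_continuation(r_p: float, tt_share: float) -> float:
    """Continuation probability for the therapist such that the stationary
    fraction of gaps with therapist speech on both sides equals
    ``tt_share`` (gap means are pattern-independent, so the count share
    equals the time share)."""
    s = min(max(tt_share, 0.0), 0.95)
    return min(s * (2.0 - r_p) / (1.0 - r_p + s), 0.97)


@dataclass
class _Regime:
    start: float
    end: float
    pause_frac: float
    r_p: float
    r_t: float


def _simulate_timeline(rng, regimes, cfg: GeneratorConfig):
    """One chronological pass over the session: alternating turn/gap
    events whose parameters come from the regime at the event's *start*
    time, so events may span regime boundaries and no in-flight time is
    ever discarded.  Only the final event is truncated, at the session
    end.  Speaker encoding: 0 = patient, 1 = therapist.

    Returns (durations, kinds, speakers): ``kinds`` is 0 for turns and 1
    for gaps; for a gap, ``speakers`` holds the *following* turn's
    speaker (used for pattern labelling).
    """
    m = (cfg.turn_duration_means[PATIENT], cfg.turn_duration_means[THERAPIST])
    mu_turn = (math.log(m[0]) - cfg.turn_log_sd ** 2 / 2.0,
               math.log(m[1]) - cfg.turn_log_sd ** 2 / 2.0)
    # per-regime gap parameters solved in closed form from the
    # renewal-reward identity p = E[gap] / (E[turn] + E[gap])
    mu_gap = []
    for reg in regimes:
        pi_t = _stationary_therapist_share(reg.r_p, reg.r_t)
        e_turn = pi_t * m[1] + (1 - pi_t) * m[0]
        p = min(max(reg.pause_frac, 0.01), 0.95)
        mu_gap.append(math.log(p / (1.0 - p) * e_turn) - cfg.gap_log_sd ** 2 / 2.0)
    reg_starts = [reg.start for reg in regimes]
    L = regimes[-1].end

    durs, kinds, spks = [], [], []
    t, speaker = 0.0, 1  # the therapist opens the session
    block, bi = None, 0
    while t < L - 1e-9:
        if block is None or bi >= block[0].size:
            n = max(int(1.3 * (L - t) / 4.0) + 16, 16)
            block = (rng.normal(0.0, cfg.turn_log_sd, n),
                     rng.normal(0.0, cfg.gap_log_sd, n),
                     rng.random(n))
            bi = 0
        td = max(math.exp(mu_turn[speaker] + block[0][bi]), cfg.min_turn)
        durs.append(min(td, L - t))
        kinds.append(0)
        spks.append(speaker)
        t += td
        if t >= L - 1e-9:
            break
        ri = bisect.bisect_right(reg_starts, t) - 1
        reg = regimes[ri]
        gd = max(math.exp(mu_gap[ri] + block[1][bi]), cfg.min_gap)
        # regime-dependent gap hazard: the part of a gap extending past a
        # regime boundary is rescaled by the ratio of gap means, so pause
        # behaviour switches at the boundary rather than one gap later
        while ri + 1 < len(regimes) and t + gd > regimes[ri + 1].start:
            b = regimes[ri + 1].start
            gd = (b - t) + (t + gd - b) * math.exp(mu_gap[ri + 1] - mu_gap[ri])
            ri += 1
        r_cont = reg.r_t if speaker == 1 else reg.r_p
        nxt = speaker if block[2][bi] < r_cont else 1 - speaker
        durs.append(min(gd, L - t))
        kinds.append(1)
        spks.append(nxt)
        speaker = nxt
        t += gd
        bi += 1
    return durs, kinds, spks


# ---------------------------------------------------------------------------
# rupture planting

def _draw_rupture_durations(rng, cfg: GeneratorConfig, kinds):
    """Durations for the requested (type, mr) list; type-level mean and SD
    are preserved while minimal-response ruptures run longer by
    ``mr_duration_factor`` on average."""
    out = []
    for rtype, mr in kinds:
        mean, sd = cfg.rupture_duration[rtype]
        q = (cfg.mr_prob_given_withdrawal if rtype == WITHDRAWAL
             else cfg.mr_prob_given_confrontation)
        base_mean = mean / (1.0 - q + q * cfg.mr_duration_factor)
        target_mean = base_mean * (cfg.mr_duration_factor if mr else 1.0)
        cv2 = (sd / mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(target_mean) - sigma2 / 2.0
        cap = 0.35 * cfg.session_length
        d = math.exp(rng.normal(mu, math.sqrt(sigma2)))
        for _ in range(200):
            if 10.0 <= d <= cap:
                break
            d = math.exp(rng.normal(mu, math.sqrt(sigma2)))
        out.append(min(max(d, 10.0), cap))
    return out


def _place_ruptures(rng, cfg: GeneratorConfig, kinds, durations):
    """Uniform placement with non-overlap by rejection sampling."""
    L = cfg.session_length
    placed = []  # (start, end, rtype, mr)
    order = np.argsort(durations)[::-1]
    margin = 0.5
    for idx in order:
        dur = durations[idx]
        rtype, mr = kinds[idx]
        ok = False
        for attempt in range(400):
            if dur >= L - 1.0:
                break
            s = rng.uniform(0.0, L - dur)
            e = s + dur
            if all(e + margin <= ps or s >= pe + margin for ps, pe, *_ in placed):
                placed.append((s, e, rtype, mr))
                ok = True
                break
            if attempt % 100 == 99:
                dur = max(dur / 2.0, 10.0)  # truncate stubborn long draws
        if not ok and not placed:
            raise ValueError(
                f"session_length={L}s too short to host the requested "
                f"{len(kinds)} rupture(s) (shortest draw {min(durations):.1f}s)"
            )
    placed.sort()
    return placed


def _build_regimes(cfg: GeneratorConfig, placed, shift: float):
    """Partition [0, session_length] into pause-target regimes: baseline,
    withdrawal pre-onset ramps (5 s steps), and rupture cells."""
    def frac(pct):
        return min(max((pct + shift) / 100.0, 0.03), 0.90)

    r0 = cfg.continuation_prob
    p_base = frac(cfg.base_pause_target)
    regimes = []
    rupture_iv = [(s, e) for s, e, *_ in placed]

    for s, e, rtype, mr in placed:
        p_cell = frac(cfg.effect_table[(rtype, mr)])
        if mr:
            p_nomr = frac(cfg.effect_table[(rtype, False)])
            base_tt = r0 / 2.0  # stationary T_T gap share with equal continuation
            added = max(p_cell - p_nomr, 0.0)
            tt_time = base_tt * p_nomr + cfg.tt_concentration * added
            r_t = _solve_therapist_continuation(r0, tt_time / p_cell)
        else:
            r_t = r0
        regimes.append(_Regime(s, e, p_cell, r0, r_t))
        # anticipatory ramp before withdrawal onsets
        if rtype == WITHDRAWAL and cfg.ramp_lead > 0:
            ramp_start = max(s - cfg.ramp_lead, 0.0)
            step = 5.0
            t0 = ramp_start
            while t0 < s - 1e-9:
                t1 = min(t0 + step, s)
                if not any(t0 < ie and t1 > ib for ib, ie in rupture_iv):
                    mid = 0.5 * (t0 + t1)
                    w = (mid - (s - cfg.ramp_lead)) / cfg.ramp_lead
                    regimes.append(_Regime(t0, t1, p_base + w * (p_cell - p_base), r0, r0))
                t0 = t1

    regimes.sort(key=lambda r: r.start)
    # fill the gaps with baseline regime
    full, t = [], 0.0
    for r in regimes:
        if r.start > t + 1e-9:
            full.append(_Regime(t, r.start, p_base, r0, r0))
        full.append(r)
        t = max(t, r.end)
    if t < cfg.session_length - 1e-9:
        full.append(_Regime(t, cfg.session_length, p_base, r0, r0))
    return full


# ---------------------------------------------------------------------------
# public operations

def generate_session(config: GeneratorConfig, dyad: int = 0, session: int = 0) -> GroundTruth:
    """Generate one session's ground truth (no audio).

    ``dyad``/``session`` are integer indices; the same (config.seed, dyad,
    session) triple always yields the identical session.
    """
    config.validate()
    if not 0 <= dyad < config.n_dyads:
        raise ValueError(f"dyad index {dyad} outside 0..{config.n_dyads - 1}")
    rng = _session_rng(config, dyad, session)
    shift = float(dyad_effects(config)[dyad]) + float(rng.normal(0.0, config.session_jitter_sd))

    # rupture kinds and placement
    n = int(rng.poisson(config.ruptures_per_session))
    mean_dur = np.mean([config.rupture_duration[t][0] for t in RUPTURE_TYPES])
    n_cap = max(int(0.45 * config.session_length / max(mean_dur, 1.0)), 0)
    if n > 0 and config.session_length < 60.0:
        raise ValueError(
            f"session_length={config.session_length}s too short to host ruptures"
        )
    n = min(n, n_cap) if n > 0 else 0
    kinds = []
    for _ in range(n):
        rtype = WITHDRAWAL if rng.random() < config.withdrawal_frac else CONFRONTATION
        q = (config.mr_prob_given_withdrawal if rtype == WITHDRAWAL
             else config.mr_prob_given_confrontation)
        kinds.append((rtype, rng.random() < q))
    if kinds:
        durations = _draw_rupture_durations(rng, config, kinds)
        placed = _place_ruptures(rng, config, kinds, durations)
    else:
        placed = []

    regimes = _build_regimes(config, placed, shift)
    durs, kinds_ev, spks = _simulate_timeline(rng, regimes, config)

    # assemble into merged turns and pattern-labelled pauses
    turns, pauses = [], []
    t = 0.0
    spk_name = (PATIENT, THERAPIST)
    cur_start, cur_spk = None, None
    for d, k, s in zip(durs, kinds_ev, spks):
        if k == 0:  # turn
            if cur_spk == s:
                pass  # same speaker continues across a segment boundary: merge
            else:
                if cur_spk is not None:
                    turns.append(SpeakerTurn(cur_start, t, spk_name[cur_spk]))
                cur_start, cur_spk = t, s
        else:  # gap; s is the following turn's speaker
            prev = cur_spk
            if cur_spk is not None:
                turns.append(SpeakerTurn(cur_start, t, spk_name[cur_spk]))
                cur_start, cur_spk = None, None
            nxt = s
            if prev is None:
                pattern = BOUNDARY
            else:
                pattern = ("P" if prev == 0 else "T") + "_" + ("P" if nxt == 0 else "T")
            pauses.append(PauseEpisode(t, t + d, pattern))
        t += d
    if cur_spk is not None:
        turns.append(SpeakerTurn(cur_start, t, spk_name[cur_spk]))
    elif pauses and abs(pauses[-1].end - config.session_length) < 1e-6:
        # session ends inside a gap: no following utterance
        pauses[-1] = pauses[-1].with_pattern(BOUNDARY)

    ruptures = [
        RuptureEpisode(s, e, rtype, mr) for s, e, rtype, mr in placed
    ]
    return GroundTruth(
        dyad_id=f"d{dyad:02d}",
        session_id=f"d{dyad:02d}_s{session:03d}",
        session_length=config.session_length,
        turns=turns,
        pauses=pauses,
        ruptures=ruptures,
    )


def generate_corpus(config: GeneratorConfig):
    """All sessions of the configured corpus plus a manifest.

    Per-session seeds are derived deterministically from the master seed,
    so corpora are reproducible bit-for-bit and individual sessions can
    be regenerated in isolation.
    """
    config.validate()
    sessions, entries = [], []
    for dyad in range(config.n_dyads):
        for sess in range(config.sessions_per_dyad):
            truth = generate_session(config, dyad, sess)
            sessions.append(truth)
            entries.append(
                {
                    "dyad_id": truth.dyad_id,
                    "session_id": truth.session_id,
                    "dyad_index": dyad,
                    "session_index": sess,
                    "session_length": config.session_length,
                    "n_ruptures": len(truth.ruptures),
                }
            )
    manifest = {
        "seed": config.seed,
        "n_dyads": config.n_dyads,
        "sessions_per_dyad": config.sessions_per_dyad,
        "sessions": entries,
    }
    return sessions, manifest


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def render_audio(truth: GroundTruth, config: GeneratorConfig,
                 seed: Optional[int] = None) -> Waveform:
    """Render a stylised single-channel waveform for a session.

    Speech is a harmonic source (distinct fundamental per speaker, a few
    harmonics, syllabic amplitude modulation, plus band noise); silence
    is low-level microphone noise.  The rendering is deliberately
    non-phonetic: the silence detector keys on amplitude variability
    only, and the diariser on coarse spectral shape.
    """
    if config.sample_rate < 8000:
        raise ValueError("sample_rate below 8000 Hz is not supported")
    if seed is None:
        seed = abs(hash((config.seed, truth.session_id))) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sr = config.sample_rate
    n = int(round(truth.session_length * sr))
    out = rng.normal(0.0, config.noise_floor, n)
    harmonics = np.array([1.0, 0.6, 0.4, 0.25, 0.15])
    for turn in truth.turns:
        i0, i1 = int(round(turn.start * sr)), min(int(round(turn.end * sr)), n)
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / sr
        f0 = config.f0[turn.speaker] * (1.0 + 0.03 * rng.normal())
        sig = np.zeros(i1 - i0)
        for k, a in enumerate(harmonics, start=1):
            sig += a * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
        sig /= np.abs(sig).max() + 1e-12
        env = 0.65 + 0.35 * np.sin(2 * np.pi * 3.5 * t + rng.uniform(0, 2 * np.pi))
        sig = sig * env + 0.10 * rng.normal(size=i1 - i0)
        out[i0:i1] += config.speech_level * sig
    np.clip(out, -1.0, 1.0, out=out)
    return Waveform(out, sr)


def truth_to_window_table(truth: GroundTruth, window: float = 10.0):
    """Ground-truth bypass: the central 10-s window table computed from
    the exact tracks instead of detected ones (delegates to
    :func:`minresp.windowing.window_session`)."""
    from .windowing import window_session

    df = window_session(truth.session_length, truth.pauses, truth.ruptures, window=window)
    df.insert(0, "session_id", truth.session_id)
    df.insert(0, "dyad_id", truth.dyad_id)
    return df
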