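"""Generator: determinism, calibration, planted structure."""
import json

import numpy as np
import pandas as pd
import pytest

from minresp._types import WITHDRAWAL
from minresp.synthetic_data import (
    GeneratorConfig,
    dyad_effects,
    generate_corpus,
    generate_session,
    read_manifest,
    render_audio,
    truth_to_window_table,
    write_manifest,
)
from minresp.silence_detection import compute_range_series


def test_same_seed_is_bit_identical(small_config):
    a = generate_session(small_config, 0, 1)
    b = generate_session(small_config, 0, 1)
    assert a.turns == b.turns and a.pauses == b.pauses and a.ruptures == b.ruptures


def test_different_seeds_differ():
    c1 = GeneratorConfig(seed=1, n_dyads=1, sessions_per_dyad=1)
    c2 = GeneratorConfig(seed=2, n_dyads=1, sessions_per_dyad=1)
    s1, _ = generate_corpus(c1)
    s2, _ = generate_corpus(c2)
    assert s1[0].turns != s2[0].turns


def test_conservation_turns_and_pauses_tile_session(small_truth):
    total = sum(t.duration for t in small_truth.turns) + sum(
        p.duration for p in small_truth.pauses
    )
    assert total == pytest.approx(small_truth.session_length, abs=1e-6)
    small_truth.validate()


def test_baseline_pause_fraction_without_ruptures():
    """With no ruptures planted, the corpus-wide pause share should sit at
    the configured 30.6% baseline (within stochastic tolerance)."""
    cfg = GeneratorConfig(n_dyads=5, sessions_per_dyad=10, session_length=600.0,
                          ruptures_per_session=0.0, seed=5)
    truths, _ = generate_corpus(cfg)
    assert len(truths) == 50
    pause = sum(p.duration for t in truths for p in t.pauses)
    frac = 100.0 * pause / sum(t.session_length for t in truths)
    assert abs(frac - 30.6) < 3.0


def test_rupture_composition_matches_configured_probabilities():
    """Over >= 200 ruptures the withdrawal fraction and P(MR | withdrawal)
    should match the planted 295/516 and 159/295."""
    cfg = GeneratorConfig(n_dyads=10, sessions_per_dyad=12, session_length=1500.0, seed=9)
    truths, _ = generate_corpus(cfg)
    rups = [r for t in truths for r in t.ruptures]
    assert len(rups) >= 200
    wd = [r for r in rups if r.dominant_type == WITHDRAWAL]
    assert abs(len(wd) / len(rups) - 295 / 516) < 0.05
    mr_wd = sum(r.minimal_response for r in wd) / len(wd)
    assert abs(mr_wd - 159 / 295) < 0.06


def test_cell_calibration(bypass_windows):
    """Empirical mean window pause percent per (type x marker) cell within
    3 points of the planted effect table."""
    table = GeneratorConfig().effect_table
    ru = bypass_windows[bypass_windows.in_rupture]
    for (ty, mr), grp in ru.groupby(["dominant_type", "minimal_response"]):
        assert abs(grp.pause_pct.mean() - table[(ty, bool(mr))]) < 3.0, (ty, mr)


def test_withdrawal_ramp_raises_preonset_pauses(bypass_corpus):
    """Mean pause share in the 20 s before withdrawal onsets exceeds the
    non-rupture baseline (the planted anticipatory ramp)."""
    _, truths, _ = bypass_corpus
    pre, base_num, base_den = [], 0.0, 0.0
    for t in truths:
        rup_iv = [(r.start, r.end) for r in t.ruptures]
        for r in t.ruptures:
            if r.dominant_type != WITHDRAWAL or r.start < 25.0:
                continue
            w0, w1 = r.start - 20.0, r.start
            if any(w0 < e and w1 > s for s, e in rup_iv if (s, e) != (r.start, r.end)):
                continue
            sec = sum(min(p.end, w1) - max(p.start, w0)
                      for p in t.pauses if p.end > w0 and p.start < w1)
            pre.append(sec / 20.0)
        base_num += sum(p.duration for p in t.pauses)
        base_den += t.session_length
    assert len(pre) > 30
    assert np.mean(pre) > base_num / base_den + 0.02


def test_session_too_short_for_ruptures_rejected():
    cfg = GeneratorConfig(session_length=30.0, ruptures_per_session=5.0, seed=0)
    with pytest.raises(ValueError, match="too short"):
        for s in range(20):  # Poisson draw of 0 is legitimate; find a draw > 0
            generate_session(cfg, 0, s)


def test_corpus_shape_and_manifest_roundtrip(tmp_path):
    cfg = GeneratorConfig(n_dyads=2, sessions_per_dyad=3, session_length=120.0, seed=3)
    truths, manifest = generate_corpus(cfg)
    assert len(truths) == 6
    assert len({t.dyad_id for t in truths}) == 2
    write_manifest(manifest, tmp_path / "m.json")
    assert read_manifest(tmp_path / "m.json") == manifest


def test_dyad_effects_centred():
    cfg = GeneratorConfig(n_dyads=10, seed=4)
    eff = dyad_effects(cfg)
    assert abs(eff.mean()) < 1e-9
    assert eff.std() > 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(withdrawal_frac=1.5).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(effect_table={("withdrawal", True): 120.0}).validate()


# --- audio rendering ---------------------------------------------------------

def test_render_deterministic(small_config, small_truth):
    a = render_audio(small_truth, small_config)
    b = render_audio(small_truth, small_config)
    assert np.array_equal(a.samples, b.samples)


def test_render_rejects_low_sample_rate(small_truth, small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, sample_rate=4000)
    with pytest.raises(ValueError, match="8000"):
        render_audio(small_truth, cfg)


def test_rendered_range_dips_over_planted_pause(small_config):
    """A single 2-s planted silence shows up as a dip in the 0.01-s range
    series at exactly that interval (+- 0.05 s)."""
    from minresp._types import GroundTruth, PauseEpisode, SpeakerTurn

    truth = GroundTruth(
        dyad_id="d00", session_id="d00_s000", session_length=8.0,
        turns=[SpeakerTurn(0.0, 3.0, "therapist"), SpeakerTurn(5.0, 8.0, "patient")],
        pauses=[PauseEpisode(3.0, 5.0, "T_P")],
        ruptures=[],
    )
    wav = render_audio(truth, small_config, seed=11)
    ranges = compute_range_series(wav, 0.01)
    thresh = 8 * small_config.noise_floor
    silent = ranges < thresh
    t = np.arange(ranges.size) * 0.01
    inside = (t >= 3.05) & (t < 4.95)
    outside = (t < 2.95) | ((t >= 5.05) & (t < 7.95))
    assert silent[inside].all()
    assert not silent[outside].any()


def test_render_all_silence_is_noise_floor(small_config):
    from minresp._types import GroundTruth, PauseEpisode

    truth = GroundTruth(
        dyad_id="d00", session_id="d00_s001", session_length=2.0,
        turns=[], pauses=[PauseEpisode(0.0, 2.0, "BOUNDARY")], ruptures=[],
    )
    wav = render_audio(truth, small_config, seed=1)
    assert np.abs(wav.samples).max() <= 8 * small_config.noise_floor


# --- ground-truth bypass -----------------------------------------------------

def test_truth_to_window_table_matches_direct_windowing(small_truth):
    from minresp.windowing import window_session

    via = truth_to_window_table(small_truth)
    direct = window_session(
        small_truth.session_length, small_truth.pauses, small_truth.ruptures
    )
    pd.testing.assert_frame_equal(via.drop(columns=["dyad_id", "session_id"]), direct)


def test_empty_truth_gives_zero_pause_columns():
    from minresp._types import GroundTruth

    truth = GroundTruth("d00", "s", 60.0, [], [], [])
    df = truth_to_window_table(truth)
    assert (df.pause_pct == 0).all()
    assert len(df) == 6


def test_planted_half_pause_session_recovers_fifty_percent():
    cfg = GeneratorConfig(n_dyads=1, sessions_per_dyad=1, session_length=600.0,
                          base_pause_target=50.0, ruptures_per_session=0.0,
                          dyad_sd=0.0, session_jitter_sd=0.0, seed=12)
    df = truth_to_window_table(generate_session(cfg, 0, 0))
    assert abs(df.pause_pct.mean() - 50.0) < 3.0
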