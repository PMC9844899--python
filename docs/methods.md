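# Methods

This note documents the models and numerical choices behind `minresp`:
what the synthetic corpus generator emulates and how it is calibrated,
how each detection stage works, and what the planted-parameter recovery
tests do and do not demonstrate about real clinical recordings.

## The synthetic session generator

### Conversation model

A session is an alternating renewal process of speech turns and silent
gaps.  Turn and gap durations are lognormal (log-SD 0.6 by default), a
heavy-right-tail shape that matches conversational timing data; mean
turn lengths default to 4.0 s (patient) and 3.0 s (therapist).  The
speaker of consecutive turns follows a two-state chain: after a turn,
the same speaker keeps the floor across the next gap with probability
0.25 (the `continuation_prob`), otherwise the floor switches.  Floor
keeping is what produces within-speaker P_P and T_T pauses; switches
produce P_T and T_P pauses.  The therapist opens the session.

For a regime with target pause fraction p the mean gap length is solved
in closed form from the renewal-reward identity
`p = E[gap] / (E[turn] + E[gap])`, with `E[turn]` taken under the
chain's stationary speaker mix.  No numerical search is needed; the
calibration property test verifies that empirical per-cell window means
land within 3 percentage points of the configured targets.

### Planted rupture structure

Rupture episodes switch the gap regime.  Key parameters, all exposed on
`GeneratorConfig` (percentages in 0–100, durations in seconds):

| parameter | default | meaning |
|---|---|---|
| `base_pause_target` | 30.6 | non-rupture pause share (%) |
| `effect_table` | 32.39 / 35.61 / 44.06 / 47.28 | target pause % per (type × marker) cell |
| `withdrawal_frac` | 295/516 | share of ruptures that are withdrawal |
| `mr_prob_given_withdrawal` | 159/295 | marker probability in withdrawal ruptures |
| `mr_prob_given_confrontation` | 27/221 | marker probability in confrontation ruptures |
| `rupture_duration` | 116.1 ± 189.9 (withdrawal), 133.4 ± 215.8 (confrontation) | lognormal mean/SD per type |
| `mr_duration_factor` | 1.913 | mean-length ratio of marker vs. non-marker ruptures |
| `ruptures_per_session` | 2 | Poisson rate |
| `ramp_lead` | 25 | anticipatory ramp before withdrawal onsets |
| `tt_concentration` | 0.7 | share of *added* marker pause time realised as T_T |
| `dyad_sd` | 6.68 | between-dyad SD of the pause level (% points) |

The four `effect_table` cells are additive by construction — the
confrontation/no-marker reference plus +3.22 for withdrawal and +11.67
for the marker — so the random-intercept model of the analysis stage
has an exactly recoverable truth.  (Observed marginal cell means on
real data differ from model-based effects through dyad composition; a
generator without dyad-by-type confounding cannot plant both at once,
and the model-based effects are the quantities the recovery run
checks.)

Minimal-response ruptures run ~1.9× longer than unmarked ones
(`mr_duration_factor`, derived from the published window-per-rupture
counts); the per-type base mean is rescaled so the *type-level* mean
durations stay at their configured values.  Rupture counts are drawn
Poisson and capped so the expected rupture time fits the session (about
45 % of the session length); placement is uniform with non-overlap by
rejection sampling, and a session too short to host any requested
rupture is rejected with a diagnostic.

Three further planted features:

* **Anticipatory ramp.**  For withdrawal ruptures only, the pause
  target in the 25 s before onset rises linearly (in 5-s steps) from
  baseline to the episode's cell target, reproducing the pre-onset
  pause build-up visible in onset-aligned time courses.
* **T_T concentration.**  Inside marker episodes the therapist's
  continuation probability is raised so that a `tt_concentration` share
  of the *added* pause time falls between two therapist turns — the
  acoustic signature of a patient skipping speaking turns.  The
  required continuation probability is solved in closed form from the
  chain's stationary distribution.
* **Dyad and session heterogeneity.**  Each dyad shifts all its pause
  targets by a normal effect (SD 6.68 points, centred across the
  corpus so that corpus-level means equal the configured targets); each
  session adds a small jitter (SD 2).  Together with the window-level
  renewal noise this yields a dyad ICC of ≈ 0.08 in Model B, matching
  the published value.

Events are simulated in one chronological pass; each event's parameters
come from the regime at its start time.  When a gap crosses a regime
boundary, the remainder beyond the boundary is rescaled by the ratio of
the two regimes' mean gap lengths — the hazard changes at the boundary
— so no pause time is discarded or smeared at rupture onsets.  The same
seed (master seed, dyad index, session index) reproduces a session
bit-for-bit; per-session seeds are spawned from the master seed.

### Audio rendering

Rendered audio is deliberately stylised: speech is a harmonic source
(five harmonics on a per-speaker fundamental, 110 Hz therapist / 220 Hz
patient, with 3 % per-turn jitter), syllabic 3.5-Hz amplitude
modulation and 10 % additive noise at level 0.3; silence is Gaussian
microphone noise at level 0.004.  There are no phonetics, no
overlapping speech, no room acoustics and no recording-level drift.
This is sufficient — and intended only — for a silence detector keyed
on amplitude variability and a diariser keyed on coarse spectral
shape.  Accuracy figures obtained on this audio therefore validate the
pipeline's mechanics, not its performance on real consulting-room
recordings.

## Detection stages

* **Silence detection.**  Ranges (max − min) over 0.01-s windows;
  histogram with Scott's-rule width 3.49 · s · n^(−1/3); the automatic
  `valley` strategy cuts at the lower edge of the leftmost valley after
  the leftmost mode (the silence peak), found on raw counts with a
  3-bin moving-average fallback; a manual `index:k` override replaces
  the original listening-based bin choice and keeps its semantics
  (right edge of 1-based bin k).  The cut-off is applied to 0.1-s
  windows; runs of silent windows become episodes; episodes shorter
  than one 0.1-s window are dropped, and the ≥ 3 s variant implements
  the conventional "silence" definition (inclusive at exactly 3.0 s).
* **Diarisation.**  The 35-feature set (13 MFCC means, 13 MFCC SDs over
  20-ms sub-frames, mean F0 by FFT autocorrelation with a 0.3 voicing
  threshold, energy, zero-crossing rate, centroid, 85 % rolloff, flux,
  flatness, bandwidth, harmonic ratio) is a fixed, documented default;
  the feature library used for the original analyses names its 35
  features only by example, so fidelity to that exact list is not
  claimed.  Unvoiced windows carry F0 = 0 with no indicator column.
  The forest uses 500 trees with sqrt feature subsampling; a mandatory
  seed makes training reproducible.  Utterances (maximal speech runs
  between detected pauses) are attributed by majority vote over their
  0.2-s windows; ties go to the previous turn's speaker, then to the
  therapist.
* **Windowing.**  Pause time is apportioned to 10-s windows exactly by
  overlap (conserving total pause seconds to grid precision); the
  trailing partial window is dropped.  A window counts as rupture when
  an episode covers at least half of it (threshold configurable; exact
  half counts as rupture).  z-scores are computed per dyad over *all*
  windows before any subsetting to rupture windows — the transformation
  is described per dyad, prior to model assembly, and the chosen order
  is documented rather than asserted as the original one.  Lag/lead
  offsets beyond the session edge are imputed with 0 (the z-mean) and
  counted in a QC report, which preserves short ruptures near session
  edges instead of dropping their rows.
* **Classifier.**  "Weighted by the length of the ruptures" is read as
  length-weighted episode allocation: within each (dyad × marker)
  stratum, shuffled episodes fill the training side until it holds 2/3
  of the stratum's rupture seconds, taking the crossing episode only if
  that lands closer to 2/3.  No probability calibration and no decision
  threshold are computed; the AUC uses the rank definition with half
  credit for ties, and scores are out-of-forest vote fractions.
* **Mixed models.**  REML fits via `statsmodels.MixedLM`; p-values are
  large-sample Wald tests (a Satterthwaite-style correction would
  differ only at far smaller group counts than used here).
  Standardised betas come from refitting on z-scored response and
  predictors.  R² follows the variance-partition formulation:
  marginal = fixed / (fixed + random + residual), conditional adds the
  random-intercept variance to the numerator.  With a single dyad the
  fit degrades gracefully to OLS (no between-group variance is
  estimable).  The time course re-bins the *raw pause track* into 10-s
  bins anchored at each rupture's onset (−20..+30 bins); the SEM at
  each offset is taken over contributing ruptures (reported missing,
  not zero, when only one contributes) — whether the original figures'
  SEM is over ruptures or windows is not fully specified, and the
  over-ruptures choice is documented here.

## Recovery runs and problem sizes

`scripts/acceptance.py` generates 22 dyads × 500 sessions of 3 000 s
(≈ 250 000 rupture windows, ≈ 80 s on one CPU) through the ground-truth
bypass and reports the pooled non-rupture and rupture window means, the
Model B fixed effects, and the withdrawal-with-marker cell mean.  The
session count is a Monte-Carlo precision choice: it puts the standard
error of the withdrawal coefficient near 0.08 points.  The test suite
runs the same recovery at 100 sessions per dyad, the classifier
recovery on ≈ 330 planted ruptures (10 dyads × 18 sessions of 1 500 s),
silence recovery on twelve 2-minute rendered sessions and diarisation
on one 20-minute session with a 5-minutes-per-speaker learning set.

What passing these runs shows: the implementation of every stage is
internally consistent and recovers known planted structure at realistic
noise levels.  What it does not show: performance on real recordings,
whose reverberation, crosstalk, non-stationary noise and rater
idiosyncrasies the generator deliberately does not model.

## Known limitations

* The generator's within-rupture pause clustering is a
  lognormal/renewal modelling convenience; no distributional form for
  real within-rupture pause clustering is claimed.
* Rendered audio contains no overlapping speech, so the diariser is
  never tested on crosstalk; unsupervised diarisation is out of scope.
* Rupture significance ratings, resolution episodes and markers other
  than minimal response are carried through the data model but not
  analysed.
* The ≥ 3 s silence variant changes only the pause track; learning-set
  extraction and rupture annotations are taken as given (emulated by
  the generator), and rater behaviour is not simulated.
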