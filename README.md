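# minresp

Automatic, pause-based detection of **minimal-response alliance-rupture
markers** in dyadic psychotherapy audio.

## The problem

In Safran and Muran's rupture-and-resolution model of the therapeutic
alliance, *withdrawal* ruptures (the patient moves away from the
therapist) are easy to miss and expensive to code: trained observers
must watch whole sessions and mark rupture episodes by hand.  The most
frequent withdrawal marker in adolescents with borderline personality
disorder is the **minimal response**: the patient goes silent or answers
minimally to statements meant to keep the conversation going.  That
marker has an acoustic shadow — speech pauses, and specifically pauses
that are both preceded and followed by *therapist* speech (the patient
skipping speaking turns).

`minresp` implements the full detection pipeline for researchers in
computational psychiatry and psychotherapy-process research:

1. **Silence detection** — amplitude-range method: signal range
   (max − min) in 0.01-s windows, histogram with Scott's-rule bin width
   (3.49 · s · n^(−1/3)), cut-off at the valley after the silence peak,
   applied to 0.1-s windows; an optional ≥ 3 s filter yields the
   conventional "silence" variant.
2. **Speaker diarisation** — 35 acoustic features (MFCC means/SDs, mean
   F0, energy, ZCR, spectral shape) per 0.2-s window, a random-forest
   speaker classifier trained on a ≥ 5-min labelled learning set, and
   utterance-level majority vote.
3. **Switching patterns** — every pause is labelled P_P, P_T, T_P or
   T_T by the speakers of the neighbouring utterances.
4. **Windowing** — a 10-s window table with exactly apportioned pause
   percentages, rupture flags, and a 44-column feature matrix
   (4 patterns × offsets 0, ±1..5 windows, z-scored per dyad).
5. **Marker classifier** — random forest (500 trees, 6 variables per
   split) trained on rupture windows only, with an episode-level
   2/3 : 1/3 split stratified by dyad and marker and weighted by rupture
   seconds; reports OOB error, permutation importance, ROC/AUC.
6. **Mixed models** — random-intercept-by-dyad models of window pause
   percentage: Model A (rupture vs. non-rupture), Model B (rupture type
   + minimal response, rupture windows only), Bonferroni adjustment,
   square-root sensitivity refits, and the rupture-onset-aligned pause
   time course.

Because the clinical recordings behind the original analyses are not
publicly available, the package ships a first-class **synthetic
corpus generator** that plants the published pause structure (30.6 %
baseline pause share; additive rupture effects of +3.22 % for
withdrawal and +11.67 % for the minimal-response marker over a 32.39 %
confrontation reference; a 25-s anticipatory pause ramp before
withdrawal onsets; T_T-concentrated pauses in minimal-response
episodes) so that every stage can be validated by planted-parameter
recovery.  See `docs/methods.md` for the generator's model and its
limitations.

## Worked example

```python
import pandas as pd
from minresp import (GeneratorConfig, generate_corpus, truth_to_window_table,
                     fit_model_a, fit_model_b)

cfg = GeneratorConfig(n_dyads=10, sessions_per_dyad=30,
                      session_length=3000.0, seed=0)
truths, _ = generate_corpus(cfg)
windows = pd.concat([truth_to_window_table(t) for t in truths],
                    ignore_index=True)
print("windows:", len(windows), " rupture windows:", int(windows.in_rupture.sum()))
print("non-rupture mean pause: %.1f%%" % windows[~windows.in_rupture].pause_pct.mean())
a = fit_model_a(windows)
print("Model A rupture effect: %.2f" % a.coef("is_rupture"))
b = fit_model_b(windows[windows.in_rupture])
print(b.table[["estimate", "se", "ci_low", "ci_high", "p"]].round(3))
```

prints

```
windows: 90000  rupture windows: 7628
non-rupture mean pause: 30.5%
Model A rupture effect: 8.65
                  estimate     se  ci_low  ci_high    p
(Intercept)         32.661  2.564  27.636   37.685  0.0
withdrawal           2.047  0.435   1.194    2.900  0.0
minimal_response    11.549  0.434  10.698   12.399  0.0
```

Read: rupture windows carry ~8.7 points more pause than non-rupture
windows; among rupture windows, confrontation episodes without the
marker average ~32.7 % pause, withdrawal adds ~2 points (the planted
value is 3.22; at 10 dyads the Monte-Carlo error is still visible) and
the minimal-response marker adds ~11.5 points.

The same pipeline runs from the shell:

```bash
minresp generate --seed 1 --out runs/corpus --audio   # WAV + label tracks
minresp detect-silence runs/corpus/d00_s000.wav --out pauses.tsv
minresp run-all --seed 1 --use-truth --out runs/full  # end-to-end, bypass audio
minresp run-all --seed 1 --silence-filter 3 --out runs/silence3   # ≥3 s variant
```

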