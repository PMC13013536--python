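# poca — peak-based oscillation classification for CPG recordings

`poca` analyzes multichannel extracellular DC recordings from the ventral
roots of isolated spinal-cord preparations, where a central pattern
generator (CPG) produces fictive locomotion: low-amplitude spontaneous
baseline oscillations, then — after dorsal-root or brainstem stimulation —
a rapid depolarization carrying high-prominence locomotor oscillations
(0.15–1.5 Hz) that alternate in phase between left/right and
flexor/extensor roots, followed by repolarization.  Assessing a
stimulation protocol currently means an expert hand-marking locomotor
cycles on an exemplar trace; `poca` automates that, for every channel.

It is aimed at electrophysiologists tuning neuromodulation protocols and
at methodologists who need a reproducible, scriptable oscillation
classifier.

## Method

Instead of segmenting the signal into fixed epochs, every **local maximum**
of the band-limited trace (500 Hz working rate, zero-phase 1.5 Hz low-pass)
is a candidate oscillation, characterized by 12 features:

* **Time, Amp** — timestamp and absolute amplitude;
* **Pro, Wid** — prominence and width from a *dynamic reference window*:
  within ±6.67 s (= ±1/0.15 Hz) the nearest strictly-higher peak on each
  side bounds a search interval; the higher of the two interval minima is
  the reference level, Pro is the peak amplitude above it and Wid the span
  between the two half-prominence crossings;
* **Pro2Dep, Pro2Base, Pro2Wid** — Pro relative to the slow depolarization
  level, to the mean baseline-period prominence, and to Wid;
* **LocDev** — Pro relative to the mean Pro of its four temporal neighbors;
* **SynIndex** — percentage of samples in a 0.4 s window whose
  Hilbert-transform instantaneous phase ϕ⁽ᶜ⁾ is within 45° of every other
  channel (locomotor alternation drives this to 0);
* **StimCK, FreqCK, nSynCK** — boolean checks: after stimulation onset,
  cycle frequency inside the 0.15–1.5 Hz band, SynIndex < 50%.

Each candidate is then classified locomotor/non-locomotor by one of three
models on per-channel min-max normalized features:

* thresholding: p = 1 iff x_fea > τ, with τ chosen by exhaustive scan
  maximizing training F1;
* RBF-SVM: p = 1 iff Σᵢ αᵢcᵢ·exp(−γ‖xᵢ−x‖²) + b > 0;
* 2-means: p = 1 iff ‖x−μ₁‖² < ‖x−μ₀‖², with μ₁ the cluster of higher
  mean prominence.

Locomotor peaks closer than 6.67 s are merged into episodes and each
channel's rhythm is summarized by 12 features (Num, Dur, mPer, PerCV, Dep,
AUC, Duty, mWid, WidCV, mPro, ProCV, mLocDev).  An evaluation module
provides SEN/PRE/ACC/F1, ICC(2,1) agreement against reference ratings, KL
divergence between feature distributions, and per-feature class
diagnostics.  A synthetic-recording generator with analytic ground-truth
crest labels makes every stage testable without recorded data.

## Worked example

```python
import pandas as pd
from poca import SimConfig, generate, match_labels, fit_model, predict_model
from poca.pipeline import analyze_recording
from poca.rhythm import rhythm_report

sim = generate(SimConfig(seed=1))                 # 120 s, 4 roots, stim at 20 s
res = analyze_recording(sim.recording)            # filter, phase, 12 features
table, cov = match_labels(sim.labels, res.table, 0.625)
model = fit_model(table, "svm")                   # RBF-SVM on 6 features
pred = predict_model(model, table)
report, episodes = rhythm_report(table, pred, res.filt, res.contexts)
```

which prints (via `report.round(3)`):

```
detected peaks: 164 | missed true events: 0
channel  Num    Dur  mPer  PerCV   Dep  Duty  mPro
    lL2 11.0 25.038 2.504  0.007 1.027 0.496 1.985
    rL2 12.0 27.242 2.477  0.020 1.037 0.502 1.924
    lL5 12.0 27.242 2.477  0.020 1.037 0.502 1.923
    rL5 11.0 25.038 2.504  0.008 1.027 0.496 1.985
training accuracy vs ground truth: 1.000
```

Each row is one ventral root: 11–12 locomotor oscillations over a ~25 s
episode with a 2.5 s mean period (the generator's 0.4 Hz rhythm), period
jitter below 2%, a depolarization of ≈1 signal unit and a duty cycle of
≈0.5.  The same pipeline is available from the shell:

```bash
poca simulate --out sim --seed 1
poca analyze --signal sim/signal.csv --meta sim/meta.yaml \
             --events sim/events.csv --out run
```

plus `train`, `predict`, `evaluate`, `cv`, `subset-search` and
`learning-curve` subcommands for the experiment harness.

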