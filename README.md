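# taprhythm

Tools for studying sensorimotor synchronization with complex cyclic rhythms:
enumeration of nondegenerate **well-formed rhythms**, rhythm- and pulse-level
**structural predictors**, **tap-performance scoring**, a **synthetic tapping
simulator** with known ground truth, and **signal-detection-style regression**
of tap probability, velocity, and timing.

## The scientific problem

In a typical tapping experiment a participant hears a repeating cycle of *N*
isochronous pulses (here every 234 ms, sounded by a cymbal), *K* of which are
additionally *cued* (a piano tone); the task is to tap only on the cued
pulses.  Well-formed rhythms — cyclic patterns whose interonset intervals take
exactly two sizes, distributed as evenly as possible — provide a principled
universe of such patterns covering both familiar duple/triple cycles and the
odd cycles (5, 7, 11, 13 pulses) typical of Balkan *aksak* and other
non-Western traditions.  With the default bounds (3–13 pulses, 2–11 cues, no
interonset interval above 5 pulses, counted up to rotation) the universe
contains exactly **91 rhythms**.

Two families of questions drive the analysis:

* **Rhythm level** — which structural properties (evenness, balance, entropy
  of the interval content, Carey's coherence and sameness quotients, cue
  density *N/K*, divisibility of the cycle by 2 or 3) make a rhythm easier to
  tap accurately?
* **Pulse level** — within a rhythm, which pulses attract taps?  Predictors
  include optimal order-*k* Markov cue probabilities, a derivative-of-Gaussian
  **edge** detector marking the boundaries of cue groups and gaps, the
  projection of the rhythm's circular centroid onto each pulse, metrical
  weights from a circular autocorrelation phase matrix, and Povel's accent
  indicators.

Because every pulse-level predictor *x* is interacted with the binary `cue`
indicator, each regression coefficient pair decomposes, exactly as in signal
detection theory, into the effect of *x* on **uncued** (false-alarm) responses
(β₂), on **cued** (hit) responses (β₂ + β₃), and on **discriminability**
(β₃ = cued − uncued).

Observation families respect how the data are recorded: per-pulse tap counts
over a 30-s performance are **binomial** (logit link); MIDI velocities are
normal with **upper censoring** at 127 (harder taps are still recorded as
127); signed tap asynchronies are normal **truncated** to the ±117-ms
assignment window; and the performance-level accuracy score — the cosine
similarity between 10-ms-Gaussian-smoothed tap and cue trains at 1-ms
resolution — is **beta** distributed in (0, 1).

## Worked example

```python
import numpy as np
from taprhythm import enumerate_wf_rhythms
from taprhythm.rhythm_features import rhythm_feature_table
from taprhythm.pulse_features import edge, markov

universe = enumerate_wf_rhythms()          # 91 rhythms
r = next(x for x in universe if x.to_string() == "10101101")
print(rhythm_feature_table([r]).round(3))
print("edge   :", np.round(edge(r), 2))
print("markov2:", np.round(markov(r, 2), 3))
```

prints

```
           N  K  mean_ioi  evenness  balance  ioi_ent  int_ent   cq    sq  duple_triple
rhythm_id
N8K5a      8  5       1.6     0.975    0.917    0.971    2.746  1.0  0.75             1
edge   : [0.22 0.07 0.02 0.07 0.2  0.22 0.07 0.2 ]
markov2: [0.667 0.    1.    0.667 1.    0.667 0.    1.   ]
```

The rhythm `N8K5a` is the 8-pulse, 5-cue pattern (1 0 1 0 1 1 0 1) with IOIs
(2 2 1 2 1).  Its mean interonset interval is 8/5 = 1.6 pulses; it is highly
even (0.975) and balanced (0.917); every generic interval comes in exactly two
sizes, so its sameness quotient is 1 − 1/(K−1) = 0.75.  The edge vector is
largest at pulses adjacent to the boundaries between cue groups and gaps, and
the Markov-2 vector gives the optimal cue probability after each two-pulse
context (e.g. the context (1 1) is always followed by silence or a cue
depending on position in this rhythm).

An end-to-end run on a small synthetic cohort:

```python
from taprhythm.cli_io import PipelineConfig, run_pipeline
from taprhythm.synthetic_tapping import SimConfig

config = PipelineConfig(out_dir="artifacts",
                        sim=SimConfig(n_participants=4, repetitions=1, seed=1))
artifacts = run_pipeline(config)
```

writes the catalog, feature tables, simulated tap log, accuracy scores, the
joined pulse-level table, and `fits.json` with the four family fits.  The
tap-probability fit for that seed gives a cue effect of **1.90 log-odds**
(odds ratio ≈ 6.7: cued pulses are about seven times more likely to be
tapped), and the decomposition for `proj_cent` reads uncued −0.09,
discriminability +0.39, cued +0.29 — with cued = uncued + discriminability
holding exactly.

The same stages are available from a shell via the `taprhythm` CLI
(`enumerate`, `features`, `pulse-features`, `simulate`, `score`, `fit`,
`recover`, `report`, `pipeline`).

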