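# emgfatigue

Fatigue-aware hand-grasp force estimation from surface electromyography
(sEMG).

Muscle fatigue is one of the main reasons sEMG-based force estimation works
in the lab but degrades in daily use: as a muscle fatigues, the RMS of its
sEMG rises and its spectral mean frequency (MNF) falls *at the same exerted
force*, so a regression trained on fresh muscle drifts once fatigue sets in.
This package implements a force-based, quantitative fatigue metric — the
**Maximum Force Loss (MFL)** — and a pipeline demonstrating that feeding MFL
to the regression as an extra input substantially improves force estimation.

For a static-contraction protocol at a required force level, with initial
maximal voluntary contraction `MVC_i`, current maximal force `MVC_t` and the
required level `MVC_f`:

```
MFL = (MVC_i - MVC_t) / (MVC_i - MVC_f)        0 = fresh, 1 = exhausted
```

The estimation comparison pits three feature sets, each driving a three-layer
feed-forward network (log-sigmoid hidden units, `S(x) = 1/(1+e^-x)`;
linear output) regressing windowed mean grasp force, scored by
`R^2 = 1 - SSE/SST` under blocked 4-fold cross-validation with a hidden-node
sweep and repeated retraining:

* **TMLM** — per-muscle RMS only (time domain);
* **CMLM** — RMS plus the MNF/ARV frequency-domain fatigue index;
* **FMLM** — RMS plus the MFL fatigue input.

Because no public recordings exist for this protocol, the package ships a
seeded synthetic session generator (`emgfatigue.synthgen`) that emulates the
whole experiment: MVC probes whose peak force declines linearly with
accumulated contraction time, 10 s steady holds at 50/60/70% `MVC_i`, sEMG
whose RMS rises and MNF falls with fatigue, and termination once the measured
MVC drops below the required force.

## Worked example

```python
from emgfatigue import SessionProtocolSpec, simulate_session, fit_session_gradient
from emgfatigue.pipeline import run_cohort_comparison

# one 70% MVC_i session with fatigue rate 0.0532 MFL/s of active contraction
spec = SessionProtocolSpec(target_level=0.7, gradient=0.0532, mvc_i=500.0, seed=42)
bundle = simulate_session(spec)
print("MVC probes:", [(t, round(v, 1)) for t, v in bundle.session.mvc_trials])
print("terminated:", bundle.session.terminated)
fit = fit_session_gradient(bundle)
print(f"fitted gradient: {fit.slope:.4f}")

# single-subject three-level comparison, reduced node sweep
cfg = {"simulation": {"n_subjects": 1},
       "estimation": {"retrains": 3, "nodes": [4, 5, 10]}}
report, _, _ = run_cohort_comparison(cfg, seed=0)
for m, v in report.means.items():
    print(f"{m}: best-node R^2 = {v:.4f}")
```

prints

```
MVC probes: [(0.0, 500.6), (15.0, 378.2), (30.0, 262.1)]
terminated: True
fitted gradient: 0.0530
TMLM: best-node R^2 = 0.6843
CMLM: best-node R^2 = 0.8082
FMLM: best-node R^2 = 0.9303
```

The MVC probes decline from 500 N toward the 350 N required level, the
session terminates once the measured maximum falls below it, and the fitted
MFL-versus-time slope recovers the injected fatigue rate. In the comparison,
the RMS-only model is badly confounded by fatigue (same RMS, different
force), the MNF/ARV input helps, and the explicit MFL input recovers most of
the lost accuracy — the package's analogue of the finding it demonstrates.

A `emgfatigue` console script exposes the stages
(`simulate`, `extract`, `fatigue`, `estimate`, `run`); try
`emgfatigue simulate --level 0.7 --gradient 0.0532 --seed 42 --out demo/`.

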