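# cbrl — cerebellar reinforcement learning in a drift-diffusion race model

`cbrl` models how primates learn arbitrary visuomotor associations — "this
symbol means release the left bar, that one the right" — and what happens to
that learning when the posterior-lateral cerebellar cortex (Crus I/II) is
reversibly inactivated with muscimol. It is written for computational
neuroscientists who want a tested, seedable implementation of the model and of
the behavioral analyses used to quantify such experiments, exercised end to
end on synthetic data generated by the model itself.

## The model

Choice and reaction time on each trial come from a race between two
independent evidence accumulators, one per hand. Each accumulator is a Wiener
process with unit diffusion, drift ν_i and a single absorbing boundary a, so
its first-passage time is Wald (inverse-Gaussian) distributed:

    V_i ~ WFPT[ν_i(t)],   f(s) = a / √(2π s³) · exp(−(a − ν s)² / 2s)

The earlier passage (plus a non-decision time) sets the choice and the RT;
passages beyond the 2800 ms deadline are abort trials. Learning acts on the
drift rates through a cerebellar error signal Δ_i^CB carried by Purkinje-cell
simple spikes:

    ν_i(t+1) = ν_i(t) + (m/r) · Δ_i^CB(t) · I_c(t) · I_i(t)
    Δ_i^CB(t) = r·[ν_i^OT − ν_i(t)]·I_c(t)·I_i(t) + (I_w(t) + I_c(t)·I_{i≠j}(t))·Δ_i^CB(t−1)

where m is the learning rate, r a scale factor, ν^OT the overtrained
(asymptotic) drift, and I_c, I_w, I_i indicate correct trials, wrong trials
and the chosen hand. Only the chosen hand updates, and only after correct
(rewarded) trials; everything else carries the previous error signal forward.
Muscimol inactivation replaces Δ_i^CB with fresh Gaussian noise on every
trial, which freezes systematic learning while leaving the gating intact.

On top of the model sit the study's behavioral statistics (sliding-window
learning curves, the 90%-crossing acquisition criterion, the conditional
read-out Pr(L_m | L_s = p) that evaluates muscimol performance at the trials
where the paired saline curve reached level p, win-stay/lose-switch and
choice-bias metrics, Lilliefors-gated location tests, lick-rate and
gaze-spread metrics) and the anatomical density quantification of charted
neurons on flattened cortical maps (200 µm binning, upper-90th-percentile
dense bins, region composition).

## Worked example

```python
import numpy as np
from cbrl import ModelParams, SymbolPairSpec, simulate_session
from cbrl.behavior import learning_curve, acquisition_trial

pair = SymbolPairSpec(pair_id="P01", difficulty=0.4)
sess = simulate_session(ModelParams(), pair, n_ot=30, n_learn=100,
                        rng=np.random.default_rng(42))

learn = sess[(sess.phase == "learning") & (sess.outcome != "abort")]
curve = learning_curve(learn)
print(curve.percent_correct[:6])   # [40. 60. 70. 70. 70. 90.]
print(acquisition_trial(curve))    # 31

ot = sess[sess.phase == "overtrained"]
print((ot.outcome == "correct").mean() * 100, ot.rt.mean())  # 100.0  508.7
```

The session starts with an overtrained block performed at 100% correct with
~509 ms mean RT, then a novel pair whose sliding-window percent correct
(window 10, step 5) climbs from chance; the acquisition trial is the start of
the first window above 90% — here trial 31, a fairly easy pair (difficulty
0.4 of 1).

The same workflow is available from the shell:

```
cbrl simulate --seed 1 --out data/          # paired saline/muscimol dataset + manifest
cbrl analyze  --out report.json data/trials.csv
cbrl fit      --out fit.json data/trials.csv
cbrl anatomy  --out anatomy.json cells.csv
cbrl calibrate --seed 1 --out calib.json
```

## Layout

    src/cbrl/model.py        race model, error-signal dynamics, RT-distribution fitting
    src/cbrl/behavior.py     behavioral metrics and gated statistics
    src/cbrl/synth.py        seeded generators (behavior, peripherals, charted cells)
    src/cbrl/anatomy.py      flattened-map density quantification
    src/cbrl/replication.py  study-scale replication runs
    src/cbrl/pipeline.py     configuration, reports, stage orchestration
    src/cbrl/cli.py          `cbrl` command-line interface
    docs/methods.md          model assumptions, parameter choices, limitations
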