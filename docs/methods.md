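# Methods

## The race model

Action selection in the two-alternative symbol-to-hand task is a race between
two independent single-boundary Wiener accumulators, one per hand. Two
independent accumulators (rather than one two-boundary diffusion) are used
because each action value carries its own first-passage process; the race is
the minimum of the two passages. With the diffusion coefficient fixed at 1
(the standard identifiability convention), an accumulator with drift ν and
boundary a has Wald (inverse-Gaussian) passage times with mean a/ν and shape
a². Sampling uses the Michael–Schucany–Haas transformation (exact); a
discrete-time Euler–Maruyama path simulator exists only as a test oracle,
since its first-passage times carry an O(√dt) boundary-overshoot bias.

Learning updates only the chosen hand's drift and only after rewarded trials;
the cerebellar error signal is the scaled distance to the overtrained drift,
carried over unchanged on wrong trials and for the unchosen hand. Two
consequences worth noting, both implemented literally: (i) under an
all-correct sequence the drift gap contracts by exactly (1 − m) per trial, a
closed form asserted to machine precision in the tests; (ii) the incorrect
hand's drift never changes during learning, so discriminability grows purely
through the correct hand's drift. Each symbol of a pair has its own
accumulator state; the symbol shown on a trial selects which state races and
learns.

Muscimol inactivation replaces the error signal with fresh draws from
Normal(noise_mu, noise_sigma) on every trial for both hands, bypassing the
carryover. Because the update gate is unchanged, the drift performs a slow
positive random walk on rewarded trials — performance stays near chance early
and creeps above it late, without ever approaching control learning. Drifts
are clamped at a floor of 1e-4: the Wald sampler requires strictly positive
drift (absorption is otherwise not certain), and the noise walk could
otherwise cross zero.

## Parameters, units, defaults

Drifts are in evidence units per ms, times in ms. The defaults are the
calibrated saline generator values, chosen once from the study's printed
behavioral bands (overtrained accuracy >95%, acquisition of a novel pair in
50–70 trials, muscimol conditional performance ~65% at the saline 100% level
and ~50% at the 50% level) and then frozen:

| parameter      | default | meaning                                      |
|----------------|---------|----------------------------------------------|
| boundary       | 100     | absorbing threshold (evidence units)         |
| ndt            | 250 ms  | non-decision time                            |
| ν_OT correct   | 0.4     | overtrained drift, correct hand (→ ~500 ms RT) |
| ν_OT incorrect | 0.02    | overtrained drift, losing hand               |
| ν_init         | 0.12    | symmetric drift at learning onset (→ ~1.1 s RT) |
| m              | 0.012   | learning rate                                |
| r              | 2.0     | error-signal scale (cancels in the update; kept for fidelity) |
| max_rt         | 2800 ms | response deadline; later passages abort      |
| noise_mu/sigma | 0.14 / 0.5 | muscimol error-signal noise moments       |

The boundary/drift scale matters: at a given mean decision time a/ν, the
passage-time CV is 1/√(aν), so small boundaries make the race so noisy that
no drift separation reaches the printed >95% overtrained accuracy, and the
accuracy-vs-drift mapping becomes too shallow for learning curves to reach
100% within the 100 analyzed trials. The default boundary of 100 puts the
overtrained CV near 0.16 and makes accuracy rise steeply over the learned
drift range, which is what the printed acquisition band and the attainment of
the 100% level jointly require.

Acquisition difficulty of a symbol pair maps multiplicatively onto the
learning rate, m·(1.4 − 0.8·d), and linearly onto the initial drift,
ν_init + 0.04·(d − 0.5), for difficulty d ∈ [0, 1]; the default library
spreads d evenly over [0, 1] (per-pair difficulties are not published, so the
spread is uniform by construction). Higher ν_init is harder: the
never-updated incorrect hand keeps that drift, so a higher starting point
means less final separation.

## Fitting

`fit_model` estimates (ν_OT correct, ν_init, m) from a trial table. The
overtrained drift minimizes the sum of squared differences between empirical
and simulated RT deciles of the overtrained block (Nelder–Mead on log-drift,
10 restarts, common random numbers so the objective is deterministic). The
initial drift and learning rate then alternate for two sweeps: ν_init is
fitted to the deciles of the first 20 learning-trial RTs simulated from the
full learning process — a fixed-drift approximation would bias ν_init upward
by ~10%, since drifts already grow within that block — and m is fitted by
least squares between the empirical mean learning curve and the simulated
one. The overtrained drift of the losing hand is held at its configured
value: with >95% accuracy it contributes on the order of 1% of overtrained
RTs and is not identifiable from deciles. Parameter recovery at 300 sessions
lands within 10% relative error on all three fitted parameters (typically
well under 3%).

## Behavioral metrics

Abort trials (both-hands release, pre-symbol release, response after
2800 ms) are removed before every analysis and their fraction reported per
condition. Learning curves are percent correct in a 10-trial window stepping
by 5, indexed by the window's first trial; only the first 100 learning trials
are analyzed. The acquisition trial is the start of the first window
strictly above 90%; "learned" additionally requires staying strictly above
80% for the windows covering the next 20 trials.

The conditional read-out Pr(L_m | L_s = p) works per symbol pair: average the
saline curves over repetitions, interpolate to trial resolution, find the
three consecutive trials bracketing the first crossing of level p (the
crossing trial and its two neighbors — a centered triplet, so its average
tracks the level itself; a triplet starting at the crossing would carry a
systematic half-slope bias), and read the pair's averaged muscimol curve at
those trials. Reading the interpolated muscimol curve rather than averaging
raw muscimol trials keeps the identity property exact — with identical
tables the read-out equals the saline value at every level — and reduces the
variance of the read-out; both choices average the same underlying trials,
differing only in weighting. Levels already exceeded at the first supported
trial clamp to the curve start: such a level is not genuinely bracketed, and
the identity-to-100p property is only meaningful for interior crossings.

Win-stay/lose-switch is defined on hands irrespective of symbol: trial t is
consistent if the previous trial was rewarded and the same hand chosen, or
unrewarded and the other hand chosen. Curve distances are trapezoidal areas
between curves over the common support, normalized by the shorter curve's
trial span. Location tests are gated by a Lilliefors normality test at
α = 0.05 (on paired differences, or on both samples), choosing between
t-tests and their Wilcoxon/Mann–Whitney alternatives; all p-values are
two-tailed, and the branch taken is reported. The gate's type-I error under
Gaussian nulls measures ~0.05 in the suite. Lick rates are trial-averaged
1 kHz contact traces smoothed with a unit-area Gaussian kernel (σ = 20
samples, nearest-edge extension so constants are preserved). The radius of
visual exploration is the FWHM (geometric mean across axes) of a 2D Gaussian
least-squares fit to a 0.5°-binned gaze-position histogram, the bin width
matching the stated tracker accuracy.

## Synthetic data

The behavioral generator *is* the model: each (pair, repetition) yields one
saline and one muscimol session for the same pair, sessions are grouped into
alternating saline/muscimol days of 3–10 sessions, and abort rows are
injected at 6% (saline) and 8% (muscimol), inside the reported <7%/<9%
bounds, at random positions with random reasons. Every session's RNG stream
descends deterministically from the root seed, and the manifest records
enough to regenerate the dataset byte-identically. Peripheral traces encode
the study's null findings by construction: gaze spread, lick bursts and
hand-movement amplitudes share one distribution across conditions.

The charted-cell generator emulates the flattened-map geography of
transneuronally labeled neurons. Region labels are multinomial with the
printed composition (prefrontal 63%, half of it PrePMd; parietal/cingulate/
retrosplenial 24%; insula/temporal 10%; orbital 1%; motor 2%); the default
cell count is the reference case's 4889. Spatially, scattered label is a
hard-core background (at most one cell per 200 µm bin) — a Poisson
background was tried and rejected because its count tail inevitably pollutes
the upper-decile bins, which no parameter setting could reconcile with the
map's reported patch geography — while PrePMd carries paired diffuse label
plus 24 Gaussian patches (σ = 120 µm), with one stray patch each in area 8
and parietal cortex so a small minority of dense bins falls outside PrePMd.
The extreme cells are pinned to bin corners so the min-anchored analysis grid
aligns with the generation lattice. Under the default analysis this yields
95.6–97.0% of dense bins in PrePMd across seeds.

What the generator does not emulate: real fractal-symbol imagery, session
fatigue beyond the 100-trial truncation, within-day performance drift,
saccade structure in gaze, histological section geometry or atlas anatomy.
Passing tests therefore demonstrate the correctness and calibration of the
computational pipeline, not properties of the original animals' data.

## Density quantification

Cells are assigned to half-open bins (boundary cells to the higher index),
200×200 µm for cerebral layer-5 maps and 200×100 µm for cerebellar
Purkinje-cell maps, with the grid origin anchored at the minimum coordinate.
The dense-bin threshold is the 90th percentile of occupied-bin counts taken
with the "higher" rule — the smallest occupied count at or above the
percentile position — and the dense set includes ties (every bin at or above
the threshold, matching a "k or more" reading). Zero bins are excluded from
the percentile because their number is arbitrary on an unbounded map. Dense
bins take the modal region label of their member cells, ties broken
lexicographically and flagged.

## Numerical choices and problem sizes

The replication runs pool six independently seeded replicate datasets of the
default 16-pair × 3-repetition library (~290 sessions per condition, ~96
pair-level groups), sized to bring the Monte-Carlo s.e.m. of the pooled
conditional read-outs to about one percentage point; overtrained accuracy
pools 100 blocks of 30 trials. Parameter recovery uses 300 sessions; the
sampler/density agreement is checked at 1e5 draws (KS < 0.01) over a
(drift, boundary) grid; the gated test's type-I error uses 2000 replicates.

## Known limitations

- The muscimol noise moments are calibration targets, not measurements; only
  their behavioral consequences (chance anchoring, ~65% at full saline
  learning) are constrained.
- The fit holds boundary and non-decision time fixed; they are jointly
  weakly identified with drift from deciles alone at a single condition.
- The conditional read-out's bracket is undefined (clamped) for levels below
  the curve's starting point; interpretation at p = 0.5 relies on curves
  starting at chance.
- Hierarchical (across-subject) fitting is out of scope; each dataset is fit
  as a single subject.
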