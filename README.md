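# heidi

A trial-level simulator for **HeiDI** ("How excitation and inhibition
determine ideo-motion"), an associative-learning model of Pavlovian
conditioning built on *reciprocal* CS–US associations. The package is for
behavioural and computational neuroscientists who want to simulate
autoshaping-style experiments, explore how individual differences in
stimulus salience produce sign-tracking versus goal-tracking phenotypes,
and recover salience parameters from observed (or synthetic) response
trajectories.

## The model

Pairing a conditioned stimulus (CS, e.g. a lever) with an unconditioned
stimulus (US, e.g. sucrose) forms a forward association V(CS→US) and a
backward association V(US→CS). Both follow a pooled-error rule of the
Rescorla–Wagner family in which the perceived salience of the **target**
sets the asymptote and the salience of the **source** sets the rate:

    ΔV(CS→US) = α_CS · (c·β_US − ΣV(TOTAL→US))
    ΔV(US→CS) = β_US · (c·α_CS − ΣV(TOTAL→CS))

with α_CS, β_US ∈ [0, 1] and c the maximum strength (default 1, in units
of V). ΣV(TOTAL→·) pools the strengths of all stimuli present on the
trial, so compound elements compete (overshadowing, blocking). When a
stimulus is absent its salience terms are zero, which extinguishes the
forward link on CS-alone trials and the backward link on US-alone trials.
The same rule, with α in place of β, covers CS–CS associations.

On CS presentation the two links combine,

    V_COMB = V(CS→US) + (1/c) · V(CS→US) · V(US→CS),

and V_COMB is distributed into a CS-oriented component R_CS (driving
sign-tracking) and a US-oriented component R_US (driving goal-tracking)
according to the CS's salience relative to the retrieved US salience:

    R_CS = α_CS / (α_CS + |V(CS→US)|/c) · V_COMB
    R_US = (|V(CS→US)|/c) / (α_CS + |V(CS→US)|/c) · V_COMB

so R_CS + R_US = V_COMB exactly. A fixed link matrix maps (R_CS, R_US)
onto six response units r1–r6 (r1 = canonical sign-tracking response,
r4 = canonical goal-tracking response). Because α and β are fixed within
a subject but vary across subjects, the model produces both quantitative
and qualitative individual differences from identical training. An
optional within-trial exponential decay of α_CS (default factor
0.81 = (1 − 0.10)² per epoch, reset each trial) moves responding from
sign-tracking early in the CS toward goal-tracking late in the CS
(inhibition of delay); learning uses the terminal (last-epoch) α.

## Worked example

Twenty reinforced trials with a low-salience lever (α_CS = .3) and a
moderately salient US (β_US = .5):

```python
from heidi import SubjectParams, build_acquisition, run_design

params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
design = build_acquisition(20, n_epochs=1)
traj = run_design(design, params)
print(traj[["trial", "v_forward", "v_backward", "r_cs", "r_us"]].tail(3).to_string(index=False))
```

```
 trial  v_forward  v_backward     r_cs     r_us
    18   0.498837    0.299998 0.243537 0.404950
    19   0.499186    0.299999 0.243601 0.405340
    20   0.499430    0.299999 0.243646 0.405613
```

The forward strength approaches its asymptote c·β_US = 0.5 and the
backward strength c·α_CS = 0.3. Because the retrieved US salience
(|V|/c ≈ .5) exceeds the CS salience (.3), the combined output is routed
mainly into R_US: this subject is a goal-tracker. Swapping the saliences
(α = .7) reverses the ordering and yields a sign-tracker.

The same machinery is exposed on the command line:

```bash
heidi acquisition --setting B --out curve.csv
# setting B (alpha=0.7, beta=0.5): terminal R_CS=0.4958, R_US=0.3542
heidi within-trial --setting A --out profile.csv   # 6 blocks x 4 epochs, decay 0.81
heidi population --config examples/population.yaml --out-dir pop/
heidi simulate --config examples/subject.yaml --out-dir run/
heidi fit --observed run/trajectory.csv --config examples/subject.yaml --out fit.json
# alpha_hat=0.3000 beta_hat=0.5000 loss=7.985e-14
```

Population runs sample per-subject (α, β) from distributions on [0, 1],
emit Poisson response counts from r1/r4, and score each subject's bias
(goal − sign)/(goal + sign); negative bias classifies a sign-tracker
(ST), non-negative a goal-tracker (GT).

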