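# Methods

## Model and assumptions

The simulator is trial-based: associative change happens once per trial,
simultaneously for all directed pairs, computed from the pre-trial state.
For every ordered pair (i, j) with source i present,

    ΔV[i→j] = s_i · (c · s_j · 1[j present] − Σ_{k present} V[k→j]),

where s is α for CSs and β for USs. This single generalized rule
subsumes the forward (CS→US), backward (US→CS) and CS–CS learning
equations: the target's salience sets the asymptote (scaled by c) and
the source's salience the rate. The pooled error for a target sums only
the associations *from stimuli present on the trial*; associations from
absent stimuli neither contribute to the error nor change. A present
source with an absent target extinguishes toward zero (the asymptote
term is gated by target presence). All strengths start at zero — no
pre-training associations.

Performance is computed for each CS present on a trial, against the
trial's reference US, from the current (pre-update) state:
V_COMB = V_f + V_f·V_b/c, split into R_CS and R_US by the ratio of the
effective CS salience to |V_f|/c. Signed V values enter V_COMB as-is;
the absolute value appears only in the distribution weights, keeping the
proportions in [0, 1] when net strengths are negative. R_CS + R_US =
V_COMB holds exactly by construction; the suite checks it to 1e-12 on
10^4 random inputs. The response vector is
r_i = (R_CS·w_CS,i + R_US·w_US,i)/c for i = 1..6.

Closed form used as an independent oracle: under single-CS continuous
reinforcement, V_f(n) = c·β·(1−(1−α)^n) and V_b(n) = c·α·(1−(1−β)^n);
the iterative updates match these to 1e-12 per trial, and converge to
the asymptotes c·β and c·α.

## Within-trial dynamics

A trial is divided into n_epochs epochs (default 4, modelling a 10-s CS
in 2.5-s bins). CS salience decays multiplicatively per epoch —
α_eff(e) = α·d^(e−1), reset at each trial start — and the decayed values
drive the per-epoch R_CS/R_US split, while the *terminal* (last-epoch)
value of α drives learning, in both the rate and the backward-asymptote
role. The published protocol writes the decay as "α_CS(1 − 0.10)^2",
which is ambiguous between a per-epoch factor and an epoch-indexed
exponent; we read it as a constant per-epoch factor d = (1 − 0.10)^2 =
0.81, because that reproduces the monotone within-trial decline of R_CS
and rise of R_US in every block. d is exposed as a parameter
(`decay_per_epoch`); SubjectParams defaults to d = 1 (no decay), and the
within-trial reproduction command sets 0.81.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| α_CS | perceived CS salience; forward rate, backward asymptote | – | per subject, [0, 1] |
| β_US | perceived US salience; backward rate, forward asymptote | – | per subject, [0, 1] |
| c | maximum associative strength | V | 1 |
| decay_per_epoch | within-trial multiplicative α decay | – | 1 (protocol runs: 0.81) |
| n_epochs | epochs per trial | – | 4 (2.5 s each) |
| link matrix | w_CS,i, w_US,i for r1–r6 | – | (.9,.6,.3,.3,.2,.1) / (.3,.2,.1,.9,.6,.3) |
| count_scale k | Poisson responses per unit V per epoch record | 1/V | 20 |

The link weights are a convention, not an estimate: the source material
depicts the links only qualitatively (CS links dominate r1–r3, US links
r4–r6), so any weights honouring that ordering give the same qualitative
phenotype structure; they are fully configurable.

## Designs and the canonical settings

Builders produce acquisition, extinction, A+/B− discrimination with
reversal (strict alternation, A first; the published order is unstated),
compound (overshadowing) and seeded Bernoulli partial-reinforcement
designs. Blocks default to equal-size partitions; the block size for
block-structured runs defaults to 10 trials (the published simulations
state 6 blocks but not trials per block — the qualitative patterns are
insensitive to this choice, which is exposed as a parameter).

Four canonical salience settings are used throughout: A (α=.3, β=.5),
B (.7, .5), C (.5, .3), D (.5, .7). At c = 1 and asymptote, α > β gives
R_CS > R_US (B, C) and α < β the reverse (A, D): the response-form law.

## Population model and count emission

α and β are fixed within a subject and vary across subjects; defaults
sample both from Beta(2, 2) — overlapping, continuous distributions on
[0, 1] that yield a continuous bias distribution containing both
phenotypes, as observed in rat populations. Each subject owns an RNG
stream spawned from the master seed keyed by subject index, so subject
i's draws are invariant to population size.

The model maps V to response *vigor*, not to counts; to produce
count-like observables we add a Poisson emission layer (an explicit
artifact choice): per epoch record, sign counts ~ Poisson(k·max(r1, 0))
and goal counts ~ Poisson(k·max(r4, 0)), summed per block. Bias =
(goal − sign)/(goal + sign), undefined (NaN in tables, an error from
`bias_score`) at zero totals. Phenotype is classified on the final-block
bias: ST if bias < 0, GT otherwise (ties → GT, documented and tested); a
median-split alternative is available.

## Fitting

`fit_subject` recovers (α, β) for single-CS designs by an 11×11 grid on
[0.05, 0.95]² followed by bounded Nelder–Mead refinement (xatol 1e-6).
Default loss: summed squared error on R_CS and R_US per trial × epoch;
a Poisson negative log-likelihood on sign/goal counts (rates k·max(r,0),
k fixed) handles count data. c, decay and k are held fixed — they are
not jointly identifiable with (α, β) from one acquisition trajectory —
and an informational log message notes when a design contains no
nonreinforced trials (identifiability then rests on acquisition
curvature and the R split alone). Noiseless recovery is exact to ~1e-6
over a 5×5 grid of true values in [0.1, 0.9]²; with Poisson noise at
k = 20 over 100 four-epoch trials the median absolute error is ~0.01.

## Numerical and degenerate-input choices

- `distribute` with α_eff = 0 and V_f = 0 raises a degenerate-input
  error (0/0); the trial loop short-circuits V_COMB = 0 to R = (0, 0),
  so the first trial of training emits zeros rather than an error.
- z-transform uses the population-SD convention (ddof = 0) by default,
  with `ddof` exposed; standardization pools across block × epoch cells
  within each group × response type, putting sign and goal measures on
  one scale per group.
- Cross-block stability uses the Pearson correlation across subjects.
- Updates within a trial are simultaneous; there are no within-trial
  ordering effects.

## What the synthetic data do and do not emulate

The generator reproduces the *structure* of autoshaping experiments —
trial sequences, blocks, epochs, per-subject salience variation, count
noise — under the model's own assumptions. It does not emulate session
effects, satiety or motivational drift, lick/press microstructure,
attentional changes in α with experience, or real-time within-trial
dynamics beyond the fixed exponential salience decay. Passing tests
therefore show internal consistency with the model's equations and the
qualitative phenomena they imply (response-form law, within-trial
crossover, reversal asymmetry, phenotype continuity), not quantitative
fits to any empirical data set.

## Problem sizes

Asymptote checks run 500 trials; closed-form checks 100 trials × 25
salience pairs; pattern reproductions 20–60 trials; the recovery study a
5×5 grid with 20-trial noiseless and 100-trial noisy designs; population
analyses 40 subjects × 60 trials. These sizes are the package's standard
demonstration conditions and are parameters of the respective functions.

## Known limitations

- Compound-*test* performance (how R components combine across
  simultaneously present CSs at test) is out of scope; performance is
  reported per present CS.
- Fitting supports single-CS, single-US designs.
- Joint estimation of (α, β, k, c, d) is not attempted.
- No inferential statistics on synthetic outputs (means, SEMs and
  correlations only).
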