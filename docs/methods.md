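# Methods

## The model

The Linear Ballistic Accumulator (LBA) describes a two-alternative decision as
a race between two independent, deterministic accumulators.  For accumulator
$i$ on a given trial, evidence starts at $k_i \sim U[0, A]$, grows linearly at
rate $d_i \sim \mathcal N(v_i, sv)$, and triggers a response when it reaches
the boundary $b = A + B$ ($B > 0$).  The observed response time is the winning
accumulator's crossing time $(b - k_i)/d_i$ plus the non-decision time $t_0$.
The joint density of (choice, RT) is defective: the winner's first-passage
density times the loser's survivor function, integrating to that choice's
probability.  Closed forms for the first-passage density and CDF use the
standard normal pdf/cdf; z-scores are clipped at $\pm 38$ and log-likelihoods
floored at $-10^{10}$ so samplers remain movable.

A participant's parameter vector is $(A, b, v_\mathrm{true}, v_\mathrm{false},
sv, t_0)$, with one $sv$ shared by both accumulators.  Trials whose two
sampled drifts are both non-positive are redrawn by the simulator; the
likelihood is not renormalised for this (rare) event, and a configuration
flag allows renormalising instead — at the parameter ranges used here the
both-negative probability is below $10^{-3}$ and the approximation is
standard.

### Scale setting

The likelihood is exactly invariant under jointly rescaling $(A, B,
v_\mathrm{true}, v_\mathrm{false}, sv)$ by any $c > 0$, so the latent
evidence unit must be pinned.  Two policies are implemented:

* **classic** — $sv_i = 1$ for every participant (excluded from the free
  parameters);
* **new** — $sv_i$ free per participant, with the population-mean hyper-prior
  $\mathrm{Mu}_{sv} \sim$ Beta$(1,1)$ remapped to $[0.999, 1.001]$, i.e. a
  near-degenerate uniform.  This de facto fixes the population mean of $sv$
  at $\approx 1$ (one evidence unit $=$ the population-level $sv$) while
  leaving individual and group differences in $sv$ estimable.  It is
  implemented as a genuine bounded prior that is actually sampled, not as a
  hard constant.

### Hierarchy and priors

Individual parameters follow truncated-normal population distributions,
$p_i \sim \mathcal N(\mathrm{Mu}_p, \mathrm{Sigma}_p)$ truncated below at 0;
$\mathrm{Sigma}_p \sim$ Beta$(1,1)$ remapped to $[0,3]$ (uninformative);
$\mathrm{Mu}_p \sim \mathcal N(\text{prior mean}, 1)$ truncated below at 0
for non-$sv$ parameters.  In addition, each participant's parameters carry
individual-level *base priors*: truncated normals centred at the same prior
means with SDs equal to the generating population SDs (0.6 for $A$ and $B$,
0.8 for the drift means, 0.4 for $sv$, 0.1 for $t_0$; the $sv$ base prior is
centred at the scale value 1).  The base priors matter structurally: because
of the rescaling invariance above, the data constrain only ratios of a
participant's scale parameters, and without an absolute individual-level
density each participant's scale is pinned only loosely through the
hierarchy.  With base priors the absolute scale is anchored per participant,
at the cost of shrinking weakly-informed parameters (chiefly
$v_\mathrm{false}$, which only error trials inform directly) toward a common
centre — visible as its much lower ICC(2,1).

The boundary is parameterised through the gap $B$ ($b = A + B$), so $b > A$
holds by construction; strictly positive parameters ($A$, $B$, $sv$, $t_0$)
are sampled on the log scale with the Jacobian included, while the hierarchy
is defined on the natural scale.

## Sampling

Posterior sampling uses blocked differential-evolution MCMC with (by
convention) three interacting chains per free parameter.  Each iteration
updates, per participant, that participant's full vector conditional on the
chain's hyper state, using crossover proposals
$x^* = x + \gamma\,(x_{r_1} - x_{r_2}) + \epsilon$ with
$\gamma = 2.38/\sqrt{2d}$, a small uniform jitter
$\epsilon \sim U(\pm 10^{-3})$, and an occasional $\gamma = 1$ proposal
(probability 0.1) for mode jumping.  During burn-in, blocks occasionally
migrate (cyclic state swaps among a random chain subset, each accepted by
Metropolis) to recover outlier chains.

The hyper conditionals factorise per parameter, so the hyper state is
updated as independent 2-d $(\mathrm{Mu}_p, \mathrm{Sigma}_p)$ blocks rather
than one joint block — a joint 12-d DE block mixes at below 1% acceptance
while the 2-d blocks sit near 20%.  Because hyper updates cost no likelihood
evaluations, three hyper sweeps run per iteration; this keeps the tight
hyper conditionals mixing in step with the individual blocks and was the
difference between 0/20 and 20/20 participants converging at desk scale.

Defaults follow the full-scale convention: burn-in 1,000, then 12,000
iterations thinned by 12 (1,000 kept per chain).  Convergence is assessed
per participant by the worst-case Gelman-Rubin PSRF over that participant's
free parameters, computed on kept draws without chain splitting; participants
with PSRF $\ge$ 1.1 are excluded from all recovery statistics.  The classic
(non-split) variant can dip marginally below 1 by sampling noise.

## Synthetic cohorts

Individual true parameters are drawn from normal distributions around the
population means with SDs 0.6 ($A$, $B$), 0.8 (drift means) and 0.4 ($sv$),
then corrected: floors of 0.05 on $A$, $B$ and $v_\mathrm{false}$, 1.3 on
$v_\mathrm{true}$, 0.01 on $sv$; then, if $v_\mathrm{true} - v_\mathrm{false}
< 0.2$, $v_\mathrm{false} := v_\mathrm{true} - 0.2$ unconditionally (the
replacement may undercut the floor; floors are applied first).  $t_0$ is a
constant 0.3 s and its recovery is never scored.  One master seed spawns one
substream per participant, so cohorts extend without reshuffling.

Table interpretation: the boundary column of the 21-configuration grid is
read as the gap $B$ (2.3/2.5/2.7), with $b = A + B$.  Under the alternative
reading ($b$ absolute, independently drawn), roughly a quarter of draws
would violate $b > A$ with no stated repair rule, so the gap reading is the
one under which the stated correction rules are complete.

The two-group design draws 50 (or, at desk scale, 15) participants per group
with $sv$ means 1.5 vs 0.5 and all other means shared ($A=2$, $B=2.5$,
$v_\mathrm{true}=2.5$, $v_\mathrm{false}=0.8$, $t_0=0.3$).

For *classic-policy recovery studies* the generating cohort sets $sv = 1$
exactly (generation-matched recovery: a fixed-$sv$ model has no
heterogeneous $sv$ to recover).  The two-group comparison instead fits both
policies to the *same* heterogeneous data — that misspecification is the
phenomenon under study.

### Prior-mean noise

Recovery-study prior means are the generating means perturbed by
$\mathcal N(0, 0.1)$ noise; the two-group design instead draws them
uniformly within $\pm 2$ standard errors of the truth, SE $=$ generating SD
$/\sqrt{n_\text{group}}$ (the group $n$, 50 at full scale, is used; a config
override exists because the convention is ambiguous).

## Scoring

Recovery is scored on $(A, b, v_\mathrm{true}, v_\mathrm{false}, sv)$ after
PSRF exclusion: Pearson $r$ (relative stability) and ICC(2,1) (two-way
random effects, single measures, absolute agreement; Shrout-Fleiss $F$-based
$p$ and CI).  Estimates are posterior means pooled over chains and kept
iterations.  Correlations aggregate across configurations through Fisher's
$Z$; ranges are min/max over per-configuration values.  Model fit uses the
deviance information criterion per participant
($\mathrm{DIC} = \bar D + p_D$, $p_D = \bar D - D(\bar\theta)$ at the
posterior-mean parameters), summed over the participants retained under both
policies.  Group differences use pooled-variance two-sample $t$-tests
(df $= n_1 + n_2 - 2$), $\alpha = 0.05$ two-sided, no multiple-testing
correction.

## Problem sizes

Two presets ship.  **full** is the original design: 21 configurations
$\times$ 100 participants $\times$ 1,000 trials, full sampler settings —
hours per fit on one CPU, run via the CLI.  **desk** is the package's
scaled-down working size: 20 participants $\times$ 300 trials (two groups of
15 for the group design), burn-in 500, 3,000 iterations thinned by 3, and
$t_0$ held at its generating constant.  The desk $t_0$ policy is deliberate:
with every true $t_0$ identical, $\mathrm{Sigma}_{t_0}$ collapses toward
zero and produces a funnel that desk-length chains cannot traverse (0/10 vs
9/10 participants converging in matched runs); since $t_0$ recovery is never
scored, desk runs fix it.  Full-scale fits keep $t_0$ free.

## What the synthetic data do and do not show

The generator reproduces the stated generating process exactly (normal
individual effects with floors and the drift-gap replacement, constant
$t_0$, uncontaminated LBA trials).  It does not emulate real data features —
contaminant responses, within-trial drift noise, parameter correlations,
condition effects, RT censoring — so passing recovery checks demonstrates
internal consistency of model, sampler and scoring under the model's own
assumptions, not robustness on empirical data.

At desk scale, recovery quality differs from full-scale behaviour in one
respect worth knowing.  The generating spread of
$v_\mathrm{false}$ is very large relative to its mean (SD 0.8 around
0.6-1.0, with floor and replacement corrections), so even heavily shrunken
estimates preserve participant ordering and its correlations rank among the
*best* parameters here, whereas scale-dependent parameters with small
relative spread ($A$, $b$, $v_\mathrm{true}$) are attenuated by residual
per-participant scale uncertainty — at 20 participants a single cohort can
put $v_\mathrm{true}$'s $r$ anywhere between roughly 0.55 and 0.9.  This is
a property of the scaled-down conditions and of this package's prior
choices, and it is reported as measured.

## Known limitations

* Two accumulators only; no DDM-style within-trial noise.
* DIC is reported knowing its limits for hierarchical latent-parameter
  models; no WAIC/LOO.
* The near-degenerate $\mathrm{Mu}_{sv}$ prior is sampled, so its chain
  variance is tiny by construction; PSRF for that hyper-parameter is
  uninformative.
* Desk-scale results are seed-noisy at $n = 20$; single-cohort correlations
  carry sampling error of roughly $\pm 0.15$.
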