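# Methods

## Allometry equations

The height–diameter relationship is modelled by the saturating pair

```
H = H0 + exp(a + d/(b + D))        (height from diameter)
D = d/(a − ln(H − H0)) − b         (diameter from height)
```

`H0` is the stem height at the first measurement; `a` sets the late-stage
asymptote `H0 + e^a`; `b` shifts the early-stage behaviour; `d` is a relative
rate that spreads the curve along the predictor axis.  The two forms are
exact algebraic inverses under `d_H←D = −d_D←H` with `a` and `b` shared
(property-tested to 1e−9 relative).  In the height-from-diameter direction
`d < 0` yields curves that increase with diameter.

Fitting is multi-start Nelder–Mead on the residual sum of squares (five
jittered, seeded starts; domain violations receive a large finite penalty so
the simplex walks back).  Model comparison uses `AIC = n ln(rss/n) + 2k`
against power-law and straight-line comparators, ties broken toward fewer
parameters; a failed candidate is reported with `AIC = +inf`, never dropped.

## Functional-mapping likelihood

Residual vectors are scored under a stationary AR(1) Gaussian model
(`Σ(s,t) = σ²ρ^|s−t|`).  The density uses the closed forms
`|Σ| = σ^2T (1−ρ²)^{T−1}` and the tridiagonal inverse, written in innovation
form, so one evaluation is O(T); individuals with missing occasions
contribute their observed sub-vector, which for an AR(1) process is still
Markov with lag correlations `ρ^gap`.  σ² is profiled analytically (its
conditional MLE is the mean quadratic form), leaving per-genotype (a, b, d)
triples and ρ free.

Maximisation is blockwise coordinate ascent: with ρ fixed the genotype
classes decouple and each triple is updated by a three-parameter simplex;
ρ is then re-profiled by a bounded scalar search.  Both steps are monotone in
the profiled likelihood, so the alternative fit warm-started at the null
optimum can never fall below it — LR ≥ 0 holds structurally, not by luck.
The LR statistic is referred to χ² with 3(J−1) df: only the allometry triple
is genotype-specific; baselines are data and the AR(1) pair is shared.

Two conventions worth noting:

* the per-individual baseline `h0` is the first height observation; the
  baseline occasion itself is excluded from the likelihood in both scan
  directions (as a response it equals the baseline by construction, as a
  predictor it sits on the boundary of the log domain);
* occasions where noise pushes a height below an individual's baseline are
  masked in the diameter-from-height direction and handled by the sub-vector
  likelihood.

Multiplicity control is Bonferroni within cross type (testcross and
intercross markers get separate genome-wide thresholds), with a combined
single-threshold option.

Genetic-effect curves average the fitted genotype-specific equation over the
individuals of each genotype at their observed predictor values.  Testcross:
effect = class difference.  Intercross: additive = homozygote − heterozygote,
dominant = heterozygote − mean of homozygotes; the additive curve represents
three-class QTLs in the network stage.

## ODE network reconstruction

Each QTL's effect curve P_k(t) is modelled as

```
dP_k/dt = U_k(P_k) + Σ_{k'≠k} U_kk'(P_k')
```

with every U a Legendre expansion of order r in its own argument, rescaled to
[−1, 1] over the argument's observed range.  Defaults and the reasons behind
them:

* **Basis order r = 2.**  The independent term is expanded in the focal
  curve's own values, and effect curves are usually monotone in time — so a
  high-order U_k can represent almost *any* smooth time course and silently
  absorb the regulator signal.  Measured on the simulated system, an order-4
  self term reduces the drive signal remaining after self-projection by three
  to four orders of magnitude; order 2 (which also matches the logistic
  complexity class of the simulated independent terms) is the default, and r
  is a parameter everywhere.
* **Constant terms live in U_k only**, and every dependent function is
  anchored at the regulator's initial level (`U_kk'(P_k'(t1)) = 0`).  Without
  the anchor the constant part of a dependent effect migrates into the
  independent term and every recovered dependent curve is shifted; with it,
  the zero-noise decomposition of the simulated system is exact
  (correlation 1.0 with truth, 18/18 edge signs).
* **Smoothing** before differentiation and basis construction is a cubic
  least-squares spline with four interior knots (effective df ≈ 8),
  differentiated analytically.  The complexity is fixed, not GCV-tuned:
  effect-curve residuals are serially correlated and GCV interprets that
  correlation as signal, undersmoothing exactly when sampling is dense.
* **Regulator selection** is greedy group-forward selection: starting from
  the unpenalised self model, the candidate whose r basis columns most reduce
  the rss of the differentiated focal curve is added with full refitting
  (this finds regulators whose relevance is conditional on a partner, which
  penalty-path entry misses); the kept size minimises an extended BIC with an
  in-degree cap of 3 (the simulated truth's mean in-degree is 1.3, and the
  real networks the model targets are sparse).  A proximal-gradient group
  lasso over a 20-point penalty path with BIC refitting is available as
  `method="lasso"`.
* **ODE refinement** minimises the squared distance between the observed
  curve and the RK4 solution started at the first observation, regulators
  held at their observed (linearly interpolated) values — so focal QTLs
  decouple.  Two seeded starts are used: a free gradient-matching regression
  and one with the initial rate pinned to the observed first derivative.  The
  pin matters for curves that take off from near an equilibrium, where a tiny
  intercept error shifts the fitted onset by several occasions and strands
  the optimiser in a local minimum.
* **Decomposition additivity is exact by construction**: the RK4 stage
  evaluations of the self and dependent terms are accumulated separately with
  the same quadrature weights, so independent + Σ dependent + P(t1)
  reproduces the fitted trajectory to machine precision.

Edge sign is the sign of the dependent curve's time average (area comparison
on an exact tie, "+" if still tied); edge weight is the mean absolute drive
`|U_kk'(P_k'(t))|`; pair labels follow the six-category
activation/neutrality/repression scheme; hubs are nodes whose total degree
exceeds the network mean.  Networks are inferred separately for piQTLs,
miQTLs, or any pooled curve set the caller passes.

## Synthetic mapping populations

Diameter grows logistically per individual (asymptote ≈ 12 mm, biweekly
occasions) with jittered rate and midpoint plus a small AR(1) measurement
residual, and height follows the allometry equation of the *observed*
diameter plus AR(1) noise — so the generated data match the likelihood's
structure exactly in the height direction while the diameter direction stays
mechanistic, mirroring real data where the two scans are informative but not
symmetric.  A planted piQTL makes (a, b, d) genotype-specific (default: a
shift in `a`, which moves the late-stage asymptote); a planted miQTL
regenerates diameters from heights through the reverse equation.  Testcross
markers segregate 1:1, intercross 1:2:1, unlinked.  Defaults (n = 180,
T = 12, baseline a = 4, b = 1, d = −18, noise sd 1 cm ≈ 5% of the ~20 cm
seasonal height gain) are sized to a typical full-sib shoot-growth trial.
What these populations do **not** emulate: linkage between markers,
errors-in-variables in the predictor trait, year effects, and selective
genotyping — power estimates here are for idealised unlinked markers.

## Network-recovery simulation study

The ground-truth system has 14 QTLs and 18 directed edges (hub Q2 with
in-degree zero, plus secondary regulators Q10 and Q13).  True independent
terms are logistic with rates 1.5–2.5 and capacities 2–4; true dependent
terms are linear with signed magnitudes 0.15–0.35; initial values place each
node's logistic midpoint on an evenly staggered grid across the season
(seeded random assignment).  The staggering is deliberate: when onsets clump,
all curves driven by the same hub become nearly collinear and *no* selection
statistic can attribute edges — the even grid is the regime in which
directed-edge recovery is informative at all.  Draws under which the coupled
system leaves [−20, 20] or stays below 1.5 in magnitude are redrawn (seeded,
logged).  Scenarios cross T ∈ {10, 30} with residual variance
ν² ∈ {0.05, 0.5} (AR(1), ρ = 0.5 by default); per replicate the selection
pipeline is run on all 14 curves and scored on directed presence:
TPR = TP/18, FPR = FP/164, and ROC-AUC from the forward-path gain scores.
Default 100 replicates (30 in the acceptance script, which keeps a from-
scratch run of all four scenarios under a minute); the report prints
mean (sd).

### What recovery levels are achievable, and why

Directed-edge recovery in this model class has a structural identifiability
ceiling that the study makes explicit rather than hiding:

1. A one-dimensional autonomous independent term forces every drive-free
   trajectory to be monotone, and any smooth function of a monotone curve can
   imitate any monotone drive — the self term absorbs regulator signals.
2. Every co-target of the hub carries the hub's signal, so candidate curves
   are mutually collinear by construction of the topology.

Concretely: given *perfectly denoised* curves, the pipeline reaches AUC ≈ 0.9
on this system, but the residual-sum-of-squares margins that separate a true
regulator from its best imposter are one to two orders of magnitude smaller
than the rss fluctuations induced by even the low-noise scenario.  The
operating levels the study reports honestly (best scenario TPR ≈ 0.32,
AUC ≈ 0.55 at 30 replicates) are therefore far below a naive reading of what
such a pipeline "should" achieve; what *is* robust, and what the acceptance
checks assert strictly, is the qualitative structure: recovery improves with
more occasions and with less noise, and the worst-noise short-series scenario
sits at chance-level AUC.  Component recovery with the topology known is
exact at zero noise; under noise the self/dependent split along
near-degenerate directions remains noise-driven for weakly coupled edges.

## Numerical conventions

* All randomness flows from a single integer seed per entry point
  (`numpy.random.SeedSequence` spawning for replicates); identical seeds give
  bit-identical outputs, including CLI files.
* RK4 uses 4 substeps per observation interval; halving the step changes
  fitted trajectories by < 1e−6 (tested).  Blow-ups during optimisation are
  clipped and penalised with large finite residuals, never NaN.
* Degenerate inputs: constant response curves fit with d ≈ 0; monomorphic or
  under-replicated markers are skipped with a recorded reason; an all-skipped
  scan raises; empty networks export a header-only edge list and have no
  hubs.
* Output files are UTF-8 TSV with `NA` for missing values and `#` header
  lines carrying the tool version, seed and a config hash.
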