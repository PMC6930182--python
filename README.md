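# allonet

Functional mapping of **height–diameter allometry QTLs** and reconstruction of
signed, weighted, directed **QTL–QTL control networks** from longitudinal
shoot-growth data in full-sib tree families.

## The problem

As a tree shoot grows, height (primary growth) and basal diameter (secondary
growth) change together: how much height is gained per unit of diameter
growth is a developmental strategy with its own genetic control.  `allonet`
maps two kinds of loci in a full-sib family measured repeatedly over a season:

* **piQTLs** ("pioneering") — loci whose genotypes differ in how height
  growth scales with diameter growth;
* **miQTLs** ("maintaining") — loci whose genotypes differ in how diameter
  growth scales with height growth;

and then asks how the detected QTLs regulate *each other*, by decomposing each
QTL's time-varying genetic-effect curve into an independent part and
regulator-driven parts through a system of ordinary differential equations.

## The model

Height–diameter allometry is described by a saturating equation read in
either direction (mutually inverse under `d_H←D = −d_D←H`):

```
H(t) = H0 + exp(a + d / (b + D(t)))          D(t) = d / (a − ln(H(t) − H0)) − b
```

Functional mapping embeds these equations in a multivariate-normal likelihood:
for a SNP with genotype classes *j* = 1..J, the expected height of individual
*i* at occasion *t* is the genotype-specific equation evaluated at that
individual's **observed** co-trait value, and residual vectors have a
stationary AR(1) covariance `σ²ρ^|s−t|` (closed-form determinant and
tridiagonal inverse, so the likelihood is O(T)).  A likelihood-ratio statistic
comparing one shared (a, b, d) triple against J genotype-specific triples is
referred to χ² with 3(J−1) df, with Bonferroni thresholds per cross type
(testcross / intercross).

For each QTL *k* the genetic-effect curve P_k(t) (difference of genotype mean
curves; additive effect for intercross QTLs) obeys

```
dP_k/dt = U_k(P_k(t)) + Σ_{k'≠k} U_kk'(P_k'(t))
```

where each U is a Legendre polynomial expansion in its own argument.
Regulators are chosen per focal QTL by greedy group-forward selection with an
extended-BIC stop (a group-lasso path backend is also provided); the selected
system is then refined by 4th-order Runge–Kutta trajectory least squares, and
the fitted trajectory splits exactly into an independent curve plus one
dependent curve per regulator.  Edges carry a sign (time-average of the
dependent curve), a weight (mean absolute drive), the six-category
activation/neutrality/repression pair labels, and hub flags (total degree
above the network mean).

## Worked example

Everything runs from synthetic data — no download needed:

```
allonet simulate-pop --n 60 --t 8 --markers 5 --causal-index 1 --seed 4 --out run
allonet scan --phenotypes run/phenotypes.tsv --markers run/markers.tsv \
        --direction pi --seed 0 --out run
```

which prints

```
wrote run/phenotypes.tsv and markers.tsv (60 individuals, 8 occasions, 5 markers)
PI: 1 significant of 5 tested markers
```

— the planted testcross piQTL (marker `m0002`) is the one marker passing the
per-type Bonferroni threshold; `run/scan_pi.tsv` holds LR, df, p and the
genotype-specific (a, b, d) estimates per marker and `run/manhattan_pi.tsv`
the −log10(p) export.  Effect curves and a network follow with

```
allonet effects --phenotypes run/phenotypes.tsv --markers run/markers.tsv \
        --direction pi --marker-id m0001 --marker-id m0002 --marker-id m0003 \
        --seed 0 --out run/curves.tsv
allonet network --curves run/curves.tsv --seed 0 --out run/net
```

The simulation study of network recovery (14 QTLs, 18 true directed edges,
hub Q2; four scenarios crossing T ∈ {10, 30} with residual variance
ν² ∈ {0.05, 0.5}) runs as

```
allonet simstudy --replicates 100 --seed 1 --out study
```

and writes `study/table1.tsv` with mean (sd) TP, FP, TPR, FPR and ROC-AUC per
scenario.

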