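# Methods

`calorimix` analyses serial-passage batch cultures of small defined gut
consortia monitored by isothermal microcalorimetry (IMC), and ships a
consumer-resource simulator that generates every input the analysis consumes.
This note documents the models, the numerical choices, and what the synthetic
study design does and does not establish.

## The community growth model

Batch growth of strains $i = 1..n$ on a shared metabolite pool $S_k$ follows
Monod kinetics with additive substrate terms:

$$\frac{dX_i}{dt} = \mu_i(S)\,X_i,\qquad
  \mu_i(S) = \min\Big(\sum_k \mu^{max}_{ik}\frac{S_k}{K_{ik}+S_k},\ \max_k \mu^{max}_{ik}\Big)$$

after a per-strain lag. The cap at the largest single-substrate rate prevents
unbounded stacking of substrate terms and produces diauxie-like behaviour
without an explicit catabolite-repression model: while a preferred substrate
lasts, growth runs at its ceiling; when it is exhausted the rate falls to the
sum of the remaining terms. A strain's observed phase rates are therefore
partial sums of its substrate terms — e.g. a strain with terms
0.88 / 0.13 / 0.07 h⁻¹ shows phases at 0.88, 0.20 and 0.07 h⁻¹.

Substrate consumption is growth-coupled, $dS_k/dt = -\sum_i r_{ik} X_i / Y^X_{ik}$
(with $r_{ik}$ the cap-rescaled contribution of substrate $k$), and products
are formed stoichiometrically via $Y^P$. Products and substrates share one
concentration pool, so cross-feeding (acetate excreted by the mucin degraders
and consumed by the butyrate producer) emerges from the stoichiometry alone.

Heat release is growth-associated only: strain $i$'s heat flow is
$P_i = Y_Q\, (dX_i/dt)\, V$ and its cumulative heat is exactly
$Q_i = Y_Q (X_i - X_i(0)) V$. We deliberately omit a maintenance term: the
cumulative heat is then strictly proportional to the biomass increment, which
is the empirical premise that justifies calorimetric growth-rate estimation in
the first place, and which `check_heat_biomass_linearity` verifies on data.
A maintenance term would add a biomass-proportional heat flow and break the
exactness of the phase-rate equality `d ln P/dt = mu`; it can be emulated by
adding a slow "maintenance substrate" if ever needed.

Integration uses LSODA with relative tolerance 1e-8 (absolute 1e-12), split
at lag times so the right-hand side is smooth per segment, with dense output
evaluated on the user grid. Concentrations are clipped at zero inside the
Monod terms. Non-finite states raise an error naming the first bad time.

Serial passaging transfers 1% v/v into fresh medium each passage; a
per-strain dilution at passage 1 reproduces under-inoculation (resilience)
experiments. Adaptation of freezer stocks is modelled as multiplicative
offsets on lag and maximum rates decaying geometrically per passage, reaching
1% of the initial offset at a configurable convergence passage.

## Rate estimation and phase segmentation

Under growth-associated heat release, $\ln P(t)$ has slope $\mu$ during any
balanced exponential phase, at all times. The default estimator fits
ln(heat flow); the classical ln(total heat) formulation is available as
`"heat-log"` and converges to the same slope but overestimates it early,
when $Q = (A/\mu)(e^{\mu t}-1)$ is still dominated by its linear term.

Polyphasic curves are segmented by exact dynamic-programming piecewise-linear
regression on $\ln P$ (smoothed by a centered 5-point moving median), with
the segment count selected by BIC (penalty $\ln n$ per extra parameter;
slope, intercept and breakpoint each count). Numerical choices that matter:

- **Signal floor.** Log fits exclude points below 3x the baseline-window SD
  and below 10⁻³ of the peak power: the near-zero tail after substrate
  exhaustion would otherwise dominate the log-scale SSE.
- **Transition segments.** At a substrate switch the heat flow *drops*, so
  $\ln P$ contains short steep steps between phases (and a terminal decay).
  The DP searches up to $2k_{max}+1$ segments so each step can occupy its own
  short segment; segments shorter than `min_duration` (default 0.5 h) are
  treated as transitions and removed rather than merged, because merging a
  step into a neighbouring phase biases that phase's slope.
- **Rate-similarity merge.** Adjacent segments whose slopes agree within 20%
  are merged: diauxic phases differ severalfold in rate, while BIC on
  low-noise data will happily split one exponential into statistically
  distinguishable but scientifically identical pieces.
- **BIC floor.** The per-point residual variance is floored at (10⁻⁶)² on the
  ln scale so that noiseless synthetic data cannot drive the likelihood term
  to $-\infty$ and defeat the penalty.
- **Ties** in the DP resolve to the earliest breakpoint (first argmin).

## Composition and heat deconvolution

Reads are divided by 16S rRNA gene copy numbers (3/5/6 for
*A. muciniphila* / *B. thetaiotaomicron* / *F. prausnitzii*) before computing
relative abundances. Consortium heat is partitioned as
$Q_i = Q_{tot}\, w_i a_i / \sum_j w_j a_j$ with abundances interpolated
linearly in fraction space and renormalized to the simplex (linear
interpolation can leave it); the partition is conservative by construction.
Equal heat yield per gDW across strains ($w_i = 1$) is the default —
partitioning heat by abundance implicitly assumes it — with per-strain
weights exposed for sensitivity analysis. Per-strain power is the time
derivative of the reconstructed heat.

Limitation: with hourly abundance sampling the reconstruction error
concentrates at moments of fast composition change (the mucin-exhaustion
hour) and minority-strain phases shorter than ~3 h are unresolvable. In the
packaged consortium, AM's and BT's first-phase rates are recoverable by
segmentation (within ~10%), while FP's sub-3 h first phase is not; FP's long
acetate-to-butyrate phase is recovered by a windowed fit instead. Abundances
sampled at 0.25 h bring the reconstruction within 5% of the true per-strain
heat throughout growth.

## Stability and resilience detection

Each ampoule's heat-flow trace over a common grid is one row of a matrix;
PCA runs on centered, unit-variance-scaled columns (zero-variance columns
dropped; component signs fixed so the largest-magnitude loading is positive).
Stability is judged in the first two PCs: with within-passage dispersion
$d_w$ (pooled mean replicate-to-centroid distance), the stable passage is the
first from which every later consecutive-passage centroid shift is at most
$k\,d_w$, default $k = 1.5$. Resilience projects the perturbed passages with
the *reference* loadings and reports the first passage whose centroid falls
within $k\,d_w$ of the reference stable-region centroid; composition recovery
is checked separately (default 5% absolute per strain).

A caution that shaped the synthetic design: with $n$ replicates of purely
independent noise, the expected noise-induced centroid shift *equals* $d_w$
(both are ~$\sigma\sqrt{2/n}$ statistics), so at $n = 3$ a fixed multiplier
like $k = 1.5$ is only ~1.5x the mean and single shifts exceed it often.
Real replicate ampoules are persistent lineages — parallel passage series
with reproducible offsets — and modelling them that way makes $d_w$ a stable
lineage spread and the detection deterministic. The clean-room unit test of
the criterion uses more replicates instead.

## Metabolite exchange

Endpoint deltas (end − start, mmol/L) are summarized per replicate. The
no-interaction null for a consortium is the *stack* of its monocultures;
we sum per replicate index rather than summing means, which reproduces the
stacked means exactly while retaining a replicate-level variance for the
two-sided equal-variance Student's t-test (stars: * p<0.05, ** p<0.01,
*** p<0.001; no multiple-testing correction by default, Benjamini–Hochberg
is a one-liner away in statsmodels if wanted). Zero-variance degenerate
cases are explicit: identical groups give t=0, p=1; separated constant
groups are reported as p→0. Exchange rates for constraint-based modeling
are $q = (\Delta C / X)\,\mu$ in mmol gDW⁻¹ h⁻¹ (negative = consumption);
the OD600→gDW factor defaults to 0.4 gDW/L per OD unit and is configurable,
since endpoint biomass is usually recorded as OD.

## Constraint-based analysis

The GEM layer stores S, bounds, one biomass objective and an
exchange-reaction registry (single-metabolite reactions; negative flux =
uptake). FBA/FVA/sampling solve LPs with HiGHS at 1e-10 feasibility
tolerances. Depletion screens close one uptake at a time and classify
substrates as essential (predicted growth < 10⁻⁶), limiting (< 95% of the
reference optimum) or dispensable; solver failures are recorded per row and
never abort a screen. "n samples at 90% of the optimum" is implemented as
random-objective vertex sampling (directions uniform on the unit sphere)
inside the fraction-optimal polytope, with exact min/max FVA exposed
separately. Because optima are degenerate, only objective values, FVA
intervals and sampled statistics are asserted anywhere — never a specific
vertex. Toy models (3–12 reactions) encode the qualitative essentiality
patterns of the three strains (am_like: three essential inputs; bt_like:
two limiting pools, sugars redundant; fp_like: three essential inputs plus
a redundant energy pool).

## The synthetic study design

The packaged fixtures emulate the consortium study: 2 mL ampoules, 24 h
passages at 1% v/v, 3 replicate lineages, 7 passages, hourly 16S sampling at
depth 10⁵, endpoint metabolite noise 0.1 mmol/L, additive instrument noise
5·10⁻⁴ of peak power. The medium is a stylized YCFAM: a shared mucin-glycan
pool (AM fast, BT slow), a peptide pool (BT), a slow polysaccharide (BT), two
private FP pools and acetate. Pool sizes, yields (0.01–0.016 gDW/mmol,
anaerobic range) and heat yield (20 kJ/gDW for all strains) were chosen once
so that:

- noiseless monoculture segmentation returns the designed phase rates
  (0.57; 0.88/0.20/0.07; 1.00/0.21/0.09 h⁻¹) within their reported SDs;
- the drift schedules converge at the designed passages (consortium 3,
  AM 4, BT 2, FP 2) and the PCA detector reports exactly those counts,
  robustly across seeds;
- 100-fold under-inoculation of AM — the specialist on the shared mucin
  pool — recovers slowest (heat recovery at passage 5, composition within 2%
  by passage 5), strictly later than the BT scenario, because a rare AM must
  re-invade a pool a large BT population is draining;
- consortium butyrate exceeds the producer's monoculture level
  (acetate limitation in monoculture, abundance in the consortium).

What passing these tests shows: the estimators recover known ground truth
through the full pipeline (ODE → heat → noise → reads → analysis) at
realistic magnitudes. What it does not show: performance on real IMC data
with baseline drift regimes, pH feedback, maintenance heat, strain
interactions beyond resource competition and cross-feeding, or amplicon
biases beyond copy number — none of which the generator emulates. The
simulator's own steady-state composition (BT 51 / AM 25 / FP 23%) reproduces
the dominance ordering but not the exact measured proportions; composition
round-trip checks therefore sample from the measured proportions directly.

## Problem sizes

Defaults keep every analysis interactive: ODE grids of 0.02–0.05 h over
24 h, PCA grids of 241 points, 84 simulated ampoule-passages for a full
stability suite (~15 s), 50-network LP-vs-enumeration checks and
2000-vertex flux sampling (~5 s each).
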