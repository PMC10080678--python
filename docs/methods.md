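# Methods

This note describes the models and procedures implemented in
`formose_dyn`, the choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Input programs

The environmental input is a stepwise-constant CaCl2 inlet
concentration. Step values are independent draws from N(mean, sigma^2)
— mean 15 mM; sigma 0, 2.89 or 5.75 mM; step intervals 30–120 s —
truncated at zero (at mean 15 mM, sigma 5.75 mM about 0.5% of draws are
clipped; the count is recorded on the signal). Multi-timescale inputs
superimpose three independently drawn components (30, 60, 120 s by
default) with equal weights on the finest grid and affinely rescale the
sum back to the target mean and SD; the rescaling is applied to the raw
sum, and clipping at zero afterwards perturbs the realised SD by ~1%.

Concentration programs become five-channel volumetric flow schedules
for a 411 uL CSTR at 120 s residence time: formaldehyde and DHA run at
fixed fractions of the total flow V/tau, the CaCl2 channel tracks the
signal, NaOH is slaved to twice the Ca inlet concentration (the fixed
1:2 Ca2+:HO- ratio), and a water channel absorbs the remainder so the
total flow — and hence the residence time — is constant to 1e-9
relative at every step. A step whose draw would drive the water channel
negative (above ~29.7 mM Ca at 50 mM formaldehyde inlet) is clipped
jointly in Ca and NaOH, preserving the 1:2 ratio; infeasibility at the
*mean* is a configuration error instead. Step signals are left-closed /
right-open in seconds from the program start, and each program carries
a 30-minute equilibration prefix before the sampling window
(configurable).

## Reactor model

Concentrations obey the CSTR mass balance

    dC_i/dt = (C_in,i(t) − C_i)/tau + Σ_r nu_ir · rate_r(C, ca)

with mass-action kinetics and a power-law catalyst modulation:
a reaction with sensitivity s runs at `k · (ca / ca_ref)^s`,
ca_ref = 15 mM. The catalyst proxy `ca` is carried as a non-consumed
species with its own mass balance, so the reactor itself low-pass
filters the applied input with time constant tau = 120 s before any
chemistry responds; this is deliberate — the analyses must see the
reactor-filtered signal, not the raw program. Whether catalysis scales
with Ca2+, OH−, or their product is not resolved by the power-law
proxy; it is a modelling choice, and the sensitivities are effective
exponents, not elementary rate laws.

Integration is segment-wise between flow-program step boundaries
(LSODA, rtol 1e-8, atol 1e-10 by default), so step discontinuities are
never smoothed across. Output is evaluated on a 2-s grid by default.
Concentrations are clamped at zero only within solver tolerance
(excursions beyond 1e-6 mM abort the run). With a constant input the
integrator reaches the algebraic steady state (right-hand-side residual
< 1e-8 mM/s beyond ~50 residence times), and with no reactions it
reproduces the washout closed forms to 1e-6 relative.

## The synthetic network

No rate constants for the real reaction network are published, so the
generator's kinetics are schematic by construction. The design goal was
not quantitative prediction but *structure*: a network in which
environmental fluctuations transfer non-uniformly, producing five
groups of compounds with collective, distinguishable responses.

The engine is a Breslow-type autocatalytic cycle — formaldehyde (C1) +
glycolaldehyde (G2) -> glyceraldehyde (G3) -> tetrose pool (T4/K4 and
isomers) -> 2x G2 by retro-aldol — fed by 50 mM formaldehyde and 50 mM
DHA (entering via triose isomerisation). The engine species themselves
are treated as unmeasured; the 28 measured compounds form five families
("modules"), each downstream of gating steps that stamp a family-wide
temporal signature:

* **core (I)** — reversible aldol adducts Q4–Q6 of the glycolaldehyde
  pool: positive, fast tracking of the catalyst.
* **II** — C8 ketoses M8a–e from glycolaldehyde addition to a slow
  off-cycle hexose pool that is drained by catalysed retro-aldol
  (sensitivity 2): negative and deeply lagged, partially offset by the
  positive glycolaldehyde term.
* **III** — the formaldehyde oligomerisation ladder F2–F4
  (uncatalysed): inherits the catalyst-*depleted* formaldehyde pool,
  i.e. a negative, fast response. Its sensitivity is indirect — zeroing
  the cycle sensitivities silences it.
* **IV** — C9 ketoses X9a–f formed from the first slow oligomer pool
  but degraded by catalysed retro-aldol (sensitivity 2): a lagged
  positive source opposed by an instantaneous negative drain.
* **V** — C9 ketoses W9a–f fed through a three-stage slow oligomer
  relay filled by catalysed DHA self-aldol (sensitivity 2): positive
  and deeply lagged, so only slow input components survive.

Within each family the members are isomers exchanging directly with
the family head (star topology) or adducts built by the same recipe;
this keeps families internally coherent while the heads' differing
transfer characteristics (sign x bandwidth x lag) keep the families
mutually separable in correlation distance. Carbon is conserved in
every reaction (checked programmatically at model construction), all
topology and rate constants live in one overridable table, and
Cannizzaro chemistry is excluded. Per-module sensitivity knobs allow
sweeps; increasing a branch's sensitivity increases its downstream
variance monotonically, and slower branches attenuate 30-s input steps
more than 120-s steps (both are regression-tested).

At the steady-state control condition the measured species span
roughly 0.03–0.9 mM. The adduct families sit below the ~0.1 mM level
one might prefer for chromatographic realism; raising their
formation fluxes further would speed the slow relay pools and erode
the lag structure that the clustering analysis depends on, so the
response geometry was kept and the lower concentrations accepted.

## Measurement model

Outlet sampling takes 50 aliquots at fixed intervals (40.8 s, or
30.6 s for the multi-timescale condition) after equilibration, linearly
interpolated from the simulation, each multiplied by a lognormal factor
with unit mean and 2% coefficient of variation. The 2% figure
represents quantification repeatability with internal standards; the
much larger sample-handling variance of real freeze-quench experiments
is deliberately *not* emulated, so passing recovery tests here bounds
algorithmic, not experimental, error.

Quantification follows the stated GC–MS rules: quadratic calibration
`c = a·A^2 + b·A + c0` per compound (monotone increasing over the
declared working range, enforced at load), a coefficient-wise averaged
curve for compounds without their own calibration (grouped by carbon
count), and the largest-of-two-peaks rule. The shipped calibration
table is synthetic (origin-passing, mild curvature, per-compound
response factors) because the real table is not published; user tables
are accepted as CSV. The forward direction (peak synthesis by inverting
the quadratic) makes the whole chain testable: quantify(synthesize(T))
recovers T to 1e-6 relative on noiseless data.

## Clustering

Pairwise distances are the correlation distance
`d(u,v) = 1 − (u−ū)·(v−v̄) / (‖u−ū‖‖v−v̄‖)` in [0, 2]; a constant
trace is a hard error (the distance is undefined, and silent
conventions corrupt dendrograms). Agglomeration is average linkage with
the proportional-average update
`d(A∪B, Y) = (|A| d(A,Y) + |B| d(B,Y)) / (|A|+|B|)`, and each merge is
recorded at height `d(A,B)/2` — half the conventional cophenetic
height, kept deliberately; `Dendrogram.to_scipy_linkage()` doubles the
heights for cross-tool comparison. Exact ties are broken by the lowest
pair of cluster indices in creation order (documented because merge
order can differ from other implementations on ties). Correlation
distance is non-metric, so height inversions are possible; they are
counted and reported, not assumed away. Flat partitions come from merge
truncation (k clusters) or a height threshold. The implementation is
checked against an independent brute-force UPGMA (cluster distances
recomputed each step as means over the original matrix) and against
scipy's average linkage on tie-free matrices.

## Multi-timescale correlation

The input program is resampled by linear interpolation (through the
step-start knots, with a final hold point) onto the outlet time axis.
For each window width (30, 60, 90, 120, 150 s) the time axis is tiled
with consecutive non-overlapping windows anchored at the first sample;
per-window means are differenced between consecutive windows,
standardised with the population SD, and the Pearson correlation
between input and compound differentials is reported per width. An
overlapping-stride mode exists behind a parameter for sensitivity
analyses; the non-overlapping tiling is the default because the
differencing definition (each window's mean minus the previous
window's) implies consecutive windows. A partial trailing window is
dropped, as are trailing windows left empty by the tiling (30-s windows
on a 30.6-s sampling grid leave exactly the last window empty at 50
samples); an *interior* empty window raises, because skipping it would
misalign the differentials. The number of differentials per width is
small (9–49 at 50 samples), so single-condition correlation values
carry sampling noise of up to ~0.3 at the widest window; seed-averaged
values are used wherever a quantitative statement is needed.

## Distribution comparisons

Compound distributions between conditions (all sampled timepoints of a
condition treated as replicates) are compared with a two-sided Welch
unequal-variance t test by default, with a Mann–Whitney option; the
test behind the original annotations is not named anywhere, so p-values
are not expected to match any published numbers. Significance stars
follow the bins ns (p > 5e-2), * (1e-2 < p <= 5e-2), ** (1e-3 < p <=
1e-2), *** (1e-4 < p <= 1e-3), **** (p <= 1e-4), with boundaries
inclusive on the right. No multiple-testing correction is applied by
default (annotations are per-comparison); Benjamini–Hochberg is
available behind a flag. Using all 50 timepoints as replicates ignores
their autocorrelation, which inflates effective sample size for slow
compounds; this caveat is inherited from the comparison convention the
package reproduces.

## Problem sizes and determinism

Statistical checks use 10,000-step programs for signal statistics (3
standard errors tolerance), 200 random matrices at n <= 8 for the
UPGMA equivalence, 20 seeds for module recovery, and 10,000 replicate
pairs for the type-I error calibration — sizes chosen so every check
has comfortable Monte-Carlo margin while the whole suite runs in a few
minutes. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (config, seed) pairs reproduce
every artifact byte-identically.

## Known limitations

* Kinetics are schematic: concentrations, sensitivities and relaxation
  times are design choices, not fits; the generator supports method
  validation, not chemical inference.
* The catalyst proxy ignores Ca2+/OH− speciation and precipitation.
* The measurement model omits derivatization losses, retention-time
  drift and the dominant experimental sampling noise.
* The windowed-differential correlation of deeply lagged families is
  weak at all tested widths even when the underlying coupling is
  strong — raw-trace clustering and windowed correlation answer
  different questions, and both are needed, which mirrors how the
  analyses are meant to be used together.
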