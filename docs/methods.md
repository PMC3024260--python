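# Methods

This note documents the models and numerical procedures implemented in
`compdbn`: the complement reaction network, its ODE simulation, the dynamic
Bayesian network (DBN) approximation with factored-frontier inference, the
two-stage parameter estimation, the sensitivity analyses, and the synthetic
data generator used for testing. It also records the design choices made
where the problem was genuinely open, and what the shipped tests do and do
not demonstrate.

## The complement reaction network

The model describes activation of the classical and lectin complement
pathways on a ligand-coated surface, up to the deposition of C3b (the
readout of antibacterial activity), together with the inhibitory programme
of C4b-binding protein (C4BP).

**Classical arm.** C-reactive protein (CRP) binds surface phosphorylcholine
(PC); deposited CRP recruits and activates the C1 complex; active C1 cleaves
C4 (releasing C4b, which deposits) and cleaves C2 within the surface
proconvertase C4b:C2 to form the C3 convertase C4bC2a, which cleaves C3.
Nascent C3b deposits on the surface (rate constant `kc2`).

**Lectin arm.** L-ficolin binds surface N-acetylglucosamine (GlcNAc),
recruits and activates MASP-2, which performs the same C4/C2 cleavages.

**Crosstalk amplification.** Deposited CRP binds fluid L-ficolin (constant
`kd01_1`) and the resulting surface complex recruits MASP-2, opening a
second protease route on PC surfaces; symmetrically, deposited L-ficolin
binds fluid CRP (`kd02_1`) and recruits C1 on GlcNAc surfaces. Both
complexes retain their original activities (simultaneous binding): the
CRP-side complex can still engage C1 and the ficolin-side complex can still
engage MASP-2. A *competition* variant of the model removes those
retained-activity reactions, so that L-ficolin binding blocks C1 engagement
and vice versa; the scenario module uses it to show that only the
simultaneous-binding architecture yields a stable enhancement.

**C4BP inhibition (mechanisms a-d).** (a) C4BP binds deposited CRP,
competing with C1 recruitment; (b) C4BP binds C4b (surface and fluid), with
factor-I-mediated proteolytic inactivation of the complex (C4BP's cofactor
activity is folded into this arm, keeping the four knockout letters
bijective with reaction groups); (c) C4BP strips C2 from the proconvertase,
preventing convertase assembly; (d) C4BP accelerates the natural decay of
C4bC2a (natural decay has its own constant `kt03_1`). Knockouts remove
exactly the reactions tagged with the corresponding letter.

**Housekeeping.** C1-inhibitor quenches the four canonical protease
complexes; factor I degrades deposited C3b/C4b species (through iC3b/iC4b to
C3dg/C4d); factor H inactivates fluid C3b. Deposited C3b decay is what gives
the C3-deposition curve its peak.

The transcription has exactly 42 species, 45 reactions and 85 kinetic
parameters, of which 14 are treated as literature-known and 71 as unknown;
these counts are validated at load time. Two of the 85 parameters are the
dimensionless condition-response exponents described below. Per-protein
conservation (CRP, L-ficolin, PC and GlcNAc sites, C4, C2, C3, C4BP moiety
totals) is declared in the model file and checked symbolically and in
simulation. C1, MASP-2 and C1-inhibitor are not declared conserved because
serpin inhibition removes protease:inhibitor complexes from the model's
scope. C4 cleavage tracks the C4a fragment; C3a is implicit (the C3 group
counts the C3b moiety).

### Units and baseline concentrations

Concentrations are nM, time is seconds. Initial concentrations are
plausible serum-scale values (C4 2.5 uM, C3 7 uM, C2 200 nM, C1 180 nM,
C4BP 260 nM — its plasma level — MASP-2 10 nM, L-ficolin 60 nM, CRP 50 nM
at baseline) with bead-surface ligand site densities of 5 nM each for PC and
GlcNAc. Surface sites are scarce relative to CRP, so CRP binding is
near-saturated at baseline — which is why simulating an elevated CRP level
alone barely changes the predicted killing rate.

### Conditions

An experimental condition bundles: initiating ligand (PC, GlcNAc or both),
pH, calcium, C4BP and CRP concentration scalings, depletions (CRP and/or
L-ficolin set exactly to zero), knockout letters, and the competition-mode
flag. Branch suppression (single-ligand initiation) zeroes the other
ligand's initial value *and* deactivates that branch's reactions, so the
suppressed branch's rate expressions are identically zero without
renumbering any parameter.

The *normal* serum condition is pH 7.4 / 2.5 mM calcium. The *patient*
(infection-inflammation) condition is pH 6.5 / 2.0 mM calcium with
acute-phase CRP elevated 10-fold over baseline (CRP is the infection marker
by which patient serum is identified; the 10x factor is an acute-phase
magnitude choice, also used for the "high CRP" control condition).

### The pH/calcium affinity surface

The CRP:L-ficolin binding affinity is a polynomial (degree 3) in pH per
calcium level, fitted by least squares to an anchor table and pinned so
affinity(pH 7.4, 2.5 mM) = 1 and affinity(6.5, 2.0)/affinity(7.4, 2.5) =
100, the reported inflammation/normal fold change. Between tabulated
calcium levels the log-affinity is interpolated linearly. The shipped
default anchors are *synthetic*: exact samples of monotone-decreasing cubics
(so the degree-3 fit reproduces them identically), chosen to honour the
100-fold ratio, the dominance of 2.0 mM over 2.5 mM calcium, positivity on
pH 5.5-7.4, and a flattening relative change toward pH 5.5. They are
explicitly not measured values and can be overridden by a CSV anchor table.

### How a condition acts on the kinetics

The affinity factor a(pH, Ca) multiplies the two crosstalk association
constants `kd01_1` and `kd02_1` (both realisations of the same molecular
interaction). In addition, the initiator-recruitment constants are scaled
by a(pH, Ca)**gamma with two registered exponents: `gamma_c` for C1
recruitment by deposited CRP and `gamma_l` for MASP-2 recruitment by
deposited L-ficolin (both ~0.21, fitted; factors of ~2.6 at the
inflammation point, against the 100x crosstalk factor). This encodes the
view that the same pH/calcium-driven conformational change of CRP and
L-ficolin that creates their mutual affinity also modulates — far more
weakly — how efficiently the surface-bound initiators engage their
proteases. A single-constant coupling (only `kd01_1`) cannot reproduce the
measured single-pathway killing rates: with L-ficolin depleted the classical
pathway contains no crosstalk-affected reaction at all, yet its measured
killing rate differs between patient and normal serum (25% vs 10%); the
exponent mechanism is the minimal extension that accounts for this while
leaving the normal condition (a = 1) exactly untouched.

### Parameter values

The 14 known constants are fixed, literature-style transcription values
(initiation on/off rates, the convertase's C3 kinetics, C4BP-C4b binding,
factor-I action on C3b and on the fluid C4b:C4BP complex). The 71 unknown
parameters carry fitted values obtained by calibrating the model against
the published endpoint observations that the original study used for
validation: the bacterial killing-rate panel (normal/patient sera with CRP
and/or L-ficolin depletions, high-CRP control) and the qualitative C4BP
signatures (titration behaviour of the two pathways; knockout ordering of
mechanisms a-d). Calibration minimised a least-squares objective over ~16
grouped log-scale rate constants; the resulting values are stored in the
model file together with bounds spanning one decade either side, which
define the parameter-space box for DBN construction, estimation and MPSA.

## ODE simulation

The integrator of record is LSODA (stiff-capable, automatic switching) at
rtol 1e-8 / atol 1e-12 nM, evaluated on the study grid {0, 100, ...,
12600} s (5 h horizon for titration scenarios). Negative undershoots are
clipped to zero on output and flagged beyond -1e-9 nM. Response summaries:
peak amplitude (max over grid), peak time (earliest argmax; ties to the
earliest time), integrated response (trapezoid AUC on the output grid; at a
100 s step the quadrature error is negligible at the stated tolerances).
Killing rates: deposited C3 at 1 h per condition, normalised so the panel
maximum equals 95%.

For ensembles of small non-stiff test systems an explicit batched mode
stacks many independent copies into one system and integrates them with
RK45 at rtol 1e-6; the 42-species model is integrated per-sample with LSODA
instead (stiffness makes a wide explicit batch impractical).

## DBN approximation

Variables (species) are discretized into 6 non-equal intervals, parameters
into 5 equal intervals over their bounds. Parameter intervals are fixed by
the bounds; variable intervals are equal-frequency (quantile) boundaries of
the pooled ensemble values — how the original interval choice was made is
not stated anywhere, and quantiles spend resolution where trajectories
actually live. Near-duplicate quantiles are collapsed (the interval count
drops when the data cannot support six distinct intervals); constant
variables become degenerate single-interval nodes. Out-of-range values are
clamped into the nearest boundary interval.

Structure: a variable node's parents at the previous slice are itself plus
every species and parameter on the right-hand side of its equation; a
parameter node's only parent is itself, and its CPT is the exact identity
(counting it instead is available behind a debug flag). CPTs are
time-variant and sparse: only parent assignments observed in the ensemble
are stored, with their support counts.

The sample-count heuristic J = K * I**u (coverage K per combination of the
I intervals of the u unknown parameters in the worst equation, K = 5 by
default) is exposed with an overflow cap; desk-scale analyses use far
smaller J, stated per experiment.

**Interval representatives.** Alongside midpoints, the builder stores
per-slice *empirical conditional means* (mean ensemble value per interval
per time slice), and expected-value series use them when available. Pure
midpoints systematically bias expected series wherever a wide interval is
populated asymmetrically (e.g. the top quantile interval early in a decay),
which measurably degrades stage-1 block identification; the conditional
means remove that bias at no extra sampling cost. Midpoints remain the
documented fallback (and the behaviour of a deserialized DBN written by an
older producer without representatives).

## Factored-frontier inference

Marginals propagate by the product-of-marginals rule over stored CPT rows,
renormalised over the *seen* mass: the stored rows stand in for the parent
assignments never observed during counting, which is the standard empirical
conditional estimator for a sparsely tabulated CPT (mixing the unseen mass
in as a uniform distribution instead was tried and measurably washes out
all parameter-conditioned signal once many parameters are clamped, besides
doubling the fidelity error against direct-simulation means). When *no*
stored row is compatible with the parent marginals at all — routine for
high-order equations under a full parameter clamp at practical sample
counts — the rows are re-weighted by a discrete kernel over interval
distance (bandwidth rho = 0.3), preserving a graded dependence on the
clamped parameter intervals; with rho = 0 this degrades to a plain uniform
fallback. Both backoff events are accumulated in a reported counter.

Evidence is filtering-only (no smoothing; the estimation objective needs
only forward expected values): clamped nodes have their marginals masked
and renormalised at the clamp time, with a contradictory clamp (zero mass)
raising an explicit error naming the node and time. Parameter clamps at
t = 0 persist through the identity CPTs. An exact dense-enumeration engine
over the joint interval distribution is provided solely as a test oracle
for tiny networks.

## Two-stage estimation

The objective in both stages is a weighted SSE. Each observed (condition,
species) series and its model counterpart are scaled by their own maxima
before residuals when the data are in arbitrary (densitometry) units; for
synthetic data sharing the model's units this normalisation can be disabled
(`Dataset.normalize = False`), which restores amplitude information and
substantially improves identifiability. Per-species weights default to 1
on the normalised scale (equalising series); they are configurable.
Multi-condition data are fitted jointly by summing per-condition objectives.

Stage 1 searches blocks (one of 5 intervals per unknown parameter); each
block is clamped as t = 0 evidence, factored-frontier expected series are
compared with the data. Block spaces up to 10^4 are enumerated
exhaustively; larger ones use the discrete-mode SRES. Stage 2 runs
continuous SRES inside the winning block — a box whose volume is I^-m of
the original for m unknowns — scored by direct ODE simulation, warm-started
at the block midpoint (which also guarantees the result is at least as good
as the block representative).

SRES is a (mu, lambda) evolution strategy with log-normal self-adaptive
step sizes and the stochastic-ranking bubble sort (objective-based
comparison with probability P_f). Defaults lambda = 200, mu = 30, P_f =
0.45, 500 generations (classic settings; scaled down in tests). With no
constraints beyond box bounds the ranking degenerates toward an objective
sort, but the randomized sweep is implemented in full. Discrete mode rounds
mutated coordinates to the nearest valid index.

## Sensitivity analysis

**Local:** scaled absolute coefficients |(p0/y0) dy/dp| of C3-deposition
peak amplitude and integrated response with respect to initial
concentrations, central differences at delta = 1% (unstated in the source
material; 1% stays well inside the linear regime at these tolerances).
Zero-baseline outputs are reported as undefined rather than silently
dropped.

**Global (MPSA):** parameter blocks sampled by a stratified
(Latin-hypercube style) draw over interval indices; each block scored by
the stage-1 objective on the DBN; samples classified good/bad at the median
objective (balanced classes; an absolute threshold is accepted too); each
parameter scored by the Kolmogorov-Smirnov distance between the good and
bad cumulative frequency curves over its interval indices (the sampled
space is discrete; no continuity correction). MPSA runs on the PC-initiated
DBN by default, matching the original analysis; the GlcNAc DBN is available
by flag.

## Synthetic data generator

`generate_dataset` emulates the calibration measurements: per condition,
the model is simulated at ground-truth parameters and the deposited
readouts are sampled at 8 equally spaced time points over 0-3.5 h —
PC-initiated conditions observe deposited CRP, C4, C3 and C4BP; GlcNAc
conditions observe deposited MASP-2, C4, C3 and C4BP (each realised by its
model species: CRPd, C4bd, C3bd, C4bd:C4BP, Lficd:MASP2a). Noise is
multiplicative unit-mean lognormal with CV 10% by default — a plausible
magnitude for Western-blot densitometry; the real measurement error is
uncharacterised — with an additive-Gaussian alternative. Noise-free mode
reproduces the simulation exactly; values are stored raw (normalisation is
the estimation objective's job). Ground truth and seed are recorded.

What the generator does *not* emulate: blot saturation and background,
inter-gel calibration drift, correlated errors across time points, and any
systematic model misspecification — so recovery tests certify the
estimation machinery, not the model's fidelity to real sera.

The small model library (2-species decay, 3-species cascade with losses,
6-species chain with one Michaelis-Menten step) keeps DBN/inference/
estimation tests independent of the 42-species model. The 3-species
cascade used for recovery experiments has bounds spanning 0.25x-1.75x of
each generating value, so the truth is the centre of the middle of the 5
parameter intervals — the standard design for a recovery study, where the
prior brackets the truth.

## Numerical and scale choices in the shipped experiments

- Killing panel: 1 h endpoint (the validation endpoint); pH/calcium
  dose-response curves: 1.5 h endpoint; titration horizon 5 h; knockout and
  pH-profile horizon 3.5 h — each matching its experiment's time frame.
- DBN fidelity experiments use the 3-species cascade at J up to 1e5 (batched
  explicit integration); agreement with the direct-simulation mean is
  expected at the resolution of the discretization, i.e. within one (the
  widest) interval of the node — quantile intervals are wide exactly where
  the marginal spreads.
- The full-scale DBN build (millions of trajectories) and the
  71-dimensional block search are out of desk scale by design; the
  configuration-level contracts (counts, search-space reduction 5^-71,
  sample-count heuristic) are checked exactly instead.

## Known limitations

- The transcription's rate constants are calibrated to endpoint killing
  rates, qualitative C4BP signatures, and non-trivial local leverage of
  the reported most-sensitive constants — not to the original time-series
  blots; absolute time courses should be read as representative, not
  measured.
- The C4-cleavage Michaelis-Menten constants sit in an equation with
  twelve unknown parameters (six per-enzyme pairs, a consequence of the
  85-parameter structural contract), which is beyond what CPT conditioning
  can resolve at desk-scale ensemble sizes: DBN-based global sensitivity
  under-ranks them even though their ODE-level leverage is real.
- With both initiators depleted the model predicts zero C3 deposition:
  alternative-pathway basal activity is outside the network's scope.
- The affinity anchor table is synthetic (constrained by the published
  100-fold ratio and saturation behaviour only).
- Factored-frontier inference carries the product-of-marginals error plus
  a uniform-fallback bias on unseen parent assignments; both shrink with J
  but do not vanish.
- The SBML interface covers exactly the subset this model family needs
  (mass action, reversible mass action, single-substrate Michaelis-Menten);
  package metadata rides in a JSON annotation.
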