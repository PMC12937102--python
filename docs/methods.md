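# Methods

## The model class

We describe a homodimeric ABC-type ATPase (ABCE1-like) with two
nucleotide-binding sites (NBSI, NBSII) as a continuous-time Markov
chain.  A state is a triple (conformation, occupancy of NBSI, occupancy
of NBSII) with conformation ∈ {open, closed} and occupancy ∈ {apo, ATP,
ADP}, where "ADP" denotes the lumped ADP+Pi product state (ADP and Pi
exchange is treated as one effective transition).  The structural
assumptions are:

1. two conformations suffice;
2. both sites always share one conformation (concerted gating);
3. the closed conformation requires both sites occupied;
4. ligand exchange only in the open conformation;
5. ATP hydrolysis only in the closed conformation;
6. no direct inter-site allostery: a transition's rate coefficient does
   not depend on the occupancy of the opposite site;
7. ADP+Pi exchange is a single lumped transition;
8. a catalytic-site mutation only rescales the hydrolysis and synthesis
   coefficients of its own site (extended classes relax this).

This gives 13 states — all 9 open occupancy combinations plus the 4
doubly-occupied closed states — and 20 reversible transitions: 12
ligand-exchange edges (2 ligands × 2 sites × 3 opposite-site
occupancies), 4 conformational edges (one per doubly occupied pair) and
4 hydrolysis edges (2 sites × 2 opposite-site occupancies).  Label
sharing under assumption 6 leaves 10 distinct forward coefficients
(4 binding, 4 conformational, 2 hydrolysis).  The canonical state order
is conformation-major (open first), then occupancy of NBSI, then NBSII,
each ordered apo < ATP < ADP; state 0 is open/apo/apo.  States are also
written compactly as e.g. `oTD` (open, ATP in I, ADP in II).

## Thermodynamically consistent rates

Rather than constraining rate coefficients directly, each state carries
a free energy and each forward transition a barrier ΔG‡ (both in kT at
the reference temperature, 298.15 K).  Eyring's form gives the forward
rate ω0·exp(−ΔG‡) with ω0 = κ·kB·T/h and κ = 1; the backward rate is
ω0·exp(−(ΔG‡ − ΔG_edge)) with ΔG_edge the free-energy step of the edge.
Detailed balance is then automatic, and the construction removes 3 of
the 20 unique coefficients: 10 barriers + 7 free-energy differences
= 17 free parameters instead of 20.

The additive (non-allosteric) state-energy rule uses seven differences:
four binding free energies (ATP and ADP at each site), one
open-to-closed offset, and two closed-state ATP-to-ADP differences.
Closed states are booked as "all-ATP closed" plus the per-site
hydrolysis difference for ADP-occupied sites.  The allosteric class
instead assigns one free energy per state (state 0 fixed at 0; 12 free
values) and one barrier per edge (20), i.e. 32 parameters.

Concentrations enter as constant factors on exchange-edge forward
rates: k·[ATP] for ATP binding, k·[ADP][Pi] for product binding (the
termolecular form keeps the lumped product step consistent).  Because a
single-valued state energy cannot carry the chemical driving force, the
standard hydrolysis free energy ΔG° = −29.288 kJ/mol enters as a
chemical-work term on the ADP+Pi exchange edges: their
forward/backward ratio is [ADP][Pi]·exp(−(ΔG_bind,ADP + ΔG°/kT)).
Consequently the product of forward/backward rate ratios around any
reaction cycle with one net hydrolysis equals
exp(−ΔG°/kT)·[ATP]/([ADP][Pi]): at 1 M reference concentrations it is
exp(11.81) ≈ 1.353×10⁵, and at the equilibrium pool ratio
[ADP][Pi]/[ATP] = exp(−ΔG°/RT) every net flux stalls.  Both closures
are enforced by tests.  Temperature changes rescale barriers as fixed
energies (ΔG‡·T_ref/T in kT) per the Eyring form.

Mutations divide the mutated site's hydrolysis *and* synthesis
coefficients by a reduction factor (default 100; the robustness scan
uses 10/100/1000).  Extended classes add per-site free knockdown
factors (log-uniform in [1e−12, 1]) and four affinity shifts per
mutation variant (uniform in [−10, 3] kT, negative = stronger binding),
applied as exp(shift) to every rate that carries the shifted site away
from the bound nucleotide — unbinding and hydrolysis/synthesis, not
conformational edges.  With two mutation variants (EQ for steady-state
assays, EA for single-turnover assays) this adds 6 parameters per
variant: 17→29 without and 32→44 with allostery.

## Observables

Steady states solve 0 = Q·π with one balance row replaced by the
normalization; a residual above 1e−8 of the matrix scale or a negative
population beyond −1e−6 raises an explicit error rather than returning
a silently clamped vector.  The ATP turnover rate is the summed net
flux of the six ADP+Pi-unbinding edges (equal, at steady state, to the
summed hydrolysis-edge flux).

k_cat is the turnover at [ATP] = 100 mol/L.  All turnover-curve
evaluations use [ADP] = [Pi] = 5×10⁻⁴ mol/L (100-fold a typical
5×10⁻⁶ mol/L enzyme concentration, standing in for product
accumulation during the assay).  K_M uses the printed two-stage
heuristic exactly: a coarse grid 10⁻⁹…10² mol/L in decade steps
(12 points); the two rates closest to k_cat/2 must bracket it; 18
additional log-spaced concentrations refine the bracket; the crossing
is interpolated linearly in concentration.  An unbracketed half-maximum
is a hard failure (the model is rejected with likelihood −∞, never
clamped).  The interpolation is linear in concentration, not log
concentration — the coarser choice, kept because the refinement step
makes the difference negligible.

Steady-state occupancies are Σᵢ nᵢπᵢ with nᵢ ∈ {0, 1, 2} the per-state
ATP (or ADP) copy numbers.  The ligand concentrations at measurement
time are estimated from the model's own integrated Michaelis–Menten
kinetics (solved implicitly per time point by bracketed root finding,
robust to extreme S₀/K_M), averaged over a configurable 4–5 min
window; initial substrate (default 10⁻³ mol/L) and enzyme concentration
(default 5×10⁻⁶ mol/L) are configuration inputs because the original
assay values are not part of this repository.

Single-turnover occupancies integrate the master equation jointly with
depleting free-ligand pools: d[ATP]/dt = −[E]·(net ATP-binding
probability flux), and likewise for ADP and Pi (making the bound system
effectively third order).  Defaults follow the assay geometry: [E] =
0.3 µM, [ATP] = 0.6 µM, ADP = Pi = 0, all enzyme initially open/apo,
integrated with a stiff implicit (Radau) solver, max step 0.1 s,
relative tolerance 1e−6, to t = 30 s.  Probability and total-nucleotide
conservation are tested invariants.

## Bayesian inference

The likelihood is a product of independent Gaussians N(xᵢ | μᵢ, σᵢ)
over the data table (6 kinetic observables, or 15 with occupancies);
the σᵢ are fixed experimental uncertainties, not nuisance parameters.
Priors are uniform boxes in free-energy space, derived from rate-coefficient
bounds per transition group (binding and unbinding 10⁻⁶…10⁷,
chemical 10⁻⁶…10¹², conformational 10⁻⁶…10⁶; the printed bounds carry
mixed concentration units for the bimolecular steps — the numerals are
applied to the concentration-free coefficients at the 1 M reference, a
unit convention of this package).  A uniform prior in barrier space is
log-uniform in rate space.  Free-energy-difference bounds combine the
forward and backward barrier bounds; allosteric state energies use a
generous ±100 kT box.

The default sampler is replica-exchange MCMC with univariate slice
sampling for local exploration: a geometric inverse-temperature ladder
(default 6 replicas down to β = 1/64), one slice sweep over all
coordinates per replica per step (initial interval 0.25 of the prior
box width, stepping-out bounded by the box; hot replicas take wider
steps ∝ β^(−1/2)), and alternating adjacent-pair swaps.  The posterior over rate parameters is strongly
multimodal — distinct reaction mechanisms fit the same kinetics — and
plain ensemble moves reliably under-explore it, which is why tempering
is the default; an affine-invariant ensemble sampler (emcee, with
differential-evolution moves) remains available as `method="ensemble"`.
Both samplers are validated on analytic toy posteriors, run as
independent seeded chains, and are bit-reproducible given a seed.

Convergence uses rank-normalized split-R̂ (ArviZ), treating each
independent run as a chain.  The highest-posterior samples can be
refined by first-choice hill climbing (accept the first improving
Gaussian perturbation of a random coordinate subset, clipped to the
box; monotone by construction).  Model classes are compared with
BIC = k·ln(n) − 2·ln L̂, with k the class's free-parameter count, n the
data count, and L̂ the best likelihood found after refinement — the
likelihood, not the posterior, since the uniform prior contributes only
a constant inside the box.  Likelihood evaluations dominate sampling
cost; the steady-state/K_M pipeline is compiled (numba) and cached per
parameter vector.

## Cycle fluxes and mechanism

A reaction cycle is a simple closed walk containing exactly one
hydrolysis edge; the 13-state graph (cycle rank 8) has 44 such cycles,
enumerated deterministically and checked against a brute-force DFS
oracle.  The four 5-state cycles in which the opposite site keeps a
fixed load are named 1T, 1D (hydrolysis in NBSI with ATP / ADP in
NBSII) and 2T, 2D (the converse).  Cycle keys are structural state
sequences (e.g. `cTT-cDT-oDT-oaT-oTT`), independent of any numbering.

The net flux Θ through each cycle is assigned by a deterministic
two-stage bottleneck scheme.  Stage 1 is conforming: among all cycles
whose every edge still carries residual flux in the traversal
direction, repeatedly assign the largest bottleneck (the minimum
residual along the cycle) and subtract it; ties break by canonical
cycle order.  Some steady states route flux through processive loops
that hydrolyse at both sites before reopening; such a loop is the edge
sum of two single-hydrolysis cycles with one cancelling edge, so no
conforming assignment exists.  Stage 2 therefore drains any remaining
hydrolysis-edge residual through the most nearly conforming cycle
(largest minimum residual over its non-hydrolysis edges), which splits
compound loops onto their single-hydrolysis constituents.  The scheme
guarantees the two conservation laws that make contributions meaningful
— the Θ assigned to each hydrolysis edge sums to that edge's net flux,
and total assigned flux equals total turnover — and reduces to the
obvious answer when one cycle exists.  The underlying decomposition of
a circulation into simple cycles is not unique; this choice is
conservative and deterministic, and is flagged here because any
cycle-level statement inherits it.

Contributions ϑ = Θ/turnover define "dominant" cycles at threshold
τ = 0.20; a reaction type is the canonical sorted set of dominant-cycle
keys (per species, or jointly over wild type and mutants), with an
empty set encoding the absence of dominant cycles.  The threshold scan
τ ∈ [0.05, 0.25] is exposed, and the packaged fixture's type is stable
across it.

Sensitivities of k_cat use adjoint (algorithmic) differentiation of the
steady-state system — solve Aᵀλ = c once and contract with ∂Q —
cross-checked against central finite differences in log-rate space to
1e−4.  Raising a state's free energy with barrier tops fixed multiplies
all its outgoing rates by exp(+δ); the rate-limiting state maximizes
|∂k_cat/∂G_state| (thermodynamic rate control); rate-limiting
transition states and coefficients are defined analogously.  Population
summaries record, per posterior sample, the most populated state (with
a ≥90% dominance flag and deterministic lowest-index tie-break), the
lowest-free-energy state, and the rate-limiting state, aggregated into
conditional-probability matrices.

## Synthetic data and the packaged fixture

No experimental values ship with the repository; the synthetic-data
module emulates the measurement table.  Ground truths are
rejection-sampled from the prior until all observables are computable
(optionally constrained to a plausible kinetic window, k_cat ∈ 10⁻⁴…10⁴
1/s); measurements add independent Gaussian noise with relative σ
(default 15%, configurable, with absolute overrides) — the real
uncertainties being unavailable, a mid-range relative error typical of
steady-state ATPase assays.  Generated data use the same CSV schema the
inference stage reads.

The packaged fixture (`data/fixture_asymmetric.yaml`, synthetic, found
once by constrained Nelder–Mead search inside the prior box and frozen)
realizes the qualitative mutant asymmetry under the 100-fold knockdown:
k_cat(E238Q)/k_cat(WT) = 0.50, k_cat(E485Q)/k_cat(WT) ≈ 84, with k_cat(WT)
≈ 0.13 1/s.  Its wild type hydrolyses almost exclusively in NBSI
through cycle 1T (ϑ ≈ 0.96) while nearly all population sits in the
open ATP/ADP trap state `oTD`, which is also the rate-limiting state;
site-II hydrolysis acts as the drainage out of 1T.  Knocking down
site II shifts ~90-fold more population into the 1T states — removing a
pathway increases throughput, a molecular Braess paradox.

What passing synthetic tests does and does not show: the generator
reproduces the *structure* of the experiments (observable set, error
model, assay concentrations), not the real measured values; recovery
and calibration results therefore validate the machinery, not the
biological parameter estimates.

## Numerical choices and scale

Problem sizes are chosen so the full test suite and analysis scripts
run on a single CPU: the end-to-end recovery study uses 4 independent
replica-exchange chains of 350 sweeps (6 replicas each) on the 6
kinetic observables; the BIC study uses short chains plus hill
climbing; the steady-state/ODE cross-check uses 50 random models.
Steady-state tolerances: residual ≤ 1e−8 of the matrix scale,
negativity ≤ 1e−6 (clipped), probability renormalized.  Cycle-flux
residual tolerance: 1e−10 of turnover, with a hard failure at 100×
that.  Degenerate inputs (zero concentrations isolating states,
unbracketed K_M, non-finite posteriors at initialization) fail loudly
and are treated as rejected models during sampling.

## Known limitations

- The cycle-flux decomposition is one deterministic choice among valid
  circulation decompositions (see above).
- K_M is the heuristic grid value, not an exact half-saturation root;
  the two agree to ~2% on Michaelis–Menten-like curves by construction
  of the refinement grid.
- The steady-state occupancy observable depends on assay inputs
  (initial substrate, enzyme concentration, measurement window) that
  are configuration, not data.
- Single-turnover integration treats the enzyme as well mixed and the
  free-ligand coupling as mean-field; no stochastic copy-number effects.
- R̂ at the scaled-down chain lengths indicates convergence of the
  cold chains, not exhaustive mode coverage; reaction-type censuses
  over posterior samples at this scale are illustrative.
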