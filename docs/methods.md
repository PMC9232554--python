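# Methods

## Model and assumptions

`txflow` models cell-free transcription–translation (TX–TL) of gene circuits
in a continuously diluted microfluidic chemostat with a coarse-grained ODE
per transcription unit: template DNA, mRNA, protein, and — for fluorescent
reporters — a dark→mature first-order maturation step with only the mature
pool observable. Rate laws are lumped into four categories:

- **K_TX** — transcription. The constitutive σ70 promoter is a linear term
  (`k_cat,TX,σ70 · DNA`): σ70 is assumed saturating and constant in the
  lysate. The inducible p19a promoter is Michaelis–Menten in the σ19
  activator with dissociation constant `K_d,σ19`; hybrid promoters carrying
  an operator share the bare promoter's `K_d,σ19`. Free σ19 is identified
  with total σ19.
- **K_reg** — operator-mediated repression acts multiplicatively on the
  transcription rate through a Hill term `1/(1 + (R/K_d)^n)`; operators sit
  downstream of the transcriptional start, so repression is transcriptional,
  not translational.
- **K_TL** — translation is linear in mRNA with an (ORF, RiboJ)-specific
  rate. The RiboJ insulator decouples operator context from translation;
  rates with and without the insulator are distinct parameters.
- **K_deg** — first-order mRNA degradation per ORF. Protein degradation is
  neglected (half-life ≫ dilution); proteins leave the reactor by outflow
  only, so every protein pool is still diluted at λ.

No resource competition between genes is modelled (ribosomes and core RNAP
are treated as non-limiting in the flow reactor). Units are nM and minutes
throughout; `k_cat` values printed as nM·min⁻¹ are applied as per-nM-template
(respectively per-nM-mRNA) turnover numbers.

An optional time-dependent *activity* factor scales both TX and TL rates.
The chemostat refreshes lysate and energy every cycle, so activity is 1
there; batch reactions deplete their resources, which is emulated by an
exponential activity decay (default 0.008 min⁻¹, a ≈2 h expression lifetime).
This factor exists so that batch experiments carry the finite information
window real batch CFPS has; it is not used in flow simulations.

## Chemostat mechanics

The hardware replaces a refresh fraction RF (default 0.40) of the reactor
volume every cycle (default 22.5 min). 70% of the refreshed volume carries
lysate/energy solution; the remaining DNA/MQ share is split between DNA
stocks and water by the per-cycle inflow fractions IF read from tab-delimited
pattern files (one row per cycle, one column per construct). Two dynamical
views are provided: the default continuous approximation (λ = RF/T, piecewise
constant `k_in = IF·RF·stock/T` — both constant within a cycle, so
integration restarts only at cycle boundaries) and a discrete per-cycle
replacement map for fidelity studies. Their DNA traces share the fixed point
`IF·stock` and agree at cycle boundaries after the loading transient. The
stock concentrations are interpreted as *delivered* concentrations, i.e. the
control law omits the lysate share; this follows the stated inflow law and
its fixed point rather than the volumetric bookkeeping, which would scale all
stocks by a constant. Sequential within-cycle loading (lysate → DNA → MQ) is
not modelled; the model assumes the pulsed template is present from the start
of its cycle.

Observation times default to cycle boundaries: the instrument images once
per cycle.

## Reference parameters

Four reference parameter tables ship with the package, one per estimation
round (individual step calibrations; the pooled database; the database
updated with pulse-decoder or bistable-switch experiments), each with means
and hard lower/upper bounds used as fitting box constraints. Only
RiboJ-variant translation rates are tabulated (plus σ19, whose construct has
no insulator); uninsulated rates default to the RiboJ rate divided by an
insulation factor of 2.0, reflecting that insulated parts generally
translate faster. Maturation rates are measured constants, never fitted:
deGFP 0.087 min⁻¹ (≈8 min half-time) and mmCherry 0.023 min⁻¹ (≈30 min),
standard literature values, configurable per `ParameterSet`. The step-round
`K_d,PhlF` mean sits outside its own bracket; the table is shipped as
recorded and bounds are only enforced during fitting.

## Sensitivities, identifiability and experimental design

Forward sensitivities are central finite differences on log-parameters
(relative step 1e-4), reported either *relatively* (θ/y·∂y/∂θ, denominators
floored at 1e-9 nM) for collinearity analysis or *absolutely* (θ·∂y/∂θ, nM)
for information scoring, where signal magnitude against a fixed
measurement-noise scale must count. Halving the step changes fixture
sensitivities by <1e-3 relative; exactness beyond that is not claimed.

The collinearity index of a parameter subset is γ = 1/σ_min of the
column-normalized sensitivity submatrix (capped at 1e6; an all-zero column
marks structural unidentifiability and reports the cap rather than raising).
Pairwise γ matrices are lumped into the four parameter categories by
averaging; scenario-level rankings use a geometric mean because structurally
collinear pairs (e.g. `k_cat,TX,σ70` with `k_cat,TL,σ19`, which enter the
observables only through their product) sit at the cap in *every* design and
would dominate an arithmetic mean. Lump-then-mean is used throughout.

Design search (`optimize_design`) is an elitist genetic algorithm over the
discrete IF grid (default steps of 0.05, matching load-step hardware
granularity), optionally co-optimizing stock concentrations, scoring designs
by log det(FIM + 1e-12·I) (D-optimality — maximized, since lower parameter
covariance is the goal) or by negated mean lumped collinearity. A robust mode
averages the score over a parameter ensemble, since the FIM depends on the
nominal parameters. The packaged "optimized" IFFL pattern was produced once
by this search (seed 2024, budget 400, 12 cycles, D-criterion at the
pooled-database means) and frozen, mirroring how a single precomputed pattern
is executed on hardware.

## Database fitting

All experiments are fitted simultaneously through global parameter labels:
shared parts share degrees of freedom across circuits. The objective is the
sum of squared residuals, each experiment normalized by its trace maximum
(placing deGFP and mmCherry on comparable footing — the weighting is a
package choice), plus a soft biophysical constraint: the fully activated
steady-state mRNA/template ratio `k_cat,TX/(k_deg + λ)` of every construct
must lie in (2, 500), enforced as a quadratic hinge (zero inside the
interval, boundaries accepted to 1e-9). Integration failures score a large
finite penalty so population searches survive pathological parameter sets.

The optimizer is differential evolution (rand/1/bin, F = 0.7, CR = 0.9) in
log-parameter space (Hill coefficients linear) on two islands with periodic
best-agent migration; agent count (≥20) and round counts are engineering
defaults. The product is an *ensemble* — all final agents within a
configurable objective factor of the best, duplicates included — rather than
a point estimate. Distribution width (mean of the five highest over mean of
the five lowest values of a parameter; needs ≥10 members) summarizes
ensemble spread; category summaries average widths within K_TX/K_TL/K_reg/
K_deg, optionally normalized to a reference run. For narrowing benchmarks
with a known ground truth, ensembles are pooled over independent restarts
and membership is thresholded at twice the χ² floor (the objective at
truth) — a single population's spread otherwise measures optimizer
convergence rather than the width of the acceptable set. The RiboJ factor
(median with/without translation-rate ratio over the repressor pairs)
extrapolates rates for parts characterized in only one configuration;
prediction bands simulate the best quantile (default 25%) of the ensemble
and report pointwise mean ± sd.

## Prediction protocols and study conditions

The pulse decoder (σ19 → PhlF ⊣ CymR ⊣ TetR ⊣ deGFP) is pre-equilibrated
without the PhlF construct until the mature-deGFP slope over one cycle drops
below 1e-4 nM/min (b = pre-pulse plateau); the PhlF template (5 nM stock) is
then fed for Δt and a is the trough of deGFP over the readout window — the
cascade is monostable, so the trough is the operational "post-pulse plateau"
and coincides with the repressed quasi-steady level for long pulses. The
default grid is nine evenly spaced durations, 0–540 min (0–24 cycles), whose
longest pulse sits on the saturated branch of the response; an unreached
plateau is flagged and the last value used.

The bistable switch (CymR ⊣ TetR-construct, TetR ⊣ CymR-construct, with
TetRO1-deGFP and CymRO1-mmCherry reporters) runs the triple-switch schedule:
0.2 nM CymR-construct baseline from cycle 0, 0.8 nM TetR-construct baseline
from cycle 8, then alternating 5 nM TetR-construct / 2 nM CymR-construct /
5 nM TetR-construct pulses at cycles 16/42/68 over 92 cycles. Conditions not
tabulated anywhere were fixed from steady-state analysis of the model and
are package choices: the σ19 driver template is 2 nM (σ19 ≈ 100 nM, well
below K_d,σ19, but strong enough that both toggle states hold their
repressor above its K_d — at 1 nM the CymR state is not a stable fixed point
at the reference means); pulse feeds last 4 cycles so the delivered template
reaches ≈80% of the nominal pulse concentration; inter-pulse gaps span ≈26
cycles (≈10 dilution time constants) because switching relaxes on the
dilution timescale. Decoder secondary constructs (`p19aCymRO1-TetR`,
reporter) default to 1 nM.

State classification normalizes each reporter by its own running maximum,
takes the sign of (deGFP − mmCherry) with a ±0.1 hysteresis band, and counts
switches aligned to pulses (one per pulse window). The bistability screen
samples parameter sets uniformly within the reference bounds (log-uniform
for rates, uniform for Hill coefficients) and classifies success as exactly
three pulse-aligned switches; roughly 2% of sets succeed, and the screen
defaults to 1000 samples so the success-median estimate is stable.

## Synthetic data

The generator simulates every entry of the characterization registry (one
step plus one optimized experiment per IFFL variant and one σ19 activation
pulse — 13 experiments over 7 models) at a known truth, samples at cycle
boundaries, and adds additive truncated Gaussian noise with
sd = max(σ_abs, σ_rel·signal), defaults σ_abs = 5 nM, σ_rel = 0.05, on the
mature-reporter observables only; observations clip at zero. Regeneration
from the same seed is bit-identical, and truth is stored separately from the
observations. The generator emulates imaging cadence, chemostat dilution and
instrument noise; it does not emulate lysate batch-to-batch variation,
fluorescence calibration error, sequential within-cycle loading, or
replicate structure (it produces single traces, corresponding to replicate
means). Tests passing on these fixtures therefore validate the inference
machinery under the model's own assumptions, not robustness to those
unmodelled effects.

## Numerical choices

LSODA (scipy `solve_ivp`) with rtol 1e-8/atol 1e-10 by default, restarted at
cycle boundaries; screening and fitting use rtol 1e-6 for speed (halving the
tolerance changes fixture observables by <1e-6 relative). Small integrator
undershoots below zero are clipped. Near-zero relative-sensitivity
denominators are floored at 1e-9 nM. Benchmarks in the test suite use
reduced problem sizes (12–16 cycle characterization runs, 4 free parameters
in fitting benchmarks, 3 restarts) chosen to exercise the scientific claims
at desk scale.

## Known limitations

- Optimizer settings, within-cycle loading granularity and replicate
  handling are engineering defaults of this package, not measured
  quantities; conclusions that depend on them should be checked against
  the user's own hardware configuration.
- The collinearity cap makes perfectly covariant pairs indistinguishable
  beyond 1e6; rankings are designed to be robust to this, not to resolve it.
- Finite-difference sensitivities limit agreement with exact
  sensitivity-equation methods to ~1e-3 relative.
- The batch/flow information comparison depends on the extract-aging rate;
  the batch-worst ordering holds at the default but its margin over the step
  design is small in this model.
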