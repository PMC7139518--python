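# Methods

## Model

One lymphocyte lineage (CD4 T, CD8 T, B or NK) is modelled as a
time-homogeneous Markov chain over four stages: PB/naive (x₁),
CSF/naive (x₂), PB/differentiated (x₃) and CSF/differentiated (x₄).
Transitions are naive migration α₁ (stage 1→2), PB differentiation β₁
(1→3), differentiated migration α₂ (3→4) and CSF differentiation β₂
(2→4). All four are probabilities per step, stored as fractions in
[0, 1]; published tables print them in percent and conversion happens
only at the I/O boundary. The model assumes a large, well-mixed cell
pool (transitions independent across cells), no recirculation from CSF
back to blood (the α's are net rates), no de-novo generation of a
subset inside the CSF, and stationarity — only steady states are
predicted, not transients. These assumptions mean the model knowingly
mis-predicts subsets that are generated intrathecally or absent from
the CSF (plasmacytoid B cells outside MS being the canonical example).

With the total pool normalised to A0 = 1, the stationary distribution
solves the linear system given in the README; it conserves mass
identically and is nonnegative iff α₁ + β₁ ≤ 1, which the package
enforces as an explicit feasibility constraint alongside the box
bounds. The system matrix has determinant (1+β₂)(1+α₂) > 0 and is
always invertible on the feasible set.

Two conventions required a decision and are worth stating:

* **Stage ordering.** The stage vector is ordered (PB/naive, CSF/naive,
  PB/diff, CSF/diff), the ordering under which the balance equations'
  inflows match the transition semantics (α₁ into stage 2 is a
  migration, β₁ into stage 3 a differentiation).
* **β₂ in the CSF balance.** The CSF/naive outflow and the CSF/diff
  inflow use β₂, the within-CSF differentiation rate. A variant in
  which both use β₁ instead also conserves mass — conservation cannot
  discriminate between the two — but only the β₂ form matches the
  stage-diagram semantics; the β₁ form is kept available behind
  `printed_variant=True` for sensitivity checks and is not otherwise
  used.

## Calibration

The objective is the unweighted mean squared deviation
(1/K) Σ_k ‖X(α, β) − X_k‖², equal to ‖X − X̄‖² plus a data-only
constant, so the fit effectively targets the cohort mean vector. No
weighting or robustness is applied (no per-patient measurement-error
estimates exist to justify either).

**Solver.** Bounded least squares (scipy's trust-region reflective
method) with the analytic Jacobian of the steady state. The linear
constraint α₁ + β₁ ≤ 1 is converted to a box bound by the substitution
β₁ = t·(1 − α₁), t ∈ [0, 1] (when only one of the pair is free, its own
bound is tightened instead). Gauss–Newton scaling matters here: the
steady state's sensitivity to β₂ is proportional to α₁, which is ~10⁻⁵
for NK cells, and generic quasi-Newton minimisers stall on such flat
directions; the trust-region least-squares solver handles them.

**Multistart and determinism.** Starts are a deterministic grid over
[0.1, 0.9] per free rate (default 3 points → 81 starts) plus the
centroid of the feasible set (1/3, 1/2, 1/3, 1/2); infeasible grid
points are radially projected onto the feasible triangle. The best
objective wins; ties within 10⁻¹² are broken by the smaller L2 norm of
the rate vector, then by grid order, making repeated fits bitwise
identical. The requested convergence tolerance defaults to 10⁻¹⁶ and is
clipped to machine epsilon, the tightest achievable in double
precision.

**Identifiability.** The steady state determines exactly three
functions of the four rates: s₁ = α₁+β₁ = 1−x₁, s₂ = α₁/(1+β₂) = x₂,
s₃ = β₁/(1+α₂) = x₃. Consequently a one-parameter family
(α₁+δ, β₁−δ, α₂', β₂') reproduces any steady state exactly;
`equivalent_rates` constructs its members and `feasible_delta_interval`
bounds δ (binding constraints for realistic small rates:
−α₁β₂/(1+β₂) ≤ δ ≤ β₁α₂/(1+α₂); the remaining box constraints are
intersected as well). Fit results therefore report the combinations and
the family width rather than pretending the raw rates are unique; tests
assert recovery of (s₁, s₂, s₃) only. Unique differentiation rates are
recovered by profile calibration with the migration rates fixed, for
which the closed forms β₁ = x₃(1+α₂) and β₂ = α₁/x₂ − 1 provide an
independent oracle.

**Stage-vector assembly.** How per-compartment percentages combine into
a four-stage vector is a modelling choice. Three modes are provided:
`count_weighted` (compartment masses proportional to recorded total
cell counts; the default whenever counts exist), `fixed_weight` (CSF
mass fixed, default 0.001 — a stated assumption reflecting that the CSF
holds a tiny fraction of the lymphocyte pool, not an estimate), and
`joint` (the record already carries a joint four-stage distribution).

## Prediction from blood only

Blood measurements constrain exactly one degree of freedom beyond the
cohort rates, so prediction personalises only β₁: solving the
stationary PB split for β₁ with the other three rates at cohort values
gives β₁ = (1−p)(1−α₁)/[p/(1+α₂) + (1−p)], p the patient's naive
fraction in PB. This reproduces the patient's blood profile exactly
with the fewest moving parts; the CSF pair is then read off the
resulting steady state. Training-cohort uncertainty is propagated by a
percentile bootstrap (default B = 1000, 95% range): resample patients
with replacement, refit (warm-started from the full-cohort solution and
the feasible-set centre — the full grid would be wasted on resamples of
the same data), re-predict. Failed refits are skipped and counted;
more than 50% failures aborts. The reported interval is clamped to
contain the point estimate so that range_low ≤ point ≤ range_high holds
even in degenerate resampling situations. The ranges quantify
calibration uncertainty only — not the patient's own measurement noise.

## Stochastic oracle

The verification oracle realises the balance equations as a linear
birth–death process: cells immigrate at rate Λ and are assigned stage 2
with probability α₁, stage 3 with probability β₁, else stage 1 (the
balance equations route α₁·A0 and β₁·A0 — flows proportional to the
source, not to x₁ — hence assignment at birth); stage-2 cells move to 4
at rate β₂, stage-3 cells at rate α₂; every cell is cleared at rate 1.
This is the simplest linear dynamics whose fixed point is exactly the
model's steady state: mean occupancy divided by Λ equals (x₁…x₄). Cells
are independent (an M/M/∞ network), so the simulation is exact per
cell and vectorised over the Poisson birth stream; time is in units of
the mean residence time, and a burn-in of a few units removes the
empty-start bias (residual bias ~e^(−burn_in)). Standard errors use
the compound-Poisson identity Var(Σ cᵢ) = ΛT·E[c²], estimated by Σcᵢ².
Agreement within 3 SE at Λ = 10⁴, horizon 200, burn-in 20 is the
package's main cross-check of the closed form.

## Synthetic cohorts

The generator emulates post-gating flow-cytometry summaries: for each
patient the model's compartment profile is computed and the number of
naive events per compartment drawn from Binomial(n_events, naive
fraction) — the dominant noise source in gated percentages. Defaults
are 10,000 events in blood and 200 in CSF, reflecting paucicellular CSF
samples; absolute counts are total_cells (default 10⁶) times the
compartment masses. Optional inter-patient heterogeneity jitters each
rate on the logit scale (keeping rates in (0, 1)); jitters violating
α₁ + β₁ ≤ 1 are redrawn a bounded number of times. Each patient's
stream is keyed on (seed, index), so records are reproducible
individually. What the generator does *not* emulate: gating and
compensation errors, panel spillover, correlated noise between
compartments, and real inter-patient biology — passing recovery tests
on synthetic cohorts therefore demonstrates correctness of the
estimation machinery under the stated noise model, not clinical
validity on real cohorts.

Default test and acceptance problem sizes (K = 75 patients matching a
control-cohort scale, 14-train/19-predict for the bootstrap design,
Λ·T = 2·10⁶ for the oracle) were chosen as the scales at which the
statistical checks are sharp while a full run stays comfortably
desk-scale.

## Known limitations

* Steady state only; no dynamics, no longitudinal data.
* No CSF→blood recirculation and no intrathecal de-novo generation;
  lineages absent from the CSF are systematically over-predicted there.
* Raw rates are reported for convenience but are identified only up to
  the equal-objective family; comparisons between groups are safest on
  the identifiable combinations or with matched fitting protocols.
* The bootstrap range is a stand-in for whatever variance decomposition
  produced published prediction ranges; it quantifies training-cohort
  sampling only.
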