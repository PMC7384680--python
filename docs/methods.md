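# Methods

This note records the model, its assumptions, the defaults and why they
were chosen, and what the synthetic study does and does not establish.

## The circuit meta-model

The meta-model describes the *scbR*/*scbA* circuit in two well-mixed
compartments (cell, culture medium). Intracellular species are counted in
molecules per cell (operators in copies per cell); extracellular GBL is a
concentration in nM, converted via the cell volume (1 molecule/cell ≈
1.66 nM at V_cell = 10⁻¹⁵ L). The full configuration (scenario H) has 18
species, 41 reactions and 51 parameters; scenarios A–G are obtained by
removing the reactions of disabled mechanisms, which removes the production
routes of their species (duplex, AR, O_A′ states), leaving them
structurally zero.

Kinetics are elementary mass action with four special rate laws:

* **Transcription.** Each gene's initiation rate is its firing rate k_F
  scaled by the occupancy of its operator (free, one R₂ dimer, two dimers —
  sequential binding with dissociation constants K_d1/K_d7 for O_R and
  K_d2/K_d8 for O_A; residual activities ρ₁ ≥ ρ₂ for the occupied states),
  for *scbA* further multiplied by the activation folds of the RA and R_act
  mechanisms when enabled. Convergent-promoter interference multiplies each
  rate by a collision-escape probability 1/(1 + τ_i·f_j), where f_j is the
  opposing occupancy-modulated firing rate and τ_i = aspect·(L_i +
  L_overlap)/v_elong is the window during which a polymerase occupies the
  shared region. This is a contract-level reconstruction of the overlapping
  promoter model in the convergent geometry: interference is mutual, grows
  with the opposing promoter's effective rate, and vanishes as the coupling
  goes to zero. It deliberately uses the pre-interference rate of the
  opposing promoter, keeping the rates explicit (no fixed point). The
  escape formula is isolated in one function so a different interference
  law can be swapped in.
* **Diffusion.** C crosses the membrane passively at k_diff; the flux into
  the medium is scaled by the instantaneous cell number and the volume
  ratio N·V_cell/V_env, so extracellular signal accumulates as the culture
  grows.
* **Replication.** Each operator state is replicated at μ(t). Combined with
  dilution this keeps the total at one copy per cell while letting the
  bound/free partition evolve freely — DNA duplication exactly tracks
  growth.
* **Dilution.** All cell-compartment species are diluted at
  μ(t) = Ṅ/N; the medium compartment is not diluted.

Truncated transcripts produced by polymerase collisions are not tracked;
interference only reduces full-length mRNA output, which is the observed
quantity. The SCB–repressor stoichiometry C₂•R₂ is modelled as a single
second-order-in-C binding step (fewest species honouring the 2:1
stoichiometry). GBL precursor metabolism is absorbed into the synthesis
rate k_C (production of C proportional to A). The R_act mechanism is a
multiplicative fold on *scbA* transcription proportional to the R₂
occupancy of O_R (the repressor's own operator), neutral at fold 1; the RA
mechanism both sequesters R₂ (relieving repression) and activates *scbA*
in proportion to the AR-bound fraction of O_A′.

## Growth model

The culture follows the six-parameter Baranyi–Roberts model with Richards
exponent m and lag adjustment α(t) = q(t)/(1+q(t)), q(t) = q₀e^{vt},
q₀ = 1/(e^{vλ}−1). Because the ODE is separable in the adjusted time
A(t) = ∫α, N(t) and μ(t) are evaluated in closed form (numerically
stabilised with softplus/logistic primitives); the m = 1, λ = 0 limit
reduces to the logistic equation and serves as an oracle. Fitting uses
multi-start trust-region least squares on log population (multiplicative
error), parameters in log space with positivity bounds; all converged fits
within 1.05× of the best SSE form the confidence set — with only ~11
observations many parameter vectors fit comparably and the set's spread is
the reported uncertainty. v and λ are fitted jointly (no h₀ = vλ tie).
Flat observations are returned as a flagged degenerate fit rather than an
optimiser result. Default ground truth sits mid-range of the reference
culture: K = 8·10¹² cells, N₀ = 10¹¹, μ_max = 0.005 min⁻¹, v = 0.01 min⁻¹,
m = 1.2, λ = 600 min.

## Priors and sampling

Each of the 44 sampled parameters carries an independent log-normal prior
elicited as: median = most plausible value, scale set so the plausible
range is the central 95% interval. The shipped table is a reconstructed,
literature-plausible elicitation (e.g. mRNA half-lives of minutes, ScbA
degradation spanning 10⁻³–10⁻¹ min⁻¹, GBL synthesis spanning 10⁻³–10
min⁻¹); it is a package default, fully overridable from a TSV file, and
the prior-table hash is recorded in every run manifest. The promoter
overlap length is a degenerate prior (53 bp exactly). Two parameters are
derived, not sampled: χ = k_FR/k_FA (the promoter heterogeneity factor)
and d_Ce = d_C (internal and external SCBs degrade at the same rate); five
are fixed structural constants (compartment volumes, operator copy
numbers), giving 44 + 2 + 5 = 51. Promoter-strength sweep arms are
realised by rejection-resampling only the (k_FR, k_FA) pair, leaving all
other marginals untouched. The same seeded ensemble is reused for every
scenario, which is what makes pass counts comparable across mechanisms.

## Simulation

LSODA (BDF in the stiff regime) with rtol 10⁻⁶ / atol 10⁻⁹ and an internal
step budget of 6000 steps per output interval, so pathological members
fail fast and are recorded as `solver_failed` instead of raising —
downstream scoring gives them −∞ likelihood. The output grid is 5-min
spaced over the 60 h horizon. Negative excursions above −10⁻⁹ (relative to
the trajectory magnitude) are clipped to zero; larger ones mark the result
`nonphysical`. At compile time, reactions that can never fire from the
canonical initial state (zero rate constant, or a rate-determining species
with no production route) are pruned; this is what makes nested scenarios
(e.g. the antisense scenario with duplex rate 0) integrate bit-identically
to their reduced counterparts. The general-purpose right-hand-side entry
point does not prune, since callers may evaluate arbitrary states.

## Scoring

TLL is the sum of independent Gaussian log-densities (normalisation
constants included, so it is an absolute quantity) over all target points,
on the linear scale by default with a log-scale (multiplicative) option.
Simulated transcripts map to target units through per-member observation
scale factors s_r, s_a — transcriptomics intensities are not absolute
concentrations, so the scale is itself an uncertain sampled parameter. The
activation threshold is extracted as the intracellular GBL concentration
(nM) at the last upcrossing of the unrepressed-O_A fraction through 50%;
this extraction rule is isolated and configurable. Members that never
activate receive a fixed penalty (default −25) instead of a Gaussian term:
strong enough to matter against typical TLL spreads, finite so a single
missing feature does not erase an otherwise well-fitting member. The pass
criterion is strict: TLL > −140. Predictive density (the ensemble-average
likelihood) is computed with log-sum-exp; failed members contribute zero.

## Enrichment statistics

High-TLL members are compared with the full ensemble by per-parameter
two-sample K–S tests at α/44 (strict Bonferroni over the sampled
parameters) and by bin-wise enrichment: 20 log-spaced bins spanning the
sampled range (enough to resolve per-decade structure without starving
counts), expected probabilities from the full ensemble's empirical
distribution (not the analytic prior — the comparison is against what was
actually sampled), observed counts from the selection, a two-tailed
binomial test per bin, and BH FDR control at 0.05 across the bins of each
parameter (a Bonferroni option exists). Bins with zero expected
probability are merged into neighbours. Growth parameters, which are
fitted rather than sampled, get two-sample K–S tests Bonferroni-corrected
over the six parameters.

## The synthetic study

The generator emulates the reference experiment: hourly transcript targets
over 60 h, eleven growth observations, one activation-threshold value.
The default ground truth runs scenario C (interference + antisense) and
produces the reference shape — transcripts repressed after an initial
equilibration transient, a derepression burst peaking near the growth
transition (~28 h), decline to near zero as fast ScbA turnover starves GBL
synthesis and the reactivated repressor shuts both promoters down; the
activation threshold is ~58 nM and the true promoter-strength ratio is
χ = 4. Injected noise is multiplicative log-normal (default sd 0.1 for
transcripts, 0.05 for growth); quoted uncertainties are 30% of the value
plus a floor of 10% of the profile peak, the conservative error bar a
single-replicate transcriptomics series warrants. With these conditions
the maximal achievable TLL is ≈ +19, the generating member scores ≈ +17,
and the −140 criterion separates roughly-right-shaped members from
wrong-mechanism ones while leaving enough passing members for enrichment
analysis.

What passing tests show: the pipeline recovers a known mechanism and known
parameter regions from data of the reference study's size and noise —
the generating member ranks in the top percentile, the generating scenario's
pass count and predictive density dominate the repressor-as-activator
alternative, and threshold-level selection concentrates χ (2–8 window) and
the ScbA degradation rate near their generating values while rejecting
extreme GBL synthesis rates. What they do not show: identifiability of
every parameter (k_C in particular is only weakly constrained at threshold
level), robustness to microarray platform effects beyond a multiplicative
scale factor, or anything about spatial/filamentous structure, stochastic
switching, or death-phase growth, none of which are modelled.

## Problem sizes and numerical defaults

Default analysis sizes are chosen for a single CPU: the demonstration and
acceptance runs use 250–500 members per scenario (a 250×8 run takes ~4
minutes); the API scales to the 10,000-member ensembles of a full study by
raising `n`. Solver tolerances, the TLL threshold, bin counts, the
interference coupling and the threshold-extraction rule are all exposed in
configuration. Ties in the BH step-up are handled by stable sorting;
repression factors are clamped on construction to ρ₂ ≤ ρ₁ ≤ 1; exact zeros
are accepted for rate constants only, as switch-off limits of mechanisms.

## Known limitations

* The interference law and the activation-threshold extraction are
  contract-level reconstructions; both are isolated behind single
  functions and documented as replacement points.
* Operator binding is modelled with explicit bound-state ODEs; the
  equilibrium-occupancy route (`occupancy_fractions`) exists for reduced
  oracles but is not the simulator default.
* The likelihood treats target points as independent; temporally
  correlated residuals would require a covariance model the target format
  does not carry.
* Biomass-to-cell-count calibration is out of scope: the generator emits
  cell counts directly.
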