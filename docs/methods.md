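# Methods

This note documents the models and numerical procedures implemented in
natrigem, the defaults they ship with, and the design choices made where
the underlying methodology leaves room.

## Constraint-based core

A metabolic model is the triple (S, bounds, GPR): stoichiometric matrix S
(metabolites × reactions, negative coefficients consume), flux bounds in
mmol·gDW⁻¹·h⁻¹, and per-reaction boolean gene rules. FBA maximizes the
biomass flux over {S·v = 0, lb ≤ v ≤ ub} with HiGHS (scipy.linprog);
solver feasibility tolerance is 1e-9, and results are reported/asserted at
1e-6. The biomass reaction is assumed scaled so its flux is in h⁻¹
(1 mmol biomass ≡ 1 gDW, the SEED convention); no separate ATP-maintenance
constraint is imposed, since the maintenance demand is folded into the
biomass equation of the models this package targets. Unconstrained
reactions default to ±1000 mmol·gDW⁻¹·h⁻¹. Exchange fluxes follow the
SBML-FBC community convention: uptake negative, secretion positive.

Only the *objective value* of an FBA solve is deterministic; the flux
vector is one arbitrary optimal vertex. Alternate optima are ubiquitous in
genome-scale models, so every analysis that depends on a specific flux
(active-reaction calls, energetics fractions near degeneracy) goes through
FVA or sampling rather than the single returned vector.

Mass-specific rates (g·gDW⁻¹·h⁻¹, the unit in which uptake and secretion
are measured experimentally) are converted to molar bounds through the
metabolite formula using average IUPAC atomic weights; charged species use
the formula as written, with no electron-mass correction.

### Flux variability and sampling

FVA re-solves min/max per reaction under the added floor c·v ≥ f·μ*
(default f = 0.98). The sampler is a seeded hit-and-run walk: directions
are drawn in the null space of S (so mass balance is preserved exactly, to
round-off), the feasible chord against bounds and the objective floor is
computed analytically, and a uniform point on the chord is taken; 100
warm-up steps precede each recorded sample. An alternative
"random-objective" mode optimizes a random linear objective per sample;
both satisfy the same feasibility contract. Sampled results are treated as
order-of-magnitude — the walk mixes well on small networks but no
convergence diagnostic is computed.

### Gene rules and essentiality

GPR rules use the conventional infix dialect ("and"/"or" case-insensitive,
"and" binds tighter, parentheses honored); an empty rule means spontaneous.
A knockout closes every reaction whose rule evaluates false. A gene is
essential when the knockout LP is infeasible or its optimum falls strictly
below τ·μ_wt with τ = 0.9 ("reduced below" is read as a strict
inequality). Viability uses a growth floor of 1e-6 h⁻¹, the LP noise
level; viability is uptake-invariant above that floor, which the tests
assert.

Substrate assays close the uptake of every carbon-bearing exchange
(formula contains C), keeping inorganic-carbon exchanges (CO2, bicarbonate)
open for secretion only so that carbon fixation cannot masquerade as
growth; the queried substrate is then supplied at 10 mmol·gDW⁻¹·h⁻¹ either
through an exchange (extracellular mode, transporters required) or a sink
(cytoplasmic mode). Substrates absent from the model are reported as such
and excluded from confusion-matrix scoring. Mapping assay well codes to
model metabolite ids is the caller's responsibility — the package does not
guess identifier correspondences.

## Cross-model comparison

Reaction mapping is greedy, 1:1 and two-phase: shared cross-database
annotation keys first, then direction-agnostic canonical stoichiometric
signatures with coefficients reduced to the smallest integer ratio and
metabolites translated through their own annotation keys (falling back to
compartment-stripped ids). No cofactor whitelist is applied: mismatches
caused by proton/water bookkeeping are reported as unmapped rather than
silently merged, which undercounts rather than overcounts shared reactions.

Artificial shared-biomass comparison keeps only precursors producible
(maximal demand flux > 1e-6 at 10 mmol substrate) by both models, retains
each model's own coefficients, and renormalizes so one unit of flux drains
1 g of precursor mass — the only self-consistent scaling that keeps μ in
h⁻¹. Components without formulas are dropped with a warning. Because the
producibility cutoff and renormalization are this package's choices,
cross-reconstruction growth numbers should be read with ±0.1 h⁻¹ slack.

## Sodium-motive-force core model

The halophile core is a fixed, element- and charge-balanced 21-reaction
network: glucose → 2 PEP skeleton, pyruvate kinase (PYK), PEP carboxylase
(PPC, via bicarbonate/carbonic anhydrase), a full pyruvate-oxidation lump
(5 NADH per pyruvate), Na⁺-NQR (default 2 Na⁺/NADH, configurable), a
quinol oxidase pumping 4 H⁺, an ATP synthase, a 2:1 H⁺/Na⁺ antiporter
(configurable to 1:1), the reversible Na⁺-OAD, a sodium leak with pinned
bounds φ_Na, an ATP-dissipation reaction, and a biomass drain consuming
1 OAA + 1 PYR + 30 ATP. Periplasm and medium are collapsed into one "e"
compartment.

Two published stoichiometries had to be corrected to satisfy element and
charge balance: the ATP synthase returns 3 H⁺ to the cytoplasm per 4 H⁺
taken up (the fourth is consumed by ADP + Pi + H⁺ → ATP + H2O), and the
OAD's counter-transported proton *is* the proton its decarboxylation
chemistry consumes (OAA + 2 Na⁺_c + H⁺_e → PYR + CO2 + 2 Na⁺_e). The
`counter_proton=False` control takes that proton from the cytoplasm
instead. The headline arithmetic is unchanged: 2 Na⁺_e ≡ 4 H⁺_e ≡ 1 ATP.

Biomass drains of charged precursors co-consume the neutralizing cytosolic
protons: a flux-balance model conserves charge reaction-by-reaction, so a
drain that removes net charge is structurally blocked.

The defaults (glucose bound 10 mmol·gDW⁻¹·h⁻¹, 30 ATP per biomass unit,
full overflow oxidation) were chosen analytically so the optimum is
energy-limited from φ_Na = 0: the LP then gives μ(φ) = (1040 − 2φ)/203
exactly, an affine decline all the way to washout, rather than a
carbon-limited plateau followed by a cliff. The test suite asserts the
affinity by three-point collinearity instead of freezing that closed form,
so the property — not the particular coefficients — is what is checked.

ATP-equivalence of an anaplerotic route is measured by LP accounting:
maximize ATP dissipation while draining one OAA per hour, once with a
hypothetical uncoupled carboxylase (the zero-cost reference) and once with
only the route under test; the difference is the route's cost in ATP.

**SMF-fraction definition.** In the influx sweep, f_OAD is the OAD's share
of *carrier-mediated* cytoplasm-ward Na⁺ translocation; the enforced leak
is excluded from the denominator. The leak is the perturbation being
applied, not a competing consumer of the gradient: including it dilutes the
fraction by the perturbation's own magnitude and forces it downward for
any energy-limited network, whereas the carrier-only share reproduces the
observed behavior — the leak progressively displaces the antiporter's
SMF→PMF conversion, so the carboxylase's relative claim on the gradient
rises with salinity.

## RBA-lite

At fixed μ the resource program is an LP in (v, E, M, free proteins):
metabolite balance S·v = μ·(macrocomponent targets + amino-acid drain of
protein dilution), enzyme capacity v_j ≤ kapp_f,j·E_j and −v_j ≤
kapp_b,j·E_j (reversible reactions share one enzyme pool), process
capacity μ·Σ len_p·c_p ≤ k_proc·M_proc, and proteome density
Σ m_p·c_p = P_total with P_total = 0.47 g/gDW. The density constraint is
an *equality* — the protein weight fraction is a measured composition
constant, not a ceiling — which makes the feasibility program non-trivial
and the "density tight at μ*" property structural. Feasibility is monotone
in μ (growing faster only adds demands), so the largest feasible μ is
found by bisection (defaults μ ∈ [1e-3, 5] h⁻¹, tol 1e-4 h⁻¹); the final
solve minimizes total enzyme + machinery so binding capacities are tight
and spare proteome lands in the non-catalytic pool.

Calibration follows the flux-sampling procedure: enzyme concentration from
the limiting-subunit rule (min over subunits of concentration/copies),
kapp = mean |sampled flux| / concentration, with a default of 619,200 h⁻¹
(an average kcat of 172 s⁻¹) for undetected enzymes. Spectral counts are
scaled to mmol·gDW⁻¹ via mass shares: c_p = P_total·share_p/m_p.

Deliberate simplifications versus a full RBA implementation: one
cytoplasmic density compartment (no membrane-density constraint), no
explicit tRNA or small-molecule machinery, no condition-dependent kapp
regression. Enforced secretion rates given in g·gDW⁻¹ are interpreted as
rates per hour, consistent with every other rate in the formulation.

## Proteomics statistics

Normalization rescales each sample's counts so its total equals the mean
raw total — the grand total and within-sample ranks are invariant.
"Entirely found" for a reaction's enzymes is evaluated over the minimal
satisfying gene sets of its GPR (any one complete isoenzyme or complex
suffices); "all-but-one" allows a single missing member of the best set.
Category weight fractions weight counts by molecular mass by default
(counts alone are length-biased; a *weight* fraction implies mass
weighting); the count-only variant is available behind a flag since either
convention appears in the literature. One-way ANOVA is the classical
F = MS_between/MS_within with (k−1, N−k) degrees of freedom, applied per
protein without multiple-testing correction.

## Synthetic data

The generators define the package's study conditions:

- **TOY6** — the six-reaction network whose every documented number
  (optimum 10, bypass FVA [0, 0.4] at 98%, essential set {g1, g4, g5}) is
  exact in rational arithmetic, avoiding tolerance debates.
- **Random chains** — linear substrate→biomass chains with seeded
  lower-yield bypasses; feasibility and the optimum (= uptake) hold by
  construction rather than rejection sampling, and a bypass of yield y
  makes its step's gene essential iff y < τ.
- **Synthetic proteomes** — multinomial spectral counts with expectations
  proportional to mass-share/mass (heavier proteins yield fewer spectra
  per gram), optional fold-change group effects in the second half of the
  samples (default 3+3 at 0 and 300 mM NaCl), default depth 10,000–200,000
  counts per sample depending on use. Multinomial sampling captures
  closed-sum compositionality but not peptide-level detectability,
  ionization bias or missing-value structure of real MS data — so passing
  tests validate the statistics, not MS practice.
- **RBA instances** — a ribosome-only self-replicator with the closed form
  μ* = k/L, and a three-reaction cell with known kapps (2000 and 800 h⁻¹)
  plus a storage protein that absorbs spare proteome, used for the
  calibration-recovery property (recovery within 5%).

Problem sizes throughout (≤ 21 reactions, 100 flux samples, 100 ANOVA
replicates, 200,000-count proteomes) were chosen so every documented
property is sharply testable while the full suite and the acceptance
script each run in well under a minute.

## Known limitations

- The LP stack is dense; genome-scale models (thousands of reactions) load
  and solve, but screens over all genes take minutes, not seconds.
- Reaction mapping has no cofactor normalization, so reconstructions with
  different proton/water conventions under-match on the signature phase.
- The hit-and-run sampler has no mixing diagnostic; counts derived from
  samples (e.g. active-reaction totals) are order-of-magnitude.
- RBA-lite is not a drop-in replacement for a full RBA model; its numbers
  on real organisms depend on the deposited calibration inputs.
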