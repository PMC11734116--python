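# Methods

## The model

`seabed_era` implements a discrete Bayesian network (BN) for quantifying the
ecological risk that seabed mining poses to benthic fauna, with the Chatham
Rise (SW Pacific) phosphorite-nodule case as the packaged default.  A BN is a
directed acyclic graph whose nodes are discrete variables and whose edges
carry conditional probability tables (CPTs); the product of all CPTs defines
the joint distribution

    P(X1..Xn) = prod_i P(Xi | parents(Xi)).

The default network has 73 variables and 154 edges in four tiers:

* **operational** (5 decision variables): mining intensity {50, 75, 100 % of
  the block}, depth of extracted sediment {<10, 10–30, >30 cm}, processing
  return technique {10 m above seafloor, at seafloor}, nodule removal
  {yes, no}, and the spatial domain of the query {inside, near-field,
  far-field}.  Decision variables carry no CPT; they are fixed as evidence
  (or given an explicit prior when sampling without evidence).
* **environment** (3): particle-size composition (nominal), sediment
  contaminant load, and food availability after disturbance.
* **pressure** (5): extracted volume, near-bed suspended sediment
  concentration (SSC, mg L⁻¹ classes), sediment deposition (cm classes),
  contaminant release, and changes in sediment characteristics.
* **biota** (60): for each of 15 trait-based functional groups, four nodes —
  direct, indirect, immediate and one-year decrease in abundance — each over
  five ordinal bins {0–20, 21–40, 41–60, 61–80, 81–100 %} relative to the
  pre-disturbance state.  Only decrease is modelled; post-disturbance
  abundance increases are deliberately out of scope.

Seven variables are parentless: the five decision variables plus the two
environmental roots (particle size, contaminant load).  State labels are
ordinal categories, not parsed intervals; the only numeric reading of the
decrease bins is through their midpoints (0.1, 0.3, 0.5, 0.7, 0.9) in
summary statistics and the deterministic constructors below.

## Inference

Exact inference uses variable elimination over factors.  The elimination
order is the min-fill heuristic with a lexicographic tie-break, which is
deterministic and adequate at this network's treewidth (sub-second queries
for all 68 posteriors of a scenario).  Normalization happens once, at the
end of each query; evidence with probability zero raises an error rather
than propagating NaNs.  Two independent cross-checks guard the
implementation: a brute-force tensor-product enumeration of the full joint
(guarded at 10⁶ cells) and forward ancestral sampling.  The test suite
requires agreement with enumeration to 1e-9 across 50 random networks and
total-variation distance < 0.01 between 10⁵ forward samples and the exact
marginals of the default model.

CPT columns must sum to one within 1e-9; columns off by at most 1e-6 are
renormalized with a logged warning, larger deviations are validation
failures.

## CPT generation from minimal expert input

Eliciting the 18-column CPT of every plume-response node directly is
infeasible, so the package implements a best/worst-case interpolation
scheme.  For a child with parents i = 1..m the input is:

* a best-case beta distribution Beta(α_b, β_b) — the child's decrease when
  every parent is at its most favorable state;
* a worst-case Beta(α_w, β_w) — every parent at its least favorable state;
* per parent, a weight w_i ≥ 0 and a score s_ij ∈ [0, 1] per state j,
  nondecreasing over the ordinal state order with min 0 and max 1.

For a parent configuration c the relevance index is

    λ(c) = Σ_i w_i s_i(c) / Σ_i w_i  ∈ [0, 1],

the interpolated response is Beta(α(λ), β(λ)) with α and β linear in λ
between the elicited endpoints, and the CPT column is the vector of bin
masses I(e_{k+1}; α, β) − I(e_k; α, β), where I is the regularized
incomplete beta function.  λ = 0 and λ = 1 reproduce the elicited endpoint
columns exactly (to 1e-12 in the tests).

Two properties justify the linear-(α, β) choice.  First, the mean
α(λ)/(α(λ)+β(λ)) is a ratio of linear functions of λ and hence monotone from
the best-case mean to the worst-case mean, for any admissible endpoint pair.
Second, when the worst case dominates the best case in likelihood-ratio
order (α_w ≥ α_b and β_w ≤ β_b) every pair of interpolants is MLR-ordered in
λ, so the whole family is stochastically increasing and raising any single
parent's state can never lower the expected decrease.  This LR condition is
not implied by mean ordering alone — a near-point-mass best case against a
U-shaped worst case can make the binned expectation dip mid-path — so the
ordinal-coherence property is asserted (and should be relied on) for
LR-ordered specs; every shipped default satisfies the condition.
Interpolating moments (mean/precision) instead of (α, β) is a defensible
alternative; it was not adopted because it loses the exact-endpoint property
under moment fitting and complicates the monotonicity argument.

Nominal parents (particle size) bypass the scheme: their CPTs are specified
directly in the configuration.

### Empirical best cases

Where survey data exist, the best-case distribution is fitted rather than
elicited: bootstrap replicates of the relative decrease 1 − mean_impact /
mean_control (clipped to [0, 1], 1000 replicates by default) are fed to a
method-of-moments beta fit, α = m(m(1−m)/v − 1), β = (1−m)(m(1−m)/v − 1),
with samples clipped to [0.001, 0.999] and a hard error when the sample
variance is incompatible with any beta distribution (v ≥ m(1−m) or v = 0);
the advice in that case is a point-mass column.

## Deterministic biota constructors

**Direct removal.**  Inside the mined block the fraction removed is
p(intensity) · (1 − escape) · d(depth), zero elsewhere.  p is the mined-area
share {0.5, 0.75, 1.0}; escape is 0 for sessile epifauna and infauna, 0.2
for mobile epifauna, 0.3 for hyperbenthos (most organisms in the tool's path
are removed, a small portion of mobile fauna can flee); d is 1 for
epifauna/hyperbenthos and {0.8, 0.95, 1.0} at {<10, 10–30, >30 cm} for the
six infaunal groups, encoding that a shallow cut spares deeper-dwelling
individuals.  All three vectors are configurable; the depth multipliers are
a reconstruction, not published values.  The direct CPT is a point mass on
the bin containing the fraction; a fraction exactly on a bin edge goes to
the lower-impact bin (so 0.4 at 50 % intensity lands in 21–40 %).

**Immediate combination.**  With the direct decrease D1 uniform on its bin
and the indirect decrease D2 uniform on its bin, the total immediate
decrease is T = 1 − (1−D1)(1−D2): the plume can only affect fauna the tool
left behind.  Columns are computed by midpoint quadrature on a 200×200 grid
(≥50 enforced), agree with the closed form for the (0–20, 0–20) cell,
P(T ≤ 0.2) = 25(0.2 + 0.8 ln 0.8) ≈ 0.537, to 2e-4, and are symmetric and
stochastically dominant over both inputs by construction.

**One-year outcome.**  Given the immediate bin and a habitat state, a
fraction r of the lost abundance is regained: the one-year decrease is
D(1−r) with D uniform on the immediate bin, split over the outcome bins
analytically.  Recovery factors encode the qualitative recovery narrative:
meiofauna 0.5, mobile macroinfauna 0.3, sessile macroinfauna 0.2,
hyperbenthos 0.7 (recolonization), hard-substrate sessile epifauna 0.15 —
each cut (to 0.2/0.1/0.05/0.4/0.02 respectively) when sediment changes are
significant, since habitat alteration and complete nodule removal remove
the settlement substrate.  The soft-bodied erect group recolonizes quickly
(r = 0.8, no habitat parent); the two mobile epifauna groups instead
respond to food availability (r = 0.40 → 0.48 when food increases on
disturbed sediment).  The food bonus is deliberately small: it must stay
below the scenario gap in far-field immediate impact, otherwise a harsher
mining plan could paradoxically predict a *lower* expected one-year decrease
through its food subsidy.

## Pressure parameterization

Pressure CPTs use a compact ordinal-response rule: each parent state maps to
a severity contribution, the clipped total t ∈ [0.02, 0.98] drives a
binomial column Binomial(K−1, t) over the child's K ordered states.  This
yields monotone, smoothly varying columns from a handful of coefficients.
The coefficients (and the root priors: particle size most likely mixed,
contaminant load most likely low) were set so that the assembled model
reproduces the qualitative posterior pattern of the assessed scenarios:
moderate SSC most likely inside and near-field with low SSC far-field; high
deposition inside and low far-field; significant contaminant release under
50 % probability everywhere (release depends only on the environmental
roots, so it barely distinguishes scenarios); significant sediment change
confined to the mined block under intermediate disturbance but extending
outside it under high disturbance.  The two scenario definitions are
high = (100 %, >30 cm, at seafloor, nodules removed) and intermediate =
(50 %, <10 cm, at seafloor, nodules not fully removed); treating nodule
removal as "no" under the intermediate plan encodes that half the block's
nodules remain, and is what separates the sediment-change footprints of the
two plans.

These numbers are a calibrated reconstruction of an expert-built model, not
field-measured rates; every coefficient, weight, beta pair and recovery
factor can be overridden through a JSON patch merged over the default
configuration.

## Synthetic data

The survey generator draws negative-binomial core counts (patchy benthic
counts are overdispersed; Poisson would understate the spread) with
configurable dispersion, a control arm at the group's mean density and an
impact arm scaled by 1 − true decrease.  The default recovery experiment
uses 200 cores per arm, density 50 per core, dispersion 5 and a true
decrease of 0.4; at that design a single survey's decrease estimate has a
standard error of about 0.026 plus a small ratio-estimator bias, so recovery
is judged on the across-seed mean of the fitted beta means (within ±0.05
over 10 seeds).  The random-network generator (random topological order,
parents drawn from predecessors, symmetric-Dirichlet CPT columns) exists
purely to exercise inference against the enumeration oracle.

What the generators do *not* emulate: spatial autocorrelation between
cores, taxonomic structure within functional groups, measurement error in
pressure variables, and any real field data.  Passing tests therefore
demonstrate internal correctness and calibration of the reconstruction, not
predictive validity for the Chatham Rise.

## Numerical and interface choices

* Probability tolerance 1e-9; renormalization window 1e-6; elimination
  tie-breaks lexicographic; all RNG seeds are explicit arguments, no global
  state.
* Bin-edge ties always resolve to the lower-impact bin, uniformly across
  the direct, combination and recovery constructors.
* Most-likely-outcome ties resolve to the lower-impact state.
* Reported time steps are immediate and year-1; direct and indirect nodes
  are internal.  Output ordering (scenario, domain, group, time step) is
  fixed so CSV diffs are deterministic; probabilities print with 6 decimals.
* Scenario comparison uses signed differences of expected decrease and
  total-variation distance between bin posteriors.
* Test problem sizes: oracle suite 50 networks of 10 ternary nodes;
  Monte-Carlo check of the combination rule 10⁶ draws per bin pair (10
  pairs); sampling consistency 10⁵ draws; survey recovery 10 seeds × 200
  cores × 1000 bootstrap replicates.

## Known limitations

The edge set and all parameters are one consistent reconstruction
constrained to the published structure counts (73 variables, 154 edges,
7 independent variables) and qualitative results; the archived original
model is authoritative and is deliberately not a dependency.  The model is
not spatially explicit (homogeneous impacts within each domain), has no
feedback loops or time slicing beyond the one-year step, excludes noise,
microbial, pelagic and socioeconomic components, and its
intermediate-scenario inside-the-block immediate impacts show more spread
than the high scenario — under the removal calculus used here the 81–100 %
modal decrease for sessile and infaunal groups inside the block is a
high-scenario result.
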