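# Methods

## Overview

`silicogut` builds a personalized in silico gut microbiota for each
individual in a cohort: per-sample genome-coverage tables are turned
into relative strain abundances, each strain is represented by a
genome-scale (here: toy-scale) metabolic model, and the community is
simulated as individuals on a grid that grow by flux balance analysis
(FBA) while exchanging metabolites through one shared, well-mixed pool.
The short-chain fatty acid (SCFA) concentrations that accumulate in the
environment — butyrate, propionate, isobutyrate, acetate, and
L-lactate — are emergent read-outs; group differences between healthy
and dysbiotic communities, and personalized dietary supplements that
restore SCFA output, are derived from them.

## Abundance estimation

Coverage depth of a strain is `mapped_reads / genome_length` (reads per
bp).  Strains whose *breadth* of coverage (fraction of genome positions
covered at least once, carried as `covered_fraction`) is below 1 % are
treated as cross-mapping false positives and removed; the comparison is
inclusive (breadth = 1 % is kept).  Breadth is the filtering quantity
because a depth threshold of 0.01 reads/bp would scale with genome
size; depth remains the abundance weight.  Remaining depths are
normalized per sample to relative abundances summing to one.  Samples
are compared with Bray–Curtis dissimilarity (scipy) and classical
metric scaling (PCoA, via scikit-bio); explained-variance fractions are
computed over positive eigenvalues only, with negative eigenvalues
clamped to zero and no Lingoes/Cailliez correction.  Model repertoires
are compared with the Jaccard distance between per-sample reaction-id
unions.

### Rank-sum test

Group differences use the two-sided Wilcoxon rank-sum test.  For
combined n ≤ 20 the p-value is exact: all `C(n, n1)` label assignments
of the observed midranks are enumerated, and the two-sided p doubles
the smaller one-sided tail (capped at 1).  This differs from textbook
exact tables only in the presence of ties, where midrank enumeration is
the correct permutation null.  Larger samples fall back to the
tie-corrected normal approximation (scipy).  If all values are tied,
p = 1.  The exact branch is independently verified in the test suite
against a pure-Python full enumeration and against scipy's exact method
on tie-free inputs.

## Metabolic models and FBA

Models follow the standard constraint-based conventions: compartments
`c`/`e`, flux bounds in mmol·gDW⁻¹·h⁻¹, boundary exchange reactions
`EX_<met>_e` moving one extracellular metabolite with coefficient −1
(negative flux = uptake), and a single biomass objective whose flux is
read as the specific growth rate µ (h⁻¹; one flux unit of biomass
metabolite ≡ 1 gDW).  I/O is SBML Level 3 + FBC and the COBRA JSON
dialect, both through COBRApy; the LP backend is optlang/GLPK.
Degenerate alternative optima are accepted: the objective value is the
contract, individual fluxes are reported as returned by the solver.
Infeasible problems carry an explicit `infeasible` status and are
interpreted by the simulator as µ = 0, not as death.

## Toy models (synthetic data)

Real gut reconstructions are thousands of reactions; the synthetic
world distills the division of labor relevant to SCFA cross-feeding
into five fixed role templates of ≤ 6 internal reactions each.  Every
metabolite carries an integer carbon pseudo-element (`C<n>` formula) and
every internal reaction is exactly carbon-balanced, so stoichiometric
consistency is checkable without real chemistry; exchanges, transports
and the biomass drain are boundary reactions and exempt, as usual.

| role | class | pathways (carbon-balanced) |
|---|---|---|
| fiber fermenter | Bacteroidia | fiber(C24) → 3 propionate + 0.5 isobutyrate + 4 acetate + biomass(C5); glc → biomass + 0.5 acetate |
| butyrate crossfeeder | Clostridia | 2 glc → biomass(C12); 8 acetate → biomass(C12) + butyrate |
| lactate producer | Bacilli | 2 glc → 3 L-lactate + biomass(C3) |
| acetate producer | Gammaproteobacteria | glc → 2 acetate + biomass(C2) |
| generalist | Other | 2 glc → biomass(C6) + 1.5 isobutyrate; fiber and acetate burned to inert waste |

Two uptake regimes shape the dynamics.  Glucose uptake is fast
(lb = −10), so the glucose pool is consumed within the first steps and
fuels early divisions.  Fiber and acetate uptake are slow (lb = −0.05),
so over 24 h their consumption is *capacity*-limited: the share of a
substrate pool a taxon converts is proportional to its abundance, which
is what makes the SCFA output an emergent function of community
composition — and what leaves headroom for a 100× supplement to raise
consumption.  The generalist competes for fiber and acetate without
producing SCFAs from them, so that the fermenters' substrate share
tracks their relative, not absolute, abundance.  Isobutyrate comes
mostly from the generalist with a low-yield contribution from the fiber
fermenters; the attribution of the residual isobutyrate/acetate
production is a modeling choice, not an observed mechanism.

## Synthetic cohort

A fixed universe of 25 strains (5 per taxon class, deterministic genome
lengths of 2.5–6.1 Mb) underlies the cohort.  Each sample draws a
species count from its group's diversity range (healthy 12–18,
dysbiotic 6–10), selects strains without replacement with probabilities
proportional to the group's class mix, and draws abundances from a
Dirichlet with per-strain concentration `τ·mix(class)/5` (τ = 60,
clipped at 0.3).  Default class mixes: healthy 0.35/0.35/0.10/0.10/0.10
and dysbiotic 0.05/0.05/0.35/0.35/0.20 over
Bacteroidia/Clostridia/Bacilli/Gammaproteobacteria/Other.  Coverage
tables are produced by inverting the abundance model at a total mapping
depth of 0.05 reads/bp, with breadth following the Lander–Waterman
saturation `1 − exp(−150·depth)`; 2–4 absent strains per sample receive
sub-threshold depths so the 1 % filter is always exercised.  All
randomness flows through one seeded generator; regeneration is
byte-identical.

What the generator does *not* emulate: read-level errors, strain-level
genomic variation, compositional coupling between sequencing depth and
community size, intra-class metabolic diversity, and any host signal.
Passing tests therefore demonstrate the pipeline's correctness and the
qualitative emergent behavior of the modeled ecology, not quantitative
agreement with stool metabolomics.

## Community simulation

The arena is a 100 × 100 grid (10,000 cells) declared to span
0.025 cm².  A depth of 0.01 cm (configurable) gives a volume of
2.5e-4 mL, required to convert between concentrations and amounts;
amount (µmol) = concentration (mM) × volume (L) × 1000.  Each sample is
seeded with `ceil(500·aᵢ)` founder agents per species — every detected
species gets at least one individual, totals are ≥ 500 — at founder
biomass m₀ = 5e-13 gDW (the order of one bacterial cell's dry weight)
on distinct uniformly random cells.  The rich medium contains the union
of all metabolites any present species can take up, each at 0.2 µM.

Each of the 24 hourly steps visits the live agents in a freshly drawn
random order.  Per agent: exchange lower bounds are tightened to
`max(lb, −pool/(m·dt))` so cumulative uptake can never drive a pool
negative; FBA maximizes the biomass reaction; pools are updated
immediately by `flux · m · dt` (sequential updates — later agents see
earlier agents' consumption, which prevents oversubscription of finite
pools); biomass grows linearly, `m ← m·(1 + µ·dt)` (with dt = 1 h and
sequential pool coupling, higher-order integration would add nothing);
agents at `m ≥ 2·m₀` divide into two halves, the daughter placed on a
random free cell.  Because the environment is well-mixed, positions
carry no metabolic meaning and random placement at division stands in
for movement.  If the grid is full the division is suppressed and
biomass capped (logged).  A death rule — removal after K consecutive
zero-growth steps — is available but disabled by default (K = ∞),
since the modeled dynamics specify no mortality; with the default
substrate pools a finite K would simply remove whichever taxa exhaust
their substrate first.  Identical (species, effective-bounds) LP
subproblems within a run share one cached solution; this is exact, not
an approximation, because the solution depends only on the bounds.

Numerical notes: when an uptake hits the pool-derived bound, the logged
amount is capped at exactly the remaining pool, so mass bookkeeping
closes to ≤ 1e-9 relative at every step by construction (and is
asserted on every simulated cohort).  Pools are stored in mmol;
concentrations are mmol / volume = mM.

## SCFA signatures and attribution

A sample's signature is the five SCFA concentrations at t = 24 h (the
final state; earlier time points are accessible).  An SCFA absent from
the sample's entire metabolite namespace is reported as 0 mM with a
warning.  Taxon attribution sums the logged per-agent exchange amounts
(flux × biomass × dt, i.e. mmol moved) per class and metabolite — an
exact decomposition of each pool's net change, unlike re-integrated
average fluxes.  Group comparisons report raw rank-sum p-values as
primary, plus a separately labeled Benjamini–Hochberg column.

## Treatment prediction

Candidates are diet metabolites taken up by at least one present model
of the depleted classes (Clostridia, Bacteroidia) and — in the default
strict mode — by no present model of the overrepresented classes
(Gammaproteobacteria, Bacilli).  The comparative phrasing "preferential
uptake" is genuinely ambiguous, so a relaxed mode (beneficial uptakers
strictly outnumber detrimental ones) is available behind a flag.  Each
candidate is screened independently, one at a time, against every
present beneficial model and every SCFA: both LPs allow all diet
metabolites at uptake 1 mmol·gDW⁻¹·h⁻¹, the boosted LP relaxes only the
candidate to 1000 mmol·gDW⁻¹·h⁻¹, and the gain is the increase of the
maximal SCFA secretion (non-negative by construction, asserted).  A
candidate with gain > 1e-6 mmol·gDW⁻¹·h⁻¹ in any screen joins the plan;
"recovery to healthy levels" has no operational single-model
definition, so the healthy-level question is deferred to community
validation.  A cumulative screening mode (candidates added on top of
one another) is not implemented; the independent-screen interpretation
keeps plans order-invariant.

Validation runs paired 24-h simulations with the same seed: rich medium
versus rich medium plus the plan's supplements at 100 × 0.2 µM.  Per
SCFA, the individual is a responder when the final concentration rises
by ≥ 25 % (zero baseline: any positive treated concentration counts).
Patients without any beneficial-class species get an empty plan and an
all-false report with reason code `empty_plan` — the untreatable-patient
case.  Supplement categories (mucus glycan, glycosaminoglycan, plant
polysaccharide, sugar, other) come from a shipped catalog TSV used for
labeling only.

## Problem sizes and defaults

The default cohort is 10 healthy + 10 dysbiotic samples over the
25-strain universe, each community seeded with ~500–510 agents and
simulated for 24 hourly steps; a full cohort run (generation, 20
simulations, statistics) completes in seconds on one core.  These sizes
were chosen so the pipeline's emergent contrasts are resolvable with
exact small-sample statistics while remaining desk-scale; they are a
miniature of, not a substitute for, a metagenomic cohort against
hundreds of curated reconstructions.

## Known limitations

* No host compartment: SCFA uptake by the gut epithelium is absent, so
  healthy/dysbiotic concentration ratios overstate in vivo differences.
* Well-mixed environment: no spatial gradients, diffusion, or
  chemotaxis; grid positions only enforce a carrying capacity.
* Toy stoichiometry: one model per role; intra-class metabolic
  diversity and realistic yields are out of scope.
* The agent count at 24 h depends on division/death defaults (here: no
  death, division at 2·m₀) and is not calibrated to any reported
  population size.
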