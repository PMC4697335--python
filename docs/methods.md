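# Methods

## Scope and model structure

butyflux models the carbon flow of butyrogenic lysine and fructoselysine
fermentation at three levels: exact elemental stoichiometry of the overall
conversions, positional ¹³C isotopomer composition of the products at
isotopic steady state, and the macroscopic growth curve. The levels are
deliberately decoupled: the balancer knows nothing about atom maps, the
tracer consumes only the atom-mapped network, and growth kinetics are fitted
independently of both.

## Pathway representation

The packaged network (`butyflux/data/pathway.yaml`, `schema_version: 1`)
contains 22 metabolites and 19 atom-mapped reactions in four branches:

* **lysine** (10 enzymatic steps): lysine-2,3-aminomutase,
  β-lysine-5,6-aminomutase, 3,5-diaminohexanoate dehydrogenase, the
  3-keto-5-aminohexanoate cleavage enzyme, 3-aminobutyryl-CoA ammonia-lyase,
  butyryl-CoA dehydrogenase, the butyryl-CoA:acetoacetate CoA transferase
  (AtoD-A), thiolytic cleavage of acetoacetyl-CoA, phosphate
  acetyltransferase and acetate kinase;
* **acetyl_coa**: thiolase condensation, 3-hydroxybutyryl-CoA dehydrogenase,
  crotonase, and the butyryl-CoA:acetate CoA transferase (the
  crotonyl→butyryl reduction is shared with the lysine branch);
* **fructoselysine_entry**: kinase, deglycase (lysine + glucose-6-phosphate),
  lumped Embden–Meyerhof glycolysis with the canonical hexose → 2 pyruvate
  atom map, and pyruvate:ferredoxin oxidoreductase;
* **overflow**: lactate dehydrogenase.

Carbon indices are 1-based from the carboxyl carbon; fructoselysine carbons
1–6 are the lysine moiety and 7–12 the deoxyfructose moiety. Only C/H/O/N
are tracked; CoA thioesters and phosphorylated intermediates appear as their
free-acid/dephospho carbon skeletons, which is sufficient because the
elemental balancer is applied to free-acid conversions only and the atom
maps follow carbons only. Validation enforces, per reaction, a bijection
between substrate and product carbons (instance suffixes `name/k`
disambiguate species with coefficient > 1), and globally that butyrate is
reachable from each declared labelled substrate.

## Elemental balancing

For substrates S and products P with the reference substrate fixed at
coefficient 1 (plus optional fixed ratios, e.g. one acetate co-consumed),
the per-element balance is solved exactly over the rationals (sympy
Gauss–Jordan). The solution-space dimension is reported. For dimension 1,
the selected member is the minimal non-negative all-integer solution
(coefficient sum minimized, coefficients capped at 60); this convention
reproduces the fructoselysine-alone conversion (2 butyrate, 2 NH₃, 1 CO₂,
1 lactate per fructoselysine) without auxiliary constraints, and the family
there admits exactly one such member. Dimensions above 1 raise an ambiguity
error asking for constraints. Infeasible systems raise an error naming the
inconsistent element rows. Output is invariant under permutation of the
input species (species are sorted internally).

Ammonia assimilation into biomass is deliberately **not** a reaction:
equations are balanced over free species, and the shortfall between
stoichiometric and measured NH₃ is reported downstream as the
ammonia-sequestration gap.

## Isotope tracer

The tracer computes exact distributions over the 2ⁿ positional labelling
states (n ≤ 12 here, so full enumeration is cheap; no EMU decomposition).
Assumptions:

* **Isotopic steady state.** Supernatants are sampled after overnight/
  end-point growth; no time-resolved labelling dynamics.
* **Well-mixed acetyl-CoA pool.** The two units condensing to
  acetoacetyl-CoA are independent draws from one pool.
* **Single mixing weight θ_lys** pools lysine-branch and condensation
  butyrate; no compartments.
* **Natural ¹³C abundance (1.1%) ignored** — quantification is relative to
  enriched positions.

Butyrate: B = θ·δ(substrate C3..C6) + (1−θ)·(x ⊗ x), where the condensation
places one acetyl unit on C1–C2 and the other on C3–C4 (methyl carbons on C2
and C4). Acetate is the pool x itself. The pool solves

x = w_lys·δ(C1C2 fragment) + w_rec·[θ·½(half₁₂ + half₃₄) + (1−θ)·x]
  + w_exo·δ(acetate pattern) + w_gly·d_glycolysis

The recycled source models the CoA-transferase/thiolase exchange at the
acetoacetyl-CoA node: acetyl units recovered by thiolytic cleavage of the
exchange pool, whose condensation marginals collapse to x and whose
lysine-branch contribution is the two halves of the butyryl skeleton. This
is the route by which a C6 label reaches butyrate C2 and produces minor
methyl-labelled acetate — both observed experimentally — and it keeps the
fixed point linear with contraction factor w_rec(1−θ). The equation is
solved by damped iteration (default tolerance 1e−10 in max norm, cap 10⁴
iterations); it is singular, and a degenerate-input error is raised, when
w_rec(1−θ) ≥ 1 (a closed recycling loop with no label source). A structural
consequence worth knowing: with unlabelled exogenous sources the pool's
methyl-label mass is capped at ½, so the model cannot produce
p24 > p2 — observations outside that manifold fit with a boundary solution
and a non-zero residual.

Carbon routing is **derived from the packaged atom maps** at run time
(`branch_carbon_fate` composes maps to a fixed point), not hard-coded; the
derived maps (lysine 3→1 … 6→4 into butyrate, lysine 1,2 into the acetyl
fragment) are pinned by tests.

The three HMBC classes are the marginals of the butyrate distribution by
C2/C4 status among labelled molecules; label at C1/C3 only is tracked as
`p_other` and excluded from the three-class normalization because the HMBC
procedure observes C2/C4 enrichment only.

### Flux-split fitting

`FluxSplitModel` estimates (θ_lys, w_rec) — with the lysine-fragment weight
absorbing the remainder and exogenous/glycolysis weights fixed, matching the
lysine-only experiments — by a 41×41 grid search followed by Nelder–Mead
refinement of the squared-error loss on (p2, p4, p24). w_rec is bounded at
0.98 to keep the fixed point away from singularity. Degenerate data produce
flat ridges (e.g. a pure-[4-¹³C] observation is explained by any θ once
w_rec = 0); ties are broken deterministically toward the largest θ, and a
flat-direction probe (±0.05 steps, loss change < 1e−9) sets the
non-identifiability flag.

## HMBC correction

With integrals a = I(H2–C4, non-split), b = I(H2–C4, split),
c = I(H4–C2, non-split), d = I(H4–C2, split): f = b/d, c′ = f·c,
S = a + b + c′, and (p2, p4, p24) = (c′, a, b)/S. The direction of f (moving
the H4 side onto the H2 scale) and the use of b rather than (b + f·d)/2 for
p24 are pure representation choices — both are invariant under rescaling
either side, which is exactly the attenuation the factor corrects. If both
split peaks are zero there is no doubly labelled population to calibrate on;
fractions are computed with f = 1 and flagged. Split peaks are expected
pre-summed over doublet components; no spectral processing is done here.

## Fermentation accounting

Carbon recovery uses Δconcentration × carbon number sums; NH₃ contributes
zero carbon, CO₂ one when measured. Biomass carbon is not estimated;
recovery < 1 is read as assimilation plus unmeasured products. Percent
values are rounded to integers for display only. Specific activity converts
ΔA min⁻¹ to mM min⁻¹ by Beer–Lambert (default ε₃₁₀ = 15.1 mM⁻¹ cm⁻¹, 1 cm
path), to µmol min⁻¹ (= U) via the assay volume in ml, per mg protein. Note
that a 237 vs 71 U mg⁻¹ pair is a 3.34-fold change; quoted "3.5-fold"
figures round this.

## Growth kinetics

The Zwietering modified Gompertz form on y = ln(OD/OD₀) gives μmax the units
h⁻¹ directly. Starting values are data-driven (A₀ = max y, μ₀ = steepest
finite-difference slope, λ₀ = zero-crossing of the tangent at the steepest
point, clamped at 0) and the optimizer is bounded trust-region least squares
(deterministic; no seeds). Curves never rising 0.05 above baseline in ln
units raise a no-growth error rather than returning meaningless parameters.
Generation time is defined as ln 2 / μmax throughout; note that a growth
rate of 0.1 h⁻¹ corresponds to 6.93 h under this convention — quoted
generation times computed with other conventions will differ, so no target
is pinned to that pairing. Parameter standard errors come from the Gauss–
Newton covariance s²(JᵀJ)⁻¹.

## Synthetic-data generators

All generators are deterministic functions of (spec, seed) via
`numpy.random.default_rng`.

* **Time courses** follow the Gompertz shape, normalized so that substrate
  consumption completes at the final time point (48 h default — the culture
  is stationary by then); each product tracks consumption times its
  stoichiometric coefficient. Defaults emulate the lysine fermentation:
  16.8 mM substrate, (A, μmax, λ) = (2.0, 0.1 h⁻¹, 5 h). Noise is additive
  Gaussian truncated at zero; the endpoint record is the noiseless closure.
  Product formation is rigidly tied to substrate consumption — sufficient
  for testing balance/recovery code, but real time courses decouple (e.g.
  maintenance metabolism), so passing tests say nothing about kinetic
  decoupling.
* **HMBC integrals**: (a, b, c, d) = (a_H2·p4, a_H2·p24, a_H4·p2,
  a_H4·p24)·T plus truncated Gaussian noise; composed with the estimator
  this is the identity at zero noise for any positive attenuation pair
  (p24 > 0 required to calibrate the factor — at p24 = 0 the attenuation is
  unidentifiable, which the estimator flags).
* **Labelling observations**: tracer output with multiplicative lognormal
  noise, renormalized.

The noise models are modelling choices (measurements are reported as means ±
s.d. of duplicates only); they exercise the estimators' invariances, not the
instruments' error structure.

## Verification strategy and problem sizes

The analytic tracer is checked against an independent Monte-Carlo oracle
(tests/mc_oracle.py): a particle simulation of the acetyl pool over 40
generations (contraction ≤ 0.48 for the sampled configurations, so the
generation truncation error is ~1e−13) with 10⁵ particles and 10⁵ butyrate
draws, across 20 seeded random configurations; agreement is required within
3 standard errors per class, where the s.e. combines the draw binomial term
with the pool-propagation term 4/(N(1−k²)). Oracle configurations use label
positions {2, 4, 6} — positions 1/3/5 route label exclusively to butyrate
C1/C3 where the three observed classes are undefined. The HMBC
generator/estimator roundtrip is property-tested over 200 randomized
fraction/attenuation cases plus hypothesis-driven invariance tests; Gompertz
recovery is exact on noiseless curves and within 10% median μmax error over
50 replicates at σ = 0.02. The full suite runs in well under a minute.

## Known limitations

* No kinetic (time-resolved) isotopomer dynamics, no ²H/¹⁵N tracing.
* No thermodynamics, ΔG, genome-scale modelling or flux-balance analysis.
* The flux split is identified from a 2-degree-of-freedom observation; with
  richer parameterizations (free exogenous/glycolysis weights) it is
  under-determined and the fitter should be given the fixed weights of the
  actual experiment.
* CO₂ partitioning between gas and bicarbonate-buffered medium is not
  modelled; recovery computations use measured concentrations as given.
* Whether quoted generation times derive from OD or product-formation curves
  is experiment-dependent; the growth module fits OD only.
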