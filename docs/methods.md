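# Methods

## The statistical model

### Stage 1 — single-site spatial analysis

Each site is analysed with the individual-tree mixed model

    y = X β + Z_b b + Z_a a + e

where `y` are tree heights in decimetres, `β` holds fixed block and
provenance effects (reference-level constraints, first level dropped), `b`
are iid bulk-seed-lot effects (bulk trees only; their lot, not their family,
is the group-mean term), and `a ~ N(0, A σ²_a)` are additive genetic effects
with `A` the pedigree numerator relationship matrix. Two residual structures
are fitted: iid (`I σ²_e`, the a-priori design model) and the a-posteriori
spatial model

    Var(e) = σ²_ξ [AR1(ρ_col) ⊗ AR1(ρ_row)] + σ²_η I,

a separable first-order autoregressive field (restricted to occupied grid
cells) plus an independent nugget. Adjusted phenotypes subtract the
estimated block effects and the BLUP of the spatially dependent residual
ξ̂ from the raw heights; genetic effects and the nugget are untouched.

### Stage 2 — multi-site analysis

Adjusted phenotypes from all sites are stacked and fitted with fixed
provenance-within-site cell means, additive effects
`a ~ N(0, Σ_a ⊗ K)` with an unstructured k×k across-site covariance `Σ_a`
and relationship matrix `K`, bulk-lot effects `b ~ N(0, Σ_b ⊗ I)`, and
site-wise heterogeneous diagonal residuals. Because every tree grows at
exactly one site, cross-site *residual* covariances are not identifiable
from this layout; the residual structure is therefore diagonal by site (a
deliberate reading of the across-site residual covariance: its off-diagonal
elements never touch the likelihood).

Model flavours: ABLUP-1 uses `A`; ABLUP-2 uses the partial-selfing matrix
`A₂`; ssGBLUP-1/2 use the single-step matrices `H`/`H₂`; GBLUP uses the
blended genomic matrix `G_w` on the genotyped trees at the genotyped site
only. `H₂` blends `G` with `A₂`'s own genotyped block (so `G_w = A₂₂`
degenerates `H₂` to `A₂` exactly, mirroring the `H`/`A` limit).

### Relationship matrices

* `A` — tabular method; founders 1 on the diagonal, known parents p,q give
  `a_ij = ½(a_pj + a_qj)`, `a_ii = 1 + ½ a_pq`.
* `A₂` — open-pollinated records (known mother `d`, unknown father) are
  treated as selfed with probability `s`:
  `a_ij = ½(1+s) a_dj`, `a_ii = 1 + ½ s a_dd`. At `s = 0` this is bitwise
  identical to `A`. Its agreement with the selfing-probability mixture is
  validated against a gene-dropping Monte-Carlo oracle rather than a second
  closed-form implementation.
* `G` — VanRaden: allele frequencies from the post-QC genotyped panel,
  missing calls mean-imputed as `2pᵢ` (zero weight after centring),
  `G = WW′ / 2Σpᵢ(1−pᵢ)`; monomorphic loci contribute nothing.
* `G_w = 0.90 G + 0.10 A₂₂` — no further tuning or rescaling of `G` to
  `A₂₂` is applied beyond the blend.
* `H` — the standard single-step block composition; `A₂₂` is inverted via a
  symmetric positive-definite factorisation, and failure surfaces a
  conditioning diagnostic instead of silent regularisation.

### REML

Variance components maximise the restricted log-likelihood
`−½ (log|V| + log|X′V⁻¹X| + y′Py)` (the additive constant is omitted; the
brute-force dense formula is the test oracle). Updates are
average-information (AI) steps on transformed parameters — log variances,
Fisher-z spatial correlations, and Cholesky factors (log-diagonal, free
off-diagonal) for unstructured covariances, which keeps every `Σ` positive
semidefinite by construction and makes boundary (singular) optima reachable
without rejected steps. Failed AI steps escalate a Levenberg–Marquardt
ridge (λ up to 10× the mean AI diagonal) with step-halving; if no improving
step exists a Nelder–Mead simplex refines the fit, but only on problems of
≤ 900 observations — each simplex evaluation costs a dense Cholesky, so
larger non-converged fits return the best AI point flagged `converged =
False`. Convergence requires |Δ logL| < 1e−8 and a maximum natural-scale
parameter change < 1e−6. Variances are floored at 1e−10 × var(y) and
reported as boundary when pinned. Approximate standard errors come from the
inverse AI matrix by the delta method; standard errors of derived statistics
(e.g. heritability) use Monte-Carlo propagation through the same normal
approximation. Stage-2 fits start from the stage-1 estimates (additive and
bulk variances per site, nugget as residual, across-site correlation 0.4),
which roughly halves the AI iteration count.

BLUE/BLUP/PEV are computed in the phenotypic-covariance form of Henderson's
equations: `β̂` by GLS, `û = Cov(u,y) P y`,
`PEV = Var(u) − Cov(u,y) P Cov(u,y)′` — algebraically identical to the
mixed-model equations and convenient for predicting individuals without
observations (an unphenotyped, unrelated individual gets `û = 0`,
`PEV = (1+F)σ²ₐ`, accuracy 0).

## Derived statistics

All follow the standard definitions: `h² = σ²ₐ/(σ²ₐ+σ²ₑ+σ²_b)` per site;
`r_a` from `Σ_a`; `Acc = √(1 − PEV/((1+Fᵢ)σ²ₐ))` with `Fᵢ` from the fitted
matrix's diagonal, clipped to [0,1] after a tolerance check;
`E = (Acc_ssGBLUP − Acc_ABLUP)/(Acc_GBLUP − Acc_ABLUP)` at the genotyped
site; net breeding value = provenance-within-site BLUE + BV (+ lot BLUP for
bulk trees, whose lot plays the provenance role); gain = percent increase of
mean net BV in the selected fraction; ranking overlap and provenance shares
use stable (value, id) tie-breaking. Prediction bias PB regresses the
reference breeding values on the predictions, so slope 1 = unbiased.

Cross-validation masks the phenotypes of each fold of genotyped trees and
re-solves each model's BLUP system **at the full-data REML variance
components** (refitting REML per fold × model × scheme would dominate the
runtime while changing the components within their own noise); stage-1
adjustment is likewise computed once on the full data. The reference is the
full-data single-step fit of the matching inbreeding scenario.

## Selfing-rate estimation and pedigree correction

The selfing rate is estimated by inverting the half-sib-with-selfing
expectation `E[relatedness] = 0.25(1+s)²`:
`ŝ = clamp(2√(m_w − m_b) − 1)`, where `m_w` is the mean relatedness of
within-family pairs and `m_b` the mean over same-provenance,
different-family pairs — a baseline that removes the shift introduced by
centring markers on the panel's own allele frequencies. Both means use
**pairwise-complete** relatedness (each pair scaled by the heterozygosity of
its co-observed loci), because mean imputation deflates pairwise values by
the co-missingness fraction. With differentiated provenances a small
residual compression of the contrast (a few percent of the panel-vs-
provenance heterozygosity ratio) remains; at study scale it amounts to
roughly −0.03 on ŝ and is accepted rather than corrected by an ad-hoc
factor.

Pedigree correction also runs on this pedigree-scale relatedness (baseline
per provenance pair subtracted), so thresholds keep their textbook meaning.
A genotyped tree whose mean relatedness to its recorded maternal sibs falls
below 0.15 is flagged; it is reassigned (family label *and* maternal link)
to the family maximising its mean relatedness if that maximum reaches 0.20,
otherwise removed as a parentage conflict. The reassignment threshold sits
above the unrelated baseline noise (≈ 0 ± 0.04 for family-sized panels) and
below the outcross half-sib expectation 0.25: under partial selfing an
outcross tree's expected mean relatedness to its own family (a mix of
selfed and outcross sibs) is about 0.33, so a threshold above 0.25 would
remove honest family members. Trees recorded in families with no genotyped
sibs cannot be validated and are skipped with a warning. Both thresholds
are configuration values, reported in every run.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
three (configurable) provenances of ~20 open-pollinated families each, bulk
seed lots of unknown parentage, partial selfing at rate `s` (default 0.30),
biallelic SNPs gene-dropped through the realized pedigree, three sites of
rectangular grids with contiguous-band blocks, a separable AR1 × AR1
spatial field plus nugget, heights in decimetres with Table-1-like site
means (8–18 dm), and per-locus/per-individual missingness mixtures plus
near-monomorphic loci to exercise the QC filters.

Key choices:

* **Pollen pool** — every outcross event draws a fresh, unique, unrelated
  male founder from the same provenance (infinite pollen pool). This keeps
  the outcross half-sib expectation at exactly 0.25; real wild stands may
  carry background co-ancestry that this deliberately excludes. The
  wild-stand mating structure is unknown; this is an explicit assumption.
* **Provenance structure** — founder allele frequencies drift per
  provenance by a Balding–Nichols model at `provenance_fst` (default 0.10),
  and per bulk lot, so the genotyped provenances cluster in G and PCA the
  way real seed sources do.
* **Trait mechanism** — by default breeding values are genic: every SNP
  carries per-site effects, correlated across sites at the configured
  genetic correlation and scaled so the *within-provenance* founder BV
  variance matches the configured σ²ₐ (the variance the models estimate
  once provenance means are fixed effects). This makes markers genuinely
  informative about breeding values — the condition the genomic models
  exist for. A marker-free alternative (`bv_mechanism="pedigree"`,
  recursive Mendelian-sampling draws from the realized pedigree) exists for
  checks that need trait–marker independence. The expected BV covariance
  equals `Σ_a ⊗ A₂(s)` under both mechanisms.
* **What is not emulated** — inbreeding depression (breeding values do not
  decline with F, so the family inbreeding–height correlation is ≈ 0 in
  synthetic data and is reported, not asserted), mutation, linkage maps,
  selection over generations, genotyping-plate artefacts, and
  provenance-specific selfing rates. Passing tests therefore show the
  *machinery* recovers what it models; they do not certify behaviour under
  biological features outside this list.

## Problem sizes and test design

The validation suite runs desk-scale versions of the study conditions,
chosen so the whole suite completes in a few minutes on one core:

* parameter recovery: 3 sites × 1,032 trees (63 families × 14 + 25 bulk
  lots × 6), 2,000 SNPs, ~250 genotyped trees, 15 planted maternity swaps
  and 8 planted intruders; estimates are compared to truth at two
  approximate standard errors (site-aggregated), the selfing rate at ±0.05;
* directional model comparisons: ten seeds of 3 sites × 183 trees without
  spatial trend (at ~150 trees/site the spatial REML can legitimately place
  the genetic signal in a smooth field — a small-data identifiability
  limit, not an estimation bug — which would confound the *model*
  comparison these runs exist for);
* the acceptance script: 3 sites × 730 trees with the full model set and
  ten-fold cross-validation.

Two replication notes. The theoretical-accuracy advantage of single-step
over pedigree evaluation is asserted for the matched (with-selfing) model
pair: in the no-selfing scenario ABLUP-1's inflated σ̂²ₐ mechanically
inflates its own theoretical accuracy, an artefact rather than better
prediction (the same inversion appears in the real-data comparison at the
genotyped site). And the within-provenance vs random cross-validation
difference, while non-negative on average here, is close to zero: both
schemes share ~90 % of the training data per fold, and the generator lacks
the provenance-specific inbreeding differentials that plausibly drive the
clearer gap seen in real data.

## Numerical details and degenerate inputs

* AR1 correlations are constrained to (−1, 1) via Fisher-z; exact ρ = 0 is
  handled explicitly in the derivative of ρ^d.
* Duplicate grid occupancy, cyclic pedigrees, unknown parent references,
  all-monomorphic panels, empty matrices, rank-deficient fixed designs and
  singular `A₂₂` all raise typed errors naming the offending records.
* PCA of a relationship matrix uses a deterministic sign convention (the
  largest-magnitude loading of each component is positive).
* Selection ties are broken by stable (value, id) order.
* All randomness flows from a single integer seed per run; pipeline outputs
  are a pure function of (inputs, configuration, seed).
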