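# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

The canonical input is a wide per-sample table: one row per sampled
individual (or pooled replicate), with `species`, `plant_type`
(`ephemeral` / `non_ephemeral`), `elevation_m`, `replicate`, and one
numeric column per trait. The default catalog holds 26 traits in three
functional categories — 7 economic (leaf resource-economics: LDMC, SLA,
LC, LN, LP, LC/N, LN/P), 11 nutrient (root element pools and leaf/root
carbohydrates: RC, RN, RP, RC/N, RN/P, LSS, LS, LNSC, RSS, RS, RNSC) and
8 defensive (structure and secondary metabolites: LCC, LLC, LTPC, LTFC,
RCC, RLC, RTPC, RTFC). Units are free-text metadata; nothing converts
them. Missing values are explicit NaN. Correlations use pairwise
deletion (preserving the most pairs for a 26×26 matrix); the linear
models delete listwise per trait.

Phylogenies are rooted Newick trees with nonnegative branch lengths, one
tip per species. Polytomies and zero-length internal branches are
accepted; a tip covariance matrix with condition number above 1e12
raises rather than being silently regularized.

## Importance values

`IV = (relative frequency + relative density + relative coverage) / 3`,
where frequency counts occupied quadrats (the sampling unit; a flag
switches to plots), density sums counts and coverage sums cover. Each
component is normalized over species, so components and IVs are
simplex-valued, and IV is invariant to rescaling all covers. Ties in
ranking break by species label. Recorded plant height is carried but
unused — the IV formula names only frequency, density and coverage. If
all covers are zero while counts are not, the coverage component is set
to zero for every species and the result is flagged.

## Two-group comparisons and PCA

Per trait, a Shapiro–Wilk gate (per group, α = 0.05; groups with n < 3
fail the gate with a warning) selects the test: a paired *t*-test when
both groups look normal, otherwise a two-sided Mann–Whitney test (exact
when combined n ≤ 20 without ties, normal approximation with tie
correction otherwise; all-tied samples short-circuit to p = 1). The data
define no natural pairing for the paired test, so pairs default to the
per-type mean values within each (elevation band, replicate index) cell
— elevation is the shared stratum; an unpaired switch exists, and
unmatched pairs fall back to an unpaired *t* with a warning. A
Benjamini–Hochberg column is reported for reference; nothing gates on
it, since the workflow interprets raw per-trait p-values.

PCA standardizes each trait to mean 0 and sample SD 1 (ddof = 1;
zero-variance traits are dropped with a warning) and eigendecomposes the
correlation matrix. Components are ordered by decreasing eigenvalue;
each component's sign is fixed so its largest-magnitude loading is
positive; rank-deficient directions are reported with exactly zero
variance. Variance fractions sum to 1 by the trace identity.

## Elevation models

Each trait is modeled by OLS as
`trait ~ type + elevation_c + type:elevation_c`, with elevation
continuous in meters and centered for numerical stability. Effects are
tested by sequential (Type-I) sums of squares in the stated order
(type, elevation, interaction) — the default of the usual statistical
environments for this design; Type-II is available via a flag. The
group factor is the two plant types by default; an 8-level per-species
variant is a flag away. When the interaction is significant (α = 0.05,
configurable), per-type simple regressions report slopes with
confidence intervals; otherwise the pooled model is retained explicitly.

Environmental regressions join site records (soil pH/C/N/P/EC, MAP,
MASR, MAT) to samples by elevation band and fit one simple OLS per
(trait, variable). Traits are first normalized; the exact transform
being unspecified by convention, the default is the Blom rank-based
inverse-normal transform (monotone, distribution-free), with `log` and
`none` as alternatives.

## Phylogenetic signal

Blomberg's K compares the ratio of phylogenetically uncorrected to
corrected trait variance against its Brownian-motion expectation on the
given tree. With C the shared-path-length matrix and â the GLS root
estimate:

    MSE0 = (x − â)ᵀ(x − â)/(n − 1)
    MSE  = (x − â)ᵀC⁻¹(x − â)/(n − 1)
    K    = (MSE0/MSE) / ([tr C − n/(1ᵀC⁻¹1)]/(n − 1))

K = 1 under BM; on a star tree C ∝ I makes K ≡ 1 for any trait vector
(useful as a machine-precision self-check). K is invariant to affine
transforms of the trait and to global branch-length rescaling. C is
inverted via a solve, not an explicit inverse. Replicates collapse to
species means (the collapse is configurable) because the tree has one
tip per species; means pool all elevations.

Significance uses a tip-shuffle permutation null: trait values are
permuted across tips n_perm times (default 999) and
`p = (1 + #{K_null ≥ K_obs}) / (n_perm + 1)` — the add-one correction
keeps p > 0 and gives resolution 1/1000 at 999 shuffles. The comparison
uses a 1e-12 tolerance so exact ties (star trees) count as exceedances.

## Trait networks

Spearman ρ is computed per trait pair on complete cases; pairs with
fewer than 5 observations are flagged and can never form an edge.
Two-sided p-values use the *t* approximation with df = n − 2 for
n ≥ 10 and exact enumeration of all orderings below that. An edge
requires |ρ| strictly greater than 0.2 **and** p strictly below 0.05 —
both inequalities read literally from the thresholded-network rule; no
multiplicity adjustment is applied to the binarization (a BH column is
available upstream for inspection).

Metrics: degree; edge density `E/(n(n−1)/2)`; Newman modularity
`Q = Σ_c [e_c/m − (d_c/2m)²]` of a detected partition; average shortest
path over connected unordered pairs, with an explicit flag when the
network is disconnected (thresholded networks often are) and NaN when
edgeless; relative importance of a category = mean degree of its traits
divided by the summed degree of all traits (scale-invariant in the
degrees). Edgeless networks report Q = 0 with singleton modules.

Community detection is deterministic by construction. Maximizing Q is
NP-hard and greedy agglomeration can stall in local optima even on
6-node graphs, so graphs with ≤ 8 nodes are solved exactly by
enumerating all partitions (Bell(8) = 4140 — negligible cost); larger
graphs use greedy agglomeration (merge the connected pair with the best
ΔQ, lowest-label tie-break, tracking the best partition along the full
merge path) followed by deterministic refinement passes of single-node
moves, community merges and joint two-node moves until none improves Q.
Identical inputs always give identical partitions and Q.

Stratified comparisons build one network per stratum (plant type or
elevation band), pooling samples within the stratum, and report metrics
side by side with per-stratum hub lists (degree-sorted, label
tie-break). Strata with fewer than 5 samples are skipped with a warning.

## Synthetic data generator

The generator emulates the structure of the field design — 8 species
(half ephemeral), 3 elevation bands (600/800/1000 m), a few pooled
replicates per species × band, 26 traits — with every downstream
estimand planted explicitly:

- **Tree**: supplied, or a pure-birth (Yule) tree rescaled to depth 1.
  Because the birth process stops at the n-th birth, terminal edges are
  extended equally (tree stays ultrametric) so the tip covariance is
  nonsingular.
- **Phylogenetic signal**: per trait, the species-level base value is
  `species_sd · (√λ · BM_z + √(1−λ) · ε)` with BM_z a standardized
  Brownian draw on the tree and ε iid standard normal. λ tunes signal as
  a blend weight rather than targeting an exact K (K has no closed-form
  inverse); tests assert monotonicity of K in λ, not exact values.
- **Group and gradient effects**: additive type offsets (ephemeral
  minus non-ephemeral, in replicate-noise SD units), elevation slopes
  per kilometre of centered elevation (kilometres keep slopes O(1)),
  and type × elevation interaction slopes.
- **Correlation modules**: disjoint trait sets share a per-sample
  latent factor with loading ρ, giving within-module pairwise
  correlation ρ² and zero between-module correlation at the replicate
  level; replicate noise has SD `noise_sd`.
- **Environments**: per-band soil and climate values from the built-in
  site table, linearly interpolated for other bands.
- **Determinism**: all draws derive from one seed; identical configs
  give byte-identical outputs.

`species_sd` (default 1) scales the species-level base component. The
default emulates real interspecific heterogeneity; setting it to 0 is
the correct null for calibration experiments, because with only 8
species the random species means (i) cluster samples within species,
invalidating the nominal level of tests that treat samples as
independent, and (ii) induce realized between-trait correlations of
order 1/√8 that are not planted effects. The type-I and
module-recovery experiments therefore run at `species_sd = 0`; the
phylogenetic-signal experiments keep the default.

Quadrat surveys are simulated per quadrat as multinomial counts (30
individuals by default) over normalized abundance weights, with cover
proportional to counts times lognormal noise.

### What the generator does not emulate

No instrument-specific assay noise, no spatial autocorrelation between
plots, no missing-data mechanism, no trait-specific units or scales
(everything is in standardized units), and no environment-driven trait
responses beyond the linear elevation slopes. Passing tests therefore
demonstrate correctness and calibration of the estimators under the
planted model, not robustness to every property of field data —
in particular, with real data the comparison and model tests inherit
the usual caveat that samples from the same species are not independent.

## Problem sizes used in the validation experiments

The calibration experiments are sized to give stable Monte-Carlo
estimates while staying cheap: 500 Brownian traits on one 32-tip tree
for the K calibration (Monte-Carlo SE of the mean ≈ 0.02); 100 random
vectors for the star identity; 20 seeded graphs of 4–8 nodes for the
brute-force community-detection audit; 48-sample datasets (8 species ×
3 bands × 2 replicates — the closest factorial layout to 50 samples)
for module recovery, with the between-module false-edge rate averaged
over 20 datasets because a single 225-pair dataset has binomial SE
≈ 1.5%; 1,000 null datasets × 2 traits for the type-I rates (SE ≈
0.5%); and 999 permutations wherever a permutation p is reported.

## Known limitations

- The paired *t* pairing is a modeling convention; with unbalanced
  designs it falls back to unpaired with a warning.
- Spearman p-values for 5 ≤ n < 10 enumerate all orderings under the
  assumption of exchangeability; ties are handled by average ranks in
  the statistic but the permutation distribution conditions on the
  observed tie pattern.
- Greedy community detection above 8 nodes is a strong deterministic
  heuristic, not an exact optimizer; reported Q values are
  algorithm-dependent, as they are for every modularity method.
- Average path length on disconnected networks covers connected pairs
  only and is flagged; comparing it across networks with different
  component structures needs care.
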