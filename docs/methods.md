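# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Receptor-noise-limited colour model

A stimulus is a vector of relative quantum catches for the four single-cone
classes of the UVS avian retina (UV, SW, MW, LW) plus the double cone.
Metrics:

- **Luminance** is the double-cone catch, unchanged — the avian achromatic
  channel.
- **Saturation** normalises the four single-cone catches to proportions and
  places the stimulus in the regular tetrahedron whose vertices lie at
  distance 0.75 from the centre (UV at (0, 0, 0.75); SW/MW at
  (∓√6/4, −√2/4, −0.25); LW at (0, √2/2, −0.25)). Saturation is the norm of
  that position: 0 for equal catches, 0.75 at a vertex. The exact-surd
  coordinates are used so a pure-vertex stimulus scores exactly 0.75.
- **Hue** is the opponency ratio (LW + UV)/(SW + MW); it is scale-invariant
  and increases for redder and/or more UV-reflective colours. SW + MW = 0 is
  a hard error, not infinity.
- **Chromatic contrast** uses the log-linear receptor-noise model with
  Δf_i = ln(a_i/b_i):

      ΔS² = Σ_{i<j} (Δf_i − Δf_j)² Π_{k∉{i,j}} e_k²  /  Σ_i Π_{k≠i} e_k²

  over the four single cones only (the double cone carries no chromatic
  information). The tetrachromatic form reduces to the textbook dichromat
  expression |Δf₁ − Δf₂|/√(e₁²+e₂²) as the other two channels become
  infinitely noisy; the test suite verifies that convergence numerically.
- **Achromatic contrast** is |ln(dbl_a/dbl_b)|/ω.

Channel noise follows e_i = ω·√(η_ref/η_i) with the reference set to the most
abundant class, so e_ref = ω exactly; a simpler ω/√η_i convention is
selectable (`VisualSystem(convention="simple")`). ω defaults to 0.05. Blue
tit relative cone abundances (uv:sw:mw:lw = 0.37:0.70:0.99:1.00, the commonly
circulated UVS ratios) ship as a documented configuration default
(`BLUETIT_VS`); every unit test uses the symmetric system η = (1,1,1,1) so no
literature-derived constant is load-bearing in the test suite.

Conventions chosen where the convention is genuinely open:

- JND = 1 exactly is classified *indiscriminable*; discriminability requires
  strictly more than 1 JND.
- Zero or negative catches are hard errors everywhere a logarithm or
  proportion is taken. Flooring catches silently would corrupt JNDs; the
  generator guarantees positivity instead.

## Image stage

Images are linear multi-band stacks (one band per cone channel) with an
integer label mask: marking, background, low/high grey standard, off-wing.
The only photometric correction is the per-band affine map sending the
observed standard means onto their true reflectances (7% and 93%); that
removes any global gain/offset while preserving region contrasts, is
idempotent on already-calibrated images, and errors out on equal or inverted
standard means. Camera linearization is assumed upstream (an optional
power-law linearizer defaults to the identity). Region means are plain
arithmetic means over labelled pixels; relative marking area is
100·|marking|/(|marking|+|background|) and therefore scale-free. Masks are
supplied as label arrays (0-based, row-major) rather than polygons — the
interactive freehand selection of the original workflow is out of scope.

## Phylogenetic machinery

The Brownian covariance of a rooted tree has C[i,j] equal to the shared
root-to-MRCA branch length and C[i,i] the root-to-tip distance; Pagel's λ
multiplies the off-diagonal entries only. Non-ultrametric trees (e.g.
genetic-distance branch lengths) are accepted without rescaling. Terminal
branches of (near-)zero length are floored at 10⁻⁸ of tree depth with a
warning, since they make C singular.

PGLS uses ML estimation throughout: σ̂² = rᵀC_λ⁻¹r/n and
logL = −½[n·ln(2πσ̂²) + ln|C_λ| + n], matching the default behaviour of the
comparative-methods packages this module is interchangeable with (REML is not
implemented). λ is profiled over [0, 1] by bounded scalar minimisation
(tolerance 10⁻⁶) on the sub-intervals (0, ½), (½, 1) and (0, 1) plus the
endpoints, guarding against local optima; the upper bound stays at 1 rather
than the largest λ keeping C_λ positive definite, because λ = 1 is the
Brownian reference model. Per-term F statistics compare whitened residual
sums of squares of nested fits evaluated at the same λ̂ (sequential and
marginal F coincide for the single-predictor models the screens mostly
retain). Species means enter unweighted by per-species sample size (a
deliberate mirror of field practice where N = 1 species get full weight);
`aggregate_species_means` exposes pooled-individuals versus mean-of-sex-means
aggregation, defaulting to pooling.

Support collapsing removes every internal edge whose child node has bootstrap
support below the threshold (default 70%), adding the removed edge's length
to each child branch so all root-to-tip distances are preserved exactly.
Nodes without a support value are treated as fully supported — absence of
evidence of conflict is not treated as conflict.

## Synthetic study generator

The generator produces the minimal structure that makes every fitted model in
the screens identifiable:

- a pure-birth tree rescaled to unit root-to-tip depth (tips sp01…spNN); the
  simulator's final speciation leaves zero-length twigs, so every terminal is
  extended by the Exp(n·birth-rate) waiting time to the next birth, which is
  the exact conditional distribution;
- species-level log toxin X ~ MVN(μ·1, σ²C_λ); a latent colour axis
  G = b·(X − μ) + independent λ-BM deviate at the same rate, where b is the
  generative **honesty slope**; an independent λ-BM deviate for marking area;
- individuals per species × sex × year cell: the species value plus additive
  shifts (male, 2016) and N(0, noise_sd) noise; lognormal body mass. RNG
  streams are split hierarchically by (seed, species, sex, year), so changing
  one cell's size never reshuffles another, and a fixed seed reproduces
  byte-identical tables;
- a deterministic monotone map to cone catches: marking_i =
  brightness·(base_i + 0.55·redness·1[i=LW]), background =
  brightness·(1−darkness)·0.5 flat, double cone = mean of the patch's LW and
  MW catches; brightness = b₀·exp(coupling·G) and redness = logistic(G), so
  log luminance is exactly linear in the latent axis when honesty drives
  brightness alone (`colour_axis="brightness"`) — the configuration used for
  slope-recovery checks. It is a 4-parameter construction, not a reflectance
  model: iridescence, angle dependence and real wing shapes are deliberately
  absent, so passing tests certify the analysis chain, not optics.

Default study conditions (chosen once; the within-species variance components
are not observable from published summaries, so they are set for testability
rather than realism): 12 species, 3 individuals per cell, λ_true = 1,
σ² = 0.5 per unit depth, sex/year shifts 0.3 on the log scale, honesty slope
0 (the no-honesty null), μ = log(300) μg CNGlc per g, individual noise SD 0.1.

On the noise default: PGLS on species means treats those means as measured
without error. Un-modelled within-species sampling error adds a white
component to the species-mean covariance, and on pure-birth trees — whose
youngest internodes are short — even a small component makes the λ = 1 F test
anticonservative and attenuates slope estimates (phylogenetically amplified
regression dilution). With noise SD 0.1 and ≥ 6 individuals per species-mean
the white component is ≈ 0.2% of the Brownian variance and the stack's null
rejection rate stays within the 5% ± 2% calibration band the generator
contract promises; at noise SD 0.2 it measurably does not. Users simulating
noisier studies should expect — and will observe — inflated type-I rates;
that is a faithful property of the species-mean design, not of the optimiser.

## Statistical screens

- Transformations are per-dataset plans with recorded tags; the defaults log
  toxin concentration for 2016 datasets and apply √saturation and
  log(chromatic contrast) for the 2015 female dataset; between-year factorial
  models log luminance, hue and chromatic contrast. Out-of-domain values
  raise errors naming the offending rows.
- VIF_j = 1/(1−R²_j) from regressing predictor j on the others with
  intercept; perfect collinearity reports ∞ rather than raising. Model sets
  are grown greedily in a declared priority order: each candidate joins every
  existing subset it is compatible with (VIF ≤ 10 after joining, no two
  members of one exclusion group) and seeds a new subset otherwise. The
  chromatic trio (saturation, hue, chromatic contrast) is mutually exclusive
  by construction since all three derive from the same catches; marking area
  and the achromatic metrics are never grouped with them. Listing the
  exclusion-group members first makes each seed its own subset while shared
  predictors join all of them.
- Stepwise simplification is backwards elimination on factorial terms: at
  each step every term not marginal to a retained higher-order term is tested
  by a nested F test; the worst is dropped while p > α (= 0.05), ties
  dropping the later-listed term; the full trace (term, F, dfs, p, action) is
  emitted. Quasi-constant predictors (relative SD < 10⁻⁸) are excluded from
  PGLS designs up front, since they are numerically collinear with the
  intercept.
- The PGLS screen runs each predictor subset under both λ modes (ML and
  fixed 1) and stepwise-simplifies with the same F rule, re-estimating λ at
  every step in ML mode; every number in the emitted report tables is
  recomputable from the shipped species-means CSV and tree (tested).
- Within-species regressions require ≥ 10 individuals, run saturation- and
  hue-based families separately, and drop sex terms with a warning on
  single-sex data.

## Problem sizes and calibration checks

The replicated checks use: 1,000 null replicates at 12 species for type-I
calibration (per-test rejection in [3%, 7%], KS uniformity); 200 replicates
at 30 species and standardized slope 1.5 for power (≥ 90%); 200 replicates
per λ ∈ {0, 0.5, 1} at 100 tips for λ recovery (median within 0.1; the λ = 0
runs reproduce the lower-boundary behaviour, median λ̂ < 0.05); 500
pure-noise replicates for the stepwise engine's ≈ α retention; 2,000
replicates for Monte-Carlo covariance checks. Slope-recovery tests use 10
individuals per cell so measurement-error attenuation (above) stays well
below the 5% bias band being asserted.

## Known limitations

- No REML; ML λ̂ at small n is noisy and the associated F tests
  anticonservative (the acceptance checks run the calibration under the
  exact fixed-λ=1 mode for precisely this reason; ML-mode small-sample
  behaviour is reported, not certified).
- Within-species measurement error is generated but not modelled by the
  estimator (see above).
- The latent-colour → cone-catch map is monotone plumbing, not optics.
- Tree inference, alignment and bootstrap replication are out of scope; trees
  arrive as Newick with optional support labels.
- Hue is the fixed opponency ratio; re-deriving a hue axis per dataset by PCA
  is out of scope.
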