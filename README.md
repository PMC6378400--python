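# aposignal

Tools for asking whether warning signals are *quantitatively honest*: across a
clade of chemically defended species, does the strength of the visual signal
(as a predator sees it) track the potency of the chemical defence?

The package grew out of the study design used for aposematic burnet and
forester moths — day-flying Lepidoptera defended by cyanogenic glucosides and
bearing red-on-dark wing markings — but every stage is generic: it is aimed at
comparative biologists who have (a) calibrated multispectral wing/body images
or cone-catch tables, (b) per-specimen toxin quantifications, and (c) a
phylogeny, and who want the full analysis chain from pixels to
phylogenetically controlled regression, with a synthetic-data generator that
makes the whole chain testable end to end.

## What it computes

**Predator-vision colour metrics** (UVS avian viewer; `aposignal.vision`).
From relative quantum catches of the UV/SW/MW/LW single cones and the double
cone:

- luminance = double-cone catch;
- saturation = Euclidean distance from the centre of the tetrahedral colour
  space (vertices at distance 0.75);
- hue = (LW + UV) / (SW + MW), the colour-opponency ratio;
- chromatic contrast ΔS between two patches from the log-linear
  receptor-noise-limited model: with Δf_i = ln(a_i/b_i) and channel noise
  e_i = ω·√(η_ref/η_i),

      ΔS = sqrt( Σ_{i<j} (Δf_i − Δf_j)² Π_{k∉{i,j}} e_k²  /  Σ_i Π_{k≠i} e_k² )

  in just-noticeable differences (JND, Weber fraction ω = 0.05 by default);
- achromatic contrast = |ln(dbl_a/dbl_b)| / ω.

**Image calibration** (`aposignal.imaging`): per-band affine normalization of
linear multi-band stacks against 7% / 93% grey reflectance standards, labelled
region means, and relative marking area (% of wing).

**Phylogenetic comparative machinery** (`aposignal.phylo`): Newick I/O,
collapsing of internal nodes below a bootstrap-support threshold into
polytomies (root-to-tip distances preserved), the Brownian covariance matrix
C with C[i,j] = root-to-MRCA shared branch length, Pagel's λ transform
(off-diagonals × λ), and PGLS:

    β̂ = (XᵀC_λ⁻¹X)⁻¹ XᵀC_λ⁻¹ y,   σ̂² = rᵀC_λ⁻¹r / n (ML)

with λ either fixed (λ = 1 is the Brownian robustness re-run) or profiled out
by bounded ML over [0, 1]; per-term F tests come from whitened residual sums
of squares of nested fits at the same λ̂.

**Statistical screens** (`aposignal.pipeline`): species-mean datasets per
year × sex, per-dataset log/sqrt transformations, variance inflation factors
(VIF = 1/(1−R²)) with greedy construction of predictor subsets under the
VIF ≤ 10 rule and declared incompatibility groups, backwards stepwise
simplification of factorial models by nested F tests at α = 0.05, PGLS
honesty screens under both λ modes, and within-species regressions with
sex × metric interactions.

**Synthetic studies** (`aposignal.simulate`): pure-birth phylogenies, species
traits under λ-Brownian motion with a configurable generative "honesty slope"
linking log toxin concentration to a latent colour axis, individual-level
sex/year/noise structure, a monotone latent-colour → cone-catch map, and
rendered labelled wing images with grey standards and a global gain.

## Worked example

`examples/pgls_honesty_screen.py` simulates a 20-species study in which toxin
concentration genuinely drives wing brightness (honesty slope 1.2) and runs
the cross-species screen:

```
simulated 20 species, 240 individuals
dataset: year=2016, sex=both, transforms={'cnglc_ug_per_g': 'log'}

retained PGLS models (one row per term and lambda mode):
                     model lam_mode  lam_hat      term     F  df1  df2         p
cnglc_ug_per_g ~ luminance       ml        1 luminance 80.11    1   18 4.782e-08
cnglc_ug_per_g ~ luminance   fixed1        1 luminance 80.11    1   18 4.782e-08
```

The screen built VIF-compatible predictor subsets, eliminated everything but
luminance by nested F tests, estimated λ̂ = 1 (the data are Brownian by
construction), and flagged the luminance–toxin association at
F₁,₁₈ = 80.1 — the built-in honesty signal, recovered. The other examples show
the colour metrics on a red marking (`colour_metrics.py`: ΔS = 31.4 JND
against a dark background under blue-tit cone ratios), the imaging round trip
(`imaging_roundtrip.py`: a 2.5× gain removed to 2×10⁻¹⁶ by the grey-standard
normalization), and λ profiling (`lambda_profile.py`).

A thin CLI mirrors the library: `aposignal simulate|metrics|pgls|pipeline`
(`aposignal pipeline --seed 4 --out run/` writes `traits.csv`, `tree.nwk`,
`species_means.csv`, `table2_stepwise.csv`, `table3_pgls.csv`, a config echo
and a run log; identical seeds give hash-identical artifacts).

## Layout

```
src/aposignal/    vision, imaging, phylo, simulate, pipeline, config, cli
examples/         one narrative script per capability
tests/            unit, property and end-to-end suites (pytest + hypothesis)
docs/methods.md   models, conventions, numerical choices, limitations
```
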