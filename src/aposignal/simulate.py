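"""Synthetic study generator: phylogeny, species traits, individuals, colours, images.

The generator emulates the structure of a two-year, two-sex, multi-species
museum/rearing study of aposematic moths:

* a pure-birth phylogeny with unit root-to-tip depth;
* species-level log toxin concentration evolving as λ-transformed Brownian
  motion on that tree, MVN(μ·1, σ²·C_λ);
* a species-level latent colour axis = honesty_slope · (log toxin − μ) plus an
  independent λ-Brownian deviate with the same rate, so the "honesty slope"
  is the generative link the downstream regressions try to detect;
* individuals within each species × sex × year cell: the species value plus
  additive sex/year shifts and Gaussian individual noise; body mass lognormal;
* a deterministic monotone map from the latent colour axis to wing cone
  catches (marking and background patches), and optionally a rendered
  labelled multi-band wing image with two grey-standard patches and a global
  gain factor that the imaging stage must remove.

Every top-level call derives its random stream from ``SimulationConfig.seed``
via hierarchical ``numpy`` seed sequences keyed by (species, sex, year), so
enlarging one cell never reshuffles another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import phylo
from .errors import InvalidArgumentError
from .imaging import LABELS, LabelledStack
from .vision import SYMMETRIC_VS, ConeCatch, VisualSystem, metrics_from_catches

SEXES = ("F", "M")
YEARS = (2015, 2016)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model.

    The defaults are the study conditions the rest of the package is exercised
    under: 12 species, 3 individuals per species × sex × year cell, Brownian
    trait evolution (λ=1) at rate σ²=0.5 on a unit-depth tree, individual
    noise SD 0.1 on the log scale, sex/year shifts of 0.3, and no generative
    honesty link (slope 0 — the null the study failed to reject).
    """

    n_species: int = 12
    n_per_cell: int = 3
    lambda_true: float = 1.0
    sigma_bm: float = 0.5
    honesty_slope: float = 0.0
    sex_effect: float = 0.3
    year_effect: float = 0.3
    noise_sd: float = 0.1
    seed: int = 0
    #: mean log toxin concentration, log(μg CNGlc per g tissue)
    mu_log_toxin: float = math.log(300.0)
    #: mean log body mass (g) and its SD for the lognormal mass draw
    mu_log_mass: float = math.log(0.06)
    sd_log_mass: float = 0.15
    #: which wing attribute the latent colour axis drives
    colour_axis: str = "both"  # "brightness" | "redness" | "both"
    brightness_base: float = 0.5
    brightness_coupling: float = 0.25
    redness_coupling: float = 1.0
    background_darkness: float = 0.7
    marking_fraction: float = 0.25

    def __post_init__(self):
        if self.n_species < 1 or self.n_per_cell < 1:
            raise InvalidArgumentError("counts must be >= 1")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise InvalidArgumentError("lambda_true must lie in [0, 1]")
        if self.sigma_bm <= 0:
            raise InvalidArgumentError("sigma_bm must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.colour_axis not in ("brightness", "redness", "both"):
            raise InvalidArgumentError("colour_axis must be brightness|redness|both")
        if not 0.0 < self.marking_fraction < 1.0:
            raise InvalidArgumentError("marking_fraction must lie in (0, 1)")
        if not 0.0 <= self.background_darkness < 1.0:
            raise InvalidArgumentError("background_darkness must lie in [0, 1)")


@dataclass(frozen=True)
class LatentWingColour:
    """Low-dimensional wing description mapped onto cone catches.

    ``redness`` ∈ [0, 1] elevates the LW catch of the marking; ``brightness``
    > 0 scales every catch; ``background_darkness`` ∈ [0, 1) darkens the wing
    background; ``marking_fraction`` ∈ (0, 1) is the areal share of markings.
    """

    redness: float
    brightness: float
    background_darkness: float = 0.7
    marking_fraction: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.redness <= 1.0:
            raise InvalidArgumentError("redness must lie in [0, 1]")
        if self.brightness <= 0:
            raise InvalidArgumentError("brightness must be > 0")
        if not 0.0 <= self.background_darkness < 1.0:
            raise InvalidArgumentError("background_darkness must lie in [0, 1)")
        if not 0.0 < self.marking_fraction < 1.0:
            raise InvalidArgumentError("marking_fraction must lie in (0, 1)")


# Base marking reflectances per single cone (uv, sw, mw, lw) before the
# redness term; deliberately non-physical but monotone and positive.
MARKING_BASE = {"uv": 0.10, "sw": 0.08, "mw": 0.08, "lw": 0.12}
REDNESS_GAIN = 0.55
BACKGROUND_FLAT = 0.5


def traits_to_cone_catches(
    latent: LatentWingColour,
    base: dict | None = None,
    redness_gain: float = REDNESS_GAIN,
) -> tuple[ConeCatch, ConeCatch]:
    """Deterministic monotone map from latent wing colour to (marking, background).

    marking_i = brightness · (base_i + redness_gain·redness·1[i=LW]);
    background_i = brightness · (1 − background_darkness) · flat;
    each patch's double-cone catch is the mean of its LW and MW catches.
    Hue of the marking is strictly increasing in redness, luminance strictly
    increasing in brightness; all outputs are positive.
    """
    b = dict(MARKING_BASE if base is None else base)
    m = {k: latent.brightness * v for k, v in b.items()}
    m["lw"] += latent.brightness * redness_gain * latent.redness
    marking = ConeCatch(uv=m["uv"], sw=m["sw"], mw=m["mw"], lw=m["lw"], dbl=(m["lw"] + m["mw"]) / 2)
    bg_val = latent.brightness * (1.0 - latent.background_darkness) * BACKGROUND_FLAT
    background = ConeCatch(uv=bg_val, sw=bg_val, mw=bg_val, lw=bg_val, dbl=bg_val)
    return marking, background


def latent_wing_colour(g: float, cfg: SimulationConfig, marking_latent: float = 0.0) -> LatentWingColour:
    """Map latent colour-axis and marking-area values onto wing parameters.

    Brightness responds as exp(coupling·g) (so log luminance is linear in g
    when the axis drives brightness alone); redness as a logistic squash; the
    marking fraction is a logistic perturbation of the configured baseline by
    the independent marking deviate.
    """
    drive_b = cfg.colour_axis in ("brightness", "both")
    drive_r = cfg.colour_axis in ("redness", "both")
    brightness = cfg.brightness_base * math.exp(cfg.brightness_coupling * g if drive_b else 0.0)
    redness = 1.0 / (1.0 + math.exp(-cfg.redness_coupling * g)) if drive_r else 0.5
    logit_base = math.log(cfg.marking_fraction / (1.0 - cfg.marking_fraction))
    frac = 1.0 / (1.0 + math.exp(-(logit_base + 0.5 * marking_latent)))
    return LatentWingColour(
        redness=redness,
        brightness=brightness,
        background_darkness=cfg.background_darkness,
        marking_fraction=frac,
    )


# ---------------------------------------------------------------------------
# Species and individual layers
# ---------------------------------------------------------------------------

def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth unit-depth phylogeny with tips sp01..spNN (see phylo module)."""
    return phylo.simulate_tree(n_species, seed=seed)


def simulate_species_traits(tree: dendropy.Tree, cfg: SimulationConfig) -> pd.DataFrame:
    """Species-level log toxin and latent colour under λ-Brownian evolution.

    Returns one row per species with columns ``log_toxin`` and
    ``colour_latent`` where colour_latent = honesty_slope·(log_toxin − μ) + an
    independent λ-BM deviate at the same rate.
    """
    labels = phylo.tip_labels(tree)
    if cfg.n_species != len(labels):
        raise InvalidArgumentError(
            f"tree has {len(labels)} tips but config requests {cfg.n_species} species"
        )
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    x = phylo.simulate_bm(tree, sigma2=cfg.sigma_bm, lam=cfg.lambda_true, mu=cfg.mu_log_toxin, seed=rng)
    g0 = phylo.simulate_bm(tree, sigma2=cfg.sigma_bm, lam=cfg.lambda_true, mu=0.0, seed=rng)
    g = cfg.honesty_slope * (x - cfg.mu_log_toxin) + g0
    # Marking area evolves on its own, independent of the honesty axis.
    m = phylo.simulate_bm(tree, sigma2=cfg.sigma_bm, lam=cfg.lambda_true, mu=0.0, seed=rng)
    return pd.DataFrame(
        {"log_toxin": x, "colour_latent": g, "marking_latent": m}
    ).rename_axis("species")


def simulate_individuals(species_table: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Individual-level trait table for every species × sex × year cell.

    Each individual draws toxin and colour as its species value plus additive
    sex (male) and year (2016) shifts and N(0, noise_sd) noise; mass is
    lognormal.  The per-cell RNG stream is derived from (seed, species index,
    sex index, year index) so cells are independent and stable.
    """
    rows = []
    species_list = list(species_table.index)
    for si, sp in enumerate(species_list):
        sp_row = species_table.loc[sp]
        for xi, sex in enumerate(SEXES):
            for yi, year in enumerate(YEARS):
                ss = np.random.SeedSequence(cfg.seed, spawn_key=(1 + si, xi, yi))
                rng = np.random.default_rng(ss)
                shift = cfg.sex_effect * (sex == "M") + cfg.year_effect * (year == 2016)
                for k in range(cfg.n_per_cell):
                    tox = sp_row["log_toxin"] + shift + rng.normal(0.0, cfg.noise_sd)
                    col = sp_row["colour_latent"] + shift + rng.normal(0.0, cfg.noise_sd)
                    mk = sp_row.get("marking_latent", 0.0) + rng.normal(0.0, cfg.noise_sd)
                    mass = math.exp(rng.normal(cfg.mu_log_mass, cfg.sd_log_mass))
                    rows.append(
                        {
                            "specimen_id": f"{sp}_{sex}_{year}_{k + 1:02d}",
                            "species": sp,
                            "sex": sex,
                            "year": year,
                            "mass_g": mass,
                            "cnglc_ug_per_g": math.exp(tox),
                            "colour_latent": col,
                            "marking_latent": mk,
                        }
                    )
    return pd.DataFrame(rows)


def attach_colour_metrics(
    traits: pd.DataFrame,
    cfg: SimulationConfig,
    vs: VisualSystem = SYMMETRIC_VS,
) -> pd.DataFrame:
    """Map each individual's latent colour to cone catches and colour metrics.

    Adds the marking/background catch columns and the six metric columns the
    statistical screens consume.  Relative marking area is the generator's
    marking fraction (rendering + pixel counting reproduces it; see the
    imaging module).
    """
    recs = []
    mk = traits.get("marking_latent", pd.Series(0.0, index=traits.index)).to_numpy()
    for g, m in zip(traits["colour_latent"].to_numpy(), mk):
        latent = latent_wing_colour(float(g), cfg, marking_latent=float(m))
        marking, background = traits_to_cone_catches(latent)
        met = metrics_from_catches(
            marking, background, vs, relative_marking_area=100.0 * latent.marking_fraction
        )
        rec = met.as_dict()
        for nm, c in (("marking", marking), ("background", background)):
            for ch in ("uv", "sw", "mw", "lw", "dbl"):
                rec[f"{nm}_{ch}"] = getattr(c, ch)
        recs.append(rec)
    return pd.concat([traits.reset_index(drop=True), pd.DataFrame(recs)], axis=1)


def simulate_dataset(cfg: SimulationConfig, vs: VisualSystem = SYMMETRIC_VS):
    """One full synthetic study: (tree, individual trait table with metrics)."""
    tree = simulate_tree(cfg.n_species, seed=cfg.seed)
    species = simulate_species_traits(tree, cfg)
    traits = simulate_individuals(species, cfg)
    traits = attach_colour_metrics(traits, cfg, vs=vs)
    return tree, traits


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_wing_image(
    latent: LatentWingColour,
    size: int = 128,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    scale: float = 100.0,
) -> LabelledStack:
    """Render a labelled multi-band wing image for imaging-stage tests.

    The frame contains a wing ellipse split into a concentric marking ellipse
    (areal share = ``marking_fraction``) and background, plus two grey-standard
    patches of true reflectance 7% and 93%.  Pixel value = gain × (region cone
    catch per band) (+ optional Gaussian noise), so with gain ≠ 1 the
    normalization stage has real work to do.
    """
    if gain <= 0:
        raise InvalidArgumentError("gain must be > 0")
    if size < 32:
        raise InvalidArgumentError("size must be >= 32 pixels")
    marking, background = traits_to_cone_catches(latent)
    h = w = int(size)
    labels = np.full((h, w), LABELS["off_wing"], dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h * 0.55, w * 0.5
    ay, ax = h * 0.38, w * 0.30
    wing = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    shrink = math.sqrt(latent.marking_fraction)
    mark = ((yy - cy) / (ay * shrink)) ** 2 + ((xx - cx) / (ax * shrink)) ** 2 <= 1.0
    labels[wing] = LABELS["background"]
    labels[wing & mark] = LABELS["marking"]
    std = max(4, size // 12)
    labels[1 : 1 + std, 1 : 1 + std] = LABELS["standard_low"]
    labels[1 : 1 + std, w - 1 - std : w - 1] = LABELS["standard_high"]

    patch_values = {
        LABELS["off_wing"]: dict.fromkeys(("uv", "sw", "mw", "lw", "dbl"), 0.02),
        LABELS["background"]: {ch: getattr(background, ch) for ch in ("uv", "sw", "mw", "lw", "dbl")},
        LABELS["marking"]: {ch: getattr(marking, ch) for ch in ("uv", "sw", "mw", "lw", "dbl")},
        LABELS["standard_low"]: dict.fromkeys(("uv", "sw", "mw", "lw", "dbl"), 0.07),
        LABELS["standard_high"]: dict.fromkeys(("uv", "sw", "mw", "lw", "dbl"), 0.93),
    }
    bands = np.zeros((5, h, w))
    for b, ch in enumerate(("uv", "sw", "mw", "lw", "dbl")):
        for lab_id, vals in patch_values.items():
            bands[b][labels == lab_id] = gain * vals[ch]
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            bands[b] += rng.normal(0.0, noise_sd, size=(h, w))
    bands = np.clip(bands, 0.0, None)
    return LabelledStack(bands=bands, labels=labels, scale=scale)


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_traits_csv(traits: pd.DataFrame, path) -> None:
    """UTF-8 CSV, header row, one individual per row."""
    traits.to_csv(path, index=False)


def write_catches_csv(traits: pd.DataFrame, path) -> None:
    """Cone-catch table: specimen_id, region, uv, sw, mw, lw, dbl."""
    recs = []
    for _, row in traits.iterrows():
        for region in ("marking", "background"):
            recs.append(
                {
                    "specimen_id": row["specimen_id"],
                    "region": region,
                    **{ch: row[f"{region}_{ch}"] for ch in ("uv", "sw", "mw", "lw", "dbl")},
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)


def config_echo(cfg: SimulationConfig) -> str:
    """YAML-style echo of the generator configuration."""
    import yaml

    return yaml.safe_dump({"simulation": cfg.__dict__}, sort_keys=True)
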