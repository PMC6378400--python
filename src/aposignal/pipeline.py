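"""Statistical screens for quantitative signal honesty.

Stages, mirroring a cross-species comparative analysis of toxin concentration
versus predator-perceived wing colour:

1. species-mean datasets per collection year × sex (``both`` pools individuals
   of both sexes before averaging);
2. per-dataset variable transformations (log / sqrt) with recorded tags;
3. collinearity screening by variance inflation factors (VIF = 1/(1−R²)) and
   greedy construction of predictor subsets under a VIF ceiling plus declared
   incompatibility groups (saturation / hue / chromatic contrast are computed
   from the same cone catches, so never co-occur);
4. backwards stepwise simplification of factorial linear models by nested F
   tests at α (between-year / between-sex comparisons on individual data);
5. PGLS screens of toxin concentration on each predictor subset, simplified by
   the same F rule, run with λ estimated by ML and again fixed to 1;
6. within-species multiple regression with sex × metric interactions.

Also provides replicated null-calibration and power helpers that re-run the
whole synthetic stack many times and collect slope p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import phylo
from .errors import (
    InsufficientDataError,
    InsufficientDfError,
    InsufficientSpeciesError,
    InvalidArgumentError,
    TransformDomainError,
)
from .simulate import SimulationConfig, simulate_dataset

TOXIN_COL = "cnglc_ug_per_g"
METRIC_COLS = (
    "luminance",
    "saturation",
    "hue",
    "chromatic_contrast",
    "achromatic_contrast",
    "relative_marking_area",
)
#: Chromatic metrics derived from the same cone catches: mutually exclusive in
#: any one model.  Marking area and the achromatic metrics are never grouped
#: with them.
CHROMATIC_EXCLUSION_GROUP = frozenset({"saturation", "hue", "chromatic_contrast"})
#: Candidate priority order for model-set construction: exclusion-group members
#: first so each seeds its own subset, shared predictors joining all of them.
CANDIDATE_ORDER = (
    "saturation",
    "hue",
    "chromatic_contrast",
    "luminance",
    "achromatic_contrast",
    "relative_marking_area",
)


# ---------------------------------------------------------------------------
# Dataset construction and transformations
# ---------------------------------------------------------------------------

@dataclass
class AnalysisDataset:
    """Species-mean dataset for one year × sex combination."""

    data: pd.DataFrame  # indexed by species
    year: int
    sex: str  # "F", "M" or "both"
    transforms: dict = field(default_factory=dict)


def aggregate_species_means(
    traits: pd.DataFrame,
    year: int,
    sex: str,
    pooling: str = "pool",
    min_species: int = 3,
) -> AnalysisDataset:
    """Per-species arithmetic means of toxin and every colour metric.

    ``sex="both"`` pools individuals of both sexes before averaging (set
    ``pooling="sex_means"`` for mean-of-sex-means instead).  Fewer than
    ``min_species`` species in the subset is an error.
    """
    sub = traits[traits["year"] == year]
    if sex != "both":
        sub = sub[sub["sex"] == sex]
    cols = [TOXIN_COL] + [c for c in METRIC_COLS if c in traits.columns]
    if sub["species"].nunique() < min_species:
        raise InsufficientSpeciesError(
            f"only {sub['species'].nunique()} species for year={year}, sex={sex}"
        )
    if sex == "both" and pooling == "sex_means":
        by_sex = sub.groupby(["species", "sex"])[cols].mean()
        means = by_sex.groupby("species").mean()
    else:
        means = sub.groupby("species")[cols].mean()
    return AnalysisDataset(data=means.sort_index(), year=year, sex=sex)


def default_transform_plan(year: int, sex: str) -> dict:
    """Per-dataset transformation defaults.

    Toxin concentration is log-transformed for every 2016 dataset; the 2015
    female dataset takes sqrt(saturation) and log(chromatic contrast).  All
    other variables pass through untouched.
    """
    plan = {TOXIN_COL: "log" if year == 2016 else "none"}
    if year == 2015 and sex in ("F", "female"):
        plan["saturation"] = "sqrt"
        plan["chromatic_contrast"] = "log"
    return plan


def apply_transformations(ds: AnalysisDataset, plan: dict | None = None) -> AnalysisDataset:
    """Apply a per-variable transformation plan, recording the tags applied."""
    if plan is None:
        plan = default_transform_plan(ds.year, ds.sex)
    out = ds.data.copy()
    tags = dict(ds.transforms)
    for col, tag in plan.items():
        if col not in out.columns or tag == "none":
            tags.setdefault(col, "none")
            continue
        v = out[col]
        if tag == "log":
            bad = v[v <= 0]
            if len(bad):
                raise TransformDomainError(
                    f"log({col}) undefined for species {list(bad.index)}"
                )
            out[col] = np.log(v)
        elif tag == "sqrt":
            bad = v[v < 0]
            if len(bad):
                raise TransformDomainError(
                    f"sqrt({col}) undefined for species {list(bad.index)}"
                )
            out[col] = np.sqrt(v)
        else:
            raise InvalidArgumentError(f"unknown transformation {tag!r} for {col}")
        tags[col] = tag
    return AnalysisDataset(data=out, year=ds.year, sex=ds.sex, transforms=tags)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def compute_vifs(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1−R²) against all others.

    Perfectly collinear predictors report ``inf`` rather than raising.
    """
    if X.shape[1] < 2:
        raise InvalidArgumentError("VIFs need at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise InvalidArgumentError("VIFs need more rows than predictors")
    out = {}
    Xv = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        yj = Xv[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(Xv, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class ModelSet:
    """Predictor subsets, each respecting the VIF ceiling and exclusion groups."""

    subsets: tuple
    threshold: float = 10.0

    def __iter__(self):
        return iter(self.subsets)

    def __len__(self):
        return len(self.subsets)


def select_model_sets(
    candidates: list[str],
    X: pd.DataFrame,
    threshold: float = 10.0,
    exclusion_groups: tuple = (CHROMATIC_EXCLUSION_GROUP,),
) -> ModelSet:
    """Greedy construction of predictor subsets under the VIF-10 rule.

    Candidates are visited in the given priority order; each is added to every
    existing subset it is compatible with (no two members of one exclusion
    group, max VIF of the grown subset ≤ threshold) and seeds a new subset if
    it fits nowhere.  Deterministic given the order; the union of subsets
    always covers all candidates.
    """
    if not candidates:
        raise InvalidArgumentError("no candidate predictors")
    groups = [frozenset(g) for g in exclusion_groups]

    def incompatible(a: str, members: tuple) -> bool:
        return any(a in g and any(m in g for m in members) for g in groups)

    def vif_ok(members: list) -> bool:
        if len(members) < 2:
            return True  # VIF needs >= 2 predictors; a singleton always passes
        return bool(compute_vifs(X[members]).max() <= threshold)

    subsets: list[list[str]] = []
    for cand in candidates:
        placed = False
        for s in subsets:
            if not incompatible(cand, tuple(s)) and vif_ok(s + [cand]):
                s.append(cand)
                placed = True
        if not placed:
            subsets.append([cand])
    return ModelSet(subsets=tuple(tuple(s) for s in subsets), threshold=threshold)


# ---------------------------------------------------------------------------
# Stepwise simplification of factorial linear models
# ---------------------------------------------------------------------------

def full_factorial(factors: list[str]) -> list[tuple]:
    """All main effects and interactions of the given factors."""
    from itertools import combinations

    terms = []
    for k in range(1, len(factors) + 1):
        terms.extend(combinations(factors, k))
    return terms


def _term_str(term: tuple, categorical: set) -> str:
    return ":".join(f"C({f})" if f in categorical else f for f in term)


def _fit_ols(response: str, terms: list[tuple], data: pd.DataFrame, categorical: set):
    rhs = " + ".join(_term_str(t, categorical) for t in terms) if terms else "1"
    return smf.ols(f"{response} ~ {rhs}", data=data).fit()


def stepwise_simplify(
    response: str,
    terms: list[tuple],
    data: pd.DataFrame,
    alpha: float = 0.05,
    categorical: set | None = None,
) -> pd.DataFrame:
    """Backwards elimination of factorial model terms by nested F tests.

    At each step every currently droppable term (one not marginal to a
    retained higher-order term) is tested by comparing the model with and
    without it; the worst term is dropped while its p exceeds ``alpha`` (ties
    drop the later-listed term).  The returned trace has one row per test in
    the order performed, with a final block of rows for the retained terms.
    """
    if categorical is None:
        categorical = {f for t in terms for f in t if not pd.api.types.is_numeric_dtype(data[f])}
        categorical |= {f for t in terms for f in t if f == "year"}
    terms = [tuple(t) if isinstance(t, (tuple, list)) else (t,) for t in terms]
    current = list(terms)
    full = _fit_ols(response, current, data, categorical)
    if full.df_resid <= 0:
        raise InsufficientDfError("saturated model: no residual degrees of freedom")
    rows = []
    step = 0
    while current:
        step += 1
        droppable = [
            t for t in current if not any(set(t) < set(u) for u in current if u != t)
        ]
        full = _fit_ols(response, current, data, categorical)
        tests = []
        for t in droppable:
            red = _fit_ols(response, [u for u in current if u != t], data, categorical)
            an = sm.stats.anova_lm(red, full)
            F = float(an["F"].iloc[1])
            df1 = int(an["df_diff"].iloc[1])
            df2 = int(full.df_resid)
            p = float(an["Pr(>F)"].iloc[1])
            tests.append((t, F, df1, df2, p))
        worst = max(tests, key=lambda r: (r[4], terms.index(r[0])))
        if worst[4] > alpha:
            t, F, df1, df2, p = worst
            rows.append(
                {"step": step, "term": ":".join(t), "F": F, "df1": df1, "df2": df2,
                 "p": p, "action": "dropped"}
            )
            current.remove(t)
        else:
            for t, F, df1, df2, p in tests:
                rows.append(
                    {"step": step, "term": ":".join(t), "F": F, "df1": df1, "df2": df2,
                     "p": p, "action": "retained"}
                )
            lower = [t for t in current if t not in droppable]
            for t in lower:
                rows.append(
                    {"step": step, "term": ":".join(t), "F": np.nan, "df1": np.nan,
                     "df2": np.nan, "p": np.nan, "action": "retained (marginal)"}
                )
            break
    return pd.DataFrame(rows)


def between_year_models(
    traits: pd.DataFrame,
    metrics: tuple = METRIC_COLS,
    alpha: float = 0.05,
    log_metrics: tuple = ("luminance", "hue", "chromatic_contrast"),
) -> pd.DataFrame:
    """Year/sex/species factorial screens of toxin and each colour metric.

    For each response (toxin concentration, then every metric), fits the full
    sex × species × year model on individual-level data and stepwise-simplifies
    it.  Luminance, hue and chromatic contrast are log-transformed to meet
    model assumptions.  Returns the concatenated traces in report layout.
    """
    out = []
    data = traits.copy()
    for col in (TOXIN_COL,) + tuple(m for m in metrics if m in data.columns):
        d = data.copy()
        resp = col
        if col in log_metrics or col == TOXIN_COL:
            if (d[col] <= 0).any():
                raise TransformDomainError(f"log({col}) undefined for some individuals")
            d[f"log_{col}"] = np.log(d[col])
            resp = f"log_{col}"
        if d[col].nunique() <= 1:
            continue  # constant metric (e.g. fixed marking fraction): nothing to model
        trace = stepwise_simplify(
            resp, full_factorial(["sex", "species", "year"]), d, alpha=alpha
        )
        trace.insert(0, "metric", col)
        out.append(trace)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# PGLS screens (cross-species honesty tests)
# ---------------------------------------------------------------------------

def pgls_single(
    ds: AnalysisDataset,
    tree,
    metric: str,
    lam_mode: str = "ml",
):
    """One toxin ~ metric PGLS fit; returns (fit, F, df1, df2, p) for the slope."""
    y = ds.data[TOXIN_COL]
    X = ds.data[[metric]]
    mode, lam = ("fixed", 1.0) if lam_mode in ("fixed1", "brownian") else ("ml", None)
    fit = phylo.pgls_fit(y, X, tree=tree, mode=mode, lam=lam)
    F, df1, df2, p = phylo.pgls_ftest(fit, metric)
    return fit, F, df1, df2, p


def run_pgls_screen(
    ds: AnalysisDataset,
    tree,
    model_set: ModelSet | None = None,
    lam_modes: tuple = ("ml", "fixed1"),
    alpha: float = 0.05,
    vif_threshold: float = 10.0,
) -> pd.DataFrame:
    """Stepwise-simplified PGLS of toxin concentration on each predictor subset.

    Each subset from the VIF/model-set stage is fitted and backwards-simplified
    with nested F tests at the model's λ̂, separately under ML-estimated λ and
    λ fixed to 1.  One output row per term of each final model (plus an
    intercept-only row when everything is eliminated), in report layout:
    dataset, model, λ mode, λ̂, term, F, dfs, p.
    """
    def _varies(col: pd.Series) -> bool:
        # numerically constant predictors are collinear with the intercept
        return float(col.std()) > 1e-8 * max(1.0, float(col.abs().mean()))

    candidates = [
        c for c in CANDIDATE_ORDER if c in ds.data.columns and _varies(ds.data[c])
    ]
    if model_set is None:
        model_set = select_model_sets(candidates, ds.data[candidates], threshold=vif_threshold)
    rows = []
    for subset in model_set:
        for lam_mode in lam_modes:
            current = list(subset)
            while current:
                y = ds.data[TOXIN_COL]
                mode, lam = ("fixed", 1.0) if lam_mode == "fixed1" else ("ml", None)
                fit = phylo.pgls_fit(y, ds.data[list(current)], tree=tree, mode=mode, lam=lam)
                tests = {t: phylo.pgls_ftest(fit, t) for t in current}
                worst = max(current, key=lambda t: (tests[t][3], current.index(t)))
                if tests[worst][3] > alpha and len(current) >= 1:
                    current.remove(worst)
                else:
                    break
            model_desc = f"{TOXIN_COL} ~ " + (" + ".join(current) if current else "1")
            if current:
                for t in current:
                    F, df1, df2, p = tests[t]
                    rows.append(
                        {"year": ds.year, "sex": ds.sex, "model": model_desc,
                         "subset": " + ".join(subset), "lam_mode": lam_mode,
                         "lam_hat": fit.lam, "term": t, "F": F, "df1": df1,
                         "df2": df2, "p": p}
                    )
            else:
                rows.append(
                    {"year": ds.year, "sex": ds.sex, "model": model_desc,
                     "subset": " + ".join(subset), "lam_mode": lam_mode,
                     "lam_hat": np.nan, "term": None, "F": np.nan, "df1": np.nan,
                     "df2": np.nan, "p": np.nan}
                )
    return pd.DataFrame(rows)


def within_species_regression(
    traits: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 10,
    bases: tuple = ("saturation", "hue"),
    other_metrics: tuple = (
        "luminance",
        "chromatic_contrast",
        "achromatic_contrast",
        "relative_marking_area",
    ),
) -> dict:
    """Within-one-species multiple regression with sex × metric interactions.

    Saturation- and hue-based model families are simplified separately (the
    two never co-occur, per the VIF rule).  Requires at least ``min_n``
    individuals; single-sex data drops the sex terms with a warning.
    """
    if traits["species"].nunique() != 1:
        raise InvalidArgumentError("within_species_regression expects exactly one species")
    if len(traits) < min_n:
        raise InsufficientDataError(f"need >= {min_n} individuals, have {len(traits)}")
    has_both_sexes = traits["sex"].nunique() == 2
    if not has_both_sexes:
        warnings.warn("single-sex data: sex terms dropped from within-species models")
    traces = {}
    data = traits.copy()
    for basis in bases:
        metrics = [m for m in (*other_metrics, basis) if m in data.columns and data[m].nunique() > 1]
        terms: list[tuple] = [(m,) for m in metrics]
        if has_both_sexes:
            terms = [("sex",)] + terms + [("sex", m) for m in metrics]
        traces[basis] = stepwise_simplify(TOXIN_COL, terms, data, alpha=alpha)
    return traces


# ---------------------------------------------------------------------------
# Replicated calibration / power helpers
# ---------------------------------------------------------------------------

def replicate_slope_pvalues(
    cfg: SimulationConfig,
    n_reps: int,
    metric: str = "luminance",
    year: int = 2016,
    sex: str = "both",
    lam_mode: str = "fixed1",
    seed: int = 0,
) -> np.ndarray:
    """p-values of the toxin ~ metric PGLS slope across fresh synthetic studies.

    Each replicate regenerates tree, species traits, individuals and colour
    metrics from an independent seed, aggregates the requested year × sex
    dataset, applies the default transformation plan, and fits the
    single-predictor PGLS.  The returned array feeds type-I calibration
    (honesty_slope = 0) and power checks (honesty_slope > 0).
    """
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n_reps)]
    ps = np.empty(n_reps)
    for i, s in enumerate(seeds):
        c = replace(cfg, seed=s)
        tree, traits = simulate_dataset(c)
        ds = apply_transformations(aggregate_species_means(traits, year, sex))
        _, _, _, _, p = pgls_single(ds, tree, metric, lam_mode=lam_mode)
        ps[i] = p
    return ps
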