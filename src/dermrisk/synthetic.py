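"""Synthetic case-control cohort generator for skin-cancer risk modelling.

Emulates the data structure of a large survey-based case-control cohort:
three correlated binary skin-cancer outcomes (BCC, SCC, melanoma) driven by
a per-year hazard multiplied by the exponential of a linear predictor over
mixed survey factors plus additive genotype effects.  Age at diagnosis,
family-history indicators, missingness, and yearly follow-up waves are all
generated so that every downstream stage of the analysis has ground truth.

The disease mechanism is a discrete yearly hazard, not a single
cross-sectional logistic draw: cumulative incidence, incident cases and
ages of diagnosis therefore exist and have closed forms under constant
hazards, while cross-sectional case status still approximately follows the
logistic model the downstream GLMs fit (exactly so in the rare-disease
limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix

CANCERS = ("bcc", "scc", "melanoma")

GROUP_DEMOGRAPHIC = "Demographic"
GROUP_FAMILY = "Family"
GROUP_MOLE = "Mole"
GROUP_SUSCEPTIBILITY = "Susceptibility"
GROUP_EXPOSURE = "Exposure"
GROUP_MISC = "Miscellaneous"
GROUP_PRS = "PRS"


@dataclass
class FactorSpec:
    """One survey factor: marginal distribution, age dependence, effects.

    ``kind`` is one of ``binary``, ``ordinal``, ``continuous``,
    ``categorical``.  ``params`` holds the marginal distribution:
    ``{"p": .}`` for binary, ``{"probs": [...]}`` for ordinal,
    ``{"mean": ., "sd": .}`` for continuous, ``{"levels": [...],
    "probs": [...]}`` for categorical.  ``age_slope`` shifts the factor's
    mean (latent mean for binary/ordinal) per year of age relative to age
    60; 0 means age-independent.  ``effects`` maps cancer name to a
    per-unit log-odds-ratio (scalar) or, for categorical factors, a
    per-level vector of log-odds-ratios.
    """

    name: str
    kind: str
    group: str
    params: dict
    age_slope: float = 0.0
    effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "continuous", "categorical"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind in ("ordinal", "categorical"):
            probs = np.asarray(self.params["probs"], dtype=float)
            if probs.size < 2:
                raise ValueError(f"{self.name}: need >= 2 levels")
            if not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{self.name}: level probabilities must sum to 1")
        if self.kind == "categorical":
            levels = self.params["levels"]
            if len(levels) != len(self.params["probs"]):
                raise ValueError(f"{self.name}: levels/probs length mismatch")

    @property
    def n_levels(self) -> int:
        if self.kind == "binary":
            return 2
        if self.kind in ("ordinal", "categorical"):
            return len(self.params["probs"])
        raise ValueError("continuous factors have no levels")

    def effect_of(self, cancer: str, values: np.ndarray) -> np.ndarray:
        """Per-participant log-odds contribution of this factor."""
        eff = self.effects.get(cancer, 0.0)
        if self.kind == "categorical":
            eff = np.asarray(eff, dtype=float)
            if eff.ndim == 0:
                eff = np.full(self.n_levels, float(eff))
            codes = values.astype(int)
            return eff[codes]
        return float(eff) * values.astype(float)


def _ordinal_catalog(name, group, probs, per_unit, age_slope=0.0):
    return FactorSpec(name, "ordinal", group, {"probs": list(probs)},
                      age_slope=age_slope, effects=per_unit)


def default_factor_catalog() -> list[FactorSpec]:
    """~25-factor catalog mirroring the survey's risk-factor structure.

    Factor names and effect directions follow the skin-cancer
    risk-factor literature (dysplastic moles, actinic keratosis, skin
    pigmentation, sunbathing, tanning beds, BMI/weight, etc.); effect
    magnitudes are generator truth chosen to be realistic, not estimates.
    The dysplastic-mole melanoma effect is planted at ln(6.7).
    """
    e = lambda b, s, m: {"bcc": b, "scc": s, "melanoma": m}
    cat = [
        # --- Mole group (4 factors)
        FactorSpec("dysplastic_moles", "binary", GROUP_MOLE, {"p": 0.05},
                   effects=e(np.log(2.2), np.log(2.0), np.log(6.7))),
        FactorSpec("large_moles", "binary", GROUP_MOLE, {"p": 0.10},
                   effects=e(0.20, 0.20, 0.50)),
        _ordinal_catalog("mole_count_arm", GROUP_MOLE,
                         [0.40, 0.30, 0.15, 0.10, 0.05],
                         e(0.10, 0.10, 0.25), age_slope=-0.002),
        FactorSpec("actinic_keratosis_before_40", "binary", GROUP_MOLE,
                   {"p": 0.03},
                   effects=e(np.log(3.2), np.log(3.5), 0.30)),
        # --- Susceptibility group (8 factors)
        _ordinal_catalog("skin_color", GROUP_SUSCEPTIBILITY,
                         [0.30, 0.40, 0.20, 0.10], e(0.25, 0.25, 0.25)),
        FactorSpec("eye_color", "categorical", GROUP_SUSCEPTIBILITY,
                   {"levels": ["brown", "hazel", "green", "blue"],
                    "probs": [0.35, 0.20, 0.15, 0.30]},
                   effects={c: [0.0, 0.08, 0.15, 0.22] for c in CANCERS}),
        _ordinal_catalog("hair_color", GROUP_SUSCEPTIBILITY,
                         [0.45, 0.30, 0.15, 0.10], e(0.15, 0.15, 0.18)),
        _ordinal_catalog("freckles_face", GROUP_SUSCEPTIBILITY,
                         [0.50, 0.25, 0.15, 0.10], e(0.15, 0.15, 0.20)),
        _ordinal_catalog("freckles_body", GROUP_SUSCEPTIBILITY,
                         [0.55, 0.25, 0.12, 0.08], e(0.10, 0.10, 0.12)),
        _ordinal_catalog("sunburn_blisters", GROUP_SUSCEPTIBILITY,
                         [0.45, 0.30, 0.15, 0.10], e(0.15, 0.15, 0.20)),
        FactorSpec("sun_hair_lightening", "binary", GROUP_SUSCEPTIBILITY,
                   {"p": 0.30}, effects=e(0.10, 0.10, 0.10)),
        _ordinal_catalog("skin_reaction_sun", GROUP_SUSCEPTIBILITY,
                         [0.35, 0.35, 0.20, 0.10], e(0.20, 0.20, 0.20)),
        # --- Exposure group (8 factors)
        _ordinal_catalog("sunbathing_before_30", GROUP_EXPOSURE,
                         [0.30, 0.30, 0.20, 0.12, 0.08],
                         e(0.12, 0.12, 0.10), age_slope=0.004),
        _ordinal_catalog("tanning_bed", GROUP_EXPOSURE,
                         [0.584, 0.30, 0.116], e(0.08, 0.13, 0.08)),
        FactorSpec("childhood_latitude", "continuous", GROUP_EXPOSURE,
                   {"mean": 0.0, "sd": 1.0}, effects=e(-0.08, -0.08, -0.05)),
        FactorSpec("adult_latitude", "continuous", GROUP_EXPOSURE,
                   {"mean": 0.0, "sd": 1.0}, effects=e(-0.06, -0.06, -0.04)),
        FactorSpec("childhood_elevation", "continuous", GROUP_EXPOSURE,
                   {"mean": 0.0, "sd": 1.0}, effects=e(0.05, 0.05, 0.03)),
        FactorSpec("sun_hours_week", "continuous", GROUP_EXPOSURE,
                   {"mean": 0.0, "sd": 1.0}, age_slope=0.003,
                   effects=e(0.06, 0.06, 0.04)),
        FactorSpec("outdoor_job", "binary", GROUP_EXPOSURE, {"p": 0.15},
                   effects=e(0.10, 0.12, 0.05)),
        _ordinal_catalog("physical_activity", GROUP_EXPOSURE,
                         [0.40, 0.40, 0.20], e(0.08, 0.08, 0.08)),
        # --- Miscellaneous group (7 factors)
        FactorSpec("weight", "continuous", GROUP_MISC,
                   {"mean": 0.0, "sd": 1.0}, effects=e(0.25, 0.22, 0.15)),
        FactorSpec("bmi", "continuous", GROUP_MISC,
                   {"mean": 0.0, "sd": 1.0}, effects=e(-0.30, -0.25, -0.15)),
        FactorSpec("smoking", "binary", GROUP_MISC, {"p": 0.45},
                   effects=e(-0.06, 0.0, 0.0)),
        _ordinal_catalog("alcohol", GROUP_MISC, [0.40, 0.40, 0.20],
                         e(0.05, 0.05, 0.05)),
        FactorSpec("seasonal_allergies", "binary", GROUP_MISC, {"p": 0.25},
                   effects=e(0.05, 0.05, 0.05)),
        FactorSpec("morning_person", "binary", GROUP_MISC, {"p": 0.50},
                   effects=e(0.07, 0.07, 0.05)),
        FactorSpec("clean_desk", "binary", GROUP_MISC, {"p": 0.50},
                   effects=e(-0.05, -0.05, -0.05)),
        # --- Demographic (sex; age acts through the baseline hazard)
        FactorSpec("sex_male", "binary", GROUP_DEMOGRAPHIC, {"p": 0.40},
                   effects=e(np.log(1.6), np.log(1.6), np.log(1.6))),
    ]
    return cat


def default_baseline_hazards(age_range=(30, 90)) -> dict[str, np.ndarray]:
    """Per-cancer yearly baseline hazards, exponential in age.

    Calibrated once so that cohort prevalences at the cohort's age
    structure fall near observed survey prevalences (BCC ~ 13%, SCC ~ 6%,
    melanoma ~ 3%).
    """
    a = np.arange(age_range[0], age_range[1] + 1, dtype=float)
    return {
        "bcc": 1.2e-3 * np.exp(0.055 * (a - age_range[0])),
        "scc": 4.0e-4 * np.exp(0.065 * (a - age_range[0])),
        "melanoma": 3.0e-4 * np.exp(0.045 * (a - age_range[0])),
    }


def default_variant_effects(n_variants: int, n_causal: int = 20,
                            effect: float = np.log(1.15)) -> dict[str, np.ndarray]:
    """Sparse per-cancer additive genotype effects (log-OR per dosage unit).

    The first ``n_causal`` variants are causal for every cancer with
    alternating signs; cancers share causal variants but with shuffled
    magnitudes so the three outcomes are correlated, not identical.
    """
    out = {}
    for ci, c in enumerate(CANCERS):
        beta = np.zeros(n_variants)
        k = min(n_causal, n_variants)
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        scale = 1.0 - 0.15 * ci
        beta[:k] = signs * effect * scale
        out[c] = beta
    return out


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    ``maf`` may be None (drawn Uniform(0.05, 0.5) from the seed),
    a scalar, or a length-``n_variants`` vector.  ``baseline_hazard``
    maps cancer name to a yearly hazard over the age grid.
    ``ld_blocks`` is a list of ``(j1, j2, rho)`` triples forcing dosage
    correlation ~rho between variant columns j1 and j2 (for clumping
    tests); variants are otherwise independent.
    """

    n_participants: int = 5000
    n_variants: int = 200
    maf: Optional[object] = None
    variant_effects: Optional[dict] = None
    factor_specs: list = field(default_factory=default_factor_catalog)
    age_range: tuple = (30, 90)
    baseline_hazard: Optional[dict] = None
    followup_years: int = 2
    response_rate: float = 0.55
    recurrence_prob: float = 0.30
    missing_rate: float = 0.05
    factor_correlations: list = field(
        default_factory=lambda: [("weight", "bmi", 0.8)])
    ld_blocks: list = field(default_factory=list)
    family_effect: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_variants < 0:
            raise ValueError("n_participants must be >= 1, n_variants >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.followup_years < 0:
            raise ValueError("followup_years must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.baseline_hazard is not None:
            for c, h in self.baseline_hazard.items():
                h = np.asarray(h, dtype=float)
                if h.min() < 0 or h.max() > 1:
                    raise ValueError(f"hazards for {c} must lie in [0, 1]")

    def resolved_maf(self) -> np.ndarray:
        if self.maf is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 101]))
            maf = rng.uniform(0.05, 0.5, self.n_variants)
        else:
            maf = np.broadcast_to(
                np.asarray(self.maf, dtype=float), (self.n_variants,)).copy()
        if maf.size != self.n_variants:
            raise ValueError("maf length must equal n_variants")
        return maf

    def resolved_hazards(self) -> dict[str, np.ndarray]:
        if self.baseline_hazard is None:
            return default_baseline_hazards(self.age_range)
        out = {}
        n_ages = self.age_range[1] - self.age_range[0] + 1
        for c in CANCERS:
            h = np.asarray(self.baseline_hazard[c], dtype=float)
            if h.ndim == 0:
                h = np.full(n_ages, float(h))
            if h.size != n_ages:
                raise ValueError(f"hazard for {c} must cover the age grid")
            out[c] = h
        return out

    def resolved_variant_effects(self) -> dict[str, np.ndarray]:
        if self.variant_effects is None:
            return default_variant_effects(self.n_variants)
        out = {}
        for c in CANCERS:
            b = np.asarray(self.variant_effects.get(c, np.zeros(self.n_variants)),
                           dtype=float)
            if b.size != self.n_variants:
                raise ValueError("variant effect length must equal n_variants")
            out[c] = b
        return out


@dataclass
class Cohort:
    """Participant table plus the generator's hidden truth.

    ``table`` has one row per participant: id, sex, current age, factor
    values, family-history indicators, per-cancer case status / age at
    diagnosis / stage, and per-wave follow-up answers.  ``truth`` (only
    for generated cohorts) holds the per-cancer linear predictors used to
    drive the hazards — never consumed by the analysis stages, only by
    tests and follow-up generation.
    """

    table: pd.DataFrame
    factors: list
    cancers: tuple = CANCERS
    truth: Optional[pd.DataFrame] = None

    @property
    def n(self) -> int:
        return len(self.table)

    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]


def generate_genotypes(n: int, maf, seed: int,
                       ld_blocks: Sequence = ()) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: Binomial(2, maf_j) per variant.

    Columns are independent except for the requested ``ld_blocks``; each
    variant gets a chromosome and 1-based position on a synthetic map
    (adjacent same-chromosome variants 100 kb apart).
    """
    maf = np.asarray(maf, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if maf.ndim != 1 or maf.size == 0:
        raise ValueError("maf must be a non-empty vector")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("all maf must lie in (0, 0.5]")
    m = maf.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    # two allele draws so LD blocks can correlate at the allele level
    a1 = rng.random((n, m)) < maf
    a2 = rng.random((n, m)) < maf
    for (j1, j2, rho) in ld_blocks:
        keep = rng.random(n) < rho
        a1[keep, j2] = a1[keep, j1]
        keep = rng.random(n) < rho
        a2[keep, j2] = a2[keep, j1]
    dosages = (a1.astype(np.float64) + a2.astype(np.float64))
    chrom = (np.arange(m) % 22) + 1
    pos = (np.arange(m) // 22 + 1) * 100_000
    variants = pd.DataFrame({
        "variant_id": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": np.where(np.arange(m) % 2 == 0, "A", "G"),
        "maf": maf,
    })
    ids = [f"P{i + 1:07d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, participant_ids=ids,
                          variants=variants)


def _draw_factor(spec: FactorSpec, ages: np.ndarray, rng,
                 latent: Optional[np.ndarray] = None) -> np.ndarray:
    """Draw one factor column; ``latent`` supplies a pre-correlated
    standard-normal vector for continuous factors."""
    n = ages.size
    shift = spec.age_slope * (ages - 60.0)
    if spec.kind == "binary":
        p = np.clip(spec.params["p"] + shift, 0.005, 0.995)
        return (rng.random(n) < p).astype(float)
    if spec.kind == "continuous":
        z = latent if latent is not None else rng.standard_normal(n)
        return spec.params["mean"] + shift + spec.params["sd"] * z
    probs = np.asarray(spec.params["probs"], dtype=float)
    # latent-normal discretization; age slope shifts the latent mean
    from scipy.stats import norm
    cum = np.cumsum(probs)[:-1]
    cuts = norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    z = rng.standard_normal(n) + shift
    codes = np.searchsorted(cuts, z)
    return codes.astype(float)


def linear_predictor(table: pd.DataFrame, factors: Sequence[FactorSpec],
                     cancer: str,
                     genotypes: Optional[GenotypeMatrix] = None,
                     variant_effects: Optional[dict] = None) -> np.ndarray:
    """Generator-truth linear predictor (no intercept, no age term)."""
    eta = np.zeros(len(table))
    for spec in factors:
        col = table[spec.name]
        if spec.kind == "categorical":
            levels = list(spec.params["levels"])
            codes = col.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
            eta += spec.effect_of(cancer, codes)
        else:
            eta += spec.effect_of(cancer, col.to_numpy(dtype=float))
    if genotypes is not None and variant_effects is not None:
        eta += genotypes.dosages @ variant_effects[cancer]
    return eta


def generate_cohort(config: GeneratorConfig):
    """Generate a cohort and its genotype matrix.

    Returns ``(Cohort, GenotypeMatrix)``.  Diagnosis arises from a yearly
    hazard ``baseline(a) * exp(eta)`` applied from the minimum age to the
    participant's current age; the first success sets case status and age
    at diagnosis.  The linear predictor is centered on its cohort mean, so
    ``baseline_hazard`` is the yearly hazard of an average-risk
    participant (centering shifts only the implicit intercept; all odds
    ratios are untouched).  Family history is drawn with probability
    increasing in the participant's own linear predictor (shared-risk
    proxy).  Missingness is completely at random, factor columns only.
    """
    n = config.n_participants
    lo, hi = config.age_range
    ss = np.random.SeedSequence([config.seed, 7])
    r_age, r_fac, r_dis, r_fam, r_miss, r_extra = [
        np.random.default_rng(s) for s in ss.spawn(6)]

    maf = config.resolved_maf()
    genotypes = generate_genotypes(n, maf, config.seed,
                                   ld_blocks=config.ld_blocks) \
        if config.n_variants > 0 else GenotypeMatrix.empty(n)

    ages = np.clip(np.round(r_age.normal(58.0, 13.0, n)), lo, hi).astype(int)

    table = pd.DataFrame({
        "participant_id": genotypes.participant_ids if config.n_variants > 0
        else [f"P{i + 1:07d}" for i in range(n)],
        "enroll_order": np.arange(n),
        "current_age": ages,
    })

    # correlated continuous factors via a Gaussian copula block
    cont = [f.name for f in config.factor_specs if f.kind == "continuous"]
    latents = {}
    if cont:
        C = np.eye(len(cont))
        idx = {nm: i for i, nm in enumerate(cont)}
        for (n1, n2, rho) in config.factor_correlations:
            if n1 in idx and n2 in idx:
                C[idx[n1], idx[n2]] = C[idx[n2], idx[n1]] = rho
        L = np.linalg.cholesky(C)
        Z = r_fac.standard_normal((n, len(cont))) @ L.T
        latents = {nm: Z[:, i] for nm, i in idx.items()}

    for spec in config.factor_specs:
        vals = _draw_factor(spec, ages, r_fac, latent=latents.get(spec.name))
        if spec.kind == "categorical":
            levels = list(spec.params["levels"])
            table[spec.name] = pd.Categorical.from_codes(
                vals.astype(int), categories=levels)
        else:
            table[spec.name] = vals

    veffects = config.resolved_variant_effects()
    hazards = config.resolved_hazards()
    age_grid = np.arange(lo, hi + 1)
    n_ages = age_grid.size
    truth = {}
    clipped_py = 0
    total_py = 0
    for c in CANCERS:
        eta = linear_predictor(table, config.factor_specs, c,
                               genotypes if config.n_variants > 0 else None,
                               veffects if config.n_variants > 0 else None)
        eta = eta - eta.mean()
        truth[f"eta_{c}"] = eta
        H = hazards[c][None, :] * np.exp(eta)[:, None]
        valid = age_grid[None, :] <= ages[:, None]
        clipped_py += int(((H > 1.0) & valid).sum())
        total_py += int(valid.sum())
        H = np.clip(H, 0.0, 1.0)
        hit = (r_dis.random((n, n_ages)) < H) & valid
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        table[f"case_{c}"] = any_hit.astype(int)
        age_dx = np.where(any_hit, lo + first, np.nan)
        table[f"age_dx_{c}"] = age_dx
        # optional clinical descriptors, cases only
        stage = np.full(n, np.nan)
        ncases = int(any_hit.sum())
        if ncases:
            stage[any_hit] = r_extra.choice(
                [1, 2, 3, 4], size=ncases, p=[0.75, 0.18, 0.05, 0.02])
        table[f"stage_{c}"] = stage
        nrec = np.full(n, np.nan)
        if ncases:
            nrec[any_hit] = 1 + r_extra.poisson(0.4, ncases)
        table[f"n_recent_dx_{c}"] = nrec
    if total_py and clipped_py / total_py > 0.01:
        warnings.warn(
            f"hazard clipping affected {clipped_py / total_py:.1%} of "
            "person-years; effect sizes too large for the baseline hazard")

    # family history from the proband's own (standardized) mean eta
    eta_mean = np.mean([truth[f"eta_{c}"] for c in CANCERS], axis=0)
    sd = eta_mean.std()
    z = (eta_mean - eta_mean.mean()) / sd if sd > 0 else np.zeros(n)
    for rel, icpt in [("father", -1.7), ("mother", -1.8),
                      ("sibling", -1.9), ("child", -3.3)]:
        p = 1.0 / (1.0 + np.exp(-(icpt + config.family_effect * z)))
        table[f"fh_{rel}"] = (r_fam.random(n) < p).astype(float)

    # MCAR missingness on factor columns only
    if config.missing_rate > 0:
        for spec in config.factor_specs:
            if spec.name == "sex_male":
                continue
            mask = r_miss.random(n) < config.missing_rate
            if spec.kind == "categorical":
                col = table[spec.name].copy()
                col[mask] = np.nan
                table[spec.name] = col
            else:
                table.loc[mask, spec.name] = np.nan

    cohort = Cohort(table=table, factors=list(config.factor_specs),
                    truth=pd.DataFrame(truth))
    return cohort, genotypes


def generate_followup(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Append yearly follow-up waves to a generated cohort.

    Baseline controls convert with their yearly hazard at
    ``current_age + k``; the wave-k survey answer ``diagnosed_last_year``
    covers that year only (a wave-1 convert answering wave 2 reports 0),
    matching how a "diagnosed in the last 12 months" question behaves.
    Baseline cases report ``treated_last_year`` per the recurrence
    probability; each wave is answered by a ``response_rate`` fraction
    (non-response = missing).  Requires the generator truth carried on
    the cohort.
    """
    if config.followup_years < 1:
        raise ValueError("followup_years must be >= 1")
    if cohort.truth is None:
        raise ValueError("follow-up generation needs the generator truth "
                         "(cohort must come from generate_cohort)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    table = cohort.table.copy()
    hazards = config.resolved_hazards()
    lo, hi = config.age_range
    n = len(table)
    ages = table["current_age"].to_numpy(dtype=int)
    incident_already = {c: np.zeros(n, dtype=bool) for c in CANCERS}
    for k in range(1, config.followup_years + 1):
        responded = rng.random(n) < config.response_rate
        for c in CANCERS:
            eta = cohort.truth[f"eta_{c}"].to_numpy()
            a_idx = np.clip(ages + k - lo, 0, hi - lo)
            h = np.clip(hazards[c][a_idx] * np.exp(eta), 0.0, 1.0)
            is_case = table[f"case_{c}"].to_numpy() == 1
            new_dx = (~is_case & ~incident_already[c]
                      & (rng.random(n) < h))
            incident_already[c] |= new_dx
            diag = np.where(is_case, 0.0, new_dx.astype(float))
            treat = np.where(
                is_case, (rng.random(n) < config.recurrence_prob).astype(float),
                np.nan)
            diag = np.where(responded, diag, np.nan)
            treat = np.where(responded & is_case, treat, np.nan)
            table[f"fu{k}_diag_{c}"] = diag
            table[f"fu{k}_treat_{c}"] = treat
    return Cohort(table=table, factors=cohort.factors, truth=cohort.truth)
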