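"""Synthetic general-population cohort generator.

Emulates the statistical structure the decline analysis assumes: an
ageing cohort (truncated-normal age), a latent general cognitive ability
G driving five correlated test scores, an age-dependent annual rate of
cognitive decline, and baseline biomarkers whose group contrasts arise
through their age slopes. Anchors (means, SDs, prevalences) default to
the published control-group values of the study population this package
models; age slopes are calibration parameters documented in the methods
note. Missingness is MCAR per feature; block missingness (e.g. a
sub-cohort scanned later) is produced by :func:`mask_subset_features`.

The decline model: each subject carries an annual g-change

    d_i = base - slope * (age_i - age_mean) + noise_i ,

so older subjects decline faster; follow-up test scores are the baseline
scores shifted by the subject's g-change scaled through each test's
loading. The 5% most negative ``d`` (as re-measured through the g-factor)
define the positive class downstream, which makes age a genuine — and the
dominant — predictor, as in the population this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import rankdata, truncnorm

from .cohort import FOLLOWUP_SUFFIX, CohortTable

__all__ = [
    "TestSpec",
    "BiomarkerSpec",
    "GeneratorConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "generate_cohort",
    "oracle_age_auc",
    "mask_subset_features",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class TestSpec:
    """One cognitive test: loading on latent G, cross-sectional age slope,
    anchor mean and (residual) SD. A negative loading encodes tests scored
    in time (higher = worse)."""

    name: str
    loading: float
    age_slope: float
    mean: float
    sd: float


@dataclass
class BiomarkerSpec:
    """One baseline predictor feature.

    dist:
      * ``normal``  — mean + age_slope*(age-age_mean) + sd*eps
      * ``lognormal`` — exp(log(mean) + age_slope*(age-age_mean) + sd*eps),
        i.e. ``mean`` is the median and ``sd``/``age_slope`` act on the log
        scale (used for skewed features reported as median/IQR)
      * ``binary`` — Bernoulli(expit(logit(mean) + age_slope*(age-age_mean)));
        ``mean`` is the prevalence at age_mean, ``age_slope`` a per-year
        log-odds slope
      * ``ordinal`` — latent normal rounded and clipped to ``levels``
    """

    name: str
    category_path: str
    dist: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    age_slope: float = 0.0
    levels: tuple[float, float] | None = None

    @property
    def is_binary(self) -> bool:
        return self.dist == "binary"


@dataclass
class GeneratorConfig:
    n_subjects: int = 2542
    seed: int = 0
    age_mean: float = 60.9
    age_sd: float = 9.1
    age_range: tuple[float, float] = (45.0, 95.0)
    female_fraction: float = 0.556
    followup_mean: float = 5.7
    followup_sd: float = 0.6
    decline_base_per_year: float = -0.02
    decline_slope_per_year_of_age: float = 0.005
    decline_noise_sd: float = 0.07
    test_specs: list[TestSpec] = field(default_factory=list)
    biomarker_specs: list[BiomarkerSpec] = field(default_factory=list)
    missing_rates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in ("age_sd", "followup_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError(f"female_fraction must be in [0,1], got {self.female_fraction}")
        if self.decline_noise_sd < 0:
            raise ConfigError(f"decline_noise_sd must be >= 0, got {self.decline_noise_sd}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must be increasing, got {self.age_range}")
        for spec in self.test_specs:
            if spec.sd <= 0:
                raise ConfigError(f"test {spec.name}: sd must be > 0")
            if abs(spec.loading) > 1:
                raise ConfigError(f"test {spec.name}: |loading| must be <= 1")
        names = [s.name for s in self.test_specs] + [s.name for s in self.biomarker_specs]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate feature names: {dupes}")
        for spec in self.biomarker_specs:
            if spec.dist not in ("normal", "lognormal", "binary", "ordinal"):
                raise ConfigError(f"biomarker {spec.name}: unknown dist {spec.dist!r}")
            if spec.dist == "binary" and not 0 < spec.mean < 1:
                raise ConfigError(f"biomarker {spec.name}: prevalence must be in (0,1)")
            if spec.dist in ("normal", "lognormal", "ordinal") and spec.sd <= 0:
                raise ConfigError(f"biomarker {spec.name}: sd must be > 0")
            if spec.dist == "ordinal" and spec.levels is None:
                raise ConfigError(f"biomarker {spec.name}: ordinal needs levels")
        for feat, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigError(f"missing rate for {feat} must be in [0,1], got {rate}")
            if feat not in names and feat not in ("age", "sex"):
                raise ConfigError(f"missing rate given for unknown feature {feat!r}")


def _config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    tests = [TestSpec(**t) for t in d.pop("tests", [])]
    bios = []
    for b in d.pop("biomarkers", []):
        b = dict(b)
        if "levels" in b and b["levels"] is not None:
            b["levels"] = tuple(b["levels"])
        bios.append(BiomarkerSpec(**b))
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    cfg = GeneratorConfig(test_specs=tests, biomarker_specs=bios, **d)
    cfg.validate()
    return cfg


def load_config(path: str) -> GeneratorConfig:
    """Read a generator configuration from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def save_config(cfg: GeneratorConfig, path: str) -> None:
    d: dict = {
        k: getattr(cfg, k)
        for k in (
            "n_subjects", "seed", "age_mean", "age_sd", "female_fraction",
            "followup_mean", "followup_sd", "decline_base_per_year",
            "decline_slope_per_year_of_age", "decline_noise_sd",
        )
    }
    d["age_range"] = list(cfg.age_range)
    d["tests"] = [vars(t).copy() for t in cfg.test_specs]
    d["biomarkers"] = []
    for b in cfg.biomarker_specs:
        bd = {k: v for k, v in vars(b).items() if v is not None}
        if "levels" in bd:
            bd["levels"] = list(bd["levels"])
        d["biomarkers"].append(bd)
    d["missing_rates"] = dict(cfg.missing_rates)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def default_config(n_subjects: int | None = None, seed: int | None = None) -> GeneratorConfig:
    """The packaged default configuration (anchored to the published
    control-group means/SDs of the modelled study population)."""
    with resources.files("dsidx.data").joinpath("default_config.yaml").open() as fh:
        cfg = _config_from_dict(yaml.safe_load(fh))
    if n_subjects is not None:
        cfg.n_subjects = n_subjects
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    return cfg


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws whose *realised* mean/sd match the request.

    Truncation shifts the moments of the parent normal (a [45, 95] window
    around 60.9 +- 9.1 raises the mean by ~0.8 years), so the parent
    location/scale are solved such that the truncated distribution itself
    has the configured mean and sd. Falls back to the parent parameters
    when the solve fails (e.g. an sd infeasible for the window).
    """
    from scipy.optimize import fsolve

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return [
            truncnorm.mean(a, b, loc=loc, scale=scale) - mean,
            truncnorm.std(a, b, loc=loc, scale=scale) - sd,
        ]

    loc, scale = mean, sd
    if np.isfinite(lo) or np.isfinite(hi):
        sol, _, ok, _ = fsolve(moments, [mean, sd], full_output=True)
        if ok == 1 and abs(sol[1]) > 0:
            loc, scale = float(sol[0]), float(abs(sol[1]))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _simulate_core(cfg: GeneratorConfig, rng: np.random.Generator, n: int):
    """Age, sex, follow-up, latent G and annual decline d, in fixed draw order."""
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    sex = (rng.random(n) < cfg.female_fraction).astype(float)
    followup = _truncated_normal(
        rng, cfg.followup_mean, cfg.followup_sd, 0.1, np.inf, size=n
    )
    latent_g = rng.standard_normal(n)
    d = (
        cfg.decline_base_per_year
        - cfg.decline_slope_per_year_of_age * (age - cfg.age_mean)
        + cfg.decline_noise_sd * rng.standard_normal(n)
    )
    return age, sex, followup, latent_g, d


def generate_cohort(cfg: GeneratorConfig) -> CohortTable:
    """Generate an analysis-ready cohort; same config + seed is reproducible."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    age, sex, followup, latent_g, d = _simulate_core(cfg, rng, n)

    data: dict[str, np.ndarray] = {
        "subject_id": np.arange(1, n + 1),
        "age": age,
        "sex": sex,
        "followup_years": followup,
    }
    meta_rows = [
        {"feature": "age", "category_path": "age", "is_binary": False},
        {"feature": "sex", "category_path": "sex", "is_binary": True},
    ]

    for spec in cfg.test_specs:
        lam = spec.loading
        z = lam * latent_g + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        baseline = spec.mean + spec.age_slope * (age - cfg.age_mean) + spec.sd * z
        data[spec.name] = baseline
        # follow-up: the baseline score shifted by the g-change through the loading
        data[spec.name + FOLLOWUP_SUFFIX] = baseline + spec.sd * lam * d * followup
        meta_rows.append(
            {
                "feature": spec.name,
                "category_path": "cognitive_tests/objective_tests",
                "is_binary": False,
            }
        )

    for spec in cfg.biomarker_specs:
        shift = spec.age_slope * (age - cfg.age_mean)
        if spec.dist == "normal":
            vals = spec.mean + shift + spec.sd * rng.standard_normal(n)
        elif spec.dist == "lognormal":
            vals = np.exp(np.log(spec.mean) + shift + spec.sd * rng.standard_normal(n))
        elif spec.dist == "binary":
            p = expit(logit(spec.mean) + shift)
            vals = (rng.random(n) < p).astype(float)
        else:  # ordinal
            lo, hi = spec.levels
            vals = np.clip(
                np.rint(spec.mean + shift + spec.sd * rng.standard_normal(n)), lo, hi
            )
        data[spec.name] = vals
        meta_rows.append(
            {
                "feature": spec.name,
                "category_path": spec.category_path,
                "is_binary": spec.is_binary,
            }
        )

    df = pd.DataFrame(data)
    # MCAR missingness, independent per feature, after all value draws
    for feat in sorted(cfg.missing_rates):
        rate = cfg.missing_rates[feat]
        if rate > 0:
            df.loc[rng.random(n) < rate, feat] = np.nan

    return CohortTable(
        data=df,
        feature_meta=pd.DataFrame(meta_rows),
        test_names=[s.name for s in cfg.test_specs],
    )


def oracle_age_auc(
    cfg: GeneratorConfig, n_mc: int = 1_000_000, tail_fraction: float = 0.05,
    seed: int | None = None,
) -> float:
    """Monte-Carlo reference AUC of age as a single predictor.

    Simulates a fresh population of ``n_mc`` subjects from the generator's
    age/decline model, labels the ``tail_fraction`` steepest annual
    decliners positive, and returns the Mann-Whitney probability
    P(age_pos > age_neg) + 0.5 P(=). This is the theoretical ceiling for
    any age-only classifier under the generator, independent of the
    classifier implementation.
    """
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for a stable oracle")
    if cfg.decline_slope_per_year_of_age == 0 and cfg.decline_noise_sd == 0:
        raise ConfigError(
            "decline_slope_per_year_of_age and decline_noise_sd are both 0: "
            "the decline is constant and the tail label is undefined"
        )
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n_mc)
    d = (
        cfg.decline_base_per_year
        - cfg.decline_slope_per_year_of_age * (age - cfg.age_mean)
        + cfg.decline_noise_sd * rng.standard_normal(n_mc)
    )
    n_pos = int(np.floor(tail_fraction * n_mc))
    order = np.argsort(d, kind="stable")
    labels = np.zeros(n_mc, dtype=bool)
    labels[order[:n_pos]] = True
    ranks = rankdata(age)
    p, nn = n_pos, n_mc - n_pos
    return float((ranks[labels].sum() - p * (p + 1) / 2) / (p * nn))


def mask_subset_features(
    cohort: CohortTable, feature_names: list[str], n_subjects_masked: int, seed: int
) -> CohortTable:
    """Set the named features to missing for a seeded random subset of
    exactly ``n_subjects_masked`` subjects (block missingness, e.g. a
    sub-cohort whose diffusion MRI was acquired years later)."""
    unknown = [f for f in feature_names if f not in cohort.feature_names]
    if unknown:
        raise ValueError(f"unknown features: {unknown}")
    if n_subjects_masked > cohort.n_subjects:
        raise ValueError(
            f"cannot mask {n_subjects_masked} of {cohort.n_subjects} subjects"
        )
    out = cohort.copy()
    if n_subjects_masked == 0 or not feature_names:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(cohort.n_subjects, size=n_subjects_masked, replace=False)
    out.data.iloc[rows, [out.data.columns.get_loc(f) for f in feature_names]] = np.nan
    return out
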