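"""Synthetic cohort generation calibrated to printed cohort marginals.

The generator is a pure function of (config, seed).  Every variable is
drawn through its own counter-based random stream (Philox keyed by seed
and variable name) via inverse-CDF transforms, so participant *i* always
consumes the *i*-th uniform of each stream: appending rows never perturbs
earlier rows, and row order never changes values.

Calibration notes
-----------------
* Truncated-normal covariates and neuropsych scores solve their location
  parameter numerically so the *truncated* mean equals the configured
  target (plain truncation would bias means by up to ~0.6 units).
* Weekly food-group intakes are Gamma(shape, scale) with the scale solved
  per component so the expected component score matches its target mean.
* The outcome intercept is solved by root finding so the marginal outcome
  prevalence matches the configured target.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit

from .analysis import assign_score_groups
from .scoring import ScoringRuleSet, load_scoring_table

__all__ = [
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "generate_covariates",
    "generate_intakes",
    "score_cohort",
    "assign_outcome",
    "generate_neuropsych",
    "inject_missingness",
    "solve_intercept",
]

GROUP_PREFIX = "group:"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    """Validated generator configuration (see data/cohort_defaults.yaml)."""

    n: int
    covariates: Mapping
    intake_model: Mapping
    outcome_model: Mapping
    neuropsych_model: Mapping
    source_counts: Mapping = field(default_factory=dict)
    scoring_table: str = "MY-MINDD"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        cov = self.covariates
        for key in ("hypertension", "diabetes", "hyperlipidemia", "smoking",
                    "male", "malay", "depressive_symptoms", "dementia"):
            p = float(cov[key])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {key} must lie in [0, 1], got {p}")
        for key in ("age", "education_years", "bmi", "iadl"):
            if float(cov[key]["sd"]) <= 0:
                raise ValueError(f"{key} sd must be positive")
        prev = float(self.outcome_model["prevalence"])
        if not 0.0 < prev < 1.0:
            raise ValueError(f"outcome prevalence must lie in (0, 1), got {prev}")
        if float(self.intake_model["shape"]) <= 0:
            raise ValueError("intake gamma shape must be positive")
        for name, (mean_sd_pairs) in self.neuropsych_model.items():
            for grp in ("mci", "non_mci"):
                if float(mean_sd_pairs[grp][1]) < 0:
                    raise ValueError(f"neuropsych sd for {name}/{grp} must be >= 0")

    @classmethod
    def from_mapping(cls, doc: Mapping, **overrides) -> "CohortConfig":
        kwargs = dict(
            n=int(doc["n"]),
            covariates=doc["covariates"],
            intake_model=doc["intake_model"],
            outcome_model=doc["outcome_model"],
            neuropsych_model=doc["neuropsych_model"],
            source_counts=doc.get("source_counts", {}),
            scoring_table=doc.get("scoring_table", "MY-MINDD"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def default_config(**overrides) -> CohortConfig:
    """Packaged defaults mirroring the pooled-cohort marginals."""
    ref = resources.files("minddiet.data") / "cohort_defaults.yaml"
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return CohortConfig.from_mapping(doc, **overrides)


# ---------------------------------------------------------------------------
# random streams


def _stream_uniforms(seed: int, tag: str, n: int) -> np.ndarray:
    """First n uniforms of the (seed, tag) substream; prefix-stable in n."""
    key = zlib.crc32(tag.encode("utf-8"))
    bits = np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), key])))
    return bits.random(n)


# ---------------------------------------------------------------------------
# calibration solvers (cached: pure functions of their arguments)


@lru_cache(maxsize=512)
def _solve_truncnorm_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location such that the [lo, hi]-truncated N(loc, sd) has mean target."""
    if sd == 0:
        return target
    if not lo < target < hi:
        raise ValueError(f"target mean {target} outside truncation bounds ({lo}, {hi})")

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    return float(optimize.brentq(gap, target - 20 * sd, target + 20 * sd, xtol=1e-9))


def _truncnorm_ppf(u: np.ndarray, loc, sd, lo: float, hi: float) -> np.ndarray:
    loc = np.asarray(loc, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = np.clip(loc, lo, hi).astype(float)
    pos = sd > 0
    if np.any(pos):
        a = (lo - loc) / np.where(pos, sd, 1.0)
        b = (hi - loc) / np.where(pos, sd, 1.0)
        drawn = stats.truncnorm.ppf(u, a, b, loc=loc, scale=np.where(pos, sd, 1.0))
        out = np.where(pos, drawn, out)
    return out


def _expected_score(bands, shape: float, scale: float) -> float:
    e = 0.0
    for band in bands:
        p = stats.gamma.cdf(band.upper, shape, scale=scale) - stats.gamma.cdf(
            band.lower, shape, scale=scale
        )
        e += band.points * p
    return e


@lru_cache(maxsize=512)
def _solve_gamma_scale(bands, shape: float, target: float) -> float:
    """Gamma scale such that E[band points of Gamma(shape, scale)] = target."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"score target must lie in (0, 1), got {target}")

    def gap(log_scale: float) -> float:
        return _expected_score(bands, shape, math.exp(log_scale)) - target

    lo, hi = -10.0, 10.0
    if gap(lo) * gap(hi) > 0:
        raise ValueError(f"score target {target} not attainable for these bands")
    return math.exp(optimize.brentq(gap, lo, hi, xtol=1e-10))


@lru_cache(maxsize=64)
def _solve_poisson_lambda(cutoff: int, prevalence: float) -> float:
    """Poisson rate such that P(X >= cutoff) = prevalence."""
    if prevalence <= 0:
        return 0.0

    def gap(lam: float) -> float:
        return stats.poisson.sf(cutoff - 1, lam) - prevalence

    return float(optimize.brentq(gap, 1e-9, 60.0, xtol=1e-10))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean/sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


# ---------------------------------------------------------------------------
# generation stages


def generate_covariates(cfg: CohortConfig, seed: int, n: Optional[int] = None) -> pd.DataFrame:
    """Draw the covariate block (no diet, outcome, or neuropsych columns)."""
    n = cfg.n if n is None else int(n)
    cov = cfg.covariates

    def uniforms(tag: str) -> np.ndarray:
        return _stream_uniforms(seed, tag, n)

    df = pd.DataFrame({"id": np.arange(1, n + 1, dtype=int)})

    for name in ("age", "education_years", "bmi", "iadl"):
        spec = cov[name]
        lo = float(spec.get("min", -math.inf))
        hi = float(spec.get("max", math.inf))
        loc = _solve_truncnorm_loc(float(spec["mean"]), float(spec["sd"]), lo, hi)
        df[name] = _truncnorm_ppf(uniforms(name), loc, float(spec["sd"]), lo, hi)

    mu, sigma = _lognormal_params(
        float(cov["household_income"]["mean"]), float(cov["household_income"]["sd"])
    )
    df["household_income"] = stats.lognorm.ppf(
        uniforms("household_income"), sigma, scale=math.exp(mu)
    )

    df["sex"] = np.where(uniforms("sex") < float(cov["male"]), "male", "female")
    df["ethnicity"] = np.where(uniforms("ethnicity") < float(cov["malay"]), "malay", "non_malay")
    for name in ("hypertension", "diabetes", "hyperlipidemia", "smoking", "dementia"):
        df[name] = (uniforms(name) < float(cov[name])).astype(int)

    lam = _solve_poisson_lambda(int(cov["gds_cutoff"]), float(cov["depressive_symptoms"]))
    gds = stats.poisson.ppf(uniforms("gds15"), lam) if lam > 0 else np.zeros(n)
    df["gds15"] = np.minimum(gds, 15).astype(int)
    df["depressive_symptoms"] = (df["gds15"] >= int(cov["gds_cutoff"])).astype(int)
    return df


def generate_intakes(
    cfg: CohortConfig, seed: int, n: Optional[int] = None, rules: Optional[ScoringRuleSet] = None
) -> pd.DataFrame:
    """Draw weekly food-group intakes (columns <id>_amount / <id>_unit)."""
    n = cfg.n if n is None else int(n)
    rules = rules or load_scoring_table(cfg.scoring_table)
    shape = float(cfg.intake_model["shape"])
    targets = cfg.intake_model["score_targets"]
    out = {}
    for rule in rules.components:
        if rule.component_id not in targets:
            raise ValueError(f"no intake score target for component {rule.component_id!r}")
        scale = _solve_gamma_scale(tuple(rule.bands), shape, float(targets[rule.component_id]))
        u = _stream_uniforms(seed, f"intake:{rule.component_id}", n)
        out[f"{rule.component_id}_amount"] = stats.gamma.ppf(u, shape, scale=scale)
        out[f"{rule.component_id}_unit"] = np.repeat("per_week", n)
    return pd.DataFrame(out)


def score_cohort(df: pd.DataFrame, rules: ScoringRuleSet) -> pd.DataFrame:
    """Append per-component score columns and the diet_total column."""
    df = df.copy()
    total = np.zeros(len(df))
    unit_factor = {"per_day": 7.0, "per_week": 1.0, "per_month": 1.0 / 4.348}
    for rule in rules.components:
        if rule.input_kind == "categorical":
            col = df[f"{rule.component_id}_category"].astype(str)
            pts = col.map(rule.categories).to_numpy(dtype=float)
        else:
            amounts = df[f"{rule.component_id}_amount"].to_numpy(dtype=float)
            units = df[f"{rule.component_id}_unit"].map(unit_factor).to_numpy(dtype=float)
            pts = rule.score_array(amounts * units)
        df[f"score_{rule.component_id}"] = pts
        total = total + pts
    df["diet_total"] = total
    return df


def solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept a such that mean(expit(a + lp)) == prevalence (to 1e-6)."""
    lp = np.asarray(lp, dtype=float)

    def gap(a: float) -> float:
        return float(np.mean(expit(a + lp))) - prevalence

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"target prevalence {prevalence} unattainable for this linear predictor")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-6))


def _linear_predictor(df: pd.DataFrame, odds_ratios: Mapping) -> np.ndarray:
    lp = np.zeros(len(df))
    for term, oratio in odds_ratios.items():
        beta = math.log(float(oratio))
        if beta == 0.0:
            continue
        if term.startswith(GROUP_PREFIX):
            x = (df["score_group"] == term[len(GROUP_PREFIX):]).to_numpy(dtype=float)
        else:
            x = df[term].to_numpy(dtype=float)
        lp += beta * x
    return lp


def assign_outcome(df: pd.DataFrame, cfg: CohortConfig, seed: int) -> pd.DataFrame:
    """Assign score groups, solve the intercept, and draw the true outcome."""
    df = df.copy()
    model = cfg.outcome_model
    k = int(model.get("k_groups", 4))
    assignment = assign_score_groups(df["diet_total"].to_numpy(), k=k)
    df["score_group"] = assignment.labels
    lp = _linear_predictor(df, model["odds_ratios"])
    intercept = solve_intercept(lp, float(model["prevalence"]))
    p = expit(intercept + lp)
    u = _stream_uniforms(seed, "outcome", len(df))
    df["true_mci"] = (u < p).astype(int)
    df.attrs["outcome_intercept"] = intercept
    return df


def generate_neuropsych(df: pd.DataFrame, cfg: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw status-conditional neuropsych scores, truncated at bounds."""
    df = df.copy()
    status = df["true_mci"].to_numpy(dtype=int)
    for name, spec in cfg.neuropsych_model.items():
        lo = float(spec.get("min", -math.inf))
        hi = float(spec.get("max", math.inf))
        locs, sds = [], []
        for grp in ("non_mci", "mci"):
            mean, sd = (float(v) for v in spec[grp])
            locs.append(_solve_truncnorm_loc(mean, sd, lo, hi) if sd > 0 else mean)
            sds.append(sd)
        loc = np.where(status == 1, locs[1], locs[0])
        sd = np.where(status == 1, sds[1], sds[0])
        u = _stream_uniforms(seed, f"neuro:{name}", len(df))
        df[name] = _truncnorm_ppf(u, loc, sd, lo, hi)
    comp = cfg.covariates.get("memory_complaint", {})
    p = np.where(status == 1, float(comp.get("mci", 0.9)), float(comp.get("non_mci", 0.3)))
    u = _stream_uniforms(seed, "memory_complaint", len(df))
    df["memory_complaint"] = (u < p).astype(int)
    return df


def inject_missingness(
    df: pd.DataFrame, rate: float, variables: Sequence[str], seed: int
) -> pd.DataFrame:
    """Independently blank each selected cell with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missingness rate must lie in [0, 1), got {rate}")
    df = df.copy()
    if rate == 0.0:
        return df
    for var in variables:
        if var not in df.columns:
            raise KeyError(f"no such column: {var}")
        mask = _stream_uniforms(seed, f"missing:{var}", len(df)) < rate
        col = df[var].astype(object) if df[var].dtype.kind in "biu" else df[var]
        df[var] = col.mask(mask)
    return df


def generate_cohort(cfg: Optional[CohortConfig] = None, seed: int = 0,
                    n: Optional[int] = None) -> pd.DataFrame:
    """Full pipeline: covariates -> intakes -> scores -> outcome -> neuropsych."""
    cfg = cfg or default_config()
    rules = load_scoring_table(cfg.scoring_table)
    df = generate_covariates(cfg, seed, n=n)
    df = pd.concat([df, generate_intakes(cfg, seed, n=n, rules=rules)], axis=1)
    df = score_cohort(df, rules)
    df = assign_outcome(df, cfg, seed)
    df = generate_neuropsych(df, cfg, seed)
    return df
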