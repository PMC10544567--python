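"""Monte-Carlo verification of pooled-testing designs.

Simulates two-stage screening campaigns end to end: draw a batch of
true concentrations at a stated qualification rate, pool them, apply a
noisy (optionally LOQ-censored) pooled measurement, judge each pool
against the guard-banded limit, and individually retest flagged pools.
The empirical tests-per-sample converges to the closed form
``(1 - q^K) + 1/K`` when noise and censoring are off, and the
false-negative rate is identically zero there because the worst-case
attribution W_max can only over-state a member's concentration.

Concentration model
-------------------
Regulated plasticizers are intentional additives: a non-conforming
article carries percent-level concentrations (defaults 10 000 to
300 000 mg/kg, i.e. 1-30 % w/w), while conforming articles carry
essentially none. Qualified samples therefore default to exactly zero,
with an optional mixture fraction of low-level contamination
(50-100 mg/kg by default) to probe the known failure mode where many
individually-conforming low-concentration members push the pooled
worst-case bound over the corrected limit.

Measurement noise is multiplicative: c_meas = c_true * (1 + eps) with
eps ~ Normal(0, u_rel/100) (or lognormal with matching relative SD),
clipped so concentrations stay nonnegative. LOQ censoring zeroes any
pooled measurement whose implied mass-weighted mean sample
concentration falls below the method LOQ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import RegulationLimit, expected_tests_per_sample
from .evaluation import PoolMeasurement, SubSample, corrected_limit

__all__ = [
    "ConcentrationModel",
    "NoiseModel",
    "CampaignConfig",
    "CampaignResult",
    "draw_concentrations",
    "generate_batch",
    "simulate_pool_measurement",
    "run_campaign",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcentrationModel:
    """Distribution of true concentrations in a batch (single analyte).

    A sample is non-conforming with probability 1 - q and then draws
    uniformly from ``exceed_range``; otherwise it is zero, except for a
    ``low_level_fraction`` of conforming samples drawing uniformly from
    ``low_level_range``. All concentrations in mg/kg.
    """

    exceed_range: tuple[float, float] = (10_000.0, 300_000.0)
    low_level_fraction: float = 0.0
    low_level_range: tuple[float, float] = (50.0, 100.0)

    def __post_init__(self) -> None:
        if not 0 < self.exceed_range[0] <= self.exceed_range[1]:
            raise ValueError(f"invalid exceed_range {self.exceed_range}")
        if not 0 <= self.low_level_fraction <= 1:
            raise ValueError(
                f"low_level_fraction must be in [0, 1], got {self.low_level_fraction}"
            )
        if not 0 <= self.low_level_range[0] <= self.low_level_range[1]:
            raise ValueError(f"invalid low_level_range {self.low_level_range}")


@dataclass(frozen=True)
class NoiseModel:
    """Relative measurement noise on pooled solution concentrations.

    ``u_rel`` is the relative standard deviation in percent — the
    *standard* (not expanded) uncertainty, i.e. U_rel / k. ``family``
    is "normal" (relative error clipped at -1 so c >= 0) or
    "lognormal" (matched relative SD, always positive).
    """

    u_rel: float = 0.0
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.u_rel < 0:
            raise ValueError(f"u_rel must be >= 0, got {self.u_rel}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise family {self.family!r}")

    def apply(self, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.u_rel == 0:
            return c
        sd = self.u_rel / 100.0
        if self.family == "normal":
            eps = rng.normal(0.0, sd, size=c.shape)
            return c * np.clip(1.0 + eps, 0.0, None)
        sigma2 = math.log(1.0 + sd**2)
        factors = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=c.shape)
        return c * factors


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to simulate a screening campaign.

    n : batch size; k : group size (n >= k >= 2).
    q : qualification rate, fraction.
    limit : the regulated limit judged against.
    u_rel_guard : relative expanded uncertainty (%) used for the
        corrected limit L_cor.
    loq : method LOQ in mg/kg, or None to disable censoring.
    nominal_mass : sub-sample mass in g (equal masses by default).
    mass_tolerance : if > 0, masses draw uniformly within
        nominal * (1 +/- tolerance), emulating weighing scatter.
    volume_per_gram : extract volume per gram of pooled sample, mL/g.
    remainder : "individual" tests the n mod k leftover samples one by
        one; "short_pool" pools them as a smaller final group.
    noisy_retest : when True, stage-2 individual tests also carry noise
        (and can therefore mis-classify); by default they are
        definitive.
    """

    n: int
    q: float
    k: int
    limit: RegulationLimit
    u_rel_guard: float = 0.0
    loq: float | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    conc: ConcentrationModel = field(default_factory=ConcentrationModel)
    nominal_mass: float = 0.1
    mass_tolerance: float = 0.0
    volume_per_gram: float = 25.0
    dilution: float = 1.0
    remainder: str = "individual"
    noisy_retest: bool = False
    reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"group size k must be >= 2, got {self.k}")
        if self.n < self.k:
            raise ValueError(f"batch size n={self.n} smaller than group size k={self.k}")
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.remainder not in ("individual", "short_pool"):
            raise ValueError(f"unknown remainder policy {self.remainder!r}")
        if self.conc.exceed_range[0] <= self.limit.limit:
            raise ValueError(
                f"exceed_range lower bound {self.conc.exceed_range[0]} must lie "
                f"above the limit {self.limit.limit} mg/kg"
            )


@dataclass
class CampaignResult:
    """Aggregated outcome of a simulated campaign (means over reps)."""

    tests_per_sample: float
    s_empirical: float
    false_positive_rate: float
    false_negative_rate: float
    total_tests: float
    tests_per_sample_ci: float
    false_positive_ci: float
    false_negative_ci: float
    reps: int
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "tests_per_sample": self.tests_per_sample,
            "s_empirical": self.s_empirical,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "total_tests": self.total_tests,
            "tests_per_sample_ci": self.tests_per_sample_ci,
            "false_positive_ci": self.false_positive_ci,
            "false_negative_ci": self.false_negative_ci,
            "reps": self.reps,
            "n": self.n,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d) -> "CampaignResult":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


# --------------------------------------------------------------------------
# batch generation


def draw_concentrations(
    n: int,
    q: float,
    model: ConcentrationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """True concentrations (mg/kg) for a batch of n samples."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    conc = np.zeros(n)
    bad = rng.random(n) >= q
    n_bad = int(bad.sum())
    if n_bad:
        conc[bad] = rng.uniform(*model.exceed_range, size=n_bad)
    if model.low_level_fraction > 0:
        good = ~bad
        low = good & (rng.random(n) < model.low_level_fraction)
        n_low = int(low.sum())
        if n_low:
            conc[low] = rng.uniform(*model.low_level_range, size=n_low)
    return conc


def generate_batch(
    n: int,
    q: float,
    model: ConcentrationModel | None = None,
    seed: int | np.random.Generator | None = None,
    analyte: str = "analyte",
    nominal_mass: float = 0.1,
) -> list[SubSample]:
    """Synthetic batch as :class:`SubSample` objects with known truth.

    Reproducible under a fixed seed. Sample i is non-conforming with
    probability 1 - q.
    """
    model = model or ConcentrationModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = draw_concentrations(n, q, model, rng)
    return [
        SubSample(id=f"s{i:06d}", mass=nominal_mass, true_conc={analyte: float(c)})
        for i, c in enumerate(conc)
    ]


def simulate_pool_measurement(
    pool: Sequence[SubSample],
    noise: NoiseModel | None = None,
    loq: float | None = None,
    seed: int | np.random.Generator | None = None,
    volume_per_gram: float = 25.0,
    dilution: float = 1.0,
) -> PoolMeasurement:
    """Simulated measurement of one pooled extract.

    The ideal solution concentration is the pooled analyte mass over
    the (diluted) extract volume, c* = sum_i(m_i w_i) / (V D); noise
    multiplies it, and LOQ censoring zeroes analytes whose implied
    mass-weighted mean sample concentration c V D / m_total is below
    ``loq``.
    """
    if not pool:
        raise ValueError("empty pool")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_total = sum(s.mass for s in pool)
    volume = volume_per_gram * m_total
    names: list[str] = []
    for s in pool:
        if s.true_conc is None:
            raise ValueError(f"sub-sample {s.id!r} has no true concentrations")
        for name in s.true_conc:
            if name not in names:
                names.append(name)
    out: dict[str, float] = {}
    for name in names:
        ideal = sum(s.mass * s.true_conc.get(name, 0.0) for s in pool) / (
            volume * dilution
        )
        measured = float(noise.apply(np.asarray([ideal]), rng)[0])
        if loq is not None and measured * volume * dilution / m_total < loq:
            measured = 0.0
        out[name] = measured
    return PoolMeasurement(concentrations=out, volume=volume, dilution=dilution)


# --------------------------------------------------------------------------
# campaign


def _simulate_rep(config: CampaignConfig, rng: np.random.Generator):
    """One campaign repetition; fully vectorized over pools."""
    n, k = config.n, config.k
    conc = draw_concentrations(n, config.q, config.conc, rng)
    n_pools = n // k
    rem = n % k
    pooled = conc[: n_pools * k].reshape(n_pools, k)

    if config.mass_tolerance > 0:
        masses = rng.uniform(
            config.nominal_mass * (1 - config.mass_tolerance),
            config.nominal_mass * (1 + config.mass_tolerance),
            size=(n_pools, k),
        )
    else:
        masses = np.full((n_pools, k), config.nominal_mass)

    m_total = masses.sum(axis=1)
    m_min = masses.min(axis=1)
    volume = config.volume_per_gram * m_total
    c_ideal = (masses * pooled).sum(axis=1) / (volume * config.dilution)
    c_meas = config.noise.apply(c_ideal, rng)
    if config.loq is not None:
        implied_mean = c_meas * volume * config.dilution / m_total
        c_meas = np.where(implied_mean < config.loq, 0.0, c_meas)

    w_max = c_meas * volume * config.dilution / m_min
    l_cor = corrected_limit(
        config.limit.limit, config.u_rel_guard, config.limit.n_substances
    )
    flagged = w_max > l_cor
    truly_bad = pooled > config.limit.limit
    bad_pool = truly_bad.any(axis=1)

    # stage-2 individual tests on flagged pools
    if config.noisy_retest:
        retested = config.noise.apply(pooled[flagged].ravel(), rng)
        retest_bad = (retested > config.limit.limit).reshape(-1, k)
        missed_in_flagged = (truly_bad[flagged] & ~retest_bad).sum()
    else:
        missed_in_flagged = 0

    tests = n_pools + int(flagged.sum()) * k
    # cleared pools that actually contained a non-conforming sample
    fn_count = int(truly_bad[~flagged].sum()) + int(missed_in_flagged)

    # remainder samples
    rem_tests = 0
    if rem:
        rem_conc = conc[n_pools * k:]
        if config.remainder == "individual":
            rem_tests = rem
        else:  # short pool of size rem (>= 1)
            rem_masses = np.full(rem, config.nominal_mass)
            rem_volume = config.volume_per_gram * rem_masses.sum()
            c_id = (rem_masses * rem_conc).sum() / (rem_volume * config.dilution)
            c_m = float(config.noise.apply(np.asarray([c_id]), rng)[0])
            if (
                config.loq is not None
                and c_m * rem_volume * config.dilution / rem_masses.sum() < config.loq
            ):
                c_m = 0.0
            w = c_m * rem_volume * config.dilution / rem_masses.min()
            rem_flagged = w > l_cor
            rem_tests = 1 + (rem if rem_flagged else 0)
            if not rem_flagged:
                fn_count += int((rem_conc > config.limit.limit).sum())
    tests += rem_tests

    n_bad_samples = int(truly_bad.sum()) + int(
        (conc[n_pools * k:] > config.limit.limit).sum() if rem else 0
    )
    n_clean_pools = int((~bad_pool).sum())
    fp_pools = int((flagged & ~bad_pool).sum())

    return (
        tests / n,
        fp_pools / n_clean_pools if n_clean_pools else 0.0,
        fn_count / n_bad_samples if n_bad_samples else 0.0,
        tests,
    )


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Simulate ``config.reps`` independent campaigns and aggregate.

    Monte-Carlo uncertainty is reported as 1.96 * SD / sqrt(reps)
    (normal-approximation 95 % CI half-width over repetitions).
    Identical config (including seed) reproduces identical results.
    """
    rng = np.random.default_rng(config.seed)
    tps, fps, fns, totals = [], [], [], []
    for _ in range(config.reps):
        t, fp, fn, total = _simulate_rep(config, rng)
        tps.append(t)
        fps.append(fp)
        fns.append(fn)
        totals.append(total)
    tps_a, fps_a, fns_a = np.asarray(tps), np.asarray(fps), np.asarray(fns)

    def half_width(x: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(1.96 * x.std(ddof=1) / math.sqrt(len(x)))

    result = CampaignResult(
        tests_per_sample=float(tps_a.mean()),
        s_empirical=float(1.0 - tps_a.mean()),
        false_positive_rate=float(fps_a.mean()),
        false_negative_rate=float(fns_a.mean()),
        total_tests=float(np.mean(totals)),
        tests_per_sample_ci=half_width(tps_a),
        false_positive_ci=half_width(fps_a),
        false_negative_ci=half_width(fns_a),
        reps=config.reps,
        n=config.n,
        k=config.k,
    )
    logger.info(
        "campaign: q=%.3f K=%d -> tests/sample %.4f (analytic %.4f), FP %.4g, FN %.4g",
        config.q,
        config.k,
        result.tests_per_sample,
        expected_tests_per_sample(config.q, config.k),
        result.false_positive_rate,
        result.false_negative_rate,
    )
    return result
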