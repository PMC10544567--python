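"""Pool-size design for quantitative two-stage (Dorfman) composite testing.

A batch of samples with an expected qualification rate ``q`` is screened
in pools of ``K``: one quantitative test per pool, and ``K`` individual
confirmation tests whenever the pool cannot be cleared. Three group
sizes govern the design:

``K_opt``
    The group size minimizing the expected number of tests per sample,

        N/n = (1 - q^K) + 1/K,

    equivalently maximizing the saved workload ``S = q^K - 1/K``.
``K_max``
    The largest group size at which the dilution inherent in pooling
    still leaves the method sensitive enough to detect a limit-level
    contaminant:

        K_max = floor( L * (1 - U_rel/100) * F / (Q_M * I) )

    with ``L`` the regulated limit (mg/kg), ``U_rel`` the relative
    expanded measurement uncertainty (%), ``Q_M`` the method limit of
    quantification (mg/kg), ``I`` the number of substances summed in
    the limit and ``F`` an empirical safety factor. ``K_max <= 1``
    means pooling cannot be applied at all.
``K_a``
    The group size actually used: ``min(K_opt, K_max)``, additionally
    capped (by default at 10) for practical handling reasons.

Pooling only pays off when the qualification rate is high: below
q = 0.70 the expected tests per sample exceed 1 for every K, so the
planner refuses to pool there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import check_positive, round_half_up

__all__ = [
    "AnalyteSpec",
    "RegulationLimit",
    "DesignParams",
    "PoolPlan",
    "expected_tests_per_sample",
    "savings",
    "find_k_opt",
    "compute_loq_from_idl",
    "compute_k_max",
    "choose_k_a",
    "generate_reference_table",
    "column_minima",
    "plan_composite_test",
    "MIN_QUALIFICATION_RATE",
]

logger = logging.getLogger(__name__)

#: Below this qualification rate pooling costs more tests than it saves.
MIN_QUALIFICATION_RATE = 0.70

# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AnalyteSpec:
    """Per-substance method characteristics.

    Parameters
    ----------
    name
        Substance identifier (e.g. ``"DEHP"``).
    loq
        Method limit of quantification Q_M, mg/kg. May be ``None`` if
        ``idl`` is given, in which case it is derived from the
        instrument detection limit at planning time.
    expanded_uncertainty
        Relative expanded uncertainty U_rel, %.
    idl
        Instrument detection limit Q_I, mg/L (optional).
    """

    name: str
    loq: float | None = None
    expanded_uncertainty: float | None = None
    idl: float | None = None

    def __post_init__(self) -> None:
        if self.loq is not None:
            check_positive(self.loq, f"{self.name}: loq")
        if self.idl is not None:
            check_positive(self.idl, f"{self.name}: idl")
        if self.expanded_uncertainty is not None:
            u = float(self.expanded_uncertainty)
            if not 0 <= u < 100:
                raise ValueError(
                    f"{self.name}: expanded_uncertainty must be in [0, 100)%, got {u}"
                )

    def resolve_loq(self, volume: float | None, min_mass: float | None) -> float:
        """Q_M in mg/kg, derived from the IDL when not given directly."""
        if self.loq is not None:
            return self.loq
        if self.idl is not None and volume is not None and min_mass is not None:
            return compute_loq_from_idl(self.idl, volume, min_mass)
        raise ValueError(
            f"analyte {self.name!r}: no LOQ and insufficient data to derive one "
            "(need idl plus extract volume and minimum mass)"
        )


@dataclass(frozen=True)
class RegulationLimit:
    """A regulated concentration limit, possibly over a sum of substances.

    ``limit`` is canonically in mg/kg (0.1 % w/w == 1000 mg/kg).
    ``n_substances`` is I, the number of substances whose summed
    concentration the limit constrains (1 for a per-substance limit).
    """

    limit: float
    n_substances: int = 1
    analytes: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        check_positive(self.limit, "limit")
        if self.n_substances < 1:
            raise ValueError(f"n_substances must be >= 1, got {self.n_substances}")
        if self.analytes and self.n_substances > 1 and len(self.analytes) != self.n_substances:
            raise ValueError(
                f"limit sums {self.n_substances} substances but lists "
                f"{len(self.analytes)} analytes"
            )

    @classmethod
    def from_percent(
        cls,
        percent: float,
        n_substances: int = 1,
        analytes: Sequence[str] = (),
        label: str = "",
    ) -> "RegulationLimit":
        """Build from a %-w/w limit (0.1 % -> 1000 mg/kg)."""
        return cls(
            limit=float(percent) * 10_000.0,
            n_substances=n_substances,
            analytes=tuple(analytes),
            label=label,
        )


@dataclass(frozen=True)
class DesignParams:
    """Planner inputs beyond the limit and analyte specs.

    q : expected qualification rate, fraction in (0, 1].
    safety_factor : F, tightens the sensitivity budget for
        inter-laboratory variability; 0.8 by default.
    k_cap : practical upper bound on the group size (handling,
        homogenization); 10 by default.
    extract_volume / min_mass : final extract volume (mL) and minimum
        sub-sample mass (g), used only to derive missing LOQs from
        instrument detection limits.
    k_search : inclusive search range for K_opt.
    """

    q: float
    safety_factor: float = 0.8
    k_cap: int = 10
    extract_volume: float | None = None
    min_mass: float | None = None
    k_search: tuple[int, int] = (2, 100)

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if not 0 < self.safety_factor <= 1:
            raise ValueError(f"safety_factor must be in (0, 1], got {self.safety_factor}")
        if self.k_cap < 2:
            raise ValueError(f"k_cap must be >= 2, got {self.k_cap}")


@dataclass
class PoolPlan:
    """Result of planning a composite-testing campaign."""

    applicable: bool
    k_opt: int | None = None
    k_max: int | None = None
    k_a: int | None = None
    tests_per_sample: float | None = None
    savings: float | None = None
    u_rel_max: float | None = None
    loq_max: float | None = None
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "k_opt": self.k_opt,
            "k_max": self.k_max,
            "k_a": self.k_a,
            "tests_per_sample": self.tests_per_sample,
            "savings": self.savings,
            "u_rel_max": self.u_rel_max,
            "loq_max": self.loq_max,
            "reasons": list(self.reasons),
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PoolPlan":
        return cls(
            applicable=d["applicable"],
            k_opt=d.get("k_opt"),
            k_max=d.get("k_max"),
            k_a=d.get("k_a"),
            tests_per_sample=d.get("tests_per_sample"),
            savings=d.get("savings"),
            u_rel_max=d.get("u_rel_max"),
            loq_max=d.get("loq_max"),
            reasons=list(d.get("reasons", [])),
            warnings=list(d.get("warnings", [])),
        )


# --------------------------------------------------------------------------
# workload formulas


def _check_q(q: float) -> float:
    q = float(q)
    if not 0 < q <= 1:
        raise ValueError(f"qualification rate q must be in (0, 1], got {q}")
    return q


def _check_k(k: int) -> int:
    if isinstance(k, bool) or int(k) != k:
        raise ValueError(f"group size K must be an integer, got {k!r}")
    k = int(k)
    if k < 2:
        raise ValueError(
            f"group size K must be >= 2 (K=1 is individual testing), got {k}"
        )
    return k


def expected_tests_per_sample(q: float, k: int) -> float:
    """Expected number of tests per sample, N/n = (1 - q^K) + 1/K.

    One pooled test clears all K members with probability q^K;
    otherwise the pool test is followed by K individual tests.
    """
    q = _check_q(q)
    k = _check_k(k)
    return (1.0 - q**k) + 1.0 / k


def savings(q: float, k: int) -> float:
    """Saved workload fraction S = q^K - 1/K = 1 - N/n.

    Negative values mean pooling costs more tests than individual
    testing at this (q, K).
    """
    q = _check_q(q)
    k = _check_k(k)
    return q**k - 1.0 / k


def find_k_opt(q: float, k_range: tuple[int, int] = (2, 100)) -> int | None:
    """Group size minimizing the expected tests per sample.

    Exhaustive search over the inclusive integer range; ties break
    toward the smaller K (fewer samples at risk per retest round).
    Returns ``None`` when even the best K needs >= 1 test per sample,
    i.e. pooling never saves work at this qualification rate.
    """
    q = _check_q(q)
    lo, hi = int(k_range[0]), int(k_range[1])
    lo = max(lo, 2)
    if hi < lo:
        raise ValueError(f"empty K search range {k_range}")
    ks = np.arange(lo, hi + 1)
    values = (1.0 - q ** ks.astype(float)) + 1.0 / ks
    best = int(ks[np.argmin(values)])  # argmin returns the first (smallest K) tie
    if values.min() >= 1.0:
        return None
    return best


# --------------------------------------------------------------------------
# sensitivity constraint


def compute_loq_from_idl(idl: float, volume: float, min_mass: float) -> float:
    """Method LOQ (mg/kg) implied by an instrument detection limit.

    Q_M = Q_I * V / m_min, with Q_I in mg/L, V the final extract volume
    in mL and m_min the minimum sub-sample mass in g.
    """
    check_positive(idl, "idl")
    check_positive(volume, "volume")
    check_positive(min_mass, "min_mass")
    return idl * volume / min_mass


def compute_k_max(
    limit: float,
    u_rel_max: float,
    loq_max: float,
    n_substances: int = 1,
    safety_factor: float = 0.8,
) -> int | None:
    """Maximum allowable group size from the sensitivity budget.

    K_max = floor( L * (1 - U_rel/100) * F / (Q_M * I) ).

    Returns ``None`` (pooling not applicable) when the floor is <= 1:
    even an unpooled measurement then has no sensitivity headroom for
    dilution.

    Parameters
    ----------
    limit : regulated limit L, mg/kg.
    u_rel_max : worst-case relative expanded uncertainty over the
        substances covered by the limit, %.
    loq_max : worst-case method LOQ over those substances, mg/kg.
    n_substances : I, number of substances the limit sums.
    safety_factor : F in (0, 1].
    """
    check_positive(limit, "limit")
    check_positive(loq_max, "loq_max")
    if not 0 <= u_rel_max < 100:
        raise ValueError(f"u_rel_max must be in [0, 100)%, got {u_rel_max}")
    if n_substances < 1:
        raise ValueError(f"n_substances must be >= 1, got {n_substances}")
    if not 0 < safety_factor <= 1:
        raise ValueError(f"safety_factor must be in (0, 1], got {safety_factor}")
    raw = limit * (1.0 - u_rel_max / 100.0) * safety_factor / (loq_max * n_substances)
    # tiny epsilon so exact-integer ratios are not floored down by float error
    k_max = math.floor(raw + 1e-9)
    if k_max <= 1:
        return None
    return k_max


def choose_k_a(
    k_opt: int | None,
    k_max: int | None,
    k_cap: int = 10,
    k_max_applicable: bool = True,
) -> int | None:
    """Final group size: min(K_opt, K_max, cap); ``None`` means test individually.

    ``k_max_applicable=False`` forces the individual-testing
    recommendation regardless of the other inputs (the sensitivity
    gate failed).
    """
    if not k_max_applicable:
        return None
    if k_opt is None and k_max is None:
        raise ValueError("at least one of k_opt and k_max must be provided")
    candidates = [v for v in (k_opt, k_max, k_cap) if v is not None]
    k_a = min(candidates)
    if k_a < 2:
        return None
    return int(k_a)


# --------------------------------------------------------------------------
# quick-reference table


def generate_reference_table(
    q_values: Sequence[float] = (0.69, 0.70, 0.80, 0.90, 0.95, 0.99),
    k_values: Sequence[int] = tuple(range(2, 16)),
) -> pd.DataFrame:
    """Expected tests per sample for a grid of (K, q), rounded to 3 dp.

    Rows are group sizes K, columns qualification rates q. The cell
    value below 1.0 closest to 0 in each column marks the most
    efficient group size for that qualification rate (see
    :func:`column_minima`).
    """
    data = {
        q: [round_half_up(expected_tests_per_sample(q, k), 3) for k in k_values]
        for q in q_values
    }
    df = pd.DataFrame(data, index=list(k_values))
    df.index.name = "K"
    df.columns.name = "q"
    return df


def column_minima(table: pd.DataFrame) -> dict[float, list[int]]:
    """Group sizes attaining each column's minimum (ties all reported)."""
    out: dict[float, list[int]] = {}
    for q in table.columns:
        col = table[q]
        out[q] = [int(k) for k in col.index[col == col.min()]]
    return out


# --------------------------------------------------------------------------
# end-to-end planner


def plan_composite_test(
    analytes: Sequence[AnalyteSpec] | Mapping[str, AnalyteSpec],
    limit: RegulationLimit,
    params: DesignParams,
) -> PoolPlan:
    """Full planning pass: gate on q, size the pool, report the rationale.

    Steps
    -----
    1. Refuse pooling when ``q`` is below 0.70 (pooling then costs more
       tests than it saves for every K).
    2. Resolve the worst-case U_rel and LOQ over the substances covered
       by the limit (missing specs are an error listing the names).
    3. Compute K_max from the sensitivity budget; K_max <= 1 means
       individual testing.
    4. Compute K_opt from the workload formula and take
       K_a = min(K_opt, K_max, cap).

    Returns a :class:`PoolPlan` whose ``reasons`` narrate the decision
    path and whose ``warnings`` flag thin sensitivity margins.
    """
    if isinstance(analytes, Mapping):
        spec_by_name = dict(analytes)
    else:
        spec_by_name = {a.name: a for a in analytes}

    plan = PoolPlan(applicable=False)

    if params.q < MIN_QUALIFICATION_RATE:
        plan.reasons.append(
            f"qualification rate q={params.q:.2f} is below "
            f"{MIN_QUALIFICATION_RATE:.2f}: pooled testing needs more tests than "
            "individual testing for every group size; test individually"
        )
        logger.info("plan: refused, %s", plan.reasons[-1])
        return plan

    members = limit.analytes or tuple(spec_by_name)
    missing = [name for name in members if name not in spec_by_name]
    if missing:
        raise ValueError(f"missing analyte specs for: {', '.join(sorted(missing))}")

    u_values = []
    for name in members:
        spec = spec_by_name[name]
        if spec.expanded_uncertainty is None:
            raise ValueError(f"analyte {name!r} has no expanded uncertainty")
        u_values.append(spec.expanded_uncertainty)
    plan.u_rel_max = max(u_values)
    plan.loq_max = max(
        spec_by_name[name].resolve_loq(params.extract_volume, params.min_mass)
        for name in members
    )

    plan.k_max = compute_k_max(
        limit.limit,
        plan.u_rel_max,
        plan.loq_max,
        limit.n_substances,
        params.safety_factor,
    )
    if plan.k_max is None:
        plan.reasons.append(
            f"sensitivity gate failed: worst-case LOQ {plan.loq_max:g} mg/kg "
            f"leaves no dilution headroom under limit {limit.limit:g} mg/kg "
            f"(U_rel {plan.u_rel_max:g}%, I={limit.n_substances}, "
            f"F={params.safety_factor:g}); test individually"
        )
        logger.info("plan: refused, %s", plan.reasons[-1])
        return plan
    if plan.k_max <= 3:
        plan.warnings.append(
            f"K_max={plan.k_max} sits at the edge of applicability: the "
            "sensitivity margin is thin and conservative practice may prefer "
            "individual testing"
        )

    plan.k_opt = find_k_opt(params.q, params.k_search)
    plan.k_a = choose_k_a(plan.k_opt, plan.k_max, params.k_cap)
    if plan.k_a is None:
        plan.reasons.append("no group size >= 2 satisfies all constraints; test individually")
        logger.info("plan: refused, %s", plan.reasons[-1])
        return plan

    plan.applicable = True
    plan.tests_per_sample = expected_tests_per_sample(params.q, plan.k_a)
    plan.savings = savings(params.q, plan.k_a)
    plan.reasons.append(
        f"K_opt={plan.k_opt}, K_max={plan.k_max}, cap={params.k_cap} -> "
        f"K_a={plan.k_a}; expected {plan.tests_per_sample:.3f} tests/sample "
        f"({100 * plan.savings:.1f}% workload saved)"
    )
    logger.info("plan: %s", plan.reasons[-1])
    return plan
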