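"""Conformity evaluation of pooled quantitative measurements.

A pooled test cannot attribute analyte to a particular sub-sample, so
the verdict is built on a worst case: assume everything detected came
from the lightest sub-sample. The resulting upper bound

    W_max = c * V * D / m_min        (mg/kg)

(c the measured solution concentration in mg/L, V the extract volume in
mL, D the dilution ratio, m_min the minimum sub-sample mass in g) is
compared against the regulated limit shrunk by a measurement-uncertainty
guard band and shared across the I substances of a sum limit:

    L_cor = L * (1 - U_rel/100) / I  (mg/kg)

If every analyte's W_max <= L_cor the whole pool is cleared; otherwise
all members are retested individually. Because W_max is a guaranteed
upper bound on any member's true concentration, a noise-free pooled
test can never clear a non-conforming sample — the scheme errs only on
the side of unnecessary retests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._util import check_positive, round_half_up
from .design import AnalyteSpec, RegulationLimit

__all__ = [
    "SubSample",
    "PoolMeasurement",
    "Verdict",
    "validate_pool_masses",
    "compute_w_max",
    "corrected_limit",
    "judge_pool",
    "expected_pool_reference",
    "recovery_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubSample:
    """One weighed portion in a pool.

    ``true_conc`` (analyte -> mg/kg) is known only for spiked or
    simulated material and is used to compute reference values.
    """

    id: str
    mass: float
    true_conc: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        check_positive(self.mass, f"sub-sample {self.id!r}: mass")


@dataclass(frozen=True)
class PoolMeasurement:
    """Measured state of one pooled extract.

    concentrations : analyte -> solution concentration c, mg/L.
    volume : constant-volume of the extraction liquid V, mL.
    dilution : dilution ratio D (>= 1).
    """

    concentrations: Mapping[str, float]
    volume: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        check_positive(self.volume, "volume")
        if self.dilution < 1:
            raise ValueError(f"dilution must be >= 1, got {self.dilution}")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}: {c}")


@dataclass
class Verdict:
    """Outcome of judging one pool."""

    decision: str  # "pass" | "retest-individually"
    w_max: dict[str, float]
    l_cor: float
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.decision == "pass"

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "w_max": dict(self.w_max),
            "l_cor": self.l_cor,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Verdict":
        return cls(
            decision=d["decision"],
            w_max=dict(d["w_max"]),
            l_cor=d["l_cor"],
            warnings=list(d.get("warnings", [])),
        )


# --------------------------------------------------------------------------


def validate_pool_masses(
    subsamples: Sequence[SubSample],
    nominal: float = 0.1,
    tolerance: float = 0.10,
) -> list[str]:
    """Check sub-sample masses against nominal +/- tolerance.

    Routine practice weighs every portion to the same nominal mass
    (0.1 g) within a relative tolerance (10 %); unequal masses inflate
    the worst-case bound through m_min. Returns a list of violation
    messages (empty means all masses conform); an empty pool is an
    error.
    """
    if not subsamples:
        raise ValueError("empty pool")
    check_positive(nominal, "nominal")
    lo = nominal * (1.0 - tolerance)
    hi = nominal * (1.0 + tolerance)
    violations = []
    for s in subsamples:
        if not lo <= s.mass <= hi:
            violations.append(
                f"sub-sample {s.id!r}: mass {s.mass:g} g outside "
                f"[{lo:g}, {hi:g}] g ({nominal:g} g +/- {100 * tolerance:g}%)"
            )
    return violations


def compute_w_max(c: float, volume: float, dilution: float, min_mass: float) -> float:
    """Worst-case single-sub-sample concentration, mg/kg.

    W_max = c * V * D / m_min: all detected analyte attributed to the
    lightest portion.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    check_positive(volume, "volume")
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution}")
    check_positive(min_mass, "min_mass")
    return c * volume * dilution / min_mass


def corrected_limit(
    limit: float,
    u_rel: float,
    n_substances: int = 1,
    mode: str = "divide_total",
) -> float:
    """Guard-banded decision limit L_cor, mg/kg.

    The default reading divides the whole guard-banded limit by the
    number of summed substances, L_cor = L * (1 - U_rel/100) / I — the
    same placement of I as in the K_max sensitivity budget. The
    alternative reading L * (1 - U_rel/(100*I)) is available as
    ``mode="divide_uncertainty"``.
    """
    check_positive(limit, "limit")
    if not 0 <= u_rel < 100:
        raise ValueError(f"u_rel must be in [0, 100)%, got {u_rel}")
    if n_substances < 1:
        raise ValueError(f"n_substances must be >= 1, got {n_substances}")
    if mode == "divide_total":
        return limit * (1.0 - u_rel / 100.0) / n_substances
    if mode == "divide_uncertainty":
        return limit * (1.0 - u_rel / (100.0 * n_substances))
    raise ValueError(f"unknown mode {mode!r}")


def judge_pool(
    measurement: PoolMeasurement,
    subsamples: Sequence[SubSample],
    limit: RegulationLimit,
    specs: Sequence[AnalyteSpec] | Mapping[str, AnalyteSpec] = (),
    strict_sum: bool = False,
    mode: str = "divide_total",
) -> Verdict:
    """Pass/retest decision for one pool.

    m_min is the minimum mass among all sub-samples in the pool.
    Each member analyte's W_max is compared to L_cor (boundary
    inclusive: W_max == L_cor passes). With ``strict_sum=True`` the sum
    of the member analytes' W_max is additionally compared to the
    undivided guard-banded limit L * (1 - U_rel/100).

    A warning is attached when two or more analytes are quantifiable
    (W_max at or above the analyte LOQ) yet below L_cor: pools rich in
    low-concentration members can exceed L_cor in aggregate even when
    every member conforms individually, forcing unnecessary retests.
    """
    if not subsamples:
        raise ValueError("empty pool")
    if isinstance(specs, Mapping):
        spec_by_name = dict(specs)
    else:
        spec_by_name = {s.name: s for s in specs}

    members = limit.analytes or tuple(measurement.concentrations)
    m_min = min(s.mass for s in subsamples)

    u_values = [
        spec_by_name[name].expanded_uncertainty
        for name in members
        if name in spec_by_name and spec_by_name[name].expanded_uncertainty is not None
    ]
    u_rel_max = max(u_values) if u_values else 0.0
    l_cor = corrected_limit(limit.limit, u_rel_max, limit.n_substances, mode)

    w_max = {
        name: compute_w_max(
            measurement.concentrations.get(name, 0.0),
            measurement.volume,
            measurement.dilution,
            m_min,
        )
        for name in members
    }

    failed = [name for name, w in w_max.items() if w > l_cor]
    warnings: list[str] = []

    low_level = [
        name
        for name, w in w_max.items()
        if name in spec_by_name
        and spec_by_name[name].loq is not None
        and spec_by_name[name].loq <= w <= l_cor
    ]
    if len(low_level) >= 2:
        warnings.append(
            "several analytes quantifiable below the corrected limit "
            f"({', '.join(low_level)}): pools with many low-concentration "
            "members inflate the worst-case bound and may force retests of "
            "conforming samples"
        )

    if strict_sum:
        total = sum(w_max[name] for name in members)
        band = limit.limit * (1.0 - u_rel_max / 100.0)
        if total > band:
            failed.append("sum")
            warnings.append(
                f"summed W_max {total:g} mg/kg exceeds the guard-banded "
                f"limit {band:g} mg/kg"
            )

    decision = "retest-individually" if failed else "pass"
    logger.info(
        "judge_pool: decision=%s l_cor=%.6g failed=%s", decision, l_cor, failed
    )
    return Verdict(decision=decision, w_max=w_max, l_cor=l_cor, warnings=warnings)


def expected_pool_reference(
    subsamples: Sequence[SubSample],
    analytes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Reference W_max an ideal measurement of the pool would yield.

    With known true concentrations, a noise-free, 100 %-recovery
    measurement reports the pooled analyte mass exactly, so the
    worst-case attribution gives

        reference = sum_i(mass_i * conc_i) / m_min    (mg/kg)

    per analyte. Blanks contribute zero mass of analyte but do count
    toward m_min. Invariant to sub-sample order and to rescaling all
    masses by a common factor.
    """
    if not subsamples:
        raise ValueError("empty pool")
    for s in subsamples:
        if s.true_conc is None:
            raise ValueError(f"sub-sample {s.id!r} has no true concentrations")
    if analytes is None:
        names: list[str] = []
        for s in subsamples:
            for name in s.true_conc:
                if name not in names:
                    names.append(name)
    else:
        names = list(analytes)
    m_min = min(s.mass for s in subsamples)
    return {
        name: sum(s.mass * s.true_conc.get(name, 0.0) for s in subsamples) / m_min
        for name in names
    }


def recovery_rate(measured: float, reference: float) -> float:
    """Recovery in percent, rounded to 1 dp: 100 * measured / reference."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    if measured < 0:
        raise ValueError(f"measured must be >= 0, got {measured}")
    return round_half_up(100.0 * measured / reference, 1)
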