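"""Measurement-uncertainty budgets for pooled conformity testing.

Combines the relative standard-uncertainty components of a chemical
analysis (mass, volume, standard working solution, recovery,
accuracy/precision) into a combined relative standard uncertainty by
root-sum-of-squares, and expands it with a coverage factor, following
the GUM (ISO/IEC Guide 98-3) uncorrelated-input propagation rule:

    u_rel = sqrt(u_m^2 + u_V^2 + u_std^2 + u_rec^2 + u_rsd^2)
    U_rel = k * u_rel

All uncertainties are relative and expressed in percent. ``k = 2``
corresponds to roughly 95 % coverage under normality.

Full precision is kept internally; rounding to one decimal place is a
display concern and happens only in report formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import check_finite_nonnegative, check_positive

__all__ = [
    "COMPONENT_NAMES",
    "UncertaintyBudget",
    "combine_relative_uncertainty",
    "expand_uncertainty",
]

#: Canonical order of the five budget components (all in %).
COMPONENT_NAMES = ("u_mass", "u_volume", "u_standard", "u_recovery", "u_precision")


def combine_relative_uncertainty(
    components: Sequence[float],
    extra: Iterable[float] = (),
) -> float:
    """Combined relative standard uncertainty (%) by root-sum-of-squares.

    Parameters
    ----------
    components
        The five relative standard-uncertainty components in percent,
        in the order mass, volume, standard solution, recovery,
        accuracy/precision.
    extra
        Optional further components (e.g. environment, operator) folded
        into the same quadrature sum. The five-component budget is the
        default because those are the sources that dominate a routine
        extraction/GC-MS workflow; additional sources may be supplied
        when a laboratory's budget identifies them.

    Returns
    -------
    float
        ``sqrt(sum(c_i^2))`` in percent, unrounded.

    Raises
    ------
    ValueError
        If any component is negative or non-finite; the message names
        the offending component.
    """
    components = tuple(components)
    if len(components) != len(COMPONENT_NAMES):
        raise ValueError(
            f"expected {len(COMPONENT_NAMES)} components "
            f"{COMPONENT_NAMES}, got {len(components)}"
        )
    total = 0.0
    for name, value in zip(COMPONENT_NAMES, components):
        total += check_finite_nonnegative(value, name) ** 2
    for i, value in enumerate(extra):
        total += check_finite_nonnegative(value, f"extra[{i}]") ** 2
    return math.sqrt(total)


def expand_uncertainty(u_rel: float, k: float = 2.0) -> float:
    """Relative expanded uncertainty ``U_rel = k * u_rel`` (%).

    ``k`` is the coverage factor; 2 gives ~95 % coverage for a normally
    distributed measurand.
    """
    check_finite_nonnegative(u_rel, "u_rel")
    check_positive(k, "k")
    return k * u_rel


@dataclass(frozen=True)
class UncertaintyBudget:
    """A resolved uncertainty budget for one analyte.

    All components in percent. ``u_combined`` and ``U_expanded`` are
    derived on construction and kept at full precision.
    """

    u_mass: float
    u_volume: float
    u_standard: float
    u_recovery: float
    u_precision: float
    extra: tuple[float, ...] = ()
    k: float = 2.0
    u_combined: float = field(init=False)
    U_expanded: float = field(init=False)

    def __post_init__(self) -> None:
        u = combine_relative_uncertainty(self.components, self.extra)
        object.__setattr__(self, "u_combined", u)
        object.__setattr__(self, "U_expanded", expand_uncertainty(u, self.k))

    @property
    def components(self) -> tuple[float, float, float, float, float]:
        return (
            self.u_mass,
            self.u_volume,
            self.u_standard,
            self.u_recovery,
            self.u_precision,
        )
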