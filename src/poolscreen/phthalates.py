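"""Bundled reference data for the phthalate (PAE) screening application.

The seven phthalate esters regulated in toys and childcare articles —
DIBP, DBP, BBP, DEHP, DNOP, DINP, DIDP — are the worked application of
this package: per-analyte uncertainty budgets from a GC-MS validation
study, certified concentrations of three positive PVC reference
materials, and the composition and measured results of six spiked
validation pools (group sizes 3, 6 and 10). These constants back the
worked examples, the regression tests and the ``poolscreen fixtures``
command.

Masses are in g, sample concentrations in mg/kg, uncertainties in %.

The blank portion of each validation pool is represented as a single
aggregated sub-sample (its per-portion masses were not recorded
separately); because the aggregate outweighs every positive portion,
the minimum mass — and hence the worst-case reference value — is set
by the positive portion, matching how the study reported its
reference rows.
"""

from __future__ import annotations

from .evaluation import SubSample
from .uncertainty import UncertaintyBudget

__all__ = [
    "PAE_NAMES",
    "UNCERTAINTY_COMPONENTS",
    "uncertainty_budgets",
    "CRM_CONCENTRATIONS",
    "LOQ_RANGE",
    "LOQ_MAX",
    "VALIDATION_POOLS",
    "validation_pool_subsamples",
    "SCENARIOS",
]

PAE_NAMES = ("DIBP", "DBP", "BBP", "DEHP", "DNOP", "DIDP", "DINP")

#: Relative standard-uncertainty components (%) per analyte, in the
#: order mass, volume, standard solution, recovery, accuracy/precision.
UNCERTAINTY_COMPONENTS: dict[str, tuple[float, float, float, float, float]] = {
    "DIBP": (0.17, 1.2, 5.3, 3.1, 7.6),
    "DBP": (0.17, 1.2, 5.3, 2.3, 7.3),
    "BBP": (0.17, 1.2, 5.3, 2.7, 6.8),
    "DEHP": (0.17, 1.2, 5.3, 2.8, 7.1),
    "DNOP": (0.17, 1.2, 5.3, 2.3, 5.8),
    "DIDP": (0.17, 1.2, 5.3, 3.0, 9.1),
    "DINP": (0.17, 1.2, 5.3, 3.6, 9.6),
}


def uncertainty_budgets(k: float = 2.0) -> dict[str, UncertaintyBudget]:
    """Resolved uncertainty budgets for the seven PAEs."""
    return {
        name: UncertaintyBudget(*components, k=k)
        for name, components in UNCERTAINTY_COMPONENTS.items()
    }


#: Certified / assigned concentrations (mg/kg) of the three positive
#: PVC materials used for spiking: #A a national CRM, #B a commercial
#: reference material, #C an in-house QC sample.
CRM_CONCENTRATIONS: dict[str, dict[str, float]] = {
    "A": {"DIBP": 1200, "DBP": 2300, "BBP": 2050, "DEHP": 1460,
          "DNOP": 1800, "DINP": 1520, "DIDP": 1160},
    "B": {"DIBP": 926, "DBP": 1109, "BBP": 1076, "DEHP": 980,
          "DNOP": 1061, "DINP": 1041, "DIDP": 1166},
    "C": {"DIBP": 407, "DBP": 554, "BBP": 508, "DEHP": 402,
          "DNOP": 712, "DINP": 567, "DIDP": 529},
}

#: Experimentally determined method LOQ range across the 7 PAEs (mg/kg).
LOQ_RANGE = (9.1, 41.8)
LOQ_MAX = 41.8

_BLANK = {name: 0.0 for name in PAE_NAMES}

#: Spiked validation pools: group size, positive portions as
#: (material, mass_g), aggregated blank mass, and the measured W_max
#: values (mg/kg) reported by the validation study.
VALIDATION_POOLS: dict[str, dict] = {
    "G-1": {
        "k": 3,
        "positives": [("B", 0.1054)],
        "blank_mass": 0.1969,
        "measured": {"DIBP": 1017, "DBP": 1025, "BBP": 1129, "DEHP": 987,
                     "DNOP": 1143, "DINP": 1169, "DIDP": 1061},
    },
    "G-2": {
        "k": 3,
        "positives": [("C", 0.0950)],
        "blank_mass": 0.2065,
        "measured": {"DIBP": 440, "DBP": 565, "BBP": 557, "DEHP": 394,
                     "DNOP": 732, "DINP": 561, "DIDP": 530},
    },
    "G-3": {
        "k": 6,
        "positives": [("A", 0.1052)],
        "blank_mass": 0.5060,
        "measured": {"DIBP": 1243, "DBP": 2362, "BBP": 2085, "DEHP": 1470,
                     "DNOP": 1829, "DINP": 1491, "DIDP": 1070},
    },
    "G-4": {
        "k": 6,
        "positives": [("A", 0.1028), ("C", 0.1018)],
        "blank_mass": 0.4062,
        "measured": {"DIBP": 1603, "DBP": 2822, "BBP": 2506, "DEHP": 1817,
                     "DNOP": 2694, "DINP": 2048, "DIDP": 1660},
    },
    "G-5": {
        "k": 10,
        "positives": [("B", 0.0986)],
        "blank_mass": 0.9220,
        "measured": {"DIBP": 1008, "DBP": 1161, "BBP": 1045, "DEHP": 1026,
                     "DNOP": 1078, "DINP": 1135, "DIDP": 1148},
    },
    "G-6": {
        "k": 10,
        "positives": [("B", 0.1013), ("C", 0.1027)],
        "blank_mass": 0.7994,
        "measured": {"DIBP": 1435, "DBP": 1689, "BBP": 1534, "DEHP": 1394,
                     "DNOP": 1795, "DINP": 1662, "DIDP": 1721},
    },
}


def validation_pool_subsamples(pool_id: str) -> list[SubSample]:
    """Sub-samples of one validation pool, blanks aggregated.

    The aggregated blank carries zero concentration for every analyte
    and, being heavier than any positive portion, leaves m_min at the
    lightest positive portion.
    """
    try:
        pool = VALIDATION_POOLS[pool_id]
    except KeyError:
        raise KeyError(
            f"unknown pool {pool_id!r}; known: {', '.join(VALIDATION_POOLS)}"
        ) from None
    subsamples = [
        SubSample(id=material, mass=mass, true_conc=CRM_CONCENTRATIONS[material])
        for material, mass in pool["positives"]
    ]
    subsamples.append(SubSample(id="blank", mass=pool["blank_mass"], true_conc=_BLANK))
    return subsamples


#: Worked planning scenarios (per-substance method data as used in the
#: design examples; Q_M in mg/kg, U_rel in %).
SCENARIOS: dict[str, dict] = {
    "A": {
        "description": "DEHP regulated alone at 0.1 % (CPSIA/CCPSA-style)",
        "q": 0.99,
        "limit_mg_kg": 1000.0,
        "n_substances": 1,
        "analytes": {"DEHP": {"loq": 2.4, "U_rel": 14.0}},
        "safety_factor": 0.8,
    },
    "B": {
        "description": "Sum of DIBP+DBP+BBP+DEHP at 0.1 % (REACH-style)",
        "q": 0.95,
        "limit_mg_kg": 1000.0,
        "n_substances": 4,
        "analytes": {
            "DIBP": {"loq": 2.5, "U_rel": 13.0},
            "DBP": {"loq": 3.4, "U_rel": 15.0},
            "BBP": {"loq": 20.0, "U_rel": 18.0},
            "DEHP": {"loq": 2.4, "U_rel": 14.0},
        },
        "safety_factor": 0.8,
    },
    "C": {
        "description": "Sum of DNOP+DINP+DIDP at 0.1 % (GB-style)",
        "q": 0.90,
        "limit_mg_kg": 1000.0,
        "n_substances": 3,
        "analytes": {
            "DNOP": {"loq": 9.5, "U_rel": 21.0},
            "DINP": {"loq": 41.0, "U_rel": 23.0},
            "DIDP": {"loq": 65.0, "U_rel": 23.0},
        },
        "safety_factor": 0.8,
    },
}
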