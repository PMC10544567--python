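"""Registry of regulated phthalate limits by jurisdiction.

Preset keys are stable strings; regulation changes mean editing this
one table, not code elsewhere. All limits canonicalized to mg/kg
(0.1 % w/w = 1000 mg/kg). ``n_substances`` is the number of analytes
whose *summed* concentration the limit constrains; per-substance
limits (CPSIA, ASTM F963, Australia) have n_substances = 1.
"""

from __future__ import annotations

from .design import RegulationLimit

__all__ = ["LIMIT_PRESETS", "limit_registry"]

LIMIT_PRESETS: dict[str, RegulationLimit] = {
    "REACH-4": RegulationLimit(
        limit=1000.0,
        n_substances=4,
        analytes=("DEHP", "BBP", "DBP", "DIBP"),
        label="EU REACH: DEHP + BBP + DBP + DIBP <= 0.1 %",
    ),
    "REACH-3": RegulationLimit(
        limit=1000.0,
        n_substances=3,
        analytes=("DINP", "DIDP", "DNOP"),
        label="EU REACH (mouthable): DINP + DIDP + DNOP <= 0.1 %",
    ),
    "GB6675-3": RegulationLimit(
        limit=1000.0,
        n_substances=3,
        analytes=("DEHP", "BBP", "DBP"),
        label="China GB 6675.1: DEHP + BBP + DBP <= 0.1 %",
    ),
    "GB24613-3": RegulationLimit(
        limit=1000.0,
        n_substances=3,
        analytes=("DINP", "DIDP", "DNOP"),
        label="China GB 24613: DINP + DIDP + DNOP <= 0.1 %",
    ),
    "CPSIA-8": RegulationLimit(
        limit=1000.0,
        n_substances=1,
        analytes=("DIBP", "BBP", "DBP", "DEHP", "DCHP", "DHEXP", "DINP", "DPENP"),
        label="US CPSIA: each of 8 phthalates <= 0.1 % (per-substance)",
    ),
    "CPSIA-DEHP": RegulationLimit(
        limit=1000.0,
        n_substances=1,
        analytes=("DEHP",),
        label="US CPSIA: DEHP <= 0.1 %",
    ),
    "ASTM-F963-DEHP": RegulationLimit(
        limit=30000.0,
        n_substances=1,
        analytes=("DEHP",),
        label="US ASTM F963: DEHP <= 3 %",
    ),
    "SOR-2016-188-3": RegulationLimit(
        limit=1000.0,
        n_substances=3,
        analytes=("DEHP", "DBP", "BBP"),
        label="Canada SOR/2016-188: DEHP + DBP + BBP <= 0.1 %",
    ),
    "SOR-2016-188-3b": RegulationLimit(
        limit=1000.0,
        n_substances=3,
        analytes=("DINP", "DIDP", "DNOP"),
        label="Canada SOR/2016-188 (mouthable): DINP + DIDP + DNOP <= 0.1 %",
    ),
    "AU-DEHP": RegulationLimit(
        limit=10000.0,
        n_substances=1,
        analytes=("DEHP",),
        label="Australia Consumer Protection Act 2011: DEHP <= 1 %",
    ),
}

# convenience aliases
LIMIT_PRESETS["GB-3sum"] = LIMIT_PRESETS["GB24613-3"]


def limit_registry(preset: str) -> RegulationLimit:
    """Look up a limit preset; unknown keys raise with the known list."""
    try:
        return LIMIT_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown limit preset {preset!r}; known presets: "
            f"{', '.join(sorted(LIMIT_PRESETS))}"
        ) from None
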