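"""Shared fixtures: frozen published values and small synthetic inputs."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Published quick-reference grid of expected tests per sample (rows: K,
# columns: q in Q_GRID), frozen at its printed 3-dp precision.
Q_GRID = (0.69, 0.70, 0.80, 0.90, 0.95, 0.99)
REFERENCE_TABLE = {
    2: (1.024, 1.010, 0.860, 0.690, 0.598, 0.520),
    3: (1.005, 0.990, 0.821, 0.604, 0.476, 0.363),
    4: (1.023, 1.010, 0.840, 0.594, 0.435, 0.289),
    5: (1.044, 1.032, 0.872, 0.610, 0.426, 0.249),
    6: (1.059, 1.049, 0.905, 0.635, 0.432, 0.225),
    7: (1.068, 1.061, 0.933, 0.665, 0.445, 0.211),
    8: (1.074, 1.067, 0.957, 0.695, 0.462, 0.202),
    9: (1.076, 1.071, 0.977, 0.724, 0.481, 0.198),
    10: (1.076, 1.072, 0.993, 0.751, 0.501, 0.196),
    11: (1.074, 1.071, 1.005, 0.777, 0.522, 0.196),
    12: (1.072, 1.069, 1.015, 0.801, 0.543, 0.197),
    13: (1.069, 1.067, 1.022, 0.823, 0.564, 0.199),
    14: (1.066, 1.065, 1.027, 0.843, 0.584, 0.203),
    15: (1.063, 1.062, 1.031, 0.861, 0.603, 0.207),
}

# Published per-analyte uncertainty table (%): the five components and
# the printed combined / expanded columns at 1 dp.
UNCERTAINTY_TABLE = {
    "DIBP": ((0.17, 1.2, 5.3, 3.1, 7.6), 9.8, 19.7),
    "DBP": ((0.17, 1.2, 5.3, 2.3, 7.3), 9.4, 18.8),
    "BBP": ((0.17, 1.2, 5.3, 2.7, 6.8), 9.1, 18.2),
    "DEHP": ((0.17, 1.2, 5.3, 2.8, 7.1), 9.4, 18.7),
    "DNOP": ((0.17, 1.2, 5.3, 2.3, 5.8), 8.3, 16.6),
    "DIDP": ((0.17, 1.2, 5.3, 3.0, 9.1), 11.0, 22.0),
    "DINP": ((0.17, 1.2, 5.3, 3.6, 9.6), 11.6, 23.2),
}

# Published reference (ideal worst-case) values of the six spiked
# validation pools, mg/kg; the study mixes rounding and truncation so
# regression tests compare within +/- 1.
VALIDATION_REFERENCES = {
    "G-1": {"DIBP": 926, "DBP": 1109, "BBP": 1076, "DEHP": 980,
            "DNOP": 1061, "DINP": 1041, "DIDP": 1166},
    "G-2": {"DIBP": 407, "DBP": 554, "BBP": 508, "DEHP": 402,
            "DNOP": 712, "DINP": 567, "DIDP": 529},
    "G-3": {"DIBP": 1200, "DBP": 2300, "BBP": 2050, "DEHP": 1460,
            "DNOP": 1800, "DINP": 1520, "DIDP": 1160},
    "G-4": {"DIBP": 1619, "DBP": 2877, "BBP": 2578, "DEHP": 1877,
            "DNOP": 2529, "DINP": 2102, "DIDP": 1700},
    "G-5": {"DIBP": 926, "DBP": 1109, "BBP": 1076, "DEHP": 980,
            "DNOP": 1061, "DINP": 1041, "DIDP": 1166},
    "G-6": {"DIBP": 1338, "DBP": 1671, "BBP": 1591, "DEHP": 1388,
            "DNOP": 1783, "DINP": 1616, "DIDP": 1702},
}

# Published recovery rates (%) of the validation pools at 1 dp.
VALIDATION_RECOVERIES = {
    "G-1": {"DIBP": 109.8, "DBP": 92.4, "BBP": 104.9, "DEHP": 100.7,
            "DNOP": 107.7, "DINP": 112.3, "DIDP": 91.0},
    "G-2": {"DIBP": 108.1, "DBP": 102.0, "BBP": 109.6, "DEHP": 98.0,
            "DNOP": 102.8, "DINP": 98.9, "DIDP": 100.2},
    "G-3": {"DIBP": 103.6, "DBP": 102.7, "BBP": 101.7, "DEHP": 100.7,
            "DNOP": 101.6, "DINP": 98.1, "DIDP": 92.2},
    "G-4": {"DIBP": 99.0, "DBP": 98.1, "BBP": 97.2, "DEHP": 96.8,
            "DNOP": 106.5, "DINP": 97.4, "DIDP": 97.6},
    "G-5": {"DIBP": 108.9, "DBP": 104.7, "BBP": 97.1, "DEHP": 104.7,
            "DNOP": 101.6, "DINP": 109.0, "DIDP": 98.5},
    "G-6": {"DIBP": 107.2, "DBP": 101.1, "BBP": 96.4, "DEHP": 100.4,
            "DNOP": 100.7, "DINP": 102.8, "DIDP": 101.1},
}


# Per-analyte method LOQs (mg/kg) as used in the worked design examples.
EXAMPLE_LOQS = {"DIBP": 2.5, "DBP": 3.4, "BBP": 20.0, "DEHP": 2.4,
                "DNOP": 9.5, "DINP": 41.0, "DIDP": 65.0}


@pytest.fixture
def analyte_spec_csv(tmp_path):
    """Analyte spec table with LOQs and uncertainty components, as CSV."""
    lines = ["name,loq_mg_kg,u_mass_pct,u_volume_pct,u_std_pct,u_recovery_pct,u_precision_pct,k"]
    for name, (components, _, _) in UNCERTAINTY_TABLE.items():
        lines.append(
            f"{name},{EXAMPLE_LOQS[name]},"
            + ",".join(str(c) for c in components)
            + ",2"
        )
    path = tmp_path / "specs.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
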