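"""Configuration and tabular I/O: analyte spec tables, pool sheets, reports.

Canonical units in files: mg/kg for sample concentrations and limits,
mg/L for solution concentrations, mL for volumes, g for masses;
percent-valued columns carry a ``_pct`` suffix.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from ._util import round_half_up
from .design import AnalyteSpec, DesignParams, PoolPlan, compute_loq_from_idl
from .evaluation import PoolMeasurement, SubSample, Verdict
from .simulation import CampaignResult
from .uncertainty import combine_relative_uncertainty, expand_uncertainty

__all__ = [
    "load_analyte_specs",
    "read_pool_sheet",
    "write_pool_sheet",
    "render_report",
    "report_dict",
    "ProjectConfig",
    "load_config",
    "save_config",
]

_COMPONENT_COLUMNS = (
    "u_mass_pct",
    "u_volume_pct",
    "u_std_pct",
    "u_recovery_pct",
    "u_precision_pct",
)

#: Explicit vs derived values printed at 1 dp may disagree by up to
#: half a unit in the last place.
_CONSISTENCY_TOL = 0.06


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def load_analyte_specs(path: str | Path) -> list[AnalyteSpec]:
    """Read an analyte spec table (CSV or YAML) into validated specs.

    Required: a ``name`` column. Each analyte needs an expanded
    uncertainty, either explicit (``U_rel_pct``) or derived from the
    five component columns (``u_mass_pct``, ``u_volume_pct``,
    ``u_std_pct``, ``u_recovery_pct``, ``u_precision_pct``) with an
    optional coverage factor ``k`` (default 2). The LOQ comes from
    ``loq_mg_kg`` or is derived from ``idl_mg_L`` with
    ``extract_volume_mL`` and ``min_mass_g``. When both an explicit
    and a derivable value are present they must agree to display
    precision, else an error quotes both numbers.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        if not raw:
            raise ValueError(f"empty analyte spec file: {path}")
        df = pd.DataFrame(raw["analytes"] if isinstance(raw, Mapping) else raw)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty analyte spec file: {path}")
    if "name" not in df.columns:
        raise ValueError(f"analyte spec file {path} is missing required column 'name'")

    specs = []
    for _, row in df.iterrows():
        name = str(row["name"])
        row = row.to_dict()

        u_explicit = row.get("U_rel_pct")
        u_derived = None
        if all(not _is_missing(row.get(c)) for c in _COMPONENT_COLUMNS):
            k = row.get("k")
            k = 2.0 if _is_missing(k) else float(k)
            u_derived = expand_uncertainty(
                combine_relative_uncertainty(
                    [float(row[c]) for c in _COMPONENT_COLUMNS]
                ),
                k,
            )
        if not _is_missing(u_explicit) and u_derived is not None:
            if abs(float(u_explicit) - round_half_up(u_derived, 1)) > _CONSISTENCY_TOL:
                raise ValueError(
                    f"analyte {name!r}: explicit U_rel {float(u_explicit):g}% "
                    f"contradicts value derived from components "
                    f"{round_half_up(u_derived, 1):g}%"
                )
        u_rel = u_derived if u_derived is not None else (
            None if _is_missing(u_explicit) else float(u_explicit)
        )
        if u_rel is None:
            raise ValueError(
                f"analyte {name!r}: no U_rel_pct and incomplete uncertainty "
                f"components (need all of {', '.join(_COMPONENT_COLUMNS)})"
            )

        loq_explicit = row.get("loq_mg_kg")
        loq_derived = None
        idl = row.get("idl_mg_L")
        if (
            not _is_missing(idl)
            and not _is_missing(row.get("extract_volume_mL"))
            and not _is_missing(row.get("min_mass_g"))
        ):
            loq_derived = compute_loq_from_idl(
                float(idl), float(row["extract_volume_mL"]), float(row["min_mass_g"])
            )
        if not _is_missing(loq_explicit) and loq_derived is not None:
            if abs(float(loq_explicit) - loq_derived) > max(
                0.05, 0.005 * loq_derived
            ):
                raise ValueError(
                    f"analyte {name!r}: explicit LOQ {float(loq_explicit):g} mg/kg "
                    f"contradicts value derived from IDL {loq_derived:g} mg/kg"
                )
        loq = (
            float(loq_explicit)
            if not _is_missing(loq_explicit)
            else loq_derived
        )

        specs.append(
            AnalyteSpec(
                name=name,
                loq=loq,
                expanded_uncertainty=u_rel,
                idl=None if _is_missing(idl) else float(idl),
            )
        )
    return specs


# --------------------------------------------------------------------------
# pool sheets


def read_pool_sheet(
    path: str | Path,
) -> dict[str, tuple[list[SubSample], PoolMeasurement]]:
    """Read a pool sheet CSV.

    One row per sub-sample: ``pool_id, subsample_id, mass_g`` plus the
    pool-level columns ``V_mL``, ``D`` and one ``c_<analyte>_mg_L``
    column per analyte (identical within a pool; the first row's values
    are used).
    """
    df = pd.read_csv(path)
    required = {"pool_id", "subsample_id", "mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pool sheet {path} missing columns: {', '.join(sorted(missing))}")
    conc_cols = [c for c in df.columns if c.startswith("c_") and c.endswith("_mg_L")]
    out: dict[str, tuple[list[SubSample], PoolMeasurement]] = {}
    for pool_id, group in df.groupby("pool_id", sort=False):
        subsamples = [
            SubSample(id=str(r.subsample_id), mass=float(r.mass_g))
            for r in group.itertuples()
        ]
        first = group.iloc[0]
        if "V_mL" not in group.columns or _is_missing(first["V_mL"]):
            raise ValueError(f"pool {pool_id!r}: missing extract volume V_mL")
        if "D" not in group.columns or _is_missing(first["D"]):
            raise ValueError(f"pool {pool_id!r}: missing dilution ratio D")
        conc = {
            col[len("c_"):-len("_mg_L")]: float(first[col]) for col in conc_cols
        }
        out[str(pool_id)] = (
            subsamples,
            PoolMeasurement(
                concentrations=conc,
                volume=float(first["V_mL"]),
                dilution=float(first["D"]),
            ),
        )
    return out


def write_pool_sheet(
    pools: Mapping[str, tuple[Sequence[SubSample], PoolMeasurement]],
    path: str | Path,
) -> None:
    """Write pools to the pool-sheet CSV layout read by :func:`read_pool_sheet`."""
    analytes: list[str] = []
    for _, (_, meas) in pools.items():
        for name in meas.concentrations:
            if name not in analytes:
                analytes.append(name)
    rows = []
    for pool_id, (subsamples, meas) in pools.items():
        for s in subsamples:
            row = {
                "pool_id": pool_id,
                "subsample_id": s.id,
                "mass_g": s.mass,
                "V_mL": meas.volume,
                "D": meas.dilution,
            }
            for name in analytes:
                row[f"c_{name}_mg_L"] = meas.concentrations.get(name, 0.0)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# reports


def report_dict(obj: PoolPlan | Verdict | CampaignResult) -> dict:
    """Machine-readable report carrying unrounded values."""
    return obj.to_dict()


def render_report(obj: PoolPlan | Verdict | CampaignResult) -> str:
    """Deterministic human-readable report.

    Formatting conventions: 3 dp for expected tests per sample, 1 dp
    for percentages, integer mg/kg for concentrations.
    """
    if isinstance(obj, PoolPlan):
        lines = ["Composite testing plan", "----------------------"]
        if obj.applicable:
            lines += [
                f"applicable:        yes",
                f"K_opt:             {obj.k_opt}",
                f"K_max:             {obj.k_max}",
                f"K_a (chosen):      {obj.k_a}",
                f"tests per sample:  {round_half_up(obj.tests_per_sample, 3):.3f}",
                f"workload saved:    {round_half_up(100 * obj.savings, 1):.1f}%",
            ]
        else:
            lines += ["applicable:        no (individual testing recommended)"]
            if obj.k_max is not None:
                lines.append(f"K_max:             {obj.k_max}")
        for reason in obj.reasons:
            lines.append(f"note: {reason}")
        for warning in obj.warnings:
            lines.append(f"warning: {warning}")
        return "\n".join(lines)

    if isinstance(obj, Verdict):
        lines = ["Pool verdict", "------------"]
        lines.append(f"corrected limit L_cor: {round_half_up(obj.l_cor, 0):.0f} mg/kg")
        for name, w in obj.w_max.items():
            flag = "over" if w > obj.l_cor else "ok"
            lines.append(f"W_max[{name}]: {round_half_up(w, 0):.0f} mg/kg ({flag})")
        if obj.passed:
            lines.append("decision: pass - all samples in the group are qualified")
        else:
            lines.append("decision: retest all group members individually")
        for warning in obj.warnings:
            lines.append(f"warning: {warning}")
        return "\n".join(lines)

    if isinstance(obj, CampaignResult):
        lines = ["Campaign simulation result", "--------------------------"]
        lines += [
            f"batch size n:       {obj.n}",
            f"group size K:       {obj.k}",
            f"repetitions:        {obj.reps}",
            f"tests per sample:   {round_half_up(obj.tests_per_sample, 3):.3f} "
            f"(+/- {obj.tests_per_sample_ci:.4f})",
            f"workload saved:     {round_half_up(100 * obj.s_empirical, 1):.1f}%",
            f"false-positive rate: {obj.false_positive_rate:.4g} "
            f"(+/- {obj.false_positive_ci:.4g})",
            f"false-negative rate: {obj.false_negative_rate:.4g} "
            f"(+/- {obj.false_negative_ci:.4g})",
        ]
        return "\n".join(lines)

    raise TypeError(f"cannot render report for {type(obj).__name__}")


# --------------------------------------------------------------------------
# project configuration


@dataclass
class ProjectConfig:
    """Resolved project configuration for an end-to-end run."""

    analyte_specs: str
    limit_preset: str | None = None
    limit_mg_kg: float | None = None
    n_substances: int = 1
    q: float = 0.95
    safety_factor: float = 0.8
    k_cap: int = 10
    extract_volume: float | None = None
    min_mass: float | None = None
    simulation: dict = field(default_factory=dict)
    output_dir: str = "."
    log_level: str = "INFO"

    def design_params(self) -> DesignParams:
        return DesignParams(
            q=self.q,
            safety_factor=self.safety_factor,
            k_cap=self.k_cap,
            extract_volume=self.extract_volume,
            min_mass=self.min_mass,
        )


def load_config(path: str | Path) -> ProjectConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    return ProjectConfig(**raw)


def save_config(config: ProjectConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def dump_json(obj: PoolPlan | Verdict | CampaignResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_dict(obj), indent=2, sort_keys=True))
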