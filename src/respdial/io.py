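"""CSV/YAML plumbing: blood-gas tables, run configuration, result writers.

Column names carry explicit units (``pco2_mmHg``, ``qb_ml_min``) to prevent
unit drift between files.  All CSVs round-trip losslessly (full float
precision is written).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chemistry import IonComposition
from .constants import DEFAULT_CONSTANTS, EquilibriumConstants
from .dialysate import PUBLISHED_DESIGN, DesignConstraints
from .errors import PairingError, ValidationError
from .removal import (
    DEFAULT_SCALE_FACTOR,
    BloodGasRecord,
    RemovalResult,
    vco2_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "GAS_CSV_COLUMNS",
    "read_blood_gas_csv",
    "records_from_dataframe",
    "analyze_blood_gases",
    "write_composition_csv",
    "load_run_config",
]

#: required columns of the blood-gas exchange schema
GAS_CSV_COLUMNS = (
    "condition_id",
    "qb_ml_min",
    "qd_ml_min",
    "inlet_pco2_target",
    "side",
    "replicate",
    "ph",
    "pco2_mmHg",
)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration assembled from YAML."""

    constants: EquilibriumConstants = DEFAULT_CONSTANTS
    design: DesignConstraints = PUBLISHED_DESIGN
    final_chloride: float | None = 135.6
    scale_area_full: float = 0.9
    scale_area_bench: float = 0.04
    replicates: int = 3
    bench_subset: bool = False
    seed: int = 0
    rig_overrides: dict = field(default_factory=dict)
    outdir: Path = Path("respdial_out")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Recognised blocks: ``constants:`` (field overrides), ``design:``
    (DesignConstraints fields), ``analysis:`` (scale areas, final
    chloride), ``rig:`` (RigConfig field overrides), plus top-level
    ``seed``, ``replicates``, ``bench_subset`` and ``outdir``.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    constants = DEFAULT_CONSTANTS.with_overrides(raw.get("constants", {}) or {})
    design_kwargs = raw.get("design", {}) or {}
    if "target_ph_range" in design_kwargs:
        design_kwargs["target_ph_range"] = tuple(design_kwargs["target_ph_range"])
    if "adjustable_ions" in design_kwargs:
        design_kwargs["adjustable_ions"] = tuple(design_kwargs["adjustable_ions"])
    design = DesignConstraints(**design_kwargs) if design_kwargs else PUBLISHED_DESIGN
    analysis = raw.get("analysis", {}) or {}
    return RunConfig(
        constants=constants,
        design=design,
        final_chloride=analysis.get("final_chloride", 135.6),
        scale_area_full=analysis.get("scale_area_full", 0.9),
        scale_area_bench=analysis.get("scale_area_bench", 0.04),
        replicates=int(raw.get("replicates", 3)),
        bench_subset=bool(raw.get("bench_subset", False)),
        seed=int(raw.get("seed", 0)),
        rig_overrides=raw.get("rig", {}) or {},
        outdir=Path(raw.get("outdir", "respdial_out")),
    )


def read_blood_gas_csv(path: str | Path) -> pd.DataFrame:
    """Read a pre/post blood-gas CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = set(GAS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"blood-gas CSV {path} lacks required columns {sorted(missing)}"
        )
    bad = set(df["side"].unique()) - {"pre", "post"}
    if bad:
        raise ValidationError(f"side column contains invalid values {sorted(bad)}")
    return df


def records_from_dataframe(df: pd.DataFrame) -> list[BloodGasRecord]:
    """Convert schema rows into :class:`BloodGasRecord` objects."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BloodGasRecord(
                condition_id=str(row.condition_id),
                side=str(row.side),
                replicate=int(row.replicate),
                ph=float(row.ph),
                pco2=float(row.pco2_mmHg),
                hemoglobin=float(row.hb_g_dl)
                if hasattr(row, "hb_g_dl") and pd.notna(row.hb_g_dl)
                else None,
            )
        )
    return records


def analyze_blood_gases(
    df: pd.DataFrame,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
    factor: float = DEFAULT_SCALE_FACTOR,
) -> pd.DataFrame:
    """Per-condition CO2 removal summary from a blood-gas table.

    Pairs pre/post rows by (condition_id, replicate), computes the removal
    rate per pair, then aggregates replicate means and sds per condition.
    Unpaired replicates raise :class:`PairingError`.
    """
    rows = []
    for (cond, rep), sub in df.groupby(["condition_id", "replicate"]):
        sides = dict(zip(sub["side"], sub.index))
        if set(sides) != {"pre", "post"}:
            raise PairingError(
                f"condition {cond!r} replicate {rep} lacks a matched pre/post pair"
            )
        pre_row = sub.loc[sides["pre"]]
        post_row = sub.loc[sides["post"]]
        pre = BloodGasRecord(cond, "pre", int(rep), float(pre_row["ph"]),
                             float(pre_row["pco2_mmHg"]))
        post = BloodGasRecord(cond, "post", int(rep), float(post_row["ph"]),
                              float(post_row["pco2_mmHg"]))
        qb = float(pre_row["qb_ml_min"])
        r: RemovalResult = vco2_rate(pre, post, qb / 1000.0, k, factor)
        rows.append(
            {
                "condition_id": cond,
                "replicate": int(rep),
                "qb_ml_min": qb,
                "qd_ml_min": float(pre_row["qd_ml_min"]),
                "inlet_pco2_target": float(pre_row["inlet_pco2_target"]),
                "vco2_bench_ml_min": r.vco2_bench,
                "vco2_scaled_ml_min": r.vco2_scaled,
                "delta_hco3_mmol_L": r.delta_hco3,
                "delta_pco2_mmHg": r.delta_pco2,
                "delta_ph": r.delta_ph,
                "scale_factor": r.scale_factor,
            }
        )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby(
            ["condition_id", "qb_ml_min", "qd_ml_min", "inlet_pco2_target",
             "scale_factor"],
            as_index=False,
        )
        .agg(
            n=("replicate", "count"),
            vco2_bench_ml_min=("vco2_bench_ml_min", "mean"),
            vco2_bench_sd=("vco2_bench_ml_min", "std"),
            vco2_scaled_ml_min=("vco2_scaled_ml_min", "mean"),
            vco2_scaled_sd=("vco2_scaled_ml_min", "std"),
            delta_hco3_mmol_L=("delta_hco3_mmol_L", "mean"),
            delta_pco2_mmHg=("delta_pco2_mmHg", "mean"),
            delta_ph=("delta_ph", "mean"),
        )
        .sort_values(["inlet_pco2_target", "qb_ml_min", "qd_ml_min"])
        .reset_index(drop=True)
    )
    return agg


def write_composition_csv(comp: IonComposition, path: str | Path) -> None:
    """Write a dialysate composition as ion, mmol_per_L, role rows."""
    roles = comp.meta.get("roles", {})
    rows = [
        {"ion": ion, "mmol_per_L": getattr(comp, ion), "role": roles.get(ion, "fixed")}
        for ion in ("na", "k", "ca", "mg", "cl", "lactate", "phosphate", "hco3")
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
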