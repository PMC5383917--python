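"""End-to-end run: design the dialysate, simulate the bench campaign,
analyze removal, summarise pH — one bundle of CSVs plus a text summary."""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

from . import __version__
from .chemistry import sid_from_ions
from .dialysate import design_dialysate, dialysate_ph, hcl_adjust
from .fixtures import load_table2
from .io import RunConfig, analyze_blood_gases, write_composition_csv
from .removal import percent_change, ph_delta_table, scale_factor
from .rig import (
    FluidState,
    condition_inlet_blood,
    default_rig_config,
    bench_grid,
    plasma_like_ions,
    run_experiment_grid,
    BLOOD_ATOT,
    BLOOD_SID,
)

logger = logging.getLogger(__name__)

__all__ = ["run_report"]


def run_report(config: RunConfig) -> dict:
    """Execute design -> simulate -> removal -> summaries.

    Returns a dict of output paths plus the headline numbers.  With
    ``config.replicates == 0`` only the design stage and the published
    pH-grid analysis run (no simulation).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    k = config.constants
    paths: dict = {}
    summary_lines = [f"respdial {__version__} report", ""]

    # --- dialysate design -------------------------------------------------
    comp = design_dialysate(config.design, k)
    if config.final_chloride is not None:
        comp_final = hcl_adjust(comp, config.final_chloride)
    else:
        comp_final = comp
    ph_modeled = dialysate_ph(comp, 0.0, k)
    ph_final = dialysate_ph(comp_final, 0.0, k)
    write_composition_csv(comp_final, out / "dialysate.csv")
    paths["dialysate"] = out / "dialysate.csv"
    summary_lines += [
        f"designed dialysate SID: {sid_from_ions(comp):.1f} mEq/L "
        f"(pH {ph_modeled:.2f} at pCO2 0)",
        f"after HCl adjustment:   {sid_from_ions(comp_final):.1f} mEq/L "
        f"(pH {ph_final:.2f}, reported {round(ph_final):d} at integer precision)",
        "",
    ]

    # --- published pH grid ------------------------------------------------
    table2 = ph_delta_table(load_table2())
    summary_lines += [
        f"published pH grid: max pH increase {table2.max_delta:.2f} "
        f"({table2.max_delta_condition})",
    ]
    for stratum, info in sorted(table2.max_delta_by_stratum.items()):
        summary_lines.append(
            f"  inlet {stratum:g} mmHg stratum: max {info['max_delta']:.2f} "
            f"({info['condition_id']})"
        )
    summary_lines.append("")

    # --- simulation + removal ---------------------------------------------
    if config.replicates > 0:
        conditions = bench_grid(bench_subset=config.bench_subset)
        blood = condition_inlet_blood(50.0, rng=config.seed, k=k)
        template = default_rig_config(qb=11.0, qd=16.0, blood=blood)
        if config.rig_overrides:
            template = replace(template, **config.rig_overrides)
        template = replace(
            template,
            blood_inlet=FluidState(
                ions=plasma_like_ions(BLOOD_SID), atot=BLOOD_ATOT,
                total_co2=blood.state.total_co2,
            ),
            seed=config.seed,
        )
        exp = run_experiment_grid(
            conditions, config.replicates, template, seed=config.seed, k=k
        )
        gases = exp.to_dataframe()
        gases.to_csv(out / "gases.csv", index=False)
        paths["gases"] = out / "gases.csv"

        factor = scale_factor(config.scale_area_full, config.scale_area_bench)
        removal = analyze_blood_gases(gases, k, factor)
        removal.to_csv(out / "removal.csv", index=False)
        paths["removal"] = out / "removal.csv"

        sim_ph = ph_delta_table(gases)
        sim_ph.table.to_csv(out / "ph_summary.csv", index=False)
        paths["ph_summary"] = out / "ph_summary.csv"

        checks = _acceptance_checks(removal, sim_ph)
        summary_lines += ["simulated campaign checks:"]
        summary_lines += [
            f"  [{'PASS' if ok else 'FAIL'}] {name}" for name, ok in checks
        ]
        summary_lines.append("")
        paths["checks"] = dict(checks)
    else:
        summary_lines.append("simulation skipped (replicates = 0)")

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    paths["summary"] = out / "summary.txt"
    paths["table2_max_delta"] = table2.max_delta
    paths["dialysate_ph"] = ph_final
    logger.info("report written to %s", out)
    return paths


def _acceptance_checks(removal, sim_ph) -> list[tuple[str, bool]]:
    """Behaviour checks on the simulated campaign.

    The recorded values carry measurement noise, so ordering checks allow
    4 standard errors of slack (pooled replicate scatter; ~60 ordered
    comparisons per campaign make a generous per-comparison allowance
    necessary) — the same allowance one would grant real bench data.
    """
    import numpy as np

    checks = []
    # pool the replicate variance across conditions: per-condition sd at
    # n = 3 is itself too noisy to set a stable allowance
    pooled_sd = float(np.sqrt(np.nanmean(removal["vco2_bench_sd"] ** 2)))
    if not np.isfinite(pooled_sd):
        pooled_sd = 0.0
    se = pooled_sd / np.sqrt(removal["n"].clip(lower=1)).to_numpy()
    removal = removal.assign(_se=se)

    mono = True
    for (qb, inlet), sub in removal.groupby(["qb_ml_min", "inlet_pco2_target"]):
        sub = sub.sort_values("qd_ml_min")
        v = sub["vco2_bench_ml_min"].to_numpy()
        s = sub["_se"].to_numpy()
        slack = 4.0 * np.sqrt(s[1:] ** 2 + s[:-1] ** 2)
        if np.any(v[1:] - v[:-1] < -slack):
            mono = False
    checks.append(("VCO2 non-decreasing in dialysate flow (4 SE slack)", mono))

    tbl = sim_ph.table.dropna(subset=["delta_ph"])
    se_ph = np.sqrt(
        tbl["pre_sd"].fillna(0.0) ** 2 / tbl["pre_n"].clip(lower=1)
        + tbl["post_sd"].fillna(0.0) ** 2 / tbl["post_n"].clip(lower=1)
    )
    checks.append(
        ("outlet pH never below inlet pH (4 SE slack)",
         bool((tbl["delta_ph"] >= -4.0 * se_ph).all()))
    )
    checks.append(
        ("pH increase <= 0.15 (4 SE slack)",
         bool((tbl["delta_ph"] <= 0.15 + 4.0 * se_ph).all()))
    )

    qb_effect = True
    for (qd, inlet), sub in removal.groupby(["qd_ml_min", "inlet_pco2_target"]):
        if sub["qb_ml_min"].nunique() == 2:
            sub = sub.sort_values("qb_ml_min")
            v = sub["vco2_bench_ml_min"].to_numpy()
            s = sub["_se"].to_numpy()
            if v[1] <= v[0] - 4.0 * float(np.hypot(s[0], s[1])):
                qb_effect = False
    checks.append(("VCO2 increases with blood flow (4 SE slack)", qb_effect))

    lo = removal[removal["inlet_pco2_target"] == 50.0]
    hi = removal[removal["inlet_pco2_target"] == 100.0]
    if not lo.empty and not hi.empty:
        merged = lo.merge(hi, on=["qb_ml_min", "qd_ml_min"], suffixes=("_50", "_100"))
        if not merged.empty:
            ratio = (
                merged["vco2_bench_ml_min_100"] / merged["vco2_bench_ml_min_50"]
            ).mean()
            pct = percent_change(1.0, float(ratio))
            checks.append(
                (f"doubling inlet pCO2 raises VCO2 by {pct:.0f}%", bool(ratio > 1.0))
            )
    return checks
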