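"""Single-pass bench-rig simulator.

Emulates the in-vitro circuit: conditioned blood (inlet pCO2 held near a
target, hemoglobin ~12 g/dL) flows through the fibers of a small dialyzer
while zero-bicarbonate dialysate flows counter-currently on the shell
side.  The fiber bundle is discretised into axial segments; within each
segment every transferable species s crosses the membrane at

    J_s = f_s * Qtilde * (C_blood,s - C_dialysate,s),
    f_s = 1 - exp(-(K0A_s / n_segments) / Qtilde),   Qtilde = Qb*Qd/(Qb+Qd)

the analytic co-current exchange over the segment with overall
mass-transfer coefficient K0A_s (mL/min); for small per-segment K0A this
reduces to the linear flux (K0A_s/n)*(C_b - C_d) and for large K0A it is
bounded at full flow-weighted equilibration, so the scheme stays stable in
the strong-transfer limit.  Dissolved CO2 crosses as gas,

    J_CO2 = (P_CO2 / n_segments) * (pCO2_blood - pCO2_dialysate) / Vm

with P_CO2 a permeance in mL gas/(min mmHg); the combined bicarbonate+gas
CO2 flux in a segment is capped at the flow-weighted equilibration of the
total CO2 contents (an overshoot guard that is inactive at the default
coefficients).  After the fluxes, each
compartment re-equilibrates its CO2 pools (Stewart charge balance +
Henderson-Hasselbalch) under its updated strong-ion difference and total
CO2 content.  The steady-state counter-current profile is found by damped
fixed-point sweeps; mass is conserved species-by-species by construction
at convergence.

The membrane coefficients below are synthetic calibration fixtures: no
transport data exist for the bench dialyzer, so defaults were fixed once
so the simulated removal reproduces the scale of the bench measurements
(see docs/methods.md).  They are configuration, not measured claims.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    AcidBaseState,
    IonComposition,
    _equilibrate_profile_warm,
    dissolved_co2,
    equilibrate_fluid,
    equilibrate_profile,
    hh_bicarbonate,
    sid_from_ions,
    solve_ph,
)
from .constants import DEFAULT_CONSTANTS, EquilibriumConstants
from .errors import ConvergenceError, StabilityError, ValidationError
from .fixtures import table1_composition
from .removal import BloodGasRecord, FlowCondition

__all__ = [
    "FluidState",
    "ConditionedBlood",
    "RigConfig",
    "SinglePassResult",
    "SimulatedExperiment",
    "plasma_like_ions",
    "condition_inlet_blood",
    "simulate_single_pass",
    "run_experiment_grid",
    "bench_grid",
    "default_rig_config",
    "BLOOD_SID",
    "BLOOD_ATOT",
]

_STRONG = ("na", "k", "ca", "mg", "cl", "lactate")

#: whole-blood-like defaults for the conditioned bench blood, treating the
#: sample as one well-mixed compartment: the weak-acid pool lumps plasma
#: proteins, phosphate and hemoglobin (the dominant non-bicarbonate buffer)
#: into a single-Ka Atot, and the SID is the effective whole-blood value
#: that puts the inlet pH near the measured pre-dialyzer levels (~7.18 at
#: pCO2 50 mmHg, ~6.98 at 100 mmHg).
BLOOD_SID = 55.0
BLOOD_ATOT = 50.0

#: synthetic calibration fixtures for the bench dialyzer (mL/min); see
#: module docstring.
DEFAULT_K0A = {
    "na": 0.5,
    "k": 0.5,
    "ca": 0.0,
    "mg": 0.5,
    "cl": 0.75,
    "lactate": 0.5,
    "hco3": 1.5,
}
DEFAULT_CO2_PERMEANCE = 0.025  # mL gas/(min mmHg)


@dataclass(frozen=True)
class FluidState:
    """A flowing fluid parcel: strong-ion composition, weak-acid pool
    (mmol/L) and total CO2 content (mmol/L)."""

    ions: IonComposition
    atot: float
    total_co2: float

    @property
    def sid(self) -> float:
        return sid_from_ions(self.ions)

    def equilibrium(self, k: EquilibriumConstants = DEFAULT_CONSTANTS) -> AcidBaseState:
        return equilibrate_fluid(self.total_co2, self.sid, self.atot, k)


@dataclass(frozen=True)
class ConditionedBlood:
    """Inlet blood after conditioning by the oxygenator."""

    state: AcidBaseState
    ions: IonComposition
    hemoglobin: float  # g/dL

    def as_fluid(self) -> FluidState:
        return FluidState(ions=self.ions, atot=self.state.atot,
                          total_co2=self.state.total_co2)


@dataclass(frozen=True)
class RigConfig:
    """Geometry, flows, transport coefficients and noise for one run."""

    qb: float  # blood flow, mL/min
    qd: float  # dialysate flow, mL/min
    blood_inlet: FluidState
    dialysate_inlet: FluidState
    n_segments: int = 50
    membrane_area: float = 0.04  # m^2 (bench dialyzer)
    k0a: dict = field(default_factory=lambda: dict(DEFAULT_K0A))
    co2_permeance: float = DEFAULT_CO2_PERMEANCE
    noise_ph: float = 0.01
    noise_pco2: float = 1.0
    seed: int = 0
    tol: float = 1e-8
    max_sweeps: int = 10_000
    relaxation: float = 0.5

    def __post_init__(self) -> None:
        if not (self.qb > 0 and self.qd > 0):
            raise ValidationError(f"flows must be > 0, got qb={self.qb!r} qd={self.qd!r}")
        if self.n_segments < 1:
            raise ValidationError(f"n_segments must be >= 1, got {self.n_segments!r}")
        for s, v in self.k0a.items():
            if v < 0:
                raise ValidationError(f"k0a[{s!r}] must be >= 0, got {v!r}")
        if self.co2_permeance < 0:
            raise ValidationError(f"co2_permeance must be >= 0, got {self.co2_permeance!r}")
        if not (0 < self.relaxation <= 1):
            raise ValidationError(f"relaxation must lie in (0, 1], got {self.relaxation!r}")

    def config_hash(self) -> str:
        payload = {
            "qb": self.qb, "qd": self.qd, "n_segments": self.n_segments,
            "membrane_area": self.membrane_area,
            "k0a": {s: self.k0a.get(s, 0.0) for s in sorted(set(self.k0a) | set(_STRONG) | {"hco3"})},
            "co2_permeance": self.co2_permeance,
            "noise_ph": self.noise_ph, "noise_pco2": self.noise_pco2,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SinglePassResult:
    """Converged steady state of one pass plus a species flux ledger.

    ``ledger`` rows are per species (the six strong ions and total CO2):
    blood-side mass loss and dialysate-side gain in mmol/min, equal at
    convergence.
    """

    blood_out: FluidState
    blood_out_state: AcidBaseState
    dialysate_out: FluidState
    dialysate_out_state: AcidBaseState
    ledger: pd.DataFrame
    sweeps: int


def plasma_like_ions(sid: float = BLOOD_SID) -> IonComposition:
    """A plasma-like strong-ion composition carrying the requested SID,
    chloride acting as the balancing anion."""
    na, k, ca, mg, lactate = 140.0, 4.0, 2.2, 0.9, 1.0
    cl = na + k + 2 * ca + 2 * mg - lactate - sid
    if cl < 0:
        raise ValidationError(f"sid {sid!r} infeasible for plasma-like ions")
    return IonComposition(na=na, k=k, ca=ca, mg=mg, cl=cl, lactate=lactate)


def condition_inlet_blood(
    target_pco2: float,
    tolerance: float = 5.0,
    hb_target: float = 12.0,
    hb_tolerance: float = 1.0,
    sid: float = BLOOD_SID,
    atot: float = BLOOD_ATOT,
    rng: np.random.Generator | int | None = None,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> ConditionedBlood:
    """Draw one conditioned inlet blood sample.

    Inlet pCO2 is uniform in target +/- tolerance and hemoglobin uniform
    in hb_target +/- hb_tolerance (the dilution targets of the bench
    protocol); pH follows from the Stewart balance at the plasma-like SID
    and Atot.  Deterministic for a fixed rng/seed.
    """
    if tolerance < 0:
        raise ValidationError(f"tolerance must be >= 0, got {tolerance!r}")
    if hb_tolerance < 0:
        raise ValidationError(f"hb_tolerance must be >= 0, got {hb_tolerance!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pco2 = float(rng.uniform(target_pco2 - tolerance, target_pco2 + tolerance))
    hb = float(rng.uniform(hb_target - hb_tolerance, hb_target + hb_tolerance))
    ph = solve_ph(sid, pco2, atot, k)
    state = AcidBaseState(
        ph=ph, pco2=pco2, hco3=hh_bicarbonate(ph, pco2, k), sid=sid, atot=atot,
        dissolved_co2=dissolved_co2(pco2, k),
        total_co2=dissolved_co2(pco2, k) + hh_bicarbonate(ph, pco2, k),
    )
    return ConditionedBlood(state=state, ions=plasma_like_ions(sid), hemoglobin=hb)


def default_dialysate_inlet() -> FluidState:
    """The HCl-acidified zero-bicarbonate dialysate, CO2-free."""
    comp = table1_composition(final=True)
    return FluidState(ions=comp, atot=comp.phosphate, total_co2=0.0)


def default_rig_config(
    qb: float,
    qd: float,
    blood: ConditionedBlood | FluidState,
    **overrides,
) -> RigConfig:
    if isinstance(blood, ConditionedBlood):
        blood = blood.as_fluid()
    return RigConfig(qb=qb, qd=qd, blood_inlet=blood,
                     dialysate_inlet=default_dialysate_inlet(), **overrides)


def _ion_vec(comp: IonComposition) -> np.ndarray:
    return np.array([getattr(comp, s) for s in _STRONG], dtype=float)


def simulate_single_pass(
    cfg: RigConfig, k: EquilibriumConstants = DEFAULT_CONSTANTS
) -> SinglePassResult:
    """Solve the steady-state counter-current profile for one condition.

    Blood traverses segments 0..n-1; dialysate enters at segment n-1.
    Damped fixed-point iteration on the axial profiles of both streams:
    each sweep computes per-segment fluxes from the current entering
    states, rebuilds both profiles by cumulative mass balance, and
    re-equilibrates the CO2 pools (vectorised).  Convergence when the
    largest profile change falls below ``cfg.tol`` (relative).
    """
    n = cfg.n_segments
    qb, qd = cfg.qb, cfg.qd
    q_tilde = qb * qd / (qb + qd)  # flow-weighted exchange capacity, mL/min
    k0a_seg = np.array([cfg.k0a.get(s, 0.0) for s in _STRONG]) / n
    # analytic co-current exchange fraction per segment and species
    f_ion = -np.expm1(-k0a_seg / q_tilde)
    f_hco3 = -np.expm1(-(cfg.k0a.get("hco3", 0.0) / n) / q_tilde)
    perm = cfg.co2_permeance / n

    def _fluxes(b_ion, d_ion, hco3_b, hco3_d, pco2_b, pco2_d, b_tc, d_tc, k):
        j_ion = f_ion[None, :] * q_tilde * (b_ion - d_ion)
        j_raw = (f_hco3 * q_tilde * (hco3_b - hco3_d)
                 + perm * (pco2_b - pco2_d) / k.vm * 1000.0)
        cap = q_tilde * (b_tc - d_tc)
        j_co2 = np.where(
            j_raw * cap > 0,
            np.sign(j_raw) * np.minimum(np.abs(j_raw), np.abs(cap)),
            j_raw,
        )
        return j_ion, j_co2

    b_ion_in = _ion_vec(cfg.blood_inlet.ions)
    d_ion_in = _ion_vec(cfg.dialysate_inlet.ions)
    b_tc_in = cfg.blood_inlet.total_co2
    d_tc_in = cfg.dialysate_inlet.total_co2
    atot_b = cfg.blood_inlet.atot
    atot_d = cfg.dialysate_inlet.atot
    z = np.array([+1, +1, +2, +2, -1, -1], dtype=float)

    # profiles of states *entering* each segment
    b_ion = np.tile(b_ion_in, (n, 1))
    d_ion = np.tile(d_ion_in, (n, 1))
    b_tc = np.full(n, b_tc_in)
    d_tc = np.full(n, d_tc_in)

    # damped Picard iteration; the damping factor adapts downward whenever
    # the fixed-point residual grows (counter-current feedback can have
    # gain > 1 at high NTU) and creeps back up while it shrinks
    alpha = cfg.relaxation
    prev_change = np.inf
    sweeps = 0
    ph_b, pco2_b, hco3_b = equilibrate_profile(b_tc, b_ion @ z, atot_b, k)
    ph_d, pco2_d, hco3_d = equilibrate_profile(d_tc, d_ion @ z, atot_d, k)
    for sweeps in range(1, cfg.max_sweeps + 1):
        ph_b, pco2_b, hco3_b = _equilibrate_profile_warm(b_tc, b_ion @ z, atot_b, k, ph_b)
        ph_d, pco2_d, hco3_d = _equilibrate_profile_warm(d_tc, d_ion @ z, atot_d, k, ph_d)

        j_ion, j_co2 = _fluxes(b_ion, d_ion, hco3_b, hco3_d,
                               pco2_b, pco2_d, b_tc, d_tc, k)

        cum_ion = np.vstack([np.zeros(6), np.cumsum(j_ion, axis=0)])
        cum_co2 = np.concatenate([[0.0], np.cumsum(j_co2)])
        b_ion_new = b_ion_in[None, :] - cum_ion[:-1] / qb
        b_tc_new = b_tc_in - cum_co2[:-1] / qb
        # dialysate entering segment i carries fluxes picked up in i+1..n-1
        rev_ion = cum_ion[-1][None, :] - cum_ion[1:]
        rev_co2 = cum_co2[-1] - cum_co2[1:]
        d_ion_new = d_ion_in[None, :] + rev_ion / qd
        d_tc_new = d_tc_in + rev_co2 / qd

        # transients may overshoot; only the converged state must be positive
        b_tc_new = np.clip(b_tc_new, 0.0, None)
        d_tc_new = np.clip(d_tc_new, 0.0, None)
        b_ion_new = np.clip(b_ion_new, 0.0, None)
        d_ion_new = np.clip(d_ion_new, 0.0, None)

        change = max(
            np.max(np.abs(b_ion_new - b_ion) / (np.abs(b_ion) + 1.0)),
            np.max(np.abs(d_ion_new - d_ion) / (np.abs(d_ion) + 1.0)),
            np.max(np.abs(b_tc_new - b_tc) / (np.abs(b_tc) + 1.0)),
            np.max(np.abs(d_tc_new - d_tc) / (np.abs(d_tc) + 1.0)),
        )
        if change > prev_change:
            alpha = max(alpha * 0.5, 1e-3)
        else:
            alpha = min(alpha * 1.05, cfg.relaxation)
        prev_change = change
        b_ion = alpha * b_ion_new + (1 - alpha) * b_ion
        d_ion = alpha * d_ion_new + (1 - alpha) * d_ion
        b_tc = alpha * b_tc_new + (1 - alpha) * b_tc
        d_tc = alpha * d_tc_new + (1 - alpha) * d_tc
        if change <= cfg.tol:
            break
    if change > cfg.tol:
        raise ConvergenceError(
            f"single-pass sweep did not converge in {cfg.max_sweeps} sweeps",
            diagnostics={"sweeps": cfg.max_sweeps, "residual": float(change)},
        )

    # final fluxes from the converged entering profiles; applying the same
    # sums to both outlets makes the ledger balance to machine precision
    _, pco2_b, hco3_b = equilibrate_profile(b_tc, b_ion @ z, atot_b, k)
    _, pco2_d, hco3_d = equilibrate_profile(d_tc, d_ion @ z, atot_d, k)
    del ph_b, ph_d
    j_ion, j_co2 = _fluxes(b_ion, d_ion, hco3_b, hco3_d,
                           pco2_b, pco2_d, b_tc, d_tc, k)
    tot_ion = j_ion.sum(axis=0)
    tot_co2 = j_co2.sum()

    b_out_ion = b_ion_in - tot_ion / qb
    d_out_ion = d_ion_in + tot_ion / qd
    b_out_tc = b_tc_in - tot_co2 / qb
    d_out_tc = d_tc_in + tot_co2 / qd
    if min(b_out_ion.min(), d_out_ion.min(), b_out_tc, d_out_tc) < -1e-9:
        raise StabilityError(
            "negative outlet concentration; increase n_segments",
            diagnostics={"blood_out": b_out_ion.tolist(), "total_co2": float(b_out_tc)},
        )
    b_out_tc = max(b_out_tc, 0.0)
    d_out_tc = max(d_out_tc, 0.0)

    def _comp(vec: np.ndarray, phosphate: float) -> IonComposition:
        vals = {s: max(float(v), 0.0) for s, v in zip(_STRONG, vec)}
        return IonComposition(**vals, phosphate=phosphate)

    blood_out = FluidState(
        ions=_comp(b_out_ion, cfg.blood_inlet.ions.phosphate),
        atot=atot_b, total_co2=float(b_out_tc),
    )
    dial_out = FluidState(
        ions=_comp(d_out_ion, cfg.dialysate_inlet.ions.phosphate),
        atot=atot_d, total_co2=float(d_out_tc),
    )

    species = list(_STRONG) + ["total_co2"]
    blood_loss = np.append(
        qb * (b_ion_in - b_out_ion), qb * (b_tc_in - float(b_out_tc))
    ) / 1000.0  # mmol/min
    dial_gain = np.append(
        qd * (d_out_ion - d_ion_in), qd * (float(d_out_tc) - d_tc_in)
    ) / 1000.0
    ledger = pd.DataFrame(
        {"species": species, "blood_loss_mmol_min": blood_loss,
         "dialysate_gain_mmol_min": dial_gain}
    )
    return SinglePassResult(
        blood_out=blood_out,
        blood_out_state=blood_out.equilibrium(k),
        dialysate_out=dial_out,
        dialysate_out_state=dial_out.equilibrium(k),
        ledger=ledger,
        sweeps=sweeps,
    )


@dataclass(frozen=True)
class SimulatedExperiment:
    """A generated bench dataset: matched pre/post records over a grid."""

    conditions: tuple
    replicates: int
    records: tuple
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        """Records in the blood-gas CSV schema consumed by the removal
        analysis (condition_id, flows, side, replicate, ph, pco2_mmHg...)."""
        cond_by_id = {c.condition_id: c for c in self.conditions}
        rows = []
        for r in self.records:
            c = cond_by_id[r.condition_id]
            rows.append(
                {
                    "condition_id": r.condition_id,
                    "qb_ml_min": c.qb,
                    "qd_ml_min": c.qd,
                    "inlet_pco2_target": c.inlet_pco2_target,
                    "side": r.side,
                    "replicate": r.replicate,
                    "ph": r.ph,
                    "pco2_mmHg": r.pco2,
                    "hb_g_dl": r.hemoglobin,
                }
            )
        return pd.DataFrame(rows)


#: dialysate flows of the bench grid, mL/min
BENCH_QD_GRID = (2.2, 3.0, 8.0, 11.5, 16.0, 20.0, 24.0)
#: (qb, inlet pCO2) pairs with their Table-2-populated dialysate flows
_BENCH_SUBSET = {
    (11.0, 50.0): (3.0, 8.0, 11.5, 16.0, 20.0),
    (11.0, 100.0): (3.0, 8.0, 11.5, 16.0, 20.0, 24.0),
    (18.7, 50.0): (2.2, 3.0, 8.0, 11.5, 16.0),
}


def bench_grid(bench_subset: bool = False) -> list[FlowCondition]:
    """The bench flow grid.

    The full cross is qb {11, 18.7} x inlet pCO2 {50, 100} x the seven
    dialysate flows; ``bench_subset=True`` restricts to the cells the bench
    study actually ran (the populated pH-table cells).
    """
    if bench_subset:
        return [
            FlowCondition(qb=qb, qd=qd, inlet_pco2_target=inlet)
            for (qb, inlet), qds in _BENCH_SUBSET.items()
            for qd in qds
        ]
    return [
        FlowCondition(qb=qb, qd=qd, inlet_pco2_target=inlet)
        for qb in (11.0, 18.7)
        for inlet in (50.0, 100.0)
        for qd in BENCH_QD_GRID
    ]


def run_experiment_grid(
    conditions: Sequence[FlowCondition],
    replicates: int = 3,
    template: RigConfig | None = None,
    seed: int = 0,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> SimulatedExperiment:
    """Simulate the full bench campaign.

    For every condition x replicate: condition fresh inlet blood, run the
    single-pass model, then overlay Gaussian measurement noise (sd
    ``noise_ph`` / ``noise_pco2``) on the recorded pre and post pH and
    pCO2.  One global random stream seeded from ``seed``; per replicate the
    draw order is inlet pCO2, hemoglobin, then the four noise terms
    (pre pH, pre pCO2, post pH, post pCO2).
    """
    if not conditions and replicates > 0:
        raise ValidationError("conditions must be non-empty")
    rng = np.random.default_rng(seed)
    if template is None:
        template = default_rig_config(
            qb=11.0, qd=16.0, blood=FluidState(
                ions=plasma_like_ions(), atot=BLOOD_ATOT, total_co2=20.0),
        )
    records: list[BloodGasRecord] = []
    for cond in conditions:
        for rep in range(replicates):
            blood = condition_inlet_blood(
                cond.inlet_pco2_target, rng=rng, k=k,
                sid=sid_from_ions(template.blood_inlet.ions),
                atot=template.blood_inlet.atot,
            )
            cfg = replace(template, qb=cond.qb, qd=cond.qd,
                          blood_inlet=blood.as_fluid())
            result = simulate_single_pass(cfg, k)
            pre, post = blood.state, result.blood_out_state
            noise = rng.normal(size=4) * np.array(
                [template.noise_ph, template.noise_pco2,
                 template.noise_ph, template.noise_pco2]
            )
            records.append(BloodGasRecord(
                condition_id=cond.condition_id, side="pre", replicate=rep,
                ph=pre.ph + noise[0], pco2=max(pre.pco2 + noise[1], 1e-6),
                hemoglobin=blood.hemoglobin,
            ))
            records.append(BloodGasRecord(
                condition_id=cond.condition_id, side="post", replicate=rep,
                ph=post.ph + noise[2], pco2=max(post.pco2 + noise[3], 1e-6),
                hemoglobin=blood.hemoglobin,
            ))
    return SimulatedExperiment(
        conditions=tuple(conditions),
        replicates=replicates,
        records=tuple(records),
        provenance={"seed": seed, "config_hash": template.config_hash()},
    )
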