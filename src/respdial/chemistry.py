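"""Stewart physicochemical acid-base engine.

The central relation is the plasma charge balance written with [H+] as the
only unknown ("the Stewart equation"):

    SID = kc*pCO2/[H+] + 2*kc*k3*pCO2/[H+]^2 + kw/[H+]
          + ka*Atot/(ka + [H+]) - [H+]

where SID is the strong ion difference (mol/L here; mEq/L at the package
interface), pCO2 the CO2 tension in mmHg and Atot the total non-volatile
weak-acid pool.  The right-hand side is strictly decreasing in [H+], so the
inverse problem (pH from SID, pCO2, Atot) has a unique root, found by
bracketed root-finding on pH in [0, 14].

Bicarbonate *content* is computed with the Henderson-Hasselbalch equation
[HCO3-] = ks * pCO2 * 10**(pH - pK'), the same convention a blood-gas
analyzer uses.  Carbonate carries charge in the Stewart balance but is
excluded from CO2 content accounting (its share is <0.5% at relevant pCO2).

Concentrations are mmol/L (mEq/L for charges) at every public interface and
are converted to mol/L exactly once, inside this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, EquilibriumConstants
from .errors import ConvergenceError, DomainError, ValidationError

__all__ = [
    "IonComposition",
    "AcidBaseState",
    "sid_from_ions",
    "stewart_sid",
    "solve_ph",
    "hh_bicarbonate",
    "dissolved_co2",
    "equilibrate_fluid",
    "equilibrate_profile",
]

ArrayLike = Union[float, np.ndarray]

#: ion -> charge used in the strong-ion difference; phosphate and hco3 are
#: deliberately absent (phosphate enters as Atot, bicarbonate is dependent).
STRONG_ION_CHARGES = {
    "na": +1,
    "k": +1,
    "ca": +2,
    "mg": +2,
    "cl": -1,
    "lactate": -1,
}


@dataclass(frozen=True)
class IonComposition:
    """Strong-ion and weak-acid make-up of a fluid (plasma or dialysate).

    All concentrations in mmol/L.  ``phosphate`` is treated as the weak-acid
    pool Atot of the fluid; ``hco3`` is carried for input/reporting only and
    never enters the charge balance, where bicarbonate is a dependent ion.
    """

    na: float = 0.0
    k: float = 0.0
    ca: float = 0.0
    mg: float = 0.0
    cl: float = 0.0
    lactate: float = 0.0
    phosphate: float = 0.0
    hco3: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "meta":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValidationError(f"ion {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValidationError(f"ion {f.name!r} must be >= 0, got {v!r}")

    def replace(self, **changes) -> "IonComposition":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class AcidBaseState:
    """A fluid at acid-base equilibrium.

    ph is dimensionless, pco2 in mmHg, concentrations in mmol/L, sid in
    mEq/L.  total_co2 = dissolved_co2 + hco3 (carbonate excluded).
    """

    ph: float
    pco2: float
    hco3: float
    sid: float
    atot: float
    dissolved_co2: float
    total_co2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ph < 14.0):
            raise ValidationError(f"ph must lie in (0, 14), got {self.ph!r}")
        if self.pco2 < 0:
            raise ValidationError(f"pco2 must be >= 0, got {self.pco2!r}")
        if self.hco3 < 0:
            raise ValidationError(f"hco3 must be >= 0, got {self.hco3!r}")

    @property
    def h(self) -> float:
        """Hydrogen-ion activity, mol/L."""
        return 10.0 ** (-self.ph)


def sid_from_ions(comp: IonComposition) -> float:
    """Strong ion difference of a composition, mEq/L.

    Charge sum na + k + 2*ca + 2*mg - cl - lactate; phosphate (weak acid)
    and hco3 (dependent) are excluded.
    """
    return float(
        sum(z * getattr(comp, ion) for ion, z in STRONG_ION_CHARGES.items())
    )


def _charge_excess(
    h: ArrayLike, pco2: ArrayLike, atot_mol: ArrayLike, k: EquilibriumConstants
) -> ArrayLike:
    """Net anion-minus-cation charge of the dependent species, mol/L.

    Equals the SID the fluid must carry to be electroneutral at the given
    [H+] and pCO2.  Array-aware: used both by the scalar API and the
    vectorised per-segment equilibration in the rig simulator.
    """
    bicarb = k.kc * pco2 / h
    carbonate = 2.0 * k.kc * k.k3 * pco2 / (h * h)
    hydroxide = k.kw / h
    weak_acid = k.ka * atot_mol / (k.ka + h)
    return bicarb + carbonate + hydroxide + weak_acid - h


def stewart_sid(
    h: float,
    pco2: float,
    atot: float,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> float:
    """Evaluate the Stewart charge balance: the SID (mol/L) consistent with
    hydrogen-ion activity ``h`` (mol/L), ``pco2`` (mmHg) and ``atot``
    (mmol/L).

    Strictly decreasing in ``h`` for fixed other arguments.
    """
    if not (h > 0):
        raise DomainError(f"[H+] must be > 0, got {h!r}")
    if pco2 < 0:
        raise ValidationError(f"pco2 must be >= 0, got {pco2!r}")
    if atot < 0:
        raise ValidationError(f"atot must be >= 0, got {atot!r}")
    return float(_charge_excess(h, pco2, atot / 1000.0, k))


def solve_ph(
    sid: float,
    pco2: float,
    atot: float,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> float:
    """pH of a fluid with strong ion difference ``sid`` (mEq/L), ``pco2``
    (mmHg) and weak-acid pool ``atot`` (mmol/L).

    Solves the Stewart charge balance for [H+] by bracketed root-finding on
    pH in [0, 14]; the root is unique by monotonicity.
    """
    if not math.isfinite(sid):
        raise ValidationError(f"sid must be finite, got {sid!r}")
    if pco2 < 0:
        raise ValidationError(f"pco2 must be >= 0, got {pco2!r}")
    if atot < 0:
        raise ValidationError(f"atot must be >= 0, got {atot!r}")
    sid_mol = sid / 1000.0
    atot_mol = atot / 1000.0

    def residual(ph: float) -> float:
        return _charge_excess(10.0 ** (-ph), pco2, atot_mol, k) - sid_mol

    lo, hi = residual(0.0), residual(14.0)
    if not (lo < 0.0 < hi):
        raise ConvergenceError(
            "Stewart root not bracketed in pH [0, 14]",
            diagnostics={"residual_ph0": lo, "residual_ph14": hi},
        )
    return float(brentq(residual, 0.0, 14.0, xtol=1e-13, maxiter=200))


def hh_bicarbonate(
    ph: float, pco2: float, k: EquilibriumConstants = DEFAULT_CONSTANTS
) -> float:
    """Henderson-Hasselbalch bicarbonate, mmol/L: ks * pCO2 * 10**(pH - pK')."""
    if pco2 < 0:
        raise ValidationError(f"pco2 must be >= 0, got {pco2!r}")
    return k.ks * pco2 * 10.0 ** (ph - k.pk_hh)


def dissolved_co2(pco2: float, k: EquilibriumConstants = DEFAULT_CONSTANTS) -> float:
    """Physically dissolved CO2, mmol/L: ks * pCO2."""
    if pco2 < 0:
        raise ValidationError(f"pco2 must be >= 0, got {pco2!r}")
    return k.ks * pco2


def _state_from_ph_pco2(
    ph: float, pco2: float, sid: float, atot: float, k: EquilibriumConstants
) -> AcidBaseState:
    dis = dissolved_co2(pco2, k)
    bic = hh_bicarbonate(ph, pco2, k)
    return AcidBaseState(
        ph=ph,
        pco2=pco2,
        hco3=bic,
        sid=sid,
        atot=atot,
        dissolved_co2=dis,
        total_co2=dis + bic,
    )


def equilibrate_fluid(
    total_co2: float,
    sid: float,
    atot: float,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> AcidBaseState:
    """Partition a fixed CO2 content into dissolved CO2 and bicarbonate.

    Given total CO2 content (mmol/L), strong ion difference (mEq/L) and
    Atot (mmol/L), finds the unique (pH, pCO2) such that

    * dissolved + bicarbonate equals ``total_co2``,
    * bicarbonate follows Henderson-Hasselbalch, and
    * the Stewart charge balance holds.

    pCO2 is eliminated via pCO2 = total_co2 / (ks * (1 + 10**(pH - pK')))
    and the remaining scalar equation is solved for pH.  This is the
    re-equilibration step the rig simulator applies after transmembrane
    fluxes change a compartment's CO2 content or SID.
    """
    if total_co2 < 0:
        raise ValidationError(f"total_co2 must be >= 0, got {total_co2!r}")
    if total_co2 == 0.0:
        ph = solve_ph(sid, 0.0, atot, k)
        return _state_from_ph_pco2(ph, 0.0, sid, atot, k)

    sid_mol = sid / 1000.0
    atot_mol = atot / 1000.0

    def pco2_of(ph: float) -> float:
        return total_co2 / (k.ks * (1.0 + 10.0 ** (ph - k.pk_hh)))

    def residual(ph: float) -> float:
        return _charge_excess(10.0 ** (-ph), pco2_of(ph), atot_mol, k) - sid_mol

    lo, hi = residual(0.0), residual(14.0)
    if not (lo < 0.0 < hi):
        raise ConvergenceError(
            "closed-system equilibration not bracketed in pH [0, 14]",
            diagnostics={"residual_ph0": lo, "residual_ph14": hi},
        )
    ph = float(brentq(residual, 0.0, 14.0, xtol=1e-13, maxiter=200))
    state = _state_from_ph_pco2(ph, pco2_of(ph), sid, atot, k)
    imbalance = abs(residual(ph))
    if imbalance > 1e-9:
        raise ConvergenceError(
            "charge imbalance after equilibration exceeds 1e-9 mol/L",
            diagnostics={"imbalance_mol_L": imbalance, "ph": ph},
        )
    return state


def equilibrate_profile(
    total_co2: np.ndarray,
    sid: np.ndarray,
    atot: np.ndarray,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
    n_iter: int = 80,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised closed-system equilibration over arrays of fluid parcels.

    Same chemistry as :func:`equilibrate_fluid`, solved by fixed-count
    bisection on pH in [0, 14] (80 halvings bring the bracket below 1e-22
    pH units, far inside the scalar solver's tolerance).  Returns
    ``(ph, pco2, hco3)`` arrays in the interface units.  Used by the rig
    simulator, which must re-equilibrate every segment each sweep.
    """
    total_co2 = np.asarray(total_co2, dtype=float)
    sid_mol = np.asarray(sid, dtype=float) / 1000.0
    atot_mol = np.asarray(atot, dtype=float) / 1000.0
    if np.any(total_co2 < 0):
        raise ValidationError("total_co2 must be >= 0 everywhere in the profile")

    with np.errstate(divide="ignore", over="ignore"):

        def residual(ph: np.ndarray) -> np.ndarray:
            h = 10.0 ** (-ph)
            pco2 = total_co2 / (k.ks * (1.0 + 10.0 ** (ph - k.pk_hh)))
            return _charge_excess(h, pco2, atot_mol, k) - sid_mol

        lo = np.zeros_like(total_co2 + sid_mol)
        hi = np.full_like(lo, 14.0)
        if np.any(residual(lo) >= 0) or np.any(residual(hi) <= 0):
            raise ConvergenceError("profile equilibration not bracketed in pH [0, 14]")
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            neg = residual(mid) < 0
            lo = np.where(neg, mid, lo)
            hi = np.where(neg, hi, mid)
    ph = 0.5 * (lo + hi)
    pco2 = total_co2 / (k.ks * (1.0 + 10.0 ** (ph - k.pk_hh)))
    hco3 = k.ks * pco2 * 10.0 ** (ph - k.pk_hh)
    return ph, pco2, hco3


_LN10 = math.log(10.0)


def _equilibrate_profile_warm(
    total_co2: np.ndarray,
    sid: np.ndarray,
    atot: ArrayLike,
    k: EquilibriumConstants,
    ph0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warm-started Newton variant of :func:`equilibrate_profile`.

    The closed-system residual is strictly increasing in pH, so damped
    Newton from the previous sweep's pH profile converges in a few
    iterations; parcels that fail to reach |residual| < 1e-15 mol/L fall
    back to the bisection solver.  Internal fast path for the simulator.
    """
    total_co2 = np.asarray(total_co2, dtype=float)
    sid_mol = np.asarray(sid, dtype=float) / 1000.0
    atot_mol = np.asarray(atot, dtype=float) / 1000.0
    ph = np.clip(np.asarray(ph0, dtype=float).copy(), 0.5, 13.5)

    def g_and_dg(ph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = 10.0 ** (-ph)
        e = 10.0 ** (ph - k.pk_hh)
        pco2 = total_co2 / (k.ks * (1.0 + e))
        g = _charge_excess(h, pco2, atot_mol, k) - sid_mol
        dpco2 = -_LN10 * pco2 * e / (1.0 + e)
        dg = (
            (k.kc / h) * (dpco2 + _LN10 * pco2)
            + (2.0 * k.kc * k.k3 / (h * h)) * (dpco2 + 2.0 * _LN10 * pco2)
            + _LN10 * k.kw / h
            + _LN10 * h * k.ka * atot_mol / (k.ka + h) ** 2
            + _LN10 * h
        )
        return g, dg

    for _ in range(12):
        g, dg = g_and_dg(ph)
        step = np.clip(g / dg, -1.0, 1.0)
        ph = np.clip(ph - step, 0.0, 14.0)
        if np.max(np.abs(g)) < 1e-15:
            break
    g, _ = g_and_dg(ph)
    bad = np.abs(g) > 1e-15
    if np.any(bad):
        ph_b, _, _ = equilibrate_profile(
            total_co2[bad], np.asarray(sid, dtype=float)[bad],
            np.broadcast_to(np.asarray(atot, dtype=float), total_co2.shape)[bad], k
        )
        ph[bad] = ph_b
    pco2 = total_co2 / (k.ks * (1.0 + 10.0 ** (ph - k.pk_hh)))
    hco3 = k.ks * pco2 * 10.0 ** (ph - k.pk_hh)
    return ph, pco2, hco3
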