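"""Zero-bicarbonate dialysate design.

The design logic follows the Stewart view: post-dialyzer blood keeps a
normal pH as long as its strong ion difference and weak-acid pool are
preserved, even with bicarbonate and CO2 stripped out.  The designer
therefore (i) computes the SID the post-dialyzer blood must carry at the
target pH under low pCO2/bicarbonate, (ii) builds an electrolyte solution
with that SID from clinically fixed ion concentrations plus one balancing
anion (chloride by default, since dialysate sieving coefficients are ~1),
and (iii) optionally acidifies with HCl — raising chloride to a stated
final concentration — so the fluid can be read on a blood-gas analyzer.

A protein-free fluid with a physiological SID is strongly alkaline (the
weak-acid pool is only the small phosphate content), which is why the
modelled dialysate pH comes out near 10 despite the physiological SID
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import IonComposition, sid_from_ions, solve_ph, stewart_sid
from .constants import DEFAULT_CONSTANTS, EquilibriumConstants
from .errors import DesignError, ValidationError

__all__ = [
    "DesignConstraints",
    "PUBLISHED_DESIGN",
    "required_blood_sid",
    "design_dialysate",
    "hcl_adjust",
    "dialysate_ph",
]

_CATION_CHARGE = {"na": +1, "k": +1, "ca": +2, "mg": +2}
_ANION_CHARGE = {"cl": -1, "lactate": -1}


@dataclass(frozen=True)
class DesignConstraints:
    """Constraints for the dialysate designer.

    ``fixed_ions`` holds ion name -> mmol/L set by clinical choice;
    ``adjustable_ions`` is the (cation, anion) pair used to hit the target
    SID and is disjoint from the fixed set — starting concentrations for
    adjustable ions live in ``adjustable_start``.  By convention the anion
    is solved from the charge balance while the cation keeps its starting
    level.  ``target_sid`` (mEq/L) overrides derivation from the blood-side
    targets when given.  The blood-side targets express the post-dialyzer
    condition: pH within ``target_ph_range`` while bicarbonate stays below
    ``max_hco3`` and pCO2 below ``max_pco2``.
    """

    target_ph_range: tuple[float, float] = (7.35, 7.45)
    max_hco3: float = 10.0
    max_pco2: float = 20.0
    fixed_ions: dict = field(
        default_factory=lambda: {
            "k": 3.5,
            "mg": 1.0,
            "lactate": 3.0,
            "phosphate": 0.5,
        }
    )
    adjustable_ions: tuple[str, str] = ("na", "cl")
    adjustable_start: dict = field(default_factory=lambda: {"na": 134.0})
    calcium_zero: bool = True
    target_sid: float | None = None
    blood_atot: float = 17.2
    design_pco2: float = 15.0

    def __post_init__(self) -> None:
        low, high = self.target_ph_range
        if not low < high:
            raise ValidationError(
                f"target_ph_range must satisfy low < high, got {self.target_ph_range!r}"
            )
        overlap = set(self.adjustable_ions) & set(self.fixed_ions)
        if overlap:
            raise ValidationError(
                f"adjustable ions must be disjoint from fixed ions; both contain {sorted(overlap)}"
            )


#: The published design: fixed ions and an explicit target SID of 20.5 mEq/L
#: (the authors' modelled ideal post-dialyzer blood composition).
PUBLISHED_DESIGN = DesignConstraints(target_sid=20.5)


def required_blood_sid(
    target_ph: float,
    pco2: float,
    atot: float,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> float:
    """SID (mEq/L) the post-dialyzer blood must carry to sit at
    ``target_ph`` with the given ``pco2`` (mmHg) and ``atot`` (mmol/L)."""
    if not (0.0 < target_ph < 14.0):
        raise ValidationError(f"target_ph must lie in (0, 14), got {target_ph!r}")
    return stewart_sid(10.0 ** (-target_ph), pco2, atot, k) * 1000.0


def design_dialysate(
    constraints: DesignConstraints = PUBLISHED_DESIGN,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> IonComposition:
    """Build the zero-bicarbonate dialysate composition.

    Fixed ions keep their set values, calcium is zeroed when requested
    (citrate-anticoagulation compatibility; also precipitation risk at the
    alkaline dialysate pH), bicarbonate is always 0, and the balancing
    anion is solved so the composition's charge SID equals the target.
    Raises :class:`DesignError` if the balancing anion would go negative.
    """
    target = constraints.target_sid
    if target is None:
        low, high = constraints.target_ph_range
        target = required_blood_sid(
            0.5 * (low + high), constraints.design_pco2, constraints.blood_atot, k
        )

    cation, balance_anion = constraints.adjustable_ions
    if balance_anion not in _ANION_CHARGE:
        raise ValidationError(
            f"balancing ion must be an anion ({sorted(_ANION_CHARGE)}), got {balance_anion!r}"
        )
    if cation not in _CATION_CHARGE:
        raise ValidationError(
            f"adjustable cation must be one of {sorted(_CATION_CHARGE)}, got {cation!r}"
        )

    values = dict(constraints.fixed_ions)
    for ion, v in constraints.adjustable_start.items():
        values.setdefault(ion, v)
    values.setdefault("ca", 0.0)
    if constraints.calcium_zero:
        values["ca"] = 0.0
    values["hco3"] = 0.0

    cation_charge = sum(
        z * values.get(ion, 0.0) for ion, z in _CATION_CHARGE.items()
    )
    other_anion_charge = sum(
        -z * values.get(ion, 0.0)
        for ion, z in _ANION_CHARGE.items()
        if ion != balance_anion
    )
    balance = cation_charge - other_anion_charge - target
    if balance < 0:
        raise DesignError(
            f"target SID {target:g} mEq/L infeasible: balancing ion "
            f"{balance_anion!r} would need {balance:g} mmol/L",
            ion=balance_anion,
        )
    values[balance_anion] = balance
    roles = {ion: "fixed" for ion in constraints.fixed_ions}
    roles.update({ion: "fixed" for ion in constraints.adjustable_start})
    roles[balance_anion] = "balanced"
    roles["hco3"] = "fixed"
    roles["ca"] = "fixed"
    return IonComposition(**values, meta={"roles": roles, "target_sid": target})


def hcl_adjust(comp: IonComposition, final_cl: float) -> IonComposition:
    """Add HCl by raising chloride to ``final_cl`` mmol/L.

    Everything else is unchanged; the amount of acid added is recorded in
    ``meta['added_hcl_mmol_per_L']``.  Used to acidify the dialysate so it
    can be measured on a blood-gas analyzer.
    """
    if final_cl < comp.cl:
        raise ValidationError(
            f"final_cl ({final_cl!r}) must be >= current chloride ({comp.cl!r})"
        )
    meta = dict(comp.meta)
    meta["added_hcl_mmol_per_L"] = final_cl - comp.cl
    roles = dict(meta.get("roles", {}))
    if final_cl > comp.cl:
        roles["cl"] = "adjusted"
    meta["roles"] = roles
    return comp.replace(cl=final_cl, meta=meta)


def dialysate_ph(
    comp: IonComposition,
    pco2: float = 0.0,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
) -> float:
    """Modelled pH of a dialysate composition at the given pCO2 (default 0,
    the CO2-free limit appropriate for a fluid with no bicarbonate).

    The composition's phosphate is its entire weak-acid pool.
    """
    return solve_ph(sid_from_ions(comp), pco2, comp.phosphate, k)
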