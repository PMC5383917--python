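"""Physicochemical equilibrium constants for the Stewart acid-base model.

All constants are kept in one explicit, overridable record so that every
speciation routine in the package draws from the same source.  The defaults
are the values used throughout the dialysate-design and CO2-removal
calculations; they refer to plasma at 37 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Any, Mapping

from .errors import ValidationError

__all__ = ["EquilibriumConstants", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Equilibrium and solubility constants used by the speciation engine.

    Attributes
    ----------
    kc : float
        Combined CO2 equilibrium/solubility constant, mol^2/(L^2 mmHg).
        Relates pCO2 directly to the bicarbonate charge term
        [HCO3-] = kc * pCO2 / [H+].
    k3 : float
        Second dissociation constant of carbonic acid, mol/L (carbonate).
    kw : float
        Autoionization constant of plasma water, mol^2/L^2.
    ka : float
        Single apparent dissociation constant of the non-volatile weak-acid
        pool A_tot, mol/L.
    ks : float
        CO2 solubility in blood, mmol/(L mmHg).
    vm : float
        Molar volume of CO2 gas at STP, mL/mmol.
    pk_hh : float
        Apparent pK' of the Henderson-Hasselbalch equation (dimensionless).
    """

    kc: float = 2.45e-11
    k3: float = 5.76e-11
    kw: float = 2.39e-14
    ka: float = 1.77e-7
    ks: float = 0.0307
    vm: float = 22.4
    pk_hh: float = 6.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValidationError(f"constant {f.name!r} must be positive, got {v!r}")

    def hh_consistency(self) -> float:
        """Relative disagreement between kc and (ks/1000) * 10**(-pk_hh).

        The bicarbonate charge term of the Stewart equation and the
        Henderson-Hasselbalch bicarbonate are the same chemistry written
        with different constants; with the defaults they agree to <1%.
        """
        implied_kc = (self.ks / 1000.0) * 10.0 ** (-self.pk_hh)
        return abs(self.kc - implied_kc) / self.kc

    def with_overrides(self, overrides: Mapping[str, Any]) -> "EquilibriumConstants":
        """Return a copy with fields replaced from a mapping (YAML `constants:`)."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(f"unknown constants override(s): {sorted(unknown)}")
        return replace(self, **dict(overrides))


DEFAULT_CONSTANTS = EquilibriumConstants()
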