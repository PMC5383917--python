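"""Packaged reference fixtures: the published dialysate recipe and the
pre/post-dialyzer pH grid.

The values are shipped as small CSVs inside the package; a frozen sha256
per file guards against silent corruption.  Missing grid cells are absent
rows, never zeros; cells measured with fewer than three replicates carry an
``n_lt_3`` flag and are excluded from significance testing downstream.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .chemistry import IonComposition
from .errors import FixtureIntegrityError

__all__ = [
    "load_table1",
    "table1_composition",
    "FINAL_CHLORIDE",
    "load_table2",
]

_CHECKSUMS = {
    "table1_dialysate.csv": "4810b7c403b8222ad34c41eb9179bcbfd5c2f9d65f404c95bdbda1c0a4b976f1",
    "table2_ph.csv": "a09d51975cf848ed90c58d0a75f9986496895e5dd4a7761f9aa5ffce257ab47e",
}

#: chloride after HCl acidification of the dialysate, mmol/L
FINAL_CHLORIDE = 135.6


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("respdial").joinpath("data", name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"packaged fixture {name} failed its checksum "
            f"(got {digest}, expected {_CHECKSUMS[name]})"
        )
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """The dialysate recipe table: normal-plasma ranges alongside the
    zero-bicarbonate dialysate concentrations (mmol/L; pH row unitless)."""
    return _read_fixture("table1_dialysate.csv").set_index("quantity")


def table1_composition(final: bool = False) -> IonComposition:
    """The dialysate as an :class:`IonComposition`.

    ``final=False`` gives the modelled composition (chloride 116 mmol/L);
    ``final=True`` the HCl-acidified fluid actually run on the bench
    (chloride 135.6 mmol/L).
    """
    t = load_table1()["dialysate"]
    cl = FINAL_CHLORIDE if final else float(t["cl_mmol_per_L"])
    return IonComposition(
        na=float(t["na_mmol_per_L"]),
        k=float(t["k_mmol_per_L"]),
        ca=float(t["ca_mmol_per_L"]),
        mg=float(t["mg_mmol_per_L"]),
        cl=cl,
        lactate=float(t["lactate_mmol_per_L"]),
        phosphate=float(t["phosphate_mmol_per_L"]),
        hco3=float(t["hco3_mmol_per_L"]),
    )


def load_table2() -> pd.DataFrame:
    """Pre/post-dialyzer pH means +/- sd on the bench flow grid.

    Columns: qb_ml_min, inlet_pco2_target (mmHg), qd_ml_min, side
    (pre|post), ph_mean, ph_sd, n_lt_3, significant.  A ``condition_id``
    column and a ``ph`` alias of ``ph_mean`` are added so the frame plugs
    straight into :func:`respdial.removal.ph_delta_table`.
    """
    df = _read_fixture("table2_ph.csv")
    df["condition_id"] = [
        f"qb{qb:g}_qd{qd:g}_in{inlet:g}"
        for qb, qd, inlet in zip(
            df["qb_ml_min"], df["qd_ml_min"], df["inlet_pco2_target"]
        )
    ]
    df["ph"] = df["ph_mean"]
    return df
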