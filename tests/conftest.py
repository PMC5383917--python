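"""Shared fixtures: default constants, printed-table compositions, and a
session-cached noise-free simulation of the full bench flow grid."""

from __future__ import annotations

import numpy as np
import pytest

from respdial import (
    DEFAULT_CONSTANTS,
    BloodGasRecord,
    condition_inlet_blood,
    default_rig_config,
    simulate_single_pass,
    table1_composition,
    vco2_rate,
)
from respdial.rig import BENCH_QD_GRID


@pytest.fixture(scope="session")
def k():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def dialysate_modeled():
    """Printed dialysate before HCl acidification (chloride 116 mmol/L)."""
    return table1_composition(final=False)


@pytest.fixture(scope="session")
def dialysate_final():
    """Printed dialysate as run on the bench (chloride 135.6 mmol/L)."""
    return table1_composition(final=True)


@pytest.fixture(scope="session")
def grid_response():
    """Noise-free single-pass response over the full bench flow grid.

    Conditioning tolerance and measurement noise are zeroed so the map
    (qb, qd, inlet pCO2) -> (bench VCO2, pH change) reflects the model's
    systematic dose-response, uncontaminated by replicate sampling.
    Cached per session: several property tests read it.
    """
    out = {}
    for inlet in (50.0, 100.0):
        blood = condition_inlet_blood(inlet, tolerance=0.0, rng=0)
        pre = BloodGasRecord("c", "pre", 0, blood.state.ph, blood.state.pco2)
        for qb in (11.0, 18.7):
            for qd in BENCH_QD_GRID:
                cfg = default_rig_config(qb=qb, qd=qd, blood=blood)
                res = simulate_single_pass(cfg)
                post = BloodGasRecord(
                    "c", "post", 0, res.blood_out_state.ph, res.blood_out_state.pco2
                )
                rr = vco2_rate(pre, post, qb / 1000.0)
                out[(qb, qd, inlet)] = {
                    "vco2_bench": rr.vco2_bench,
                    "delta_ph": post.ph - pre.ph,
                    "result": res,
                }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
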