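"""Waiting-time assignment, progression dynamics, and division events."""
import numpy as np
import pytest

from mindiv import (
    DistParams,
    SimConfig,
    advance_progression,
    assign_doubling_time,
    assign_waiting_time,
    execute_division,
    progression_rate,
)
from mindiv.state import NONPOLAR

from conftest import make_cell, make_state


class TestAssignWaitingTime:
    def test_wt_distribution_moments(self, rng, params):
        draws = np.array(
            [assign_waiting_time(NONPOLAR, 4, "WT", rng, params) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(17.7, abs=0.2)
        assert draws.std(ddof=1) == pytest.approx(11.9, abs=0.3)

    def test_model3_polar_uses_nonpolar_distribution(self, params):
        """Identical generator state gives identical draws for both kinds."""
        a = assign_waiting_time("polar_old", 3, "minB", np.random.default_rng(5), params)
        b = assign_waiting_time(NONPOLAR, 3, "minB", np.random.default_rng(5), params)
        assert a == b

    def test_models12_distinguish_kinds(self, params):
        a = assign_waiting_time("polar_old", 2, "minB", np.random.default_rng(5), params)
        b = assign_waiting_time(NONPOLAR, 2, "minB", np.random.default_rng(5), params)
        assert a != b  # different normals from the same generator state

    def test_zero_sd_returns_mean_exactly(self, rng):
        params = DistParams(w_wt_sd=0.0)
        assert assign_waiting_time(NONPOLAR, 4, "WT", rng, params) == 17.7

    def test_blocked_site_rejected(self, rng, params):
        with pytest.raises(ValueError):
            assign_waiting_time(NONPOLAR, 4, "WT", rng, params, blocked=True)

    def test_doubling_time_dispersion(self, rng, params):
        draws = np.array([assign_doubling_time(rng, params) for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(15.0, abs=0.5)
        assert (draws > 0).all()
        assert assign_doubling_time(rng, params, shared=True) == 75.0


class TestProgressionRate:
    def test_models_1_to_3_are_unit_rate(self, params):
        for mv in (1, 2, 3):
            assert progression_rate(9999.0, 7, mv, "minB", 1.0, params) == 1.0

    def test_wt_reference_geometry_is_unit_rate(self, params):
        """One compartment at the reference length, one site -> f = 1."""
        assert progression_rate(params.Lc, 1, 4, "WT", 1.0, params) == pytest.approx(1.0)

    def test_competition_halves_rate_when_sites_double(self, params):
        f1 = progression_rate(6000.0, 2, 4, "minB", 1.0, params)
        f2 = progression_rate(6000.0, 4, 4, "minB", 1.0, params)
        assert f2 == pytest.approx(f1 / 2)

    def test_ftsz_factor_scales_rate(self, params):
        f1 = progression_rate(6000.0, 3, 4, "minB", 1.0, params)
        f2 = progression_rate(6000.0, 3, 4, "minB", 2.0, params)
        assert f2 == pytest.approx(2 * f1)

    def test_no_sites_rejected(self, params):
        with pytest.raises(ValueError):
            progression_rate(6000.0, 0, 4, "minB", 1.0, params)


class TestAdvanceProgression:
    def test_unit_rate_countdown(self):
        """Models 1-3: completion occurs exactly at t_w (to within dt)."""
        cfg = SimConfig(model_variant=1, strain="minB")
        cell = make_cell([1000.0, 1000.0], waiting=5.0)
        state = make_state([cell])
        completed = []
        for step in range(7):
            state.t = step + 1.0
            completed = advance_progression(state, 1.0, cfg)
            if completed:
                break
        assert state.t == 5.0
        assert len(completed) == 3  # both poles and the non-polar site at t_w=5

    def test_half_rate_doubles_realized_waiting(self):
        """Model 4 with f = 1/2 held fixed: completion at 2 * t_w."""
        params = DistParams()
        # geometry pinned so f = c*L/(n*Lc) = 2*L/(3*Lc) = 0.5
        L = 0.75 * params.Lc
        cfg = SimConfig(model_variant=4, strain="minB", dist_params=params)
        cell = make_cell([L / 2, L / 2], waiting=10.0)
        state = make_state([cell])
        t_done = None
        for step in range(100):
            state.t = step + 1.0
            for c in cell.compartments:  # freeze growth
                c.length = L / 2
            cell.length = L
            if advance_progression(state, 1.0, cfg):
                t_done = state.t
                break
        assert t_done == 20.0

    def test_inactive_pole_not_advanced(self):
        cfg = SimConfig(model_variant=2, strain="minB")
        cell = make_cell([1000.0, 1000.0], waiting=50.0)
        cell.polar_old.blocked = True
        cell.polar_old.t_w = float("nan")
        state = make_state([cell])
        advance_progression(state, 1.0, cfg)
        assert cell.polar_old.s == 0.0
        assert cell.np_sites[0].s == 1.0


class TestExecuteDivision:
    def _cfg(self, model=1, strain="minB"):
        return SimConfig(model_variant=model, strain=strain)

    def test_nonpolar_division_conserves_length(self, rng):
        cell = make_cell([1800.0, 2600.0], waiting=5.0)
        state = make_state([cell], t=10.0)
        site = cell.np_sites[0]
        site.s = 5.0
        execute_division(state, cell, site, rng, self._cfg())
        assert len(state.cells) == 2
        daughters = list(state.cells.values())
        assert daughters[0].length == pytest.approx(1800.0)
        assert daughters[1].length == pytest.approx(2600.0)
        assert sum(d.length for d in daughters) == pytest.approx(4400.0)
        for d in daughters:
            assert d.born_at == 10.0
            assert d.L0 == pytest.approx(d.length)
            assert len(d.np_sites) == len(d.compartments) - 1

    def test_polar_division_counts_minicell_only(self, rng):
        cell = make_cell([1800.0, 2600.0], waiting=5.0)
        state = make_state([cell], t=10.0)
        cell.polar_old.s = 5.0
        execute_division(state, cell, cell.polar_old, rng, self._cfg())
        assert state.minicell_count == 1
        assert len(state.cells) == 1
        assert cell.length == pytest.approx(4400.0)
        assert cell.polar_old.formed_at == 10.0  # pole re-formed

    def test_each_division_logs_one_event(self, rng):
        cell = make_cell([1800.0, 2600.0], waiting=5.0)
        state = make_state([cell], t=10.0)
        cell.polar_new.s = 5.0
        execute_division(state, cell, cell.polar_new, rng, self._cfg())
        assert len(state.event_log) == 1
        row = state.event_log.to_frame().iloc[0]
        assert row["event"] == "minicell"
        assert row["site_class"] == "polar_new"

    def test_blocked_site_cannot_divide(self, rng):
        cell = make_cell([1800.0, 2600.0], waiting=5.0)
        state = make_state([cell])
        cell.polar_old.blocked = True
        with pytest.raises(RuntimeError):
            execute_division(state, cell, cell.polar_old, rng, self._cfg(model=2))

    def test_carried_sites_keep_progression(self, rng):
        """Sites on each side carry s and t_w into the daughters unchanged."""
        cell = make_cell([1000.0, 1200.0, 1400.0], waiting=30.0)
        left_site = cell.np_sites[0]
        left_site.s = 12.0
        state = make_state([cell], t=20.0)
        mid = cell.np_sites[1]
        mid.s = 30.0
        execute_division(state, cell, mid, rng, self._cfg())
        d1, d2 = state.cells.values()
        assert d1.np_sites[0] is left_site
        assert left_site.s == 12.0
        assert left_site.t_w == 30.0
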