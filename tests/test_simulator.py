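"""Unit and property tests for the split-step time loop and summaries."""

import dataclasses

import numpy as np
import pytest

from sandhydrate import (ColumnState, RateConstants, TransportParams, ceq,
                         doc_max_after, generation_rate_profiles,
                         hfz_thicknesses, mud_saturation_beyond_hfz, preset,
                         run_scenario, scenario_from_config,
                         scenario_to_config, step, summarize,
                         top_hydrate_depth)
from sandhydrate.model_core import burial_depth
from sandhydrate.simulator import PRESET_NAMES

from conftest import make_mini


class TestFixedPoints:
    def test_zero_poc_stays_zero(self):
        scn = make_mini(column=dataclasses.replace(make_mini().column,
                                                   poc_mud_wt=0.0),
                        t_end=2000.0)
        res = run_scenario(scn)
        s = res.final_state
        for name in ("P", "H", "L", "E", "M", "S", "G"):
            assert np.all(getattr(s, name) == 0.0)

    def test_zero_rates_zero_diffusion_identity(self):
        scn = make_mini(
            rates=RateConstants(K_eh=0.0, K_fm=0.0, K_m=0.0),
            transport=TransportParams(D_hmw=0.0, D_lmw=0.0,
                                      D_enz=0.0, D_ch4=0.0))
        col = scn.column.build()
        state = ColumnState.initial(col)
        state.H[:] = np.linspace(0.0, 2.0, col.n_nodes)
        out = step(state, scn, column=col)
        assert out.t == state.t + scn.dt
        np.testing.assert_allclose(out.H, state.H, rtol=0, atol=1e-13)
        np.testing.assert_array_equal(out.P, state.P)
        assert np.all(out.S == 0.0)

    def test_no_hydrolysis_no_products(self):
        scn = make_mini(rates=RateConstants(K_eh=0.0, K_fm=10**-21.5,
                                            K_m=10**-21.5),
                        t_end=5000.0)
        res = run_scenario(scn)
        s = res.final_state
        for name in ("H", "L", "E", "M", "S", "G"):
            assert np.all(getattr(s, name) == 0.0)
        np.testing.assert_array_equal(s.P, res.column.poc_init)


class TestConservationAndDichotomy:
    def test_mini_ledger(self):
        res = run_scenario(make_mini())
        assert res.ledger_drift < 1e-3

    @pytest.mark.parametrize("fixture", ["wr_result", "u1325_result"])
    def test_equilibrium_dichotomy_every_snapshot(self, fixture, request):
        res = request.getfixturevalue(fixture)
        scn, col = res.scenario, res.column
        states = list(res.snapshots) + [res.final_state]
        assert states
        for s in states:
            s.validate()
            d = burial_depth(scn.burial, s.t) + col.node_depths
            ce = ceq(d, col.lithology, scn.solubility)
            frozen = s.S > 0
            if frozen.any():
                np.testing.assert_allclose(s.M[frozen], ce[frozen],
                                           rtol=1e-9)
            free = ~frozen
            assert np.all(s.M[free] <= ce[free] * (1 + 1e-9) + 1e-9)

    @pytest.mark.parametrize("fixture,max_ratio",
                             [("wr_result", 0.2), ("u1325_result", 0.8)])
    def test_sand_is_a_doc_sink(self, fixture, max_ratio, request):
        # At the DOC peak the sand bed holds less DOC than the mud: the
        # dense sand census consumes what diffuses in. The thick WR bed
        # stays nearly DOC-free; the 5 cm U1325 bed is diffusively
        # coupled to the adjacent mud, so its contrast is weaker.
        res = request.getfixturevalue(fixture)
        se = res.series
        i = int(np.nanargmax(se["max_doc_mud"]))
        assert se["max_doc_sand"][i] < max_ratio * se["max_doc_mud"][i]


class TestSelfConvergence:
    def test_split_step_second_order_on_smooth_data(self):
        # mud-only column, smooth nonuniform state, integrator regime
        # fixed (k_max*dt below the substep guard): the full split step
        # self-converges at second order (error ratio ~4 on dt halving)
        base_scn = make_mini(
            column=dataclasses.replace(make_mini().column,
                                       sand_thickness=0.0),
            t_end=2.0e4, series_interval=2.0e4)
        res = run_scenario(base_scn)
        s0, col = res.final_state, res.column
        z = col.node_depths
        bump = np.exp(-(z - 1.0) ** 2 / (2 * 0.3**2))
        for name, amp in (("H", 0.5), ("L", 0.5), ("E", 0.5), ("M", 0.5)):
            setattr(s0, name, getattr(s0, name) * (1 + amp * bump))
        s0.P = s0.P * (1 - 0.3 * bump)

        def advance(dt, T=400.0):
            s = s0.copy()
            scn = base_scn.with_(dt=dt)
            for _ in range(int(round(T / dt))):
                s = step(s, scn, column=col)
            return np.concatenate([s.P, s.H, s.L, s.E, s.M])

        a, b, c = advance(25.0), advance(12.5), advance(6.25)
        ratio = np.linalg.norm(a - b) / np.linalg.norm(b - c)
        assert 3.0 < ratio < 5.5


class TestDiagnostics:
    def test_hfz_hand_built(self):
        col = make_mini().column.build()
        state = ColumnState.initial(col)
        state.S[col.is_sand] = 0.2
        above, below = hfz_thicknesses(state, col, 0.01)
        sand_idx = np.flatnonzero(col.is_sand)
        assert above == pytest.approx(sand_idx[0] * col.dz)
        assert below == pytest.approx(
            (col.n_nodes - 1 - sand_idx[-1]) * col.dz)
        # HFZs reach both walls -> no mud beyond them carries hydrate
        assert np.isnan(mud_saturation_beyond_hfz(state, col, 0.01))

    def test_hfz_no_sand(self):
        col = dataclasses.replace(make_mini().column,
                                  sand_thickness=0.0).build()
        state = ColumnState.initial(col)
        assert np.isnan(hfz_thicknesses(state, col)[0])
        assert np.isnan(mud_saturation_beyond_hfz(state, col))

    def test_hfz_with_mud_hydrate(self):
        col = make_mini().column.build()
        state = ColumnState.initial(col)
        i0 = int(np.flatnonzero(col.is_sand)[0])
        state.S[col.is_sand] = 0.3
        state.S[i0 - 2] = 0.05    # hydrate-bearing mud, one free node between
        above, below = hfz_thicknesses(state, col, 0.01)
        assert above == pytest.approx(col.dz)
        assert mud_saturation_beyond_hfz(state, col, 0.01) == pytest.approx(
            0.05)

    def test_generation_rates_zero_state(self):
        col = make_mini().column.build()
        state = ColumnState.initial(col)
        state.P[:] = 0.0
        doc_rate, ch4_rate = generation_rate_profiles(
            state, col, make_mini().rates)
        assert np.all(doc_rate == 0.0) and np.all(ch4_rate == 0.0)

    def test_generation_rates_interface_peaked(self, wr_result):
        # mid-run snapshot: methanogenesis concentrates at the first and
        # last sand nodes, and the mud interior is orders of magnitude slower
        res = wr_result
        snap = min(res.snapshots, key=lambda s: abs(s.t - 1.0e5))
        col = res.column
        d = burial_depth(res.scenario.burial, snap.t)
        _, ch4 = generation_rate_profiles(snap, col, res.scenario.rates, d)
        sand_idx = np.flatnonzero(col.is_sand)
        assert int(np.argmax(ch4)) in (sand_idx[0], sand_idx[-1])
        interior_mud = col.is_mud.copy()
        interior_mud[sand_idx[0] - 2:sand_idx[-1] + 3] = False
        assert ch4[interior_mud].max() < 0.05 * ch4.max()

    def test_doc_max_after(self):
        res = run_scenario(make_mini())
        se = res.series
        t_cut = 2.0e4
        expected = float(se["max_doc"][se["t_yr"] > t_cut].max())
        assert doc_max_after(res, t_cut) == expected
        assert np.isnan(doc_max_after(res, 1e9))

    def test_summarize_no_hydrate(self):
        m = summarize(run_scenario(make_mini()))
        assert m["max_sh_sand_final"] == 0.0
        assert np.isnan(m["onset_time_kyr"])
        assert np.isnan(m["onset_burial_m"])
        assert np.isnan(m["top_hydrate_depth_m"])
        assert m["ledger_drift"] < 1e-3

    def test_top_hydrate_depth_threshold_override(self, wr_result):
        # a lower threshold can only be crossed earlier (shallower burial)
        d_low = top_hydrate_depth(wr_result, s_top=0.01)
        d_def = top_hydrate_depth(wr_result)
        assert d_low <= d_def


class TestMonotoneResponse:
    def test_doc_response_to_rate_constants(self):
        base = make_mini()

        def max_doc(keh_f=1.0, kfm_f=1.0):
            rc = RateConstants(K_eh=10**-12.6 * keh_f,
                               K_fm=10**-21.5 * kfm_f,
                               K_m=10**-21.5 * kfm_f, epsilon=0.04)
            return summarize(run_scenario(base.with_(rates=rc)))["max_doc"]

        by_keh = [max_doc(keh_f=f) for f in (0.5, 1.0, 2.0)]
        assert by_keh[0] < by_keh[1] < by_keh[2]
        by_kfm = [max_doc(kfm_f=f) for f in (0.5, 1.0, 2.0)]
        assert by_kfm[0] > by_kfm[1] > by_kfm[2]


class TestConfig:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_round_trip_bit_for_bit(self, name, tmp_path):
        scn = preset(name)
        text = scenario_to_config(scn)
        path = tmp_path / "scn.cfg"
        path.write_text(text)
        again = scenario_to_config(scenario_from_config(path))
        assert again == text

    def test_dict_source(self):
        scn = scenario_from_config({"name": "x", "domain_length_m": 2.0,
                                    "sand_thickness_m": 0.6, "dz_m": 0.1,
                                    "K_eh_per_mM_s": 1e-13,
                                    "K_fm_per_cell_s": 1e-22,
                                    "K_m_per_cell_s": 1e-22,
                                    "sed_rate_mm_yr": 1.0})
        assert scn.name == "x"
        assert scn.column.domain_length == 2.0

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError, match="unknown config key"):
            scenario_from_config({"not_a_key": 1.0})

    def test_bad_bool_raises(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("occupancy = maybe\n")
        with pytest.raises(ValueError):
            scenario_from_config(path)

    def test_comments_and_blank_lines(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("# header\n\nname = y  # trailing\n"
                        "domain_length_m = 2.0\nsand_thickness_m = 0.6\n"
                        "dz_m = 0.1\nK_eh_per_mM_s = 1e-13\n"
                        "K_fm_per_cell_s = 1e-22\nK_m_per_cell_s = 1e-22\n"
                        "sed_rate_mm_yr = 1.0\n")
        assert scenario_from_config(path).name == "y"

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("atlantis")

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_presets_load(self, name):
        scn = preset(name)
        assert scn.name == name


class TestRunLoop:
    def test_snapshot_times_captured(self):
        scn = make_mini(t_end=2000.0, snapshot_times=(0.0, 1000.0, 2000.0))
        res = run_scenario(scn)
        assert [s.t for s in res.snapshots] == [0.0, 1000.0, 2000.0]

    def test_partial_final_step_logged(self, caplog):
        import logging
        scn = make_mini(dt=30.0, t_end=100.0, series_interval=30.0)
        with caplog.at_level(logging.WARNING, logger="sandhydrate"):
            res = run_scenario(scn)
        assert res.final_state.t == pytest.approx(120.0)
        assert any("not a multiple" in r.message for r in caplog.records)

    def test_series_keys_and_alignment(self):
        res = run_scenario(make_mini(t_end=2000.0))
        se = res.series
        n = len(se["t_yr"])
        for key in ("burial_m", "max_doc", "max_doc_mud", "max_doc_sand",
                    "max_S_sand", "max_S_mud", "max_S", "hfz_above_m",
                    "hfz_below_m", "total_carbon"):
            assert len(se[key]) == n
        assert se["t_yr"][0] == 0.0
        np.testing.assert_allclose(
            se["burial_m"],
            burial_depth(res.scenario.burial, se["t_yr"]), rtol=1e-12)
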