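"""Compartmental framework: gating, Q10, calcium, integration, cell builders."""

import math

import numpy as np
import pytest

from granulayer import neuron as nr


@pytest.fixture(scope="module")
def grc():
    return nr.build_grc()


@pytest.fixture(scope="module")
def goc():
    return nr.build_goc()


def _passive_cell(n_comp=1, g_leak_nS=1.0, e_leak=-70.0, diam=10.0, length=20.0):
    comps = [nr.Compartment(f"c{i}", length, diam) for i in range(n_comp)]
    parents = [None] + list(range(n_comp - 1))
    leak = nr.ChannelDef("leak", gates=(), reversal=e_leak, q10_perm=1.0)
    instances = [nr.ChannelInstance(i, "leak", g_leak_nS) for i in range(n_comp)]
    return nr.CellModel(name="passive", compartments=comps, parents=parents,
                        channel_defs={"leak": leak}, instances=instances,
                        v_init=e_leak)


class TestGatingSteadyState:
    def test_equal_rates_give_half(self):
        ch = nr.ChannelDef("x", gates=(
            nr.GateDef("m", 1, lambda V, ca: 2.0, lambda V, ca: 2.0),), reversal=0.0)
        (xinf, tau), = nr.gating_steady_state(ch, -50.0)
        assert xinf == pytest.approx(0.5)
        assert tau == pytest.approx(0.25)

    def test_zero_beta_fully_open(self):
        ch = nr.ChannelDef("x", gates=(
            nr.GateDef("m", 1, lambda V, ca: 3.0, lambda V, ca: 0.0),), reversal=0.0)
        (xinf, tau), = nr.gating_steady_state(ch, -50.0)
        assert xinf == pytest.approx(1.0)
        assert tau == pytest.approx(1.0 / 3.0)

    def test_zero_total_rate_is_error(self):
        ch = nr.ChannelDef("x", gates=(
            nr.GateDef("m", 1, lambda V, ca: 0.0, lambda V, ca: 0.0),), reversal=0.0)
        with pytest.raises(ValueError):
            nr.gating_steady_state(ch, -50.0)

    def test_ode_converges_to_steady_state(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.1, 5.0, size=2)
        x, dt = 0.0, 0.001
        for _ in range(int(50 / (a + b) / dt)):
            x += dt * (a * (1 - x) - b * x)
        assert x == pytest.approx(a / (a + b), abs=1e-5)


class TestQ10:
    def test_same_temperature_unchanged(self):
        assert nr.q10_scale(7.0, 3.0, 30.0, 30.0) == 7.0

    def test_factor_of_base_per_decade(self):
        assert nr.q10_scale(1.0, 3.0, 27.0, 37.0) == pytest.approx(3.0)

    def test_fractional_decade(self):
        assert nr.q10_scale(1.0, 2.4, 23.0, 37.0) == pytest.approx(2.4 ** 1.4)

    def test_invalid_q10(self):
        with pytest.raises(ValueError):
            nr.q10_scale(1.0, 0.0, 23.0, 37.0)


class TestStepCalcium:
    def test_resting_fixed_point(self):
        p = nr.CalciumShellParams()
        assert nr.step_calcium(p.ca0_mM, 0.0, p, 10.0) == pytest.approx(p.ca0_mM)

    def test_relaxation_rate(self):
        p = nr.CalciumShellParams(beta_ca=0.6)
        ca0 = p.ca0_mM
        ca = nr.step_calcium(5 * ca0, 0.0, p, 1.0)
        expect = ca0 + 4 * ca0 * math.exp(-0.6)
        assert ca == pytest.approx(expect, rel=1e-12)

    def test_steady_state_under_constant_current(self):
        p = nr.CalciumShellParams(area_cm2=2e-7)
        i_ca = -2.0  # inward
        ca = p.ca0_mM
        for _ in range(200):
            ca = nr.step_calcium(ca, i_ca, p, 5.0)
        d_cm = p.depth_nm * 1e-7
        j = -i_ca * 1e-12 / (2 * nr.FARADAY * p.area_cm2 * d_cm * 1e-3)
        assert ca == pytest.approx(p.ca0_mM + j / p.beta_ca, rel=1e-9)


class TestVoltageIntegration:
    def test_no_conductance_no_drift(self):
        cell = _passive_cell(g_leak_nS=0.0)
        solver = nr.CellSolver(cell, dt=0.025)
        solver.V[:] = -55.0
        for _ in range(400):
            solver.step()
        assert solver.V[0] == pytest.approx(-55.0)

    def test_rc_charging_matches_closed_form(self):
        g, e = 2.0, -70.0
        cell = _passive_cell(g_leak_nS=g, e_leak=e)
        c_pF = cell.compartments[0].capacitance_pF
        tau = c_pF / g  # ms
        i_inj = 10.0
        solver = nr.CellSolver(cell, dt=min(0.025, tau / 50))
        n = int(round(5 * tau / solver.dt))
        for _ in range(n):
            solver.step(i_inj={0: i_inj})
        t = n * solver.dt
        expect = e + i_inj / g * (1 - math.exp(-t / tau))
        assert solver.V[0] == pytest.approx(expect, rel=1e-3)

    def test_two_compartment_cable_matches_fine_reference(self):
        cell = _passive_cell(n_comp=2, g_leak_nS=1.0, diam=2.0, length=50.0)

        def run(dt, t_end=20.0):
            solver = nr.CellSolver(cell, dt=dt)
            for _ in range(int(round(t_end / dt))):
                solver.step(i_inj={0: 5.0})
            return solver.V.copy()

        coarse = run(0.025)
        fine = run(1e-3)
        np.testing.assert_allclose(coarse, fine, rtol=5e-3)

    def test_equal_reversals_converge_to_common_potential(self):
        cell = _passive_cell(n_comp=3, g_leak_nS=1.0, e_leak=-60.0)
        solver = nr.CellSolver(cell, dt=0.05)
        solver.V[:] = [-80.0, -40.0, -65.0]
        for _ in range(4000):
            solver.step()
        np.testing.assert_allclose(solver.V, -60.0, atol=1e-6)


class TestGranuleCell:
    def test_resting_potential_restored(self, grc):
        solver = nr.CellSolver(grc, dt=0.025)
        solver.V[:] = -72.0
        solver.reset_gates_to_steady_state()
        for _ in range(int(300 / 0.025)):
            solver.step()
        assert solver.V[grc.soma_index] == pytest.approx(-70.0, abs=1.0)

    def test_tonic_gaba_leak_density(self, grc):
        # 0.042 nS per dendritic branch over the branch area = 60 uS/cm^2
        lkg2 = [i for i in grc.instances if i.channel == "Lkg2"]
        per_branch = sum(i.gbar_nS for i in lkg2) / 4
        branch_area = sum(grc.compartments[i.comp].area_cm2 for i in lkg2) / 4
        density_uS_cm2 = per_branch * 1e-9 / branch_area * 1e6
        assert density_uS_cm2 == pytest.approx(60.0, rel=0.01)

    def test_table_conductances_placed(self, grc):
        totals = {}
        for inst in grc.instances:
            totals[inst.channel] = totals.get(inst.channel, 0.0) + inst.gbar_nS
        assert totals["K_IR"] == pytest.approx(3.382)
        assert totals["Na"] == pytest.approx(8.589)
        assert totals["Lkg1"] == pytest.approx(0.264)
        # placement: K_IR somatic, Ca on dendritic tips with calcium shells
        kir_comps = {i.comp for i in grc.instances if i.channel == "K_IR"}
        assert kir_comps == {grc.soma_index}
        ca_comps = {i.comp for i in grc.instances if i.channel == "Ca"}
        assert ca_comps == set(grc.ca_shells)

    def test_gating_variables_stay_in_unit_interval(self, grc):
        solver = nr.CellSolver(grc, dt=0.025)
        for _ in range(int(80 / 0.025)):
            solver.step(i_inj={grc.soma_index: 10.0})
            for g in solver.gates:
                assert np.all((g >= 0.0) & (g <= 1.0))

    def test_dt_halving_convergence_subthreshold(self, grc):
        rest = nr.steady_state(grc)

        def run(dt):
            solver = nr.CellSolver(grc, dt=dt)
            solver.V = rest.V.copy()
            solver.ca = dict(rest.ca)
            solver.reset_gates_to_steady_state()
            out = []
            for _ in range(int(round(60 / dt))):
                solver.step(i_inj={grc.soma_index: 3.0})
                out.append(solver.V[grc.soma_index])
            return np.asarray(out)

        v1 = run(0.05)
        v2 = run(0.025)[1::2]
        span = v2.max() - v2.min()
        rms = np.sqrt(np.mean((v1 - v2) ** 2))
        assert rms < 0.005 * span

    def test_temperature_scaling_changes_dynamics(self):
        import yaml

        with open(nr.CONFIG_DIR / "paper_grc.yaml") as fh:
            cfg = yaml.safe_load(fh)
        cfg["temperature"] = 37.0
        warm = nr.build_grc(cfg)
        cool = nr.build_grc()

        def response(cell):
            solver = nr.steady_state(cell)
            out = []
            for _ in range(int(30 / solver.dt)):
                solver.step(i_inj={cell.soma_index: 5.0})
                out.append(solver.V[cell.soma_index])
            return np.asarray(out)

        assert np.max(np.abs(response(warm) - response(cool))) > 0.1


class TestGolgiCell:
    def test_total_capacitance(self, goc):
        assert goc.total_capacitance_pF() == pytest.approx(145.0, rel=0.01)
        caps = [c.capacitance_pF for c in goc.compartments]
        assert caps[0] == pytest.approx(23.0, rel=0.02)       # soma
        assert sum(caps[1:4]) == pytest.approx(32.0, rel=0.02)  # dendrites
        assert caps[4] == pytest.approx(90.0, rel=0.02)        # axon

    def test_passive_input_resistance_matches_area(self, goc):
        # passive-only copy: leak instances, active conductances removed
        passive = nr.CellModel(
            name="goc_passive", compartments=goc.compartments,
            parents=goc.parents, channel_defs=goc.channel_defs,
            instances=[i for i in goc.instances if i.channel == "Lkg1"],
            v_init=-55.0)
        sol0 = nr.steady_state(passive)
        sol1 = nr.steady_state(passive, i_inj_soma=10.0)
        r_in = (sol1.V[0] - sol0.V[0]) / 10.0  # mV/pA = GOhm
        # exact star-network oracle: soma leak in parallel with each branch's
        # series (axial + leak) path
        g_leak = {i.comp: i.gbar_nS for i in passive.instances}
        g_total = g_leak[0]
        for i, j, g_ax in goc.axial_conductances():
            branch = i if j == 0 else j
            g_total += g_leak[branch] * g_ax / (g_leak[branch] + g_ax)
        assert r_in == pytest.approx(1.0 / g_total, rel=0.01)
        # the cell is close to (though not exactly) electrotonically compact
        area = sum(c.area_cm2 for c in goc.compartments)
        r_lumped = 47.6e3 / area * 1e-9  # ohm cm^2 / cm^2 -> GOhm
        assert r_in == pytest.approx(r_lumped, rel=0.2)

    def test_spontaneous_pacemaking(self, goc):
        solver = nr.CellSolver(goc, dt=0.025)
        crossings = 0
        prev = solver.V[0]
        for _ in range(int(500 / 0.025)):
            solver.step()
            v = solver.V[0]
            if prev < -20.0 <= v:
                crossings += 1
            prev = v
        assert crossings >= 2
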