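"""Simulator: closed forms, oracle agreement, settle detection, decoding."""

import numpy as np
import pytest

from conftest import catalytic_rig, displacement_rig

from domaincode.circuits import build_module_stage
from domaincode.compiler import (
    Netlist, Reaction, compile_netlist, crn_from_reactions,
)
from domaincode.errors import DecodingError, DomainCodeError, SimulationError
from domaincode.kinetics import (
    Trajectory, decode_word, settle_time, simulate,
)
from domaincode.strands import (
    KineticParams, complex_species, conservation_vectors, single_species,
)


class TestClosedForms:
    def test_pseudo_first_order_limit(self):
        # G in 10^7-fold excess: O(t) = A0 (1 - exp(-k G0 t))
        crn = displacement_rig(a0=1.0, g0=1.0e7, rate=1e-9)
        traj = simulate(crn, 300, rtol=1e-10, atol=1e-12, grid_dt=0.5)
        expected = 1.0 * (1 - np.exp(-1e-9 * 1e7 * traj.t))
        assert np.max(np.abs(traj.series("O") - expected)) < 1e-6

    def test_exact_bimolecular_solution(self):
        # comparable concentrations: the exact two-body solution
        a0, g0, k = 50.0, 120.0, 3.0e-4
        crn = displacement_rig(a0=a0, g0=g0, rate=k)
        traj = simulate(crn, 800, rtol=1e-10, atol=1e-12, grid_dt=1.0)
        E = np.exp(-k * (g0 - a0) * traj.t)
        expected = a0 * g0 * (1 - E) / (g0 - a0 * E)
        assert np.max(np.abs(traj.series("O") - expected)) / a0 < 1e-6

    def test_settle_time_matches_exponential_rate(self):
        # unimolecular opening at rate r: product within 5% at ln(20)/r
        r = 0.01
        A = single_species(("sig", "A", 0, 0), "A", "input", 100.0)
        Astar = complex_species([("sig", "A", 0, 0)], "Astar", "output",
                                state="open")
        crn = crn_from_reactions([Reaction((A,), (Astar,), r)])
        traj = simulate(crn, 2000, grid_dt=0.1)
        report = settle_time(traj, outputs=["Astar"], epsilon=0.05)
        assert report.settle_time == pytest.approx(-np.log(0.05) / r, rel=0.02)


class TestOracleAgreement:
    def test_fixed_step_rk4_on_small_networks(self, rk4_integrate):
        for crn, t_end in ((displacement_rig(50.0, 120.0, 3e-4), 400.0),
                           (catalytic_rig(), 400.0)):
            dt = 0.05
            times, states, names = rk4_integrate(crn, t_end, dt)
            traj = simulate(crn, t_end, grid_dt=dt)
            scale = max(sp.init_conc for sp in crn.species)
            for j, name in enumerate(names):
                dev = np.max(np.abs(traj.series(name) - states[:, j])) / scale
                assert dev < 1e-4, f"{name}: oracle deviation {dev:.2e}"


@pytest.fixture(scope="module")
def stage_traj():
    nl = build_module_stage((1, 0), (0,))
    crn = compile_netlist(nl)
    return crn, simulate(crn, 1500)


class TestTrajectoryInvariants:
    def test_concentrations_stay_nonnegative(self, stage_traj):
        _, traj = stage_traj
        assert traj.conc.min() >= -1e-4

    def test_fluorescence_is_monotone_nondecreasing(self, stage_traj):
        _, traj = stage_traj
        for name in traj.fluorescence_names():
            y = traj.series(name)
            assert np.min(np.diff(y)) >= -1e-4 * max(1.0, y[-1])

    def test_conservation_vectors_constant_along_trajectory(self, stage_traj):
        crn, traj = stage_traj
        matrix, _ = conservation_vectors(crn.species)
        totals = traj.conc @ matrix.T
        drift = np.abs(totals - totals[0]).max() / totals.max()
        assert drift < 1e-6

    def test_solver_tolerance_independence(self, stage_traj):
        crn, traj = stage_traj
        tight = simulate(crn, 1500, rtol=0.5e-8, atol=0.5e-6)
        for name in traj.fluorescence_names():
            a, b = traj.final(name), tight.final(name)
            assert abs(a - b) <= 1e-3 * max(abs(b), 1.0)

    def test_zero_input_gives_zero_fluorescence(self):
        # same stage chemistry but no input strand present at t=0
        from domaincode.compiler import expand_gate
        from domaincode.gates import (
            make_amplifier, make_mapping_module, make_reporter,
        )
        rxns = []
        for gate in (
            make_mapping_module(1, (1, 0), ("A0",), "Y", gate_id="M.Y"),
            make_amplifier("Y", "Z", gate_id="AMP.Y"),
            make_reporter("Z", gate_id="REP.Z"),
        ):
            rxns += expand_gate(gate, unit_conc=1.0e4)
        crn = crn_from_reactions(rxns)
        traj = simulate(crn, 500)
        names = traj.fluorescence_names()
        assert names
        for name in names:
            assert np.max(np.abs(traj.series(name))) < 1e-6


class TestKineticModes:
    def test_two_step_reaches_the_same_plateau(self):
        nl = build_module_stage((1, 0), (0,))
        one = simulate(compile_netlist(nl), 2000)
        two = simulate(compile_netlist(nl, mode="two-step"), 2000)
        assert decode_word(two, nl.output_wires).word == \
            decode_word(one, nl.output_wires).word == "1"
        assert two.final("Y_Z_2") == pytest.approx(one.final("Y_Z_2"),
                                                   rel=0.02)

    def test_doubling_k_bind_never_slows_a_single_pathway(self):
        settles = []
        for k in (3.0e-4, 6.0e-4):
            nl = build_module_stage(
                (1, 0), (0,), params=KineticParams(k_bind=k))
            traj = simulate(compile_netlist(nl), 1500)
            settles.append(settle_time(traj).settle_time)
        assert settles[1] <= settles[0]


class TestDecoding:
    def _fake_traj(self, y1, y2):
        t = np.linspace(0, 10, 5)
        conc = np.tile([y1, y2], (5, 1)).astype(float)
        return Trajectory(t=t, conc=conc, names=["Y_Z_1", "Y_Z_2"])

    def test_clear_ratios_decode(self):
        assert decode_word(self._fake_traj(1000.0, 5.0), ["Z"]).bits == (0,)
        assert decode_word(self._fake_traj(5.0, 1000.0), ["Z"]).decimal == 1

    def test_both_channels_dark_is_an_error(self):
        with pytest.raises(DecodingError, match="below"):
            decode_word(self._fake_traj(0.0, 0.0), ["Z"])

    def test_ambiguous_ratio_is_an_error(self):
        with pytest.raises(DecodingError, match="ambiguous"):
            decode_word(self._fake_traj(400.0, 600.0), ["Z"])

    def test_word_is_msb_first(self):
        t = np.linspace(0, 10, 5)
        conc = np.tile([1000.0, 0.0, 0.0, 1000.0], (5, 1))
        traj = Trajectory(t=t, conc=conc,
                          names=["Y_A_1", "Y_A_2", "Y_B_1", "Y_B_2"])
        out = decode_word(traj, ["B", "A"])   # B is the MSB
        assert out.word == "10" and out.decimal == 2


class TestErrors:
    def test_bad_t_end(self):
        crn = compile_netlist(Netlist("empty"))
        with pytest.raises(SimulationError):
            simulate(crn, 0.0)

    def test_missing_species_in_settle(self):
        crn = displacement_rig()
        traj = simulate(crn, 10)
        with pytest.raises(DomainCodeError):
            settle_time(traj, outputs=["nope"])
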