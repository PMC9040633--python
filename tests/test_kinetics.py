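"""Elementary decomposition, thermodynamic sampling, simulation, stability."""

import math

import numpy as np
import pytest

from gfd.kinetics import (
    RT,
    ElementaryDecomposition,
    EnsembleMember,
    ReferenceState,
    Step,
    UnsupportedMechanismError,
    check_stability,
    decompose,
    default_dg_ranges,
    kinetic_carrier,
    net_reaction_fluxes,
    sample_member,
    screen_ensemble,
    simulate_steady_state,
    _initial_state,
)
from gfd.kinetics import TrainingCondition
from gfd.synth import make_toy_networks


@pytest.fixture(scope="module")
def two_step():
    return make_toy_networks()["two_step"].network


@pytest.fixture(scope="module")
def two_step_ref(two_step):
    v = {"EX_S": -1.0, "T_S": 1.0, "STEP1": 1.0, "STEP2": 1.0, "EX_P": 1.0}
    return ReferenceState(v_ref=v, dG_range=default_dg_ranges(v))


@pytest.fixture(scope="module")
def two_step_decomp(two_step, two_step_ref):
    return decompose(two_step, two_step_ref.v_ref)


class TestDecomposition:
    def test_uni_uni_reaction_has_three_steps(self, two_step_decomp):
        """bind, convert, release — the canonical mechanism."""
        assert len(two_step_decomp.reaction_steps["STEP1"]) == 3

    def test_summed_stoichiometry_recovers_pfor(self, decomposition, core):
        from gfd.kinetics import _is_buffered

        got = decomposition.summed_stoichiometry("PFOR")
        want = {m: float(c) for m, c in core.reaction("PFOR").stoichiometry.items()
                if not _is_buffered(core, m)}
        assert got == pytest.approx(want)

    def test_summed_stoichiometry_all_enzymatic(self, decomposition, core):
        from gfd.kinetics import _is_buffered

        for r in core.reactions:
            rid = r.id
            if rid in decomposition.lumped or not decomposition.reaction_steps.get(rid):
                continue
            got = decomposition.summed_stoichiometry(rid)
            want = {m: float(c) for m, c in r.stoichiometry.items() if not _is_buffered(core, m)}
            assert got == pytest.approx(want), rid

    def test_species_count_linear_in_reactions(self, decomposition, core):
        # each reaction adds at most substrates+products+1 enzyme states
        assert len(decomposition.species) < 62 + 10 * len(core.reactions)

    def test_too_many_substrates_rejected(self, two_step, two_step_ref):
        with pytest.raises(UnsupportedMechanismError):
            decompose(two_step, two_step_ref.v_ref, max_distinct_substrates=0)

    def test_exchanges_and_biomass_stay_lumped(self, decomposition):
        assert "EX_bdoh" in decomposition.lumped
        assert "BIOMASS" in decomposition.lumped
        assert len(decomposition.reaction_steps["EX_bdoh"]) == 1

    def test_kinetic_carrier_resolution(self, core):
        assert kinetic_carrier(core, "EX_ac") == "ACT"
        assert kinetic_carrier(core, "EX_bdoh") == "EX_bdoh"


class TestSampling:
    def test_member_reproduces_reference_fluxes(self, decomposition, reference):
        member = sample_member(decomposition, reference, seed=123)
        fluxes = net_reaction_fluxes(member, _initial_state(member, None))
        for rid, v in fluxes.items():
            assert abs(v - reference.v_ref.get(rid, 0.0)) < 1e-8, rid

    def test_thermodynamic_product_identity(self, decomposition, reference):
        """prod_i (1/R_i) = exp(-dG/RT) for every flux-carrying reaction."""
        member = sample_member(decomposition, reference, seed=5)
        for rid, R in member.reversibilities.items():
            dg = member.dG[rid]
            lhs = np.prod(1.0 / R)
            rhs = math.exp(-dg / RT)
            assert lhs == pytest.approx(rhs, rel=1e-10), rid

    def test_sampled_dg_inside_admissible_range(self, decomposition, reference):
        member = sample_member(decomposition, reference, seed=5)
        for rid, dg in member.dG.items():
            lo, hi = reference.dG_range[rid]
            if decomposition.reaction_flipped[rid]:
                lo, hi = -hi, -lo
            assert lo - 1e-12 <= dg <= hi + 1e-12

    def test_two_seeds_differ_but_share_reference(self, decomposition, reference):
        m1 = sample_member(decomposition, reference, seed=1)
        m2 = sample_member(decomposition, reference, seed=2)
        some = next(iter(m1.reversibilities))
        assert not np.allclose(m1.reversibilities[some], m2.reversibilities[some])
        f1 = net_reaction_fluxes(m1, _initial_state(m1, None))
        f2 = net_reaction_fluxes(m2, _initial_state(m2, None))
        for rid in f1:
            assert f1[rid] == pytest.approx(f2[rid], abs=1e-8)

    def test_member_json_round_trip(self, decomposition, reference, tmp_path):
        from gfd.kinetics import Ensemble

        m = sample_member(decomposition, reference, seed=9)
        ens = Ensemble([m])
        ens.save(tmp_path / "ens")
        again = Ensemble.load(tmp_path / "ens", decomposition)
        assert len(again) == 1
        assert np.allclose(again.members[0].kf, m.kf)
        assert again.members[0].seed == 9

    def test_zero_flux_reaction_parameterized_at_equilibrium(self, decomposition, reference, core):
        member = sample_member(decomposition, reference, seed=3)
        zero = [r.id for r in core.reactions
                if abs(reference.v_ref.get(r.id, 0.0)) < 1e-9 and r.id not in decomposition.lumped]
        assert zero, "expected some zero-flux reactions at the reference"
        fluxes = net_reaction_fluxes(member, _initial_state(member, None))
        for rid in zero:
            assert fluxes[rid] == pytest.approx(0.0, abs=1e-10)
            assert member.dG[rid] == 0.0


def reversible_mm_rate(kf, kb, e_tot, s, p):
    """King-Altman closed form for the 3-step uni-uni mechanism.

    E + S <-> ES <-> EP <-> E + P with rate constants (k1..k3 forward,
    r1..r3 backward); returns the net steady-state cycle flux at fixed
    substrate/product concentrations.
    """
    k1, k2, k3 = kf
    r1, r2, r3 = kb
    # state weights via King-Altman directed-tree enumeration
    a12, a21 = k1 * s, r1
    a23, a32 = k2, r2
    a31, a13 = k3, r3 * p
    wE = a21 * a31 + a23 * a31 + a21 * a32
    wES = a12 * a31 + a12 * a32 + a13 * a32
    wEP = a12 * a23 + a13 * a21 + a13 * a23
    denom = wE + wES + wEP
    num = e_tot * (a12 * a23 * a31 - a21 * a32 * a13)
    return num / denom


class TestClosedForms:
    def test_uni_uni_matches_reversible_michaelis_menten(self, two_step_decomp, two_step_ref):
        member = sample_member(two_step_decomp, two_step_ref, seed=11)
        steps = two_step_decomp.reaction_steps["STEP1"]
        kf = [member.kf[i] for i in steps]
        kb = [member.kb[i] for i in steps]
        states = two_step_decomp.enzyme_states["STEP1"]
        e_tot = sum(member.e_ref[i] for i in states)
        # at the reference (s = p = 1) the closed form must return v_ref = 1
        v = reversible_mm_rate(kf, kb, e_tot, 1.0, 1.0)
        assert v == pytest.approx(1.0, rel=1e-8)
        # and away from the reference it matches the numerically solved
        # enzyme cycle
        s, p = 1.7, 0.4
        v_closed = reversible_mm_rate(kf, kb, e_tot, s, p)
        v_numeric = _enzyme_cycle_flux(kf, kb, e_tot, s, p)
        assert v_closed == pytest.approx(v_numeric, rel=1e-8)

    def test_saturated_downstream_damps_upstream_fold_change(self, two_step, two_step_ref):
        """With STEP2 nearly saturated, doubling STEP1 barely moves the flux."""
        decomp = decompose(two_step, two_step_ref.v_ref)
        member = sample_member(decomp, two_step_ref, seed=2)
        # STEP2 (P -> external pool) has two states E0 and EP; park nearly
        # all of its enzyme in EP so the catalytic step runs at ~Vmax and
        # make catalysis irreversible: the export becomes supply-insensitive
        states2 = decomp.enzyme_states["STEP2"]
        assert len(states2) == 2
        e = member.e_ref.copy()
        e[states2[0]] = 0.001
        e[states2[1]] = 0.999
        bind, conv = decomp.reaction_steps["STEP2"]
        kf, kb = member.kf.copy(), member.kb.copy()
        kf[bind] = 1.0 / e[states2[0]]   # fast binding: flux 1 at reference
        kb[bind] = 0.0
        kf[conv] = 1.0 / e[states2[1]]   # catalysis at ~Vmax = 1/0.999
        kb[conv] = 0.0
        # STEP1 gets an even, well-reversible parameterization (R = 0.5 per
        # step) so product build-up can push back against the doubled enzyme
        states1 = decomp.enzyme_states["STEP1"]
        e[states1] = 1.0 / len(states1)
        for si in decomp.reaction_steps["STEP1"]:
            st = decomp.steps[si]
            kf[si] = 2.0 / e[st.reactants[0]]
            kb[si] = 1.0 / e[st.products[0]]
        saturated = EnsembleMember(decomp, kf, kb, e, member.reversibilities, member.dG, 2)
        base = simulate_steady_state(saturated)
        up = simulate_steady_state(saturated, {"STEP1": 2.0})
        assert base.stable and up.stable
        rel_change = abs(up.fluxes["STEP2"] - base.fluxes["STEP2"]) / base.fluxes["STEP2"]
        assert rel_change < 0.05


def _enzyme_cycle_flux(kf, kb, e_tot, s, p):
    """Steady state of the linear 3-state enzyme cycle at fixed s, p."""
    k1, k2, k3 = kf
    r1, r2, r3 = kb
    A = np.array([
        [-(k1 * s) - r3 * p * 0 , r1, k3],
        [k1 * s, -(r1 + k2), r2],
        [1.0, 1.0, 1.0],
    ])
    # note: E gains from EP via k3 and loses via k1*s and r3*p binding
    A[0, 0] = -(k1 * s + r3 * p)
    b = np.array([0.0, 0.0, e_tot])
    E, ES, EP = np.linalg.solve(A, b)
    return k3 * EP - r3 * p * E


class TestSimulation:
    def test_all_unit_fold_changes_return_reference(self, decomposition, reference):
        member = sample_member(decomposition, reference, seed=42)
        sim = simulate_steady_state(member)
        assert sim.stable
        for rid, v in sim.fluxes.items():
            assert v == pytest.approx(reference.v_ref.get(rid, 0.0), abs=1e-6), rid

    def test_acls_knockout_severs_bdo_production(self, ensemble18):
        member = ensemble18.members[0]
        sim = simulate_steady_state(member, {"ACLS": 0.0})
        if sim.stable:
            assert sim.fluxes["EX_bdoh"] < 1e-3
            assert abs(sim.fluxes["ACLS"]) < 1e-9

    def test_enzyme_totals_conserved_under_perturbation(self, decomposition, reference):
        member = sample_member(decomposition, reference, seed=42)
        sim = simulate_steady_state(member, {"PFOR": 1.5})
        assert sim.stable
        # re-integrate briefly to fetch the final state for pool accounting
        from gfd.kinetics import _lumped_fold_scale, _rate_arrays, _step_rates
        from scipy.integrate import solve_ivp

        kf, kb = _lumped_fold_scale(member, {"PFOR": 1.5})
        R_idx, P_idx = _rate_arrays(member)
        x = _initial_state(member, {"PFOR": 1.5})
        sol = solve_ivp(
            lambda t, y: decomposition.N @ _step_rates(y, kf, kb, R_idx, P_idx),
            (0, 100.0), x, method="LSODA", rtol=1e-10, atol=1e-12,
        )
        xf = sol.y[:, -1]
        for rid, states in decomposition.enzyme_states.items():
            want = 1.5 if rid == "PFOR" else 1.0
            tot0 = member.e_ref[states].sum() * want
            tot = xf[states].sum()
            assert tot == pytest.approx(tot0, rel=1e-9), rid

    def test_negative_fold_change_rejected(self, decomposition, reference):
        member = sample_member(decomposition, reference, seed=1)
        with pytest.raises(ValueError):
            simulate_steady_state(member, {"PFOR": -1.0})


class TestStability:
    def test_single_degradation_step_stable(self):
        """x' = -k x: one negative eigenvalue."""
        decomp = _manual_decomp(["X"], [Step("DEG", (0,), ())])
        member = EnsembleMember(
            decomp, kf=np.array([1.0]), kb=np.array([0.0]),
            e_ref=np.zeros(1), reversibilities={}, dG={}, seed=0,
        )
        assert check_stability(member)

    def test_autocatalytic_toy_unstable(self):
        """X -> 2X autocatalysis outpacing removal: positive eigenvalue.

        The 2x2 Jacobian is diag(2 - 0.5, -0.3): one unstable mode.
        """
        decomp = _manual_decomp(
            ["X", "A"],
            [
                Step("AUTO", (0,), (0,), {0: 1.0}),  # rate k*x, net +1 X
                Step("DEGX", (0,), ()),
                Step("DEGA", (1,), ()),
            ],
        )
        member = EnsembleMember(
            decomp, kf=np.array([2.0, 0.5, 0.3]), kb=np.zeros(3),
            e_ref=np.zeros(2), reversibilities={}, dG={}, seed=0,
        )
        assert not check_stability(member)

    def test_verdict_agrees_with_long_integration_on_toy_members(self, two_step, two_step_ref):
        decomp = decompose(two_step, two_step_ref.v_ref)
        agree = 0
        for seed in range(20):
            member = sample_member(decomp, two_step_ref, seed=seed)
            verdict = check_stability(member)
            sim = simulate_steady_state(member, {"STEP1": 1.05}, t_max=1e5)
            if verdict:
                back = sim.stable and all(
                    abs(sim.fluxes[r] - v) / max(abs(v), 1e-6) < 0.5
                    for r, v in two_step_ref.v_ref.items() if r in sim.fluxes and abs(v) > 0
                )
            else:
                back = not sim.stable
            agree += bool(back == True)
        assert agree >= 18  # small slack: borderline members may time out


def _manual_decomp(species, steps):
    import numpy as np

    from gfd.model import MetabolicNetwork, Metabolite, Reaction
    from fractions import Fraction as F

    net = MetabolicNetwork(
        [Metabolite(s) for s in species],
        [Reaction("DUMMY", {species[0]: F(1)}, 0, 1)],
        id="manual",
    )
    N = np.zeros((len(species), len(steps)))
    for j, st in enumerate(steps):
        for idx in st.reactants:
            N[idx, j] -= (st.coeffs or {}).get(idx, 1.0) if st.coeffs and idx in st.coeffs else 1.0
        for idx in st.products:
            if st.coeffs and idx in st.coeffs:
                continue  # handled below via explicit coeffs
            N[idx, j] += 1.0
    for j, st in enumerate(steps):
        if st.coeffs:
            for idx, c in st.coeffs.items():
                N[idx, j] = c
    return ElementaryDecomposition(
        net, list(species), {s: i for i, s in enumerate(species)}, len(species),
        list(steps), {"ALL": list(range(len(steps)))}, {"ALL": False}, {}, set(), N,
    )


class TestScreening:
    def test_infinite_tolerance_retains_stable_members(self, decomposition, reference):
        members = [sample_member(decomposition, reference, seed=s) for s in range(12)]
        stable = [m for m in members if check_stability(m)]
        ens = screen_ensemble(members, [], tolerance=math.inf, ensemble_size=len(members))
        assert {m.seed for m in ens.members} == {m.seed for m in stable}

    def test_member_failing_one_condition_excluded(self, two_step, two_step_ref):
        decomp = decompose(two_step, two_step_ref.v_ref)
        members = [sample_member(decomp, two_step_ref, seed=s) for s in range(6)]
        ok = TrainingCondition("ok", {"EX_S": 1.0}, {"STEP2": 1.0})
        impossible = TrainingCondition("impossible", {"EX_S": 1.0}, {"STEP2": 50.0})
        kept = screen_ensemble(members, [ok], tolerance=0.2, ensemble_size=6)
        with pytest.warns(UserWarning):
            none = screen_ensemble(members, [ok, impossible], tolerance=0.2, ensemble_size=6)
        assert len(none) == 0
        assert len(kept) >= 1
        verdicts = [r["verdict"] for r in none.provenance["screening"]]
        assert any(v.startswith("misfit@impossible") for v in verdicts)

    def test_parameter_recovery_on_toy(self, two_step, two_step_ref):
        """Screening against truth-generated data keeps truth-like members."""
        from scipy.stats import spearmanr

        decomp = decompose(two_step, two_step_ref.v_ref)
        truth = sample_member(decomp, two_step_ref, seed=1000)
        probe_fcs = [{"STEP1": f} for f in (0.5, 0.8, 1.2, 1.6, 2.0)] + [
            {"STEP2": f} for f in (0.5, 0.8, 1.2, 1.6, 2.0)
        ]

        def responses(member):
            out = []
            for fc in probe_fcs:
                sim = simulate_steady_state(member, fc)
                out.append(sim.fluxes["STEP2"] if sim.stable else np.nan)
            return np.array(out)

        truth_resp = responses(truth)
        train = [
            TrainingCondition(f"c{i}", fc, {"STEP2": float(truth_resp[i])})
            for i, fc in enumerate(probe_fcs[:3])
        ]
        candidates = [sample_member(decomp, two_step_ref, seed=s) for s in range(40)]
        kept = screen_ensemble(candidates, train, tolerance=0.02, ensemble_size=5)
        assert len(kept) >= 1
        for m in kept.members:
            rho = spearmanr(truth_resp, responses(m), nan_policy="omit").statistic
            assert rho >= 0.8
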