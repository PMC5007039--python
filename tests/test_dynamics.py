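"""Update formalism: targets, priority classes, steady-state detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qualnet as qn
from qualnet.dynamics import ClampSpec, is_fixed_point, relax_fast, target_value


def state_of(model, **acts):
    """Slow = 1 / fast = value decomposition for prescribed activities."""
    full = {n: 0.0 for n in model.node_names}
    full.update(acts)
    return qn.SystemState.from_activities(model, full)


class TestTargetValue:
    def test_single_silent_activator_gives_zero(self, toggle):
        # B at 0 means no repression: A's basal drive saturates it instead
        m = qn.make_cascade(2)
        st_ = state_of(m, X0=0.0, X1=0.3)
        assert target_value(m, ("X1", "slow"), st_) == 0.0

    def test_saturating_input_clamps_to_one(self):
        m = qn.make_self_activator(weight=2.0)
        st_ = state_of(m, X=0.9)
        assert target_value(m, ("X", "slow"), st_) == 1.0

    def test_neutral_fast_variable_is_one(self, toggle):
        st_ = state_of(toggle, A=0.5, B=0.5)
        assert target_value(toggle, ("A", "fast"), st_) == 1.0

    def test_receptor_fast_follows_absent_ligand(self, chondro):
        # without PTHRP the transcribed PPR receptor stays inactive
        st_ = state_of(chondro, PTHRP=0.0, SOX9=1.0)
        assert target_value(chondro, ("PPR", "fast"), st_) == 0.0

    def test_clamped_source_contributes_clamp_level(self, chondro):
        st_ = state_of(chondro, PTHRP=0.0)
        clamp = (ClampSpec.overactivation("PTHRP"),)
        assert target_value(chondro, ("PPR", "fast"), st_, clamp) == 1.0

    def test_unknown_variable_raises(self, toggle):
        with pytest.raises(KeyError):
            target_value(toggle, ("nope", "slow"), state_of(toggle))


class TestRelaxFast:
    def test_idempotent_at_equilibrium(self, chondro, rng):
        st0 = qn.random_state(chondro, rng)
        st1, n1, ok = relax_fast(chondro, st0, rng=rng)
        assert ok
        st2, n2, _ = relax_fast(chondro, st1, rng=rng)
        assert n2 == 0
        assert np.array_equal(st1.fast, st2.fast)

    def test_postcondition_all_fast_on_target(self, chondro, rng):
        st0 = qn.random_state(chondro, rng)
        st1, _, ok = relax_fast(chondro, st0, rng=rng)
        assert ok
        for node in chondro.node_names:
            t = target_value(chondro, (node, "fast"), st1)
            assert abs(t - st1.fast[chondro.node_names.index(node)]) <= 1e-9
        # slow variables untouched
        assert np.array_equal(st0.slow, st1.slow)


class TestSimulate:
    def test_fixed_point_converges_in_zero_updates(self, chondro, chondro_attractors, rng):
        att = chondro_attractors.attractors[0]
        res = qn.simulate(chondro, att.state, rng=rng)
        assert res.converged and res.n_slow_updates == 0

    def test_toggle_biased_starts_reach_their_pole(self, toggle, rng):
        hi_a = qn.SystemState(("A", "B"), np.array([0.9, 0.1]), np.array([1.0, 1.0]))
        res = qn.simulate(toggle, hi_a, rng=rng)
        assert res.converged
        assert res.final_state.activity_dict() == {"A": 1.0, "B": 0.0}
        hi_b = qn.SystemState(("A", "B"), np.array([0.1, 0.9]), np.array([1.0, 1.0]))
        res = qn.simulate(toggle, hi_b, rng=rng)
        assert res.final_state.activity_dict() == {"A": 0.0, "B": 1.0}

    def test_converged_state_is_a_genuine_fixed_point(self, chondro):
        rng = np.random.default_rng(7)
        for _ in range(5):
            res = qn.simulate(chondro, qn.random_state(chondro, rng), rng=rng)
            assert res.converged
            assert is_fixed_point(chondro, res.final_state)

    def test_priority_ordering_no_slow_update_with_fast_off_target(self, chondro):
        rng = np.random.default_rng(3)
        violations = []

        def observer(phase, node, state):
            if phase == "slow_update":
                for nm in chondro.node_names:
                    t = target_value(chondro, (nm, "fast"), state)
                    cur = state.fast[chondro.node_names.index(nm)]
                    if abs(t - cur) > 1e-9:
                        violations.append((node, nm))

        qn.simulate(chondro, qn.random_state(chondro, rng), rng=rng, observer=observer)
        assert not violations

    def test_determinism_under_seed(self, chondro):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            res = qn.simulate(chondro, qn.random_state(chondro, rng), rng=rng)
            outs.append((res.n_slow_updates, res.final_state.slow.copy(), res.final_state.fast.copy()))
        assert outs[0][0] == outs[1][0]
        assert np.array_equal(outs[0][1], outs[1][1])
        assert np.array_equal(outs[0][2], outs[1][2])

    def test_clamp_duration_expires_and_dynamics_resume(self, cascade):
        rng = np.random.default_rng(0)
        st0 = qn.random_state(cascade, rng)
        res = qn.simulate(cascade, st0, clamps=(ClampSpec.knockout("X0", duration=5),), rng=rng)
        # after the transient head knockout expires the chain re-fills to 1
        assert res.converged
        assert all(v == 1.0 for v in res.final_state.activity_dict().values())

    def test_permanent_knockout_silences_downstream(self, cascade, rng):
        res = qn.simulate(cascade, qn.random_state(cascade, rng),
                          clamps=(ClampSpec.knockout("X0"),), rng=rng)
        assert res.converged
        acts = res.final_state.activity_dict()
        assert acts["X0"] == 0.0 and acts["X4"] == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_variables_stay_in_unit_interval(seed):
    """Clamping invariant under fuzzed models, states and clamps."""
    rng = np.random.default_rng(seed)
    model = qn.random_network(qn.RandomNetworkSpec(n_nodes=4, edge_density=0.5, seed=seed))
    clamps = ()
    if seed % 3 == 0:
        clamps = (ClampSpec.fixed("N1", level=float(rng.uniform()), duration=int(rng.integers(0, 8))),)
    res = qn.simulate(model, qn.random_state(model, rng), clamps=clamps, rng=rng,
                      max_slow_updates=300)
    for arr in (res.final_state.slow, res.final_state.fast):
        assert np.all(arr >= 0.0) and np.all(arr <= 1.0)


class TestRandomState:
    def test_seed_contract(self, chondro):
        a = qn.random_state(chondro, np.random.default_rng(5))
        b = qn.random_state(chondro, np.random.default_rng(5))
        assert np.array_equal(a.slow, b.slow) and np.array_equal(a.fast, b.fast)

    def test_uniform_mean(self, toggle):
        rng = np.random.default_rng(0)
        draws = np.array([qn.random_state(toggle, rng).slow for _ in range(10_000)])
        assert 0.48 <= draws[:, 0].mean() <= 0.52

    def test_constitutive_nodes_start_at_one(self, chondro):
        st_ = qn.random_state(chondro, np.random.default_rng(2))
        i = chondro.node_names.index("GSK3B")
        assert st_.slow[i] == 1.0 and st_.fast[i] == 1.0
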