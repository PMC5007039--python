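"""Transient perturbations, duration plateau, transition matrix, stationary."""

import math

import numpy as np
import pytest

import qualnet as qn
from qualnet.attractors import LABELS
from qualnet.perturbation import (
    TransitionMatrix,
    build_transition_matrix,
    feasible_directions,
    stationary,
)


@pytest.fixture(scope="module")
def toggle_attractors():
    m = qn.make_toggle_switch()
    return m, qn.find_attractors(m, 1500, seed=8)


class TestPerturbAttractor:
    def test_zero_duration_is_neutral(self, chondro, chondro_attractors):
        for att in chondro_attractors:
            for node in ("BMP", "SOX9", "IHH"):
                for d in feasible_directions(att, node):
                    out = qn.perturb_attractor(chondro, att, node, d, 0, 20, seed=2)
                    assert out.outcome_fractions[att.label] == 1.0

    def test_outcome_fractions_sum_to_one(self, chondro, chondro_attractors):
        att = chondro_attractors.by_label("SOX9")
        out = qn.perturb_attractor(chondro, att, "BMP", "max", 10, 50, seed=3)
        assert sum(out.outcome_fractions.values()) == pytest.approx(1.0)

    def test_infeasible_direction_raises(self, chondro, chondro_attractors):
        att = chondro_attractors.by_label("None")
        # GSK3B is constitutive (activity 1): cannot be maximised further
        with pytest.raises(ValueError, match="infeasible"):
            qn.perturb_attractor(chondro, att, "GSK3B", "max", 5, 10, seed=1)

    def test_toggle_saturating_clamp_flips_the_switch(self, toggle_attractors):
        m, atts = toggle_attractors
        a_pole = atts.by_label("SOX9")
        out = qn.perturb_attractor(m, a_pole, "B", "max", duration=10, n_reps=50, seed=4)
        assert out.outcome_fractions["RUNX2"] == 1.0

    def test_exit_fraction_monotone_in_magnitude_on_toggle(self, toggle_attractors):
        m, atts = toggle_attractors
        a_pole = atts.by_label("SOX9")
        fracs = []
        for level in (0.2, 0.4, 0.6, 0.8):
            out = qn.perturb_attractor(m, a_pole, "B", "max", duration=10,
                                       n_reps=40, seed=5, level=level)
            fracs.append(out.exit_fraction)
        assert fracs == sorted(fracs)
        # deterministic threshold of the toggle: B level > 0.5 represses A
        assert fracs[0] == 0.0 and fracs[-1] == 1.0


class TestSaturateDuration:
    def test_plateau_on_toggle(self, toggle_attractors):
        m, atts = toggle_attractors
        t_star = qn.saturate_duration(m, atts.by_label("SOX9"), "B", "max",
                                      seed=6, n_reps=40)
        assert t_star >= 1
        out = qn.perturb_attractor(m, atts.by_label("SOX9"), "B", "max",
                                   t_star, 40, seed=7)
        assert out.outcome_fractions["RUNX2"] == 1.0

    def test_orphan_perturbation_plateaus_immediately(self):
        from qualnet.model import InteractionRule, NetworkModel, NodeSpec
        model = NetworkModel(
            nodes=(NodeSpec("A", marker_role="sox9_marker"),
                   NodeSpec("B", marker_role="runx2_marker"),
                   NodeSpec("C")),
            rules=(InteractionRule("BASAL", "A", 1, 1.0, "slow"),
                   InteractionRule("A", "B", -1, 2.0, "slow"),
                   InteractionRule("A", "C", 1, 1.0, "slow")),
        )
        atts = qn.find_attractors(model, 200, seed=1)
        t_star = qn.saturate_duration(model, atts.attractors[0], "C", "min",
                                      seed=2, n_reps=20)
        assert t_star == 1


class TestMinimalMagnitude:
    def test_zero_offset_never_exits(self, chondro, chondro_attractors):
        att = chondro_attractors.by_label("RUNX2")
        out = qn.perturb_attractor(chondro, att, "SMAD3", "max", 20, 30, seed=3,
                                   level=att.activities["SMAD3"])
        assert out.exit_fraction == 0.0

    def test_stable_node_reports_infinity(self, toggle_attractors):
        m, atts = toggle_attractors
        # pushing the winning node higher can never destabilise its own pole
        mm = qn.minimal_magnitude(m, atts.by_label("SOX9"), "A", "min",
                                  duration=1, n_reps=10, seed=2, max_offset=0.3)
        assert mm == math.inf or mm > 0.3  # small pushes of A are tolerated

    def test_toggle_threshold_located(self, toggle_attractors):
        m, atts = toggle_attractors
        mm = qn.minimal_magnitude(m, atts.by_label("SOX9"), "B", "max",
                                  duration=10, n_reps=20, seed=3)
        # exit requires the clamped repressor to clear the saddle at 1/3
        assert 0.30 <= mm <= 0.40


class TestTransitionMatrix:
    def test_single_attractor_chain_is_identity(self):
        from qualnet.model import InteractionRule, NetworkModel, NodeSpec
        model = NetworkModel(
            nodes=(NodeSpec("A", marker_role="sox9_marker"),
                   NodeSpec("B", marker_role="runx2_marker")),
            rules=(InteractionRule("BASAL", "A", 1, 1.0, "slow"),
                   InteractionRule("A", "B", -1, 2.0, "slow")),
        )
        atts = qn.find_attractors(model, 200, seed=1)
        tm = build_transition_matrix(model, atts, duration=5, n_reps=20,
                                     n_batches=1, seed=2)
        assert tm.P.shape == (1, 1)
        assert tm.P[0, 0] == pytest.approx(1.0)

    def test_rows_stochastic_on_chondrocyte(self, chondro, chondro_attractors):
        tm = build_transition_matrix(chondro, chondro_attractors, duration=10,
                                     n_reps=20, n_batches=1, seed=4)
        assert tm.labels == tuple(LABELS)
        assert np.allclose(tm.P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(tm.P >= 0) and np.all(tm.P <= 1)

    def test_row_normalisation_guard(self):
        with pytest.raises(ValueError, match="rows must sum to 1"):
            TransitionMatrix(labels=("a", "b"), P=np.array([[0.5, 0.4], [0.0, 1.0]]))


class TestStationary:
    def test_identity_reported_reducible(self):
        tm = TransitionMatrix(labels=("SOX9", "RUNX2", "None"), P=np.eye(3))
        pi = stationary(tm)
        assert not pi.irreducible
        assert pi.pi.sum() == pytest.approx(1.0)

    def test_matches_power_iteration_oracle_on_random_chains(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            P = rng.uniform(0.01, 1.0, size=(3, 3))
            P /= P.sum(axis=1, keepdims=True)
            tm = TransitionMatrix(labels=("a", "b", "c"), P=P)
            pi = stationary(tm)
            assert pi.irreducible
            limit = np.linalg.matrix_power(P, 1000)[0]
            assert np.allclose(pi.pi, limit, atol=1e-9)
            assert np.max(np.abs(pi.pi @ P - pi.pi)) < 1e-9

    def test_chondrocyte_chain_fixed_vector(self, chondro, chondro_attractors):
        tm = build_transition_matrix(chondro, chondro_attractors, duration=10,
                                     n_reps=20, n_batches=1, seed=4)
        pi = stationary(tm)
        assert pi.pi.sum() == pytest.approx(1.0)
        assert np.max(np.abs(pi.pi @ tm.P - pi.pi)) < 1e-9
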