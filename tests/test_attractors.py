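"""Attractor classification, discovery and basin estimation."""

import numpy as np
import pytest

import qualnet as qn
from qualnet.attractors import classify_activities
from qualnet.model import InteractionRule, NetworkModel, NodeSpec


class TestClassify:
    @pytest.mark.parametrize(
        "sox9, runx2, expected",
        [
            (1.0, 0.0, ("SOX9", False)),
            (0.0, 1.0, ("RUNX2", False)),
            (0.0, 0.0, ("None", False)),
            (0.04, 0.04, ("None", False)),  # both under threshold
            (0.2, 1.0, ("RUNX2", True)),  # dual state: larger marker wins
            (0.9, 0.2, ("SOX9", True)),
        ],
    )
    def test_marker_rules(self, sox9, runx2, expected):
        assert classify_activities(sox9, runx2) == expected

    def test_model_level_classify_needs_markers(self, cascade):
        with pytest.raises(KeyError):
            qn.classify(cascade, {n: 0.0 for n in cascade.node_names})

    def test_model_level_classify(self, chondro, chondro_attractors):
        att = chondro_attractors.by_label("SOX9")
        assert qn.classify(chondro, att.activities) == ("SOX9", False)


def _one_attractor_model():
    """A (sox9 marker) basally on, B (runx2 marker) repressed by A."""
    return NetworkModel(
        nodes=(NodeSpec("A", marker_role="sox9_marker"),
               NodeSpec("B", marker_role="runx2_marker")),
        rules=(InteractionRule("BASAL", "A", 1, 1.0, "slow"),
               InteractionRule("A", "B", -1, 2.0, "slow")),
    )


class TestFindAttractors:
    def test_chondrocyte_wild_type_has_three(self, chondro_attractors):
        assert sorted(chondro_attractors.labels) == ["None", "RUNX2", "SOX9"]
        assert not any(a.dual_flag for a in chondro_attractors)

    def test_sorted_by_support(self, chondro_attractors):
        supports = [a.support for a in chondro_attractors]
        assert supports == sorted(supports, reverse=True)

    def test_dedup_stable_under_halved_tolerance(self, chondro):
        a = qn.find_attractors(chondro, 1500, seed=3, delta_attr=0.005)
        b = qn.find_attractors(chondro, 1500, seed=3, delta_attr=0.0025)
        assert len(a) == len(b)

    def test_single_attractor_model(self):
        atts = qn.find_attractors(_one_attractor_model(), 500, seed=0)
        assert len(atts) == 1 and atts.attractors[0].label == "SOX9"

    def test_requires_at_least_one_restart(self, toggle):
        with pytest.raises(ValueError):
            qn.find_attractors(toggle, 0, seed=0)


class TestEstimateBasins:
    def test_fractions_and_counts_are_consistent(self, chondro):
        est = qn.estimate_basins(chondro, 600, 3, seed=21)
        assert sum(est.counts.values()) == est.n_total
        assert abs(sum(est.fractions.values()) - 1.0) < 1e-12
        assert all(isinstance(c, int) for c in est.counts.values())
        assert est.n_batches == 3
        for lab, se in est.se.items():
            p = est.fractions[lab]
            assert se == pytest.approx((p * (1 - p) / est.n_total) ** 0.5)

    def test_single_attractor_fraction_is_exactly_one(self):
        est = qn.estimate_basins(_one_attractor_model(), 400, 2, seed=1)
        assert est.fractions["SOX9"] == 1.0

    def test_toggle_half_half_within_three_se(self, toggle):
        est = qn.estimate_basins(toggle, 3000, 3, seed=2)
        se = est.se["SOX9"]
        assert abs(est.fractions["SOX9"] - 0.5) <= 3 * se

    def test_permanent_clamp_changes_basins(self, chondro):
        est = qn.estimate_basins(chondro, 400, 2, seed=3,
                                 clamps=(qn.ClampSpec.knockout("SOX9"),))
        assert est.fractions["SOX9"] == 0.0


@pytest.fixture(scope="module")
def toggle_plus_orphan_screen():
    # C has no outgoing rules: clamping it cannot move any basin
    model = NetworkModel(
        nodes=(NodeSpec("A", marker_role="sox9_marker"),
               NodeSpec("B", marker_role="runx2_marker"),
               NodeSpec("C")),
        rules=(InteractionRule("B", "A", -1, 2.0, "slow"),
               InteractionRule("A", "B", -1, 2.0, "slow"),
               InteractionRule("BASAL", "C", 1, 1.0, "slow"),
               InteractionRule("A", "C", -1, 0.5, "slow")),
    )
    return model, qn.mutant_screen(model, 800, 3, seed=5)


class TestMutantScreen:

    def test_baseline_shared_and_deltas_consistent(self, toggle_plus_orphan_screen):
        _, screen = toggle_plus_orphan_screen
        for res in screen:
            for lab in ("SOX9", "RUNX2", "None"):
                assert res.delta[lab] == pytest.approx(
                    res.basin.fractions[lab] - res.baseline.fractions[lab]
                )

    def test_knockout_of_marker_node_empties_its_basin(self, toggle_plus_orphan_screen):
        _, screen = toggle_plus_orphan_screen
        ko_a = next(r for r in screen if r.condition == ("A", "KO"))
        assert ko_a.basin.fractions["SOX9"] == 0.0
        assert ko_a.basin.fractions["RUNX2"] == 1.0

    def test_orphan_node_has_null_deltas(self, toggle_plus_orphan_screen):
        _, screen = toggle_plus_orphan_screen
        for res in screen:
            if res.node != "C":
                continue
            for lab in ("SOX9", "RUNX2"):
                assert abs(res.delta[lab]) <= 3 * res.delta_se(lab) + 1e-12

    def test_pinned_direction_is_skipped(self):
        # A sits at 1 in the single attractor: overactivation is a no-op
        screen = qn.mutant_screen(_one_attractor_model(), 300, 2, seed=9)
        assert ("A", "OE") not in [r.condition for r in screen]
        assert ("A", "KO") in [r.condition for r in screen]
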