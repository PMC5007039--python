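"""Attractor discovery, phenotype classification and basin estimation.

Attractors (fixed points of the asynchronous dynamics) are found by Monte
Carlo restarts from random initial states and classified by the activity
of the two phenotype marker nodes: a SOX9-positive state is read as a
stable (proliferating) chondrocyte, a RUNX2-positive one as hypertrophic,
and a state with neither marker active as 'None'.  The fraction of random
initial states absorbed by each phenotype estimates the relative size of
its attractor basin (robustness in canalisation); re-estimating the
fractions under a permanent single-node knockout or overactivation screens
every factor's contribution to canalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._compiled import compile_model
from ._kernel import derive_seed, random_initial_states, run_batch
from .dynamics import ClampSpec, SystemState, is_fixed_point
from .model import NetworkModel

__all__ = [
    "LABELS",
    "THETA",
    "DELTA_ATTR",
    "Attractor",
    "AttractorSet",
    "BasinEstimate",
    "ScreenResult",
    "classify",
    "classify_activities",
    "find_attractors",
    "estimate_basins",
    "mutant_screen",
]

LABELS = ("SOX9", "RUNX2", "None")

THETA = 0.05
"""Marker activity threshold for phenotype calls.  The wild-type attractors
have markers at 0 or (near) 1, so any small threshold reproduces them."""

DELTA_ATTR = 0.005
"""Max-norm tolerance for deduplicating attractor activity vectors."""


def classify_activities(
    sox9: float, runx2: float, theta: float = THETA
) -> tuple[str, bool]:
    """Label a state from its two marker activities.

    Returns ``(label, dual_flag)``; when both markers exceed ``theta`` the
    larger one wins and the dual flag is set.
    """
    s_on = sox9 > theta
    r_on = runx2 > theta
    if s_on and r_on:
        return ("SOX9" if sox9 >= runx2 else "RUNX2"), True
    if s_on:
        return "SOX9", False
    if r_on:
        return "RUNX2", False
    return "None", False


def classify(
    model: NetworkModel, activities: Mapping[str, float], theta: float = THETA
) -> tuple[str, bool]:
    """Phenotype call for a full activity vector using the model's markers."""
    sox9 = model.marker("sox9_marker")
    runx2 = model.marker("runx2_marker")
    if sox9 is None or runx2 is None:
        raise KeyError("model does not define both sox9 and runx2 marker nodes")
    return classify_activities(activities[sox9], activities[runx2], theta)


@dataclass
class Attractor:
    """A fixed point with its phenotype label.

    ``support`` is the number of restarts that converged to it; ``state``
    keeps one exact (slow, fast) representative so perturbation analyses
    can restart the dynamics from the attractor itself.
    """

    activities: dict[str, float]
    label: str | None
    dual_flag: bool
    support: int
    state: SystemState

    def activity(self, node: str) -> float:
        return self.activities[node]


@dataclass
class AttractorSet:
    attractors: list[Attractor]
    n_restarts: int
    n_unconverged: int

    def __iter__(self):
        return iter(self.attractors)

    def __len__(self) -> int:
        return len(self.attractors)

    def by_label(self, label: str) -> Attractor:
        for att in self.attractors:
            if att.label == label:
                return att
        raise KeyError(f"no attractor labelled {label}")

    @property
    def labels(self) -> list[str | None]:
        return [a.label for a in self.attractors]


def _dedup(acts: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max-norm clustering; returns (representative indices, assignment)."""
    reps: list[int] = []
    assign = np.empty(acts.shape[0], dtype=np.int64)
    for i in range(acts.shape[0]):
        found = -1
        for k, r in enumerate(reps):
            if np.max(np.abs(acts[i] - acts[r])) <= delta:
                found = k
                break
        if found < 0:
            reps.append(i)
            found = len(reps) - 1
        assign[i] = found
    return np.array(reps, dtype=np.int64), assign


def find_attractors(
    model: NetworkModel,
    n_restarts: int,
    seed: int,
    clamps: Sequence[ClampSpec] = (),
    theta: float = THETA,
    delta_attr: float = DELTA_ATTR,
    check_fixed_points: bool = True,
) -> AttractorSet:
    """Identify attractors numerically from random restarts.

    Endpoints of converged trajectories are deduplicated at max-norm
    tolerance ``delta_attr`` and returned sorted by decreasing support;
    attractors with very small basins may be missed, which is inherent to
    the Monte Carlo approach.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    cm = compile_model(model)
    S, F = random_initial_states(model, n_restarts, derive_seed(seed, 0))
    res = run_batch(model, S, F, clamps=clamps, seed=derive_seed(seed, 1))
    ok = res.converged
    acts = res.activities[ok]
    n_unconverged = int(n_restarts - ok.sum())
    if acts.shape[0] == 0:
        return AttractorSet([], n_restarts, n_unconverged)

    # cheap pre-binning, then exact greedy clustering of the bin reps
    rounded = np.round(acts / delta_attr).astype(np.int64)
    _, first_idx, counts = np.unique(
        rounded, axis=0, return_index=True, return_counts=True
    )
    reps, assign = _dedup(acts[first_idx], delta_attr)
    has_markers = cm.sox9_idx >= 0 and cm.runx2_idx >= 0

    attractors: list[Attractor] = []
    for k, r in enumerate(reps):
        members = first_idx[assign == k]
        support = int(counts[assign == k].sum())
        i0 = int(members[0])
        orig = np.nonzero(ok)[0][i0]
        state = SystemState(cm.names, res.slow[orig].copy(), res.fast[orig].copy())
        a = acts[i0]
        label: str | None = None
        dual = False
        if has_markers:
            label, dual = classify_activities(
                float(a[cm.sox9_idx]), float(a[cm.runx2_idx]), theta
            )
        att = Attractor(
            activities={nm: float(a[j]) for j, nm in enumerate(cm.names)},
            label=label,
            dual_flag=dual,
            support=support,
            state=state,
        )
        if check_fixed_points and not is_fixed_point(model, state, clamps):
            # should not happen for converged trajectories; keep but flag hard
            raise AssertionError(
                f"endpoint classified as attractor fails the fixed-point check: {att.activities}"
            )
        attractors.append(att)
    attractors.sort(key=lambda x: -x.support)
    return AttractorSet(attractors, n_restarts, n_unconverged)


@dataclass
class BasinEstimate:
    """Monte Carlo basin-size estimate per phenotype label."""

    counts: dict[str, int]
    n_total: int
    n_unconverged: int
    batch_fractions: list[dict[str, float]]
    sigma: float
    labels: tuple[str, ...] = LABELS

    @property
    def fractions(self) -> dict[str, float]:
        return {k: (v / self.n_total if self.n_total else math.nan) for k, v in self.counts.items()}

    @property
    def se(self) -> dict[str, float]:
        out = {}
        for k in self.counts:
            p = self.counts[k] / self.n_total if self.n_total else math.nan
            out[k] = math.sqrt(p * (1 - p) / self.n_total) if self.n_total else math.nan
        return out

    @property
    def n_batches(self) -> int:
        return len(self.batch_fractions)


def estimate_basins(
    model: NetworkModel,
    n_per_batch: int,
    n_batches: int,
    seed: int,
    clamps: Sequence[ClampSpec] = (),
    theta: float = THETA,
) -> BasinEstimate:
    """Estimate per-label basin fractions from ``n_batches`` independent
    Monte Carlo batches of ``n_per_batch`` random initial states.

    Clamps, if given, are applied permanently (genetic KO / overactivation).
    Non-converged trajectories are excluded from the fractions and counted
    separately.
    """
    cm = compile_model(model)
    if cm.sox9_idx < 0 or cm.runx2_idx < 0:
        raise KeyError("model does not define both sox9 and runx2 marker nodes")
    counts = {k: 0 for k in LABELS}
    batch_fractions: list[dict[str, float]] = []
    n_total = 0
    n_unconverged = 0
    for b in range(n_batches):
        S, F = random_initial_states(model, n_per_batch, derive_seed(seed, b, 0))
        res = run_batch(model, S, F, clamps=clamps, seed=derive_seed(seed, b, 1))
        acts = res.activities
        bc = {k: 0 for k in LABELS}
        for i in range(n_per_batch):
            if not res.converged[i]:
                n_unconverged += 1
                continue
            label, _ = classify_activities(
                float(acts[i, cm.sox9_idx]), float(acts[i, cm.runx2_idx]), theta
            )
            bc[label] += 1
            n_total += 1
        nb = sum(bc.values())
        batch_fractions.append({k: (bc[k] / nb if nb else math.nan) for k in LABELS})
        for k in LABELS:
            counts[k] += bc[k]
    return BasinEstimate(
        counts=counts,
        n_total=n_total,
        n_unconverged=n_unconverged,
        batch_fractions=batch_fractions,
        sigma=model.saturation,
    )


@dataclass
class ScreenResult:
    node: str
    direction: str  # "KO" | "OE"
    basin: BasinEstimate
    baseline: BasinEstimate
    delta: dict[str, float] = field(default_factory=dict)

    @property
    def condition(self) -> tuple[str, str]:
        return (self.node, self.direction)

    def delta_se(self, label: str) -> float:
        return math.hypot(self.basin.se[label], self.baseline.se[label])


def mutant_screen(
    model: NetworkModel,
    n_per_batch: int,
    n_batches: int,
    seed: int,
    nodes: Sequence[str] | None = None,
    theta: float = THETA,
    attractor_restarts: int | None = None,
) -> list[ScreenResult]:
    """Single-node KO/overactivation canalisation screen.

    Every node is permanently clamped to 0 (KO) and to 1 (OE) in turn and
    the basin fractions re-estimated against the wild-type baseline run
    with the same batch seeds (common random numbers tighten the deltas).
    A direction is skipped when the node is already pinned at that extreme
    in every wild-type attractor.
    """
    baseline = estimate_basins(model, n_per_batch, n_batches, seed, theta=theta)
    wt = find_attractors(
        model, attractor_restarts or max(1000, n_per_batch), derive_seed(seed, 999), theta=theta
    )
    node_list = list(nodes) if nodes is not None else list(model.node_names)
    results: list[ScreenResult] = []
    for node in node_list:
        values = [att.activities[node] for att in wt]
        for direction, level in (("KO", 0.0), ("OE", 1.0)):
            if values and all(abs(v - level) <= theta for v in values):
                continue  # already pinned at this extreme in all attractors
            clamp = (
                ClampSpec.knockout(node) if direction == "KO" else ClampSpec.overactivation(node)
            )
            basin = estimate_basins(
                model, n_per_batch, n_batches, seed, clamps=(clamp,), theta=theta
            )
            delta = {
                k: basin.fractions[k] - baseline.fractions[k] for k in LABELS
            }
            results.append(
                ScreenResult(node=node, direction=direction, basin=basin, baseline=baseline, delta=delta)
            )
    return results
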