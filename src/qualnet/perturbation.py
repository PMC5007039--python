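"""Transient perturbation analysis of attractors and the phenotype
transition Markov chain.

A perturbation clamps one node of a steady state to an extreme (or to an
intermediate level) for a fixed number of slow-scale ticks and then lets
the dynamics settle; repeating this and classifying the endpoints yields
the probability of staying versus transiting to another phenotype.
Averaging over all feasible single-node perturbations gives a 3-state
row-stochastic transition matrix whose stationary distribution is the
long-run phenotype mix of a population under continual random
perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from ._compiled import compile_model
from ._kernel import derive_seed, run_batch
from .attractors import Attractor, AttractorSet, LABELS, THETA, classify_activities
from .dynamics import ClampSpec
from .model import NetworkModel

__all__ = [
    "PerturbationOutcome",
    "TransitionMatrix",
    "StationaryDistribution",
    "feasible_directions",
    "perturb_attractor",
    "saturate_duration",
    "minimal_magnitude",
    "build_transition_matrix",
    "stationary",
]

DEFAULT_DURATION = 20
"""Default clamp duration in slow ticks; chosen on the plateau where doubling
the duration no longer changes the outcome distribution (see
:func:`saturate_duration`)."""


@dataclass
class PerturbationOutcome:
    origin: str | None
    node: str
    direction: str  # "max" | "min"
    magnitude: float
    duration: float
    outcome_fractions: dict[str, float]
    n_reps: int
    n_unconverged: int

    @property
    def return_fraction(self) -> float:
        return self.outcome_fractions.get(self.origin, 0.0)

    @property
    def exit_fraction(self) -> float:
        return 1.0 - self.return_fraction


def feasible_directions(attractor: Attractor, node: str, theta: float = THETA) -> list[str]:
    """Directions in which the node can be perturbed from this attractor.

    Nodes at maximal value are excluded for overactivation and nodes with
    (near-)zero activity are excluded for knockout.
    """
    a = attractor.activities[node]
    dirs = []
    if a < 1.0 - theta:
        dirs.append("max")
    if a > theta:
        dirs.append("min")
    return dirs


def perturb_attractor(
    model: NetworkModel,
    attractor: Attractor,
    node: str,
    direction: str,
    duration: float,
    n_reps: int,
    seed: int,
    level: float | None = None,
    theta: float = THETA,
) -> PerturbationOutcome:
    """Clamp ``node`` for ``duration`` slow ticks, release, settle, classify.

    ``level`` defaults to the extreme implied by ``direction`` (1 for
    ``max``, 0 for ``min``); pass an intermediate value for graded
    perturbations.  Repeats ``n_reps`` times with independent update-order
    randomness.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    if direction not in feasible_directions(attractor, node, theta):
        raise ValueError(
            f"{direction!r} perturbation of {node} is infeasible from the "
            f"{attractor.label} attractor (activity {attractor.activities[node]:.3g})"
        )
    cm = compile_model(model)
    if level is None:
        level = 1.0 if direction == "max" else 0.0
    clamp = ClampSpec.fixed(node, float(level), duration)
    S = np.tile(attractor.state.slow, (n_reps, 1))
    F = np.tile(attractor.state.fast, (n_reps, 1))
    res = run_batch(model, S, F, clamps=(clamp,), seed=derive_seed(seed, 0))
    acts = res.activities
    counts = {k: 0 for k in LABELS}
    n_ok = 0
    for i in range(n_reps):
        if not res.converged[i]:
            continue
        label, _ = classify_activities(
            float(acts[i, cm.sox9_idx]), float(acts[i, cm.runx2_idx]), theta
        )
        counts[label] += 1
        n_ok += 1
    fractions = {k: (counts[k] / n_ok if n_ok else math.nan) for k in LABELS}
    return PerturbationOutcome(
        origin=attractor.label,
        node=node,
        direction=direction,
        magnitude=abs(level - attractor.activities[node]),
        duration=duration,
        outcome_fractions=fractions,
        n_reps=n_reps,
        n_unconverged=n_reps - n_ok,
    )


def saturate_duration(
    model: NetworkModel,
    attractor: Attractor,
    node: str,
    direction: str,
    seed: int,
    n_reps: int = 100,
    tol_tv: float = 0.02,
    t_start: int = 1,
    t_max: int = 512,
) -> int:
    """Smallest clamp duration on the outcome plateau.

    Doubles the duration until the outcome distribution changes by less
    than ``tol_tv`` in total variation between consecutive durations, i.e.
    until a further increase has no effect on the result.
    """
    prev = None
    t = t_start
    k = 0
    while t <= t_max:
        out = perturb_attractor(model, attractor, node, direction, t, n_reps,
                                derive_seed(seed, k))
        if prev is not None:
            tv = 0.5 * sum(
                abs(out.outcome_fractions[l] - prev.outcome_fractions[l]) for l in LABELS
            )
            if tv < tol_tv:
                return t // 2  # the previous duration already sat on the plateau
        prev = out
        t *= 2
        k += 1
    raise RuntimeError(
        f"no outcome plateau up to duration {t_max} for {node} ({direction}); "
        f"last distributions: {prev.outcome_fractions if prev else None}"
    )


def minimal_magnitude(
    model: NetworkModel,
    attractor: Attractor,
    node: str,
    direction: str,
    duration: float,
    n_reps: int,
    seed: int,
    step: float = 0.01,
    max_offset: float = 1.0,
) -> float:
    """Smallest clamp offset from the attractor value that causes any exit.

    Scans clamp levels from the attractor's value towards the extreme in
    increments of ``step``; returns the first offset with a nonzero exit
    fraction, or ``inf`` when no scanned offset destabilises the state.
    """
    a0 = attractor.activities[node]
    n_steps = int(round(max_offset / step))
    for k in range(1, n_steps + 1):
        offset = k * step
        level = a0 + offset if direction == "max" else a0 - offset
        if level > 1.0 + 1e-12 or level < -1e-12:
            break
        level = min(1.0, max(0.0, level))
        out = perturb_attractor(
            model, attractor, node, direction, duration, n_reps,
            derive_seed(seed, k), level=level,
        )
        if out.exit_fraction > 0:
            return offset
    return math.inf


@dataclass
class TransitionMatrix:
    labels: tuple[str, ...]
    P: np.ndarray  # (3, 3) row-stochastic

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"transition matrix rows must sum to 1, got {rows}")

    def prob(self, origin: str, target: str) -> float:
        return float(self.P[self.labels.index(origin), self.labels.index(target)])


@dataclass
class StationaryDistribution:
    labels: tuple[str, ...]
    pi: np.ndarray
    irreducible: bool

    def prob(self, label: str) -> float:
        return float(self.pi[self.labels.index(label)])


def build_transition_matrix(
    model: NetworkModel,
    attractors: AttractorSet | Sequence[Attractor],
    duration: float = DEFAULT_DURATION,
    n_reps: int = 100,
    n_batches: int = 3,
    seed: int = 0,
    theta: float = THETA,
) -> TransitionMatrix:
    """Empirical 3-state transition matrix under one random single-node
    perturbation.

    For each origin attractor the outcome distributions are averaged over
    nodes; a node feasible in both directions contributes the mean of its
    two directions, so every node is equally likely to be the perturbed
    one.  Origins without an attractor (e.g. a clamped model that lost a
    phenotype) raise ``KeyError``.
    """
    atts = list(attractors)
    by_label = {a.label: a for a in atts}
    labels_present = [l for l in LABELS if l in by_label]
    if not labels_present:
        raise KeyError("no labelled attractors supplied")
    P = np.zeros((len(labels_present), len(labels_present)))
    for i, origin in enumerate(labels_present):
        att = by_label[origin]
        node_rows = []
        for j_node, node in enumerate(model.node_names):
            dirs = feasible_directions(att, node, theta)
            if not dirs:
                continue
            dir_rows = []
            for d in dirs:
                reps_rows = []
                for b in range(n_batches):
                    out = perturb_attractor(
                        model, att, node, d, duration, n_reps,
                        derive_seed(seed, i, j_node, 0 if d == "max" else 1, b),
                        theta=theta,
                    )
                    reps_rows.append([out.outcome_fractions[l] for l in labels_present])
                dir_rows.append(np.mean(reps_rows, axis=0))
            node_rows.append(np.mean(dir_rows, axis=0))
        row = np.mean(node_rows, axis=0)
        P[i] = row / row.sum()  # absorb endpoint-classification rounding
    return TransitionMatrix(labels=tuple(labels_present), P=P)


def stationary(
    tm: TransitionMatrix, tol: float = 1e-12, max_iter: int = 100_000
) -> StationaryDistribution:
    """Left fixed vector of the transition matrix.

    Computed by eigen-decomposition and cross-checked against power
    iteration; for a reducible chain the result depends on the initial
    distribution, which is reported via ``irreducible=False`` (the returned
    vector is the power-iteration limit from the uniform distribution).
    """
    P = tm.P
    k = P.shape[0]
    # reducibility: mutual reachability of all states through positive entries
    reach = np.eye(k, dtype=bool) | (P > 0)
    for _ in range(k):
        reach = reach | (reach @ reach)
    irreducible = bool(reach.all() and reach.T.all())

    w, vl = scipy.linalg.eig(P, left=True, right=False)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, i])
    pi = pi / pi.sum()

    # power-iteration cross-check (and fallback for reducible chains)
    q = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        q2 = q @ P
        if np.max(np.abs(q2 - q)) < tol:
            q = q2
            break
        q = q2
    if not irreducible or np.max(np.abs(pi - q)) > 1e-6:
        pi = q
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ P - pi)) > 1e-9:
        raise ArithmeticError("stationary vector failed the fixed-point check")
    return StationaryDistribution(labels=tm.labels, pi=pi, irreducible=irreducible)
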