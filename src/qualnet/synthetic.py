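"""Synthetic network fixtures and an independent fixed-point oracle.

Toy models (toggle switch, signalling cascade) and seeded random networks
share the structural assumptions of the main formalism — signed additive
inputs, two speed classes, values on [0, 1] — so every analysis stage can
be exercised and cross-checked without the chondrocyte model.  The
brute-force oracle enumerates a state-space grid and iterates the
*synchronous* target map, providing attractor ground truth for small
models by a route independent of the asynchronous engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._compiled import compile_model
from .model import InteractionRule, NetworkModel, NodeSpec, validate_model

__all__ = [
    "RandomNetworkSpec",
    "make_toggle_switch",
    "make_cascade",
    "make_self_activator",
    "random_network",
    "brute_force_attractors",
]


def make_toggle_switch(sigma: float = 1.0, inhibition_weight: float = 2.0) -> NetworkModel:
    """Two-node mutual-inhibition switch.

    Each node carries a basal drive and represses the other with weight
    ``inhibition_weight`` (> 1/sigma), giving exactly the two pole fixed
    points (1, 0) and (0, 1).  The nodes double as phenotype markers so the
    full classification/basin machinery runs on this fixture.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    nodes = (
        NodeSpec("A", marker_role="sox9_marker"),
        NodeSpec("B", marker_role="runx2_marker"),
    )
    rules = (
        InteractionRule("B", "A", -1, inhibition_weight, "slow", "mutual repression"),
        InteractionRule("A", "B", -1, inhibition_weight, "slow", "mutual repression"),
    )
    return NetworkModel(nodes=nodes, rules=rules, saturation=sigma, name="toggle")


def make_self_activator(sigma: float = 1.0, weight: float = 2.0) -> NetworkModel:
    """One node with positive autoregulation; bistable ({0, 1}) for
    ``weight`` > 1/sigma."""
    nodes = (NodeSpec("X", marker_role="sox9_marker"),)
    rules = (InteractionRule("X", "X", 1, weight, "slow", "autoactivation"),)
    return NetworkModel(nodes=nodes, rules=rules, saturation=sigma, name="self_activator")


def make_cascade(length: int, sigma: float = 1.0) -> NetworkModel:
    """Linear activation chain with alternating fast/slow links.

    The head node is constitutive; each link activates the next node with
    weight 1, the speed class alternating slow, fast, slow, ...  Nodes
    whose only input is fast are marked constitutive (basal transcription)
    so their slow variable is pinned, mirroring how purely
    post-translationally regulated species are modelled.
    """
    if length < 2:
        raise ValueError("cascade length must be >= 2")
    names = [f"X{i}" for i in range(length)]
    classes = ["slow" if i % 2 == 0 else "fast" for i in range(length - 1)]
    nodes = [NodeSpec(names[0], constitutive=True)]
    for i in range(1, length):
        nodes.append(NodeSpec(names[i], constitutive=(classes[i - 1] == "fast")))
    rules = [
        InteractionRule(names[i], names[i + 1], 1, 1.0, classes[i], "chain link")
        for i in range(length - 1)
    ]
    return NetworkModel(nodes=tuple(nodes), rules=tuple(rules), saturation=sigma, name="cascade")


@dataclass(frozen=True)
class RandomNetworkSpec:
    n_nodes: int
    edge_density: float = 0.4
    inhibitor_fraction: float = 0.3
    fast_fraction: float = 0.3
    weight_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.edge_density, self.inhibitor_fraction, self.fast_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_nodes < 1:
            raise ValueError("need at least one node")


def random_network(spec: RandomNetworkSpec) -> NetworkModel:
    """Seeded random model with the formalism's structural assumptions.

    Node 0 is a constitutive root; every other node is guaranteed at least
    one slow input and reachability from the root, so the model validates
    and its attractors are well defined.  Self-edges are never generated.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    names = [f"N{i}" for i in range(n)]
    roles = ["none"] * n
    if n >= 2:
        roles[1] = "sox9_marker"
    if n >= 3:
        roles[2] = "runx2_marker"
    nodes = [NodeSpec(names[i], constitutive=(i == 0), marker_role=roles[i]) for i in range(n)]

    lo, hi = spec.weight_range
    rules: dict[tuple[str, str, str], InteractionRule] = {}

    def add(src: int, tgt: int, sign: int, speed: str) -> None:
        key = (names[src], names[tgt], speed)
        if key in rules:
            return
        w = float(rng.uniform(lo, hi))
        rules[key] = InteractionRule(names[src], names[tgt], sign, w, speed, "random edge")

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rng.random() < spec.edge_density:
                sign = -1 if rng.random() < spec.inhibitor_fraction else 1
                speed = "fast" if rng.random() < spec.fast_fraction else "slow"
                add(i, j, sign, speed)

    # repair: every non-root node needs a slow input (else its slow variable
    # would be a frozen free parameter and attractors would not be isolated)
    for j in range(1, n):
        if not any(k[1] == names[j] and k[2] == "slow" for k in rules):
            src = int(rng.integers(n - 1))
            src = src if src < j else src + 1  # any node other than j
            add(src, j, 1, "slow")
    # repair: reachability from the constitutive root
    reachable = {0}
    frontier = [0]
    edges = [(names.index(k[0].split("*")[0]), names.index(k[1])) for k in rules]
    while frontier:
        cur = frontier.pop()
        for a, b in edges:
            if a == cur and b not in reachable:
                reachable.add(b)
                frontier.append(b)
    for j in range(1, n):
        if j not in reachable:
            add(0, j, 1, "slow")
            reachable.add(j)

    model = NetworkModel(
        nodes=tuple(nodes), rules=tuple(rules.values()), saturation=1.0,
        name=f"random_{spec.seed}",
    )
    rep = validate_model(model)
    if not rep.ok:  # pragma: no cover - construction guarantees validity
        raise AssertionError("generated model failed validation: " + "; ".join(rep.errors))
    return model


# ---------------------------------------------------------------------------
# brute-force oracle


def _free_variables(cm) -> list[int]:
    """Variables that are genuine degrees of freedom for the oracle grid."""
    free = []
    for v in range(cm.n_vars):
        if cm.has_rules[v]:
            free.append(v)
    return free


def brute_force_attractors(
    model: NetworkModel,
    grid_step: float = 0.01,
    delta_attr: float = 0.005,
    max_states: int = 2_000_000,
    max_iter: int = 300,
) -> list[dict[str, float]]:
    """Grid-enumeration fixed-point oracle for small models.

    Every grid state is iterated under the *damped* synchronous target map
    ``x <- x + 0.5 (target(x) - x)``, which has exactly the same fixed
    points as the dynamics but converges where the undamped map would
    oscillate; states that still move after ``max_iter`` sweeps are
    discarded.  Distinct endpoints (max-norm tolerance ``delta_attr`` on
    activities) are returned; every endpoint satisfies the fixed-point
    residual check.  Note the list contains *all* fixed points on the
    grid, including ones that are unstable under the asynchronous
    dynamics and therefore unreachable from random restarts.  Cost grows
    as ``(1/grid_step + 1) ** n_free_variables`` so only small models are
    accepted.
    """
    cm = compile_model(model)
    for m in range(cm.n):
        if not cm.has_rules[cm.n + m] and not cm.constitutive[m]:
            raise ValueError(
                f"node {cm.names[m]} has a free (undriven) slow variable; "
                "the oracle requires isolated fixed points"
            )
    free = _free_variables(cm)
    n_points = round(1.0 / grid_step) + 1
    n_states = n_points ** len(free)
    if n_states > max_states:
        raise ValueError(
            f"{n_states} grid states exceed the cap ({max_states}); "
            "use a coarser grid_step or a smaller model"
        )
    axis = np.linspace(0.0, 1.0, n_points)
    X = np.ones((n_states, cm.n_vars))
    grids = np.meshgrid(*([axis] * len(free)), indexing="ij")
    for k, v in enumerate(free):
        X[:, v] = grids[k].ravel()

    F = X[:, : cm.n]
    S = X[:, cm.n :]

    def sync_targets(S, F):
        A = np.ones((S.shape[0], cm.n + 1))  # trailing constant slot (BASAL)
        A[:, : cm.n] = S * F
        TF = np.empty_like(F)
        TS = np.empty_like(S)
        for m in range(cm.n):
            TF[:, m] = _column_target(cm, m, A, S)
            TS[:, m] = _column_target(cm, cm.n + m, A, S)
        return TS, TF

    # damped iteration; harvest settled states, keep iterating the movers
    settled_acts: list[np.ndarray] = []
    alpha = 0.5
    for _ in range(max_iter):
        if S.shape[0] == 0:
            break
        TS, TF = sync_targets(S, F)
        moved = (np.abs(TS - S).max(axis=1) > 1e-9) | (np.abs(TF - F).max(axis=1) > 1e-9)
        done = ~moved
        if done.any():
            settled_acts.append((S[done] * F[done]))
        S = S[moved] + alpha * (TS[moved] - S[moved])
        F = F[moved] + alpha * (TF[moved] - F[moved])
    # states still moving after max_iter have not reached any fixed point
    if not settled_acts:
        return []
    A = np.concatenate(settled_acts, axis=0)
    if A.shape[0] == 0:
        return []
    uniq: list[np.ndarray] = []
    # pre-bin for speed, then exact tolerance merge
    rounded = np.round(A / delta_attr)
    _, first = np.unique(rounded, axis=0, return_index=True)
    for i in first:
        a = A[i]
        if not any(np.max(np.abs(a - u)) <= delta_attr for u in uniq):
            uniq.append(a)
    return [{nm: float(u[j]) for j, nm in enumerate(cm.names)} for u in uniq]


def _column_target(cm, v, A, S):
    """Vectorised target of variable ``v`` for a batch of states."""
    n = cm.n
    if not cm.has_rules[v]:
        if v < n:
            return np.ones(A.shape[0])
        m = v - n
        return np.ones(A.shape[0]) if cm.constitutive[m] else S[:, m].copy()
    net = np.zeros(A.shape[0])
    for k in range(cm.term_ptr[v], cm.term_ptr[v + 1]):
        c = cm.term_w[k] * A[:, cm.term_src1[k]]
        if cm.term_src2[k] >= 0:
            c = c * A[:, cm.term_src2[k]]
        net += c
    if not cm.has_pos[v]:
        net += 1.0 / cm.sigma
    return np.clip(cm.sigma * net, 0.0, 1.0)
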