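"""Two-timescale asynchronous network dynamics.

Update formalism
----------------
Every node ``i`` carries a slow variable ``s_i`` (transcript level) and a
fast variable ``f_i`` (post-translational state), both on [0, 1]; its
activity is ``a_i = s_i * f_i``.  Each variable is driven towards a target

    target = clip(sigma * (sum_act w * a  -  sum_inh w * a), 0, 1)

i.e. an additive combination of upstream activities scaled by the global
saturation factor ``sigma``: the larger sigma, the less positive input a
variable needs to reach full activity.  A variable whose rule set contains
only inhibitors receives a basal drive of ``1/sigma`` (active unless
repressed).  A fast variable with no rules at all is neutral (target 1); a
slow variable with no rules holds its value (target 1 for constitutive
nodes, which are produced by default).

Updating is generally asynchronous with two priority classes: while any
fast variable is off its target, one of them (chosen uniformly at random)
is set to its target; only when all fast variables are in equilibrium is a
single randomly chosen slow variable updated.  A state where every
variable equals its target is a fixed point (steady state).

Clamps emulate knockouts / overactivations: a clamped node's activity
reads as the clamp level for the clamp's duration (counted in slow-scale
ticks; ``inf`` = permanent), and its own variables are frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from ._compiled import CompiledModel, compile_model
from .model import NetworkModel

__all__ = [
    "SystemState",
    "ClampSpec",
    "TrajectoryResult",
    "EPS",
    "random_state",
    "target_value",
    "relax_fast",
    "simulate",
]

EPS = 1e-9
"""Equilibrium tolerance: variables are assigned their algebraic target
exactly, so the tolerance only has to absorb floating-point noise."""

DEFAULT_FAST_CAP = 10_000
DEFAULT_SLOW_CAP = 2_000


@dataclass
class SystemState:
    """Per-node slow and fast variables, aligned with ``model.node_names``."""

    names: tuple[str, ...]
    slow: np.ndarray
    fast: np.ndarray

    def __post_init__(self) -> None:
        self.slow = np.asarray(self.slow, dtype=float)
        self.fast = np.asarray(self.fast, dtype=float)
        if self.slow.shape != (len(self.names),) or self.fast.shape != (len(self.names),):
            raise ValueError("state arrays must be one value per node")

    @property
    def activities(self) -> np.ndarray:
        return self.slow * self.fast

    def activity(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.slow[i] * self.fast[i])

    def activity_dict(self) -> dict[str, float]:
        a = self.activities
        return {name: float(a[i]) for i, name in enumerate(self.names)}

    def copy(self) -> "SystemState":
        return SystemState(self.names, self.slow.copy(), self.fast.copy())

    @classmethod
    def from_activities(cls, model: NetworkModel, activities: dict[str, float]) -> "SystemState":
        """Build a state with slow = 1 and fast = activity (valid decomposition
        for re-seeding simulations at a known activity vector)."""
        cm = compile_model(model)
        f = np.array([activities[nm] for nm in cm.names], dtype=float)
        return cls(cm.names, np.ones(cm.n), f)


@dataclass(frozen=True)
class ClampSpec:
    """Hold one node's activity at ``level`` for ``duration`` slow ticks."""

    node: str
    mode: str  # knockout | overactivation | fixed_level
    level: float
    duration: float = math.inf

    def __post_init__(self) -> None:
        if self.mode not in ("knockout", "overactivation", "fixed_level"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("clamp level must lie in [0, 1]")
        if self.duration < 0:
            raise ValueError("clamp duration must be >= 0")

    @classmethod
    def knockout(cls, node: str, duration: float = math.inf) -> "ClampSpec":
        return cls(node, "knockout", 0.0, duration)

    @classmethod
    def overactivation(cls, node: str, duration: float = math.inf) -> "ClampSpec":
        return cls(node, "overactivation", 1.0, duration)

    @classmethod
    def fixed(cls, node: str, level: float, duration: float = math.inf) -> "ClampSpec":
        return cls(node, "fixed_level", level, duration)


@dataclass
class TrajectoryResult:
    final_state: SystemState
    converged: bool
    n_slow_updates: int
    n_fast_updates: int
    cycle_detected: bool


# ---------------------------------------------------------------------------


def random_state(model: NetworkModel, rng: np.random.Generator) -> SystemState:
    """Independent uniform draws for every slow and fast variable;
    constitutive nodes start at full activity."""
    cm = compile_model(model)
    slow = rng.uniform(0.0, 1.0, size=cm.n)
    fast = rng.uniform(0.0, 1.0, size=cm.n)
    slow[cm.constitutive] = 1.0
    fast[cm.constitutive] = 1.0
    return SystemState(cm.names, slow, fast)


def _clamp_arrays(cm: CompiledModel, clamps: Iterable[ClampSpec]):
    clamped = np.zeros(cm.n, dtype=bool)
    level = np.zeros(cm.n, dtype=float)
    remaining = np.zeros(cm.n, dtype=float)
    for c in clamps:
        i = cm.index[c.node]
        clamped[i] = c.duration > 0
        level[i] = c.level
        remaining[i] = c.duration
    return clamped, level, remaining


def _activities(cm: CompiledModel, s, f, clamped, level) -> np.ndarray:
    """Activity vector with the trailing constant-1 slot for BASAL terms."""
    a = np.empty(cm.n + 1)
    a[: cm.n] = s * f
    a[: cm.n][clamped] = level[clamped]
    a[cm.n] = 1.0
    return a


def _target(cm: CompiledModel, v: int, a: np.ndarray, s: np.ndarray) -> float:
    """Equilibrium value variable ``v`` is driven towards, given activities."""
    n = cm.n
    if not cm.has_rules[v]:
        if v < n:  # fast: neutral
            return 1.0
        m = v - n
        return 1.0 if cm.constitutive[m] else float(s[m])
    net = 0.0
    for k in range(cm.term_ptr[v], cm.term_ptr[v + 1]):
        contrib = cm.term_w[k] * a[cm.term_src1[k]]
        if cm.term_src2[k] >= 0:
            contrib *= a[cm.term_src2[k]]
        net += contrib
    if not cm.has_pos[v]:
        net += 1.0 / cm.sigma  # basal drive: active unless repressed
    t = cm.sigma * net
    return min(1.0, max(0.0, t))


def target_value(
    model: NetworkModel,
    variable: tuple[str, str],
    state: SystemState,
    clamps: Sequence[ClampSpec] = (),
) -> float:
    """Target of one ``(node, "fast"|"slow")`` variable in ``state``."""
    cm = compile_model(model)
    node, speed = variable
    if node not in cm.index or speed not in ("fast", "slow"):
        raise KeyError(f"unknown variable {variable!r}")
    clamped, level, _ = _clamp_arrays(cm, clamps)
    a = _activities(cm, state.slow, state.fast, clamped, level)
    v = cm.index[node] + (0 if speed == "fast" else cm.n)
    return _target(cm, v, a, state.slow)


def _off_target(cm, block, s, f, a, clamped, eps):
    """Indices and targets of off-target variables in one priority class.

    ``block`` selects the class: 0 = fast variables, 1 = slow variables.
    """
    n = cm.n
    idx: list[int] = []
    tgt: list[float] = []
    cur = f if block == 0 else s
    for m in range(n):
        if clamped[m]:
            continue
        v = m + block * n
        t = _target(cm, v, a, s)
        if abs(t - cur[m]) > eps:
            idx.append(m)
            tgt.append(t)
    return idx, tgt


def relax_fast(
    model: NetworkModel,
    state: SystemState,
    clamps: Sequence[ClampSpec] = (),
    rng: np.random.Generator | None = None,
    fast_cap: int = DEFAULT_FAST_CAP,
    observer: Callable | None = None,
) -> tuple[SystemState, int, bool]:
    """Drive all fast variables to equilibrium (slow variables untouched).

    Repeatedly picks one off-target fast variable uniformly at random and
    assigns it its target.  Returns ``(new_state, n_updates, converged)``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    cm = compile_model(model)
    st = state.copy()
    clamped, level, _ = _clamp_arrays(cm, clamps)
    n_upd = 0
    while True:
        a = _activities(cm, st.slow, st.fast, clamped, level)
        idx, tgt = _off_target(cm, 0, st.slow, st.fast, a, clamped, EPS)
        if not idx:
            return st, n_upd, True
        if n_upd >= fast_cap:
            return st, n_upd, False
        k = int(rng.integers(len(idx)))
        if observer is not None:
            observer("fast_update", cm.names[idx[k]], st)
        st.fast[idx[k]] = tgt[k]
        n_upd += 1


def simulate(
    model: NetworkModel,
    initial: SystemState,
    clamps: Sequence[ClampSpec] = (),
    rng: np.random.Generator | None = None,
    max_slow_updates: int = DEFAULT_SLOW_CAP,
    fast_cap: int = DEFAULT_FAST_CAP,
    observer: Callable | None = None,
) -> TrajectoryResult:
    """Run the two-class asynchronous dynamics to a steady state.

    Alternates full fast-variable relaxation with single random slow-variable
    updates until every variable is at its target (fixed point) or a cap is
    hit.  Clamp durations are counted in slow-scale ticks; after all clamps
    expire the run continues to convergence.
    """
    rng = rng if rng is not None else np.random.default_rng()
    cm = compile_model(model)
    st = initial.copy()
    clamped, level, remaining = _clamp_arrays(cm, clamps)
    # a clamped node carries its level in whichever of its variables is
    # regulated (slow takes priority) so that on release the perturbation
    # persists exactly as long as the formalism allows: slow variables keep
    # the imprint until re-driven, fast variables re-equilibrate at once
    for m in np.nonzero(clamped)[0]:
        if cm.has_rules[cm.n + m]:  # transcriptionally driven
            st.slow[m] = level[m]
        elif cm.has_rules[m]:  # only post-translationally driven
            st.fast[m] = level[m]
        else:  # unregulated (constitutive source node)
            st.slow[m] = level[m]
            st.fast[m] = 1.0

    n_slow = 0
    n_fast_total = 0
    while True:
        sub, n_fast, ok = relax_fast(model, st, _active_specs(cm, clamped, level, remaining),
                                     rng, fast_cap, observer)
        st = sub
        n_fast_total += n_fast
        if not ok:
            return TrajectoryResult(st, False, n_slow, n_fast_total, True)

        a = _activities(cm, st.slow, st.fast, clamped, level)
        idx, tgt = _off_target(cm, 1, st.slow, st.fast, a, clamped, EPS)
        pending = bool(np.any(clamped & np.isfinite(remaining)))
        if not idx and not pending:
            _normalise_clamped(st, clamped, level)
            return TrajectoryResult(st, True, n_slow, n_fast_total, False)
        if n_slow >= max_slow_updates:
            _normalise_clamped(st, clamped, level)
            return TrajectoryResult(st, False, n_slow, n_fast_total, True)
        if idx:
            k = int(rng.integers(len(idx)))
            if observer is not None:
                observer("slow_update", cm.names[idx[k]], st)
            st.slow[idx[k]] = tgt[k]
        n_slow += 1  # idle ticks still advance the slow clock while clamps run out

        finite = np.isfinite(remaining) & clamped
        remaining[finite] -= 1.0
        expired = finite & (remaining <= 0)
        if np.any(expired):
            clamped[expired] = False


def _normalise_clamped(st: SystemState, clamped, level) -> None:
    """Make still-clamped nodes report their clamp level as activity."""
    st.slow[clamped] = level[clamped]
    st.fast[clamped] = 1.0


def _active_specs(cm, clamped, level, remaining):
    """Re-express the live clamp arrays as specs for ``relax_fast``."""
    return [
        ClampSpec(cm.names[i], "fixed_level", float(level[i]),
                  float(remaining[i]) if np.isfinite(remaining[i]) else math.inf)
        for i in np.nonzero(clamped)[0]
    ]


def is_fixed_point(
    model: NetworkModel,
    state: SystemState,
    clamps: Sequence[ClampSpec] = (),
    eps: float = 1e-6,
) -> bool:
    """One synchronous evaluation: does every variable equal its target?"""
    cm = compile_model(model)
    clamped, level, _ = _clamp_arrays(cm, clamps)
    a = _activities(cm, state.slow, state.fast, clamped, level)
    for block in (0, 1):
        idx, _ = _off_target(cm, block, state.slow, state.fast, a, clamped, eps)
        if idx:
            return False
    return True
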