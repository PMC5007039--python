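"""Compiled batch simulator for Monte Carlo analyses.

Semantics are identical to :mod:`qualnet.dynamics` (same compiled arrays,
same target formula, same two-class asynchronous scheduler); this path
exists because basin estimation and screening run millions of short
trajectories.  Equivalence with the Python engine is asserted in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from ._compiled import CompiledModel, compile_model
from .dynamics import EPS, DEFAULT_FAST_CAP, DEFAULT_SLOW_CAP, ClampSpec
from .model import NetworkModel

__all__ = ["BatchResult", "run_batch", "random_initial_states", "derive_seed"]


def derive_seed(seed: int, *stream: int) -> int:
    """Deterministic child seed (< 2**31) for an independent stream."""
    return int(np.random.SeedSequence((int(seed),) + tuple(int(x) for x in stream)).generate_state(1)[0] % (2**31))


@njit(cache=True)
def _k_target(v, n, a, s, term_ptr, term_src1, term_src2, term_w,
              has_rules, has_pos, const, sigma):
    if not has_rules[v]:
        if v < n:
            return 1.0
        m = v - n
        if const[m]:
            return 1.0
        return s[m]
    net = 0.0
    for k in range(term_ptr[v], term_ptr[v + 1]):
        c = term_w[k] * a[term_src1[k]]
        if term_src2[k] >= 0:
            c *= a[term_src2[k]]
        net += c
    if not has_pos[v]:
        net += 1.0 / sigma
    t = sigma * net
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return t


@njit(cache=True)
def _k_simulate(s, f, term_ptr, term_src1, term_src2, term_w, has_rules, has_pos,
                const, sigma, dep_ptr, dep_var, clamp_idx, clamp_level, clamp_dur,
                max_slow, fast_cap, eps):
    n = s.shape[0]
    clamped = np.zeros(n, np.bool_)
    level = np.zeros(n)
    remaining = np.zeros(n)
    for j in range(clamp_idx.shape[0]):
        i = clamp_idx[j]
        if clamp_dur[j] > 0:
            clamped[i] = True
            level[i] = clamp_level[j]
            remaining[i] = clamp_dur[j]
            # clamp level is parked in the regulated variable (slow first):
            # slow keeps the imprint after release, fast re-equilibrates
            if has_rules[n + i]:
                s[i] = clamp_level[j]
            elif has_rules[i]:
                f[i] = clamp_level[j]
            else:
                s[i] = clamp_level[j]
                f[i] = 1.0
    a = np.empty(n + 1)
    a[n] = 1.0  # constant slot for BASAL terms
    for i in range(n):
        a[i] = level[i] if clamped[i] else s[i] * f[i]

    # target cache, maintained incrementally through the dependency lists
    tgt = np.empty(2 * n)
    for v in range(2 * n):
        tgt[v] = _k_target(v, n, a, s, term_ptr, term_src1, term_src2, term_w,
                           has_rules, has_pos, const, sigma)

    off_idx = np.empty(n, np.int64)
    n_slow = 0
    n_fast = 0
    while True:
        # ---- fast relaxation (priority class 1)
        while True:
            cnt = 0
            for m in range(n):
                if not clamped[m] and abs(tgt[m] - f[m]) > eps:
                    off_idx[cnt] = m
                    cnt += 1
            if cnt == 0:
                break
            if n_fast >= fast_cap:
                return n_slow, n_fast, False
            m = off_idx[np.random.randint(cnt)]
            f[m] = tgt[m]
            a[m] = s[m] * f[m]
            n_fast += 1
            for k in range(dep_ptr[m], dep_ptr[m + 1]):
                v = dep_var[k]
                tgt[v] = _k_target(v, n, a, s, term_ptr, term_src1, term_src2, term_w,
                                   has_rules, has_pos, const, sigma)
        # ---- one slow update (priority class 2)
        cnt = 0
        for m in range(n):
            if not clamped[m] and abs(tgt[n + m] - s[m]) > eps:
                off_idx[cnt] = m
                cnt += 1
        pending = False
        for m in range(n):
            if clamped[m] and np.isfinite(remaining[m]):
                pending = True
                break
        if cnt == 0 and not pending:
            return n_slow, n_fast, True
        if n_slow >= max_slow:
            return n_slow, n_fast, False
        if cnt > 0:
            m = off_idx[np.random.randint(cnt)]
            s[m] = tgt[n + m]
            a[m] = s[m] * f[m]
            for k in range(dep_ptr[m], dep_ptr[m + 1]):
                v = dep_var[k]
                tgt[v] = _k_target(v, n, a, s, term_ptr, term_src1, term_src2, term_w,
                                   has_rules, has_pos, const, sigma)
        n_slow += 1  # idle ticks advance the slow clock while clamps run out
        for m in range(n):
            if clamped[m] and np.isfinite(remaining[m]):
                remaining[m] -= 1.0
                if remaining[m] <= 0.0:
                    clamped[m] = False
                    a[m] = s[m] * f[m]
                    tgt[m] = _k_target(m, n, a, s, term_ptr, term_src1, term_src2,
                                       term_w, has_rules, has_pos, const, sigma)
                    tgt[n + m] = _k_target(n + m, n, a, s, term_ptr, term_src1,
                                           term_src2, term_w, has_rules, has_pos,
                                           const, sigma)
                    for k in range(dep_ptr[m], dep_ptr[m + 1]):
                        v = dep_var[k]
                        tgt[v] = _k_target(v, n, a, s, term_ptr, term_src1, term_src2,
                                           term_w, has_rules, has_pos, const, sigma)


@njit(cache=True)
def _k_batch(S, F, term_ptr, term_src1, term_src2, term_w, has_rules, has_pos,
             const, sigma, dep_ptr, dep_var, clamp_idx, clamp_level, clamp_dur,
             max_slow, fast_cap, eps, seed):
    np.random.seed(seed)
    B = S.shape[0]
    converged = np.zeros(B, np.bool_)
    n_slow = np.zeros(B, np.int64)
    for b in range(B):
        ns, _nf, ok = _k_simulate(S[b], F[b], term_ptr, term_src1, term_src2, term_w,
                                  has_rules, has_pos, const, sigma, dep_ptr, dep_var,
                                  clamp_idx, clamp_level, clamp_dur,
                                  max_slow, fast_cap, eps)
        converged[b] = ok
        n_slow[b] = ns
    return converged, n_slow


@dataclass
class BatchResult:
    slow: np.ndarray  # (B, n) final slow variables
    fast: np.ndarray
    converged: np.ndarray  # bool (B,)
    n_slow: np.ndarray  # int64 (B,)

    @property
    def activities(self) -> np.ndarray:
        return self.slow * self.fast


def _clamps_to_arrays(cm: CompiledModel, clamps: Sequence[ClampSpec]):
    idx = np.array([cm.index[c.node] for c in clamps], dtype=np.int64)
    lvl = np.array([c.level for c in clamps], dtype=np.float64)
    dur = np.array([c.duration for c in clamps], dtype=np.float64)
    return idx, lvl, dur


def random_initial_states(model: NetworkModel, n: int, seed: int):
    """Vectorised equivalent of :func:`qualnet.dynamics.random_state`."""
    cm = compile_model(model)
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, 1.0, size=(n, cm.n))
    F = rng.uniform(0.0, 1.0, size=(n, cm.n))
    S[:, cm.constitutive] = 1.0
    F[:, cm.constitutive] = 1.0
    return S, F


def run_batch(
    model: NetworkModel,
    init_slow: np.ndarray,
    init_fast: np.ndarray,
    clamps: Sequence[ClampSpec] = (),
    seed: int = 0,
    max_slow: int = DEFAULT_SLOW_CAP,
    fast_cap: int = DEFAULT_FAST_CAP,
) -> BatchResult:
    """Simulate every row of ``(init_slow, init_fast)`` to steady state."""
    cm = compile_model(model)
    S = np.ascontiguousarray(init_slow, dtype=np.float64).copy()
    F = np.ascontiguousarray(init_fast, dtype=np.float64).copy()
    if S.ndim != 2 or S.shape != F.shape or S.shape[1] != cm.n:
        raise ValueError("initial state arrays must have shape (batch, n_nodes)")
    idx, lvl, dur = _clamps_to_arrays(cm, clamps)
    converged, n_slow = _k_batch(
        S, F, cm.term_ptr, cm.term_src1, cm.term_src2, cm.term_w,
        cm.has_rules, cm.has_pos, cm.constitutive, cm.sigma,
        cm.dep_ptr, cm.dep_var,
        idx, lvl, dur, max_slow, fast_cap, EPS, int(seed) % (2**31),
    )
    # permanently clamped nodes report their clamp level as activity
    for c, i in zip(clamps, idx):
        if not np.isfinite(c.duration):
            S[:, i] = c.level
            F[:, i] = 1.0
    return BatchResult(slow=S, fast=F, converged=converged, n_slow=n_slow)
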