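"""Flattened array form of a :class:`~qualnet.model.NetworkModel`.

Both the readable Python engine and the numba Monte Carlo kernel evaluate
targets from the same compiled arrays, so the two paths cannot drift apart
in how they read a model.

Variable indexing: for a model with ``n`` nodes, variable ``v < n`` is the
*fast* variable of node ``v`` and variable ``n + m`` is the *slow* variable
of node ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import NetworkModel


@dataclass(frozen=True)
class CompiledModel:
    model: NetworkModel
    n: int
    names: tuple[str, ...]
    index: dict[str, int]
    sigma: float
    constitutive: np.ndarray  # bool (n,)
    sox9_idx: int  # -1 when the model has no such marker
    runx2_idx: int
    # CSR rule terms per variable (2n variables)
    term_ptr: np.ndarray  # int64 (2n+1,)
    term_src1: np.ndarray  # int64, source node index
    term_src2: np.ndarray  # int64, second complex partner or -1
    term_w: np.ndarray  # float64, signed weight (sign folded in)
    has_rules: np.ndarray  # bool (2n,)
    has_pos: np.ndarray  # bool (2n,), any activating term
    # CSR node -> variables whose target depends on that node's activity
    dep_ptr: np.ndarray  # int64 (n+1,)
    dep_var: np.ndarray  # int64

    @property
    def n_vars(self) -> int:
        return 2 * self.n


@lru_cache(maxsize=64)
def compile_model(model: NetworkModel) -> CompiledModel:
    names = model.node_names
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    n_vars = 2 * n

    # source index n is the constant-1 slot used by BASAL pseudo-source terms;
    # consumers evaluate activities in an array of length n + 1 with a[n] = 1
    terms: list[list[tuple[int, int, float]]] = [[] for _ in range(n_vars)]
    for r in model.rules:
        tgt = index[r.target]
        v = tgt if r.speed_class == "fast" else n + tgt
        srcs = [index[s] if s != "BASAL" else n for s in r.source.split("*")]
        s1 = srcs[0]
        s2 = srcs[1] if len(srcs) > 1 else -1
        terms[v].append((s1, s2, r.sign * r.weight))

    ptr = np.zeros(n_vars + 1, dtype=np.int64)
    for v in range(n_vars):
        ptr[v + 1] = ptr[v] + len(terms[v])
    total = int(ptr[-1])
    src1 = np.empty(total, dtype=np.int64)
    src2 = np.empty(total, dtype=np.int64)
    w = np.empty(total, dtype=np.float64)
    for v in range(n_vars):
        for k, (a, b, ww) in enumerate(terms[v]):
            src1[ptr[v] + k] = a
            src2[ptr[v] + k] = b
            w[ptr[v] + k] = ww

    has_rules = np.array([len(t) > 0 for t in terms], dtype=bool)
    has_pos = np.array([any(ww > 0 for _, _, ww in t) for t in terms], dtype=bool)
    constitutive = np.array([nd.constitutive for nd in model.nodes], dtype=bool)

    deps: list[set[int]] = [set() for _ in range(n)]
    for v in range(n_vars):
        for a, b, _ww in terms[v]:
            if a < n:
                deps[a].add(v)
            if 0 <= b < n:
                deps[b].add(v)
    dep_ptr = np.zeros(n + 1, dtype=np.int64)
    for m in range(n):
        dep_ptr[m + 1] = dep_ptr[m] + len(deps[m])
    dep_var = np.empty(int(dep_ptr[-1]), dtype=np.int64)
    for m in range(n):
        dep_var[dep_ptr[m]: dep_ptr[m + 1]] = sorted(deps[m])

    sox9 = model.marker("sox9_marker")
    runx2 = model.marker("runx2_marker")

    return CompiledModel(
        model=model,
        n=n,
        names=names,
        index=index,
        sigma=float(model.saturation),
        constitutive=constitutive,
        sox9_idx=index[sox9] if sox9 is not None else -1,
        runx2_idx=index[runx2] if runx2 is not None else -1,
        term_ptr=ptr,
        term_src1=src1,
        term_src2=src2,
        term_w=w,
        has_rules=has_rules,
        has_pos=has_pos,
        dep_ptr=dep_ptr,
        dep_var=dep_var,
    )
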