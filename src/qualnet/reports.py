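"""Tabular report rendering and the therapeutic-target ranking.

All tables are pandas DataFrames written as TSV with ``#``-prefixed header
comments carrying the resolved run configuration (model name, saturation
factor, seeds, sample sizes), so any table can be regenerated
byte-identically from its own metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .attractors import BasinEstimate, LABELS, ScreenResult
from .perturbation import StationaryDistribution, TransitionMatrix

__all__ = [
    "basin_table",
    "screen_table",
    "markov_edge_table",
    "rank_targets",
    "write_table",
]


def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a TSV with ``# key: value`` header comments."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def basin_table(est: BasinEstimate) -> pd.DataFrame:
    """Per-label basin fractions with sampling errors (bar-chart data)."""
    rows = []
    for lab in LABELS:
        rows.append(
            {
                "label": lab,
                "count": est.counts[lab],
                "fraction": est.fractions[lab],
                "se": est.se[lab],
                "n": est.n_total,
                "n_batches": est.n_batches,
                "n_unconverged": est.n_unconverged,
            }
        )
    return pd.DataFrame(rows)


def screen_table(screen: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format KO/OE screen table: one row per (node, direction, label)."""
    rows = []
    for res in screen:
        for lab in LABELS:
            rows.append(
                {
                    "node": res.node,
                    "direction": res.direction,
                    "label": lab,
                    "fraction": res.basin.fractions[lab],
                    "se": res.basin.se[lab],
                    "delta": res.delta[lab],
                    "delta_se": res.delta_se(lab),
                }
            )
    return pd.DataFrame(rows)


def screen_matrix(screen: Sequence[ScreenResult]) -> pd.DataFrame:
    """Wide signed-delta matrix (node x direction/label), heatmap-ready."""
    df = screen_table(screen)
    return df.pivot_table(index="node", columns=["direction", "label"], values="delta")


def markov_edge_table(tm: TransitionMatrix, pi: StationaryDistribution | None = None) -> pd.DataFrame:
    """Edge list of the phenotype transition chain with probabilities."""
    rows = []
    for i, origin in enumerate(tm.labels):
        for j, target in enumerate(tm.labels):
            rows.append({"from": origin, "to": target, "probability": float(tm.P[i, j])})
    df = pd.DataFrame(rows)
    if pi is not None:
        df = df.merge(
            pd.DataFrame({"from": pi.labels, "stationary_from": pi.pi}), on="from", how="left"
        )
    return df


def _symbol(delta: float, se: float, n_se: float = 2.0) -> str:
    """Coarse effect symbol: '/' when |delta| < n_se * SE, else its sign."""
    if abs(delta) < n_se * se:
        return "/"
    return "+" if delta > 0 else "-"


def rank_targets(screen: Sequence[ScreenResult], n_se: float = 2.0) -> pd.DataFrame:
    """Candidate anti-hypertrophy targets from the knockout screen.

    Selects nodes whose knockout shrinks the RUNX2 basin without shrinking
    the SOX9 basin (within ``n_se`` standard errors), i.e. interventions
    predicted to suppress the hypertrophic fate while sparing — or helping
    — the chondrogenic one.  Rows are sorted by the RUNX2 delta
    (strongest suppression first) and annotated with coarse -/+// effect
    symbols.
    """
    kos = [r for r in screen if r.direction == "KO"]
    if not screen:
        return pd.DataFrame(
            columns=["node", "runx2_delta", "sox9_delta", "runx2_effect", "sox9_effect"]
        )
    if not kos:
        raise ValueError("screen contains no knockout results")
    rows = []
    for r in kos:
        d_r, d_s = r.delta["RUNX2"], r.delta["SOX9"]
        se_r, se_s = r.delta_se("RUNX2"), r.delta_se("SOX9")
        if d_r < -n_se * se_r and d_s > -n_se * se_s:
            rows.append(
                {
                    "node": r.node,
                    "runx2_delta": d_r,
                    "sox9_delta": d_s,
                    "runx2_effect": _symbol(d_r, se_r, n_se),
                    "sox9_effect": _symbol(d_s, se_s, n_se),
                }
            )
    df = pd.DataFrame(rows, columns=["node", "runx2_delta", "sox9_delta", "runx2_effect", "sox9_effect"])
    return df.sort_values("runx2_delta").reset_index(drop=True)
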