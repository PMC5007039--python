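"""Topology variants and condition tables for the WNT/BMP overactivation
experiment, plus the saturation-factor sensitivity sweep.

The variants rewire the slow (transcriptional) regulation of MEF2C:

* ``model1`` — the base network (BMP signalling, via the SMAD complex,
  and RUNX2 drive MEF2C transcription);
* ``model2`` — the BMP/SMAD-complex input is replaced by a WNT (LEF/TCF)
  input;
* ``model3`` — the BMP/SMAD-complex input is removed, leaving RUNX2 as
  the sole transcriptional regulator of MEF2C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._kernel import derive_seed
from .attractors import LABELS, estimate_basins, find_attractors
from .dynamics import ClampSpec
from .model import InteractionRule, NetworkModel, validate_model

__all__ = [
    "VariantSpec",
    "VARIANTS",
    "apply_variant",
    "overactivation_table",
    "saturation_sweep",
]

_MEF2C_BMP_KEY = ("SMAD-COMPLEX", "MEF2C", "slow")
_MEF2C_WNT_RULE = InteractionRule(
    "LEF/TCF", "MEF2C", 1, 1.0, "slow", "WNT-responsive MEF2C expression (variant)"
)


@dataclass(frozen=True)
class VariantSpec:
    name: str
    remove: tuple[tuple[str, str, str], ...] = ()
    add: tuple[InteractionRule, ...] = ()


VARIANTS: dict[str, VariantSpec] = {
    "model1": VariantSpec("model1"),
    "model2": VariantSpec("model2", remove=(_MEF2C_BMP_KEY,), add=(_MEF2C_WNT_RULE,)),
    "model3": VariantSpec("model3", remove=(_MEF2C_BMP_KEY,)),
}


def apply_variant(base: NetworkModel, spec: VariantSpec | str) -> NetworkModel:
    """Return the rewired model; ``model1`` is the base model unchanged."""
    if isinstance(spec, str):
        try:
            spec = VARIANTS[spec]
        except KeyError:
            raise KeyError(f"unknown variant {spec!r}; expected one of {sorted(VARIANTS)}")
    if spec.remove:
        present = {r.key for r in base.rules}
        for key in spec.remove:
            if key not in present:
                raise KeyError(f"variant {spec.name} removes missing rule {key}")
    model = base.without_rules(spec.remove).with_rules(spec.add)
    object.__setattr__(model, "name", f"{base.name}-{spec.name}")
    rep = validate_model(model)
    if not rep.ok:
        raise ValueError(f"variant {spec.name} produced an invalid model: {rep.errors}")
    return model


_CONDITIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("wild_type", ()),
    ("WNT+", ("WNT",)),
    ("BMP+", ("BMP",)),
    ("WNT+/BMP+", ("WNT", "BMP")),
)


def overactivation_table(
    base: NetworkModel,
    variants: Sequence[str] = ("model1", "model2", "model3"),
    n_per_batch: int = 10_000,
    n_batches: int = 3,
    seed: int = 0,
    level: float = 1.0,
) -> pd.DataFrame:
    """Basin fractions per variant under WNT/BMP overactivation.

    For every variant x condition the basin fractions are estimated with
    the overactivated nodes permanently clamped at ``level`` (1.0 = the
    node's activity fixed at 100%); deltas are reported against that
    variant's own wild-type row.  Identical seeds across variants give a
    paired comparison.
    """
    rows = []
    for variant in variants:
        model = apply_variant(base, variant)
        baseline = None
        for cond_name, nodes in _CONDITIONS:
            clamps = tuple(ClampSpec.fixed(nd, level) for nd in nodes)
            est = estimate_basins(model, n_per_batch, n_batches, seed, clamps=clamps)
            if cond_name == "wild_type":
                baseline = est
            row: dict[str, object] = {
                "variant": variant,
                "condition": cond_name,
                "sigma": model.saturation,
                "n": est.n_total,
            }
            for lab in LABELS:
                row[f"{lab}_fraction"] = est.fractions[lab]
                row[f"{lab}_delta"] = est.fractions[lab] - baseline.fractions[lab]
                row[f"{lab}_se"] = est.se[lab]
            rows.append(row)
    return pd.DataFrame(rows)


def saturation_sweep(
    model: NetworkModel,
    sigma_values: Sequence[float],
    n_per_batch: int = 3_000,
    seed: int = 0,
    n_restarts: int = 2_000,
    n_batches: int = 1,
) -> pd.DataFrame:
    """Attractor inventory and basin fractions as a function of the global
    saturation factor.

    A larger sigma lets nodes reach full activity on less positive input,
    which inflates activities across the network and shrinks the basin of
    the all-inactive 'None' state.
    """
    rows = []
    for i, sigma in enumerate(sigma_values):
        if sigma <= 0:
            raise ValueError("sigma values must be > 0")
        m = model.with_saturation(sigma)
        atts = find_attractors(m, n_restarts, derive_seed(seed, i, 0))
        est = estimate_basins(m, n_per_batch, n_batches, derive_seed(seed, i, 1))
        row: dict[str, object] = {
            "sigma": sigma,
            "n_attractors": len(atts),
            "n_unconverged": est.n_unconverged,
            "n": est.n_total,
        }
        for lab in LABELS:
            row[f"{lab}_fraction"] = est.fractions[lab]
        rows.append(row)
    return pd.DataFrame(rows)
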