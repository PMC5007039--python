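"""Network model definition, plain-text model format and validation.

A model is a set of named nodes plus signed, weighted interaction rules.
Each rule belongs to one of two priority classes: ``slow`` rules drive the
target node's transcript-level variable, ``fast`` rules drive its
post-translational variable.  A node's activity is the product of the two.
A single global saturation factor scales the summed input of every variable.

The on-disk format is line-oriented, UTF-8, tab-separated::

    #saturation 1.0
    #node RUNX2 marker=runx2
    #node GSK3B constitutive display=GSK3β
    SOURCE<TAB>TARGET<TAB>+|-<TAB>WEIGHT<TAB>fast|slow[<TAB># free-text note]

A source of the form ``A*B`` denotes a complex-formation term whose
contribution is the product of the two source activities (used for
repressive complexes that require both partners).  The pseudo-source
``BASAL`` contributes a constant activity of 1 and models species that
are active by default, with explicit rules only modulating that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "NodeSpec",
    "InteractionRule",
    "NetworkModel",
    "ValidationReport",
    "ModelError",
    "load_model",
    "loads_model",
    "write_model",
    "dumps_model",
    "validate_model",
    "chondrocyte_model",
]

SPEED_CLASSES = ("fast", "slow")
MARKER_ROLES = ("none", "sox9_marker", "runx2_marker")


class ModelError(ValueError):
    """Raised for unparseable or structurally invalid model files."""


@dataclass(frozen=True)
class NodeSpec:
    """A node of the network.

    ``constitutive`` marks species that are present/active by default and
    only modulated by explicit regulation (their unregulated variables sit
    at 1 instead of being free initial conditions).  ``marker_role`` tags
    the phenotype read-out nodes.  ``display`` keeps the publication-style
    name (Greek letters etc.) while ``name`` is the ASCII canonical form
    used in files and on the command line.
    """

    name: str
    constitutive: bool = False
    marker_role: str = "none"
    display: str | None = None

    def __post_init__(self) -> None:
        if self.marker_role not in MARKER_ROLES:
            raise ModelError(f"unknown marker role {self.marker_role!r}")

    @property
    def display_name(self) -> str:
        return self.display if self.display is not None else self.name


@dataclass(frozen=True)
class InteractionRule:
    """A signed, weighted interaction feeding one variable of ``target``.

    ``source`` is a node name, or ``"A*B"`` for a two-partner complex whose
    effective activity is the product of the partner activities.
    """

    source: str
    target: str
    sign: int
    weight: float
    speed_class: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ModelError(f"rule sign must be +1 or -1, got {self.sign}")
        if self.speed_class not in SPEED_CLASSES:
            raise ModelError(f"unknown speed class {self.speed_class!r}")

    @property
    def sources(self) -> tuple[str, ...]:
        """Individual source node names (one, or two for a complex term).

        The pseudo-source ``BASAL`` (constant activity 1, used for species
        that are active by default and only modulated by regulation) is not
        a node and is excluded here.
        """
        return tuple(s for s in self.source.split("*") if s != "BASAL")

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity triple used for duplicate detection."""
        return (self.source, self.target, self.speed_class)


@dataclass(frozen=True)
class NetworkModel:
    nodes: tuple[NodeSpec, ...]
    rules: tuple[InteractionRule, ...]
    saturation: float = 1.0
    name: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "rules", tuple(self.rules))

    # -- lookups -----------------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def rules_for(self, target: str, speed_class: str | None = None) -> tuple[InteractionRule, ...]:
        return tuple(
            r
            for r in self.rules
            if r.target == target and (speed_class is None or r.speed_class == speed_class)
        )

    def marker(self, role: str) -> str | None:
        """Name of the node tagged with ``role`` (``sox9_marker``/``runx2_marker``)."""
        for n in self.nodes:
            if n.marker_role == role:
                return n.name
        return None

    # -- editing helpers (used by the topology variants) -------------------
    def without_rules(self, keys: Iterable[tuple[str, str, str]]) -> "NetworkModel":
        drop = set(keys)
        return replace(self, rules=tuple(r for r in self.rules if r.key not in drop))

    def with_rules(self, new_rules: Iterable[InteractionRule]) -> "NetworkModel":
        return replace(self, rules=self.rules + tuple(new_rules))

    def with_saturation(self, sigma: float) -> "NetworkModel":
        return replace(self, saturation=float(sigma))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"error: {e}" for e in self.errors]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "model OK"


def validate_model(model: NetworkModel) -> ValidationReport:
    """Check structural invariants; an empty report means the model is usable.

    Errors make the model unusable for the dynamics (dangling references,
    non-positive weights, duplicate rules, bad saturation).  Warnings flag
    constructs that are legal but almost certainly transcription mistakes:
    a non-constitutive node with no input at all, or one whose slow variable
    is undriven (it would stay frozen at its random initial value).
    """
    rep = ValidationReport()
    names = [n.name for n in model.nodes]
    seen: set[str] = set()
    for name in names:
        if name in seen:
            rep.errors.append(f"duplicate node name {name}")
        seen.add(name)

    if not model.saturation > 0:
        rep.errors.append(f"saturation factor must be > 0, got {model.saturation}")

    for role in ("sox9_marker", "runx2_marker"):
        tagged = [n.name for n in model.nodes if n.marker_role == role]
        if len(tagged) > 1:
            rep.errors.append(f"marker role {role} assigned to multiple nodes: {tagged}")

    rule_keys: set[tuple[str, str, str]] = set()
    for r in model.rules:
        for src in r.sources:
            if src not in seen:
                rep.errors.append(f"{src} is not included in the model (rule {r.source} -> {r.target})")
        if r.target not in seen:
            rep.errors.append(f"{r.target} is not included in the model (rule {r.source} -> {r.target})")
        if not r.weight > 0:
            rep.errors.append(
                f"rule {r.source} -> {r.target} ({r.speed_class}) has non-positive weight {r.weight}"
            )
        if r.key in rule_keys:
            rep.errors.append(f"duplicate rule {r.source} -> {r.target} ({r.speed_class})")
        rule_keys.add(r.key)

    incoming: dict[str, set[str]] = {n: set() for n in seen}
    for r in model.rules:
        if r.target in incoming:
            incoming[r.target].add(r.speed_class)
    for n in model.nodes:
        if n.constitutive:
            continue
        if not incoming[n.name]:
            rep.warnings.append(f"node {n.name} has no incoming rule and is not constitutive")
        elif "slow" not in incoming[n.name]:
            rep.warnings.append(
                f"node {n.name} has no slow input and is not constitutive; "
                "its slow variable will stay at its initial value"
            )
    return rep


# ---------------------------------------------------------------------------
# parsing / serialisation


def loads_model(text: str, name: str = "model") -> NetworkModel:
    nodes: list[NodeSpec] = []
    rules: list[InteractionRule] = []
    saturation = 1.0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("##"):
            continue
        if line.startswith("#saturation"):
            parts = line.split()
            try:
                saturation = float(parts[1])
            except (IndexError, ValueError):
                raise ModelError(f"line {lineno}: cannot parse saturation from {line!r}")
            continue
        if line.startswith("#node"):
            nodes.append(_parse_node_line(line, lineno))
            continue
        if line.startswith("#"):
            continue  # free comment
        rules.append(_parse_rule_line(line, lineno))

    model = NetworkModel(nodes=tuple(nodes), rules=tuple(rules), saturation=saturation, name=name)
    rep = validate_model(model)
    if not rep.ok:
        raise ModelError("invalid model:\n" + "\n".join(rep.errors))
    return model


def _parse_node_line(line: str, lineno: int) -> NodeSpec:
    tokens = line.split()
    if len(tokens) < 2:
        raise ModelError(f"line {lineno}: #node line without a name")
    name = tokens[1]
    constitutive = False
    marker_role = "none"
    display: str | None = None
    for i, tok in enumerate(tokens[2:], start=2):
        if tok == "constitutive":
            constitutive = True
        elif tok.startswith("marker="):
            value = tok.split("=", 1)[1]
            if value not in ("sox9", "runx2"):
                raise ModelError(f"line {lineno}: unknown marker {value!r}")
            marker_role = f"{value}_marker"
        elif tok.startswith("display="):
            # display name may contain spaces: consume the rest of the line
            display = " ".join(tokens[i:])[len("display="):]
            break
        else:
            raise ModelError(f"line {lineno}: unknown node attribute {tok!r}")
    return NodeSpec(name=name, constitutive=constitutive, marker_role=marker_role, display=display)


def _parse_rule_line(line: str, lineno: int) -> InteractionRule:
    fields_ = line.split("\t")
    if len(fields_) < 5:
        raise ModelError(
            f"line {lineno}: expected SOURCE<TAB>TARGET<TAB>+|-<TAB>WEIGHT<TAB>fast|slow, got {line!r}"
        )
    source, target, sign_s, weight_s, speed = (f.strip() for f in fields_[:5])
    note = ""
    if len(fields_) > 5:
        note = fields_[5].lstrip("# ").strip()
    if sign_s not in ("+", "-"):
        raise ModelError(f"line {lineno}: sign must be '+' or '-', got {sign_s!r}")
    try:
        weight = float(weight_s)
    except ValueError:
        raise ModelError(f"line {lineno}: cannot parse weight {weight_s!r}")
    if speed not in SPEED_CLASSES:
        raise ModelError(f"line {lineno}: speed class must be fast|slow, got {speed!r}")
    return InteractionRule(
        source=source,
        target=target,
        sign=1 if sign_s == "+" else -1,
        weight=weight,
        speed_class=speed,
        note=note,
    )


def load_model(path: str | Path) -> NetworkModel:
    """Read and validate a model file; raise :class:`ModelError` on problems."""
    path = Path(path)
    return loads_model(path.read_text(encoding="utf-8"), name=path.stem)


def dumps_model(model: NetworkModel) -> str:
    lines = [f"#saturation {model.saturation:g}"]
    for n in model.nodes:
        parts = [f"#node {n.name}"]
        if n.constitutive:
            parts.append("constitutive")
        if n.marker_role != "none":
            parts.append(f"marker={n.marker_role.removesuffix('_marker')}")
        if n.display is not None:
            parts.append(f"display={n.display}")
        lines.append(" ".join(parts))
    for r in model.rules:
        sign = "+" if r.sign > 0 else "-"
        line = f"{r.source}\t{r.target}\t{sign}\t{r.weight:g}\t{r.speed_class}"
        if r.note:
            line += f"\t# {r.note}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def write_model(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model), encoding="utf-8")


def chondrocyte_model() -> NetworkModel:
    """The bundled 43-node chondrocyte differentiation network.

    Reconstructed from the published description of the SOX9/RUNX2 fate
    decision circuit (see the package methods note for the reconstruction
    conventions).  Deterministic: always returns the same model.
    """
    text = resources.files("qualnet.data").joinpath("chondrocyte.tsv").read_text("utf-8")
    return loads_model(text, name="chondrocyte")
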