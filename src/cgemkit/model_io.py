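"""Constraint-based metabolic model container, GPR rules, and serialization.

The in-memory model is deliberately lightweight: an ordered list of reactions,
each carrying its own stoichiometry column, bounds, boolean gene-protein-reaction
(GPR) rule and subsystem annotation.  The stoichiometric matrix ``S`` is built
on demand as a sparse matrix in (metabolite x reaction) orientation.

Three serializations are supported:

* a native JSON dialect (one object with ``model_id``, ``objective_reaction``,
  ``metabolites`` and a ``reactions`` array),
* a native TSV dialect (one reaction per row: ``id  lb  ub  gpr  subsystem
  stoichiometry`` with stoichiometry encoded as ``met:coef;met:coef``; model id
  and objective are carried in ``#`` header lines),
* SBML Level 3 + FBC via cobrapy, for interoperability with curated
  genome-scale reconstructions such as Recon3D.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

UNASSIGNED_SUBSYSTEM = "unassigned"

__all__ = [
    "GPRParseError",
    "ModelError",
    "GPRRule",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "format_gpr",
    "canonical_gpr",
    "protect_reactions",
    "load_model",
    "save_model",
]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the offending position."""


class ModelError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRRule:
    """Node of a boolean GPR expression tree.

    ``op`` is ``"gene"`` for leaves (with ``gene`` set), or ``"and"`` / ``"or"``
    for internal nodes with at least two ``children``.  AND encodes an enzyme
    complex, OR encodes isozymes.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRRule", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise GPRParseError("gene leaf must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if len(self.children) < 2 or self.gene is not None:
                raise GPRParseError(f"'{self.op}' node needs at least two children")
        else:
            raise GPRParseError(f"unknown GPR operator {self.op!r}")

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    ``and``/``or`` keywords are case-insensitive; precedence is
    parentheses > and > or (the SBML-FBC community convention).
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        raise GPRParseError("empty GPR rule")
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str, at: int) -> None:
        raise GPRParseError(f"{msg} at position {at} in {rule_text!r}")

    def parse_or() -> GPRRule:
        nonlocal pos
        terms = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRRule("or", children=tuple(terms))

    def parse_and() -> GPRRule:
        nonlocal pos
        factors = [parse_atom()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPRRule("and", children=tuple(factors))

    def parse_atom() -> GPRRule:
        nonlocal pos
        tok = peek()
        if tok is None:
            fail("unexpected end of rule", len(rule_text))
        word, at = tok
        if word == "(":
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                fail("unbalanced parenthesis", at)
            pos += 1
            return inner
        if word == ")":
            fail("unbalanced parenthesis", at)
        if word.lower() in ("and", "or"):
            fail(f"misplaced operator {word!r}", at)
        pos += 1
        return GPRRule("gene", gene=word)

    tree = parse_or()
    if pos != len(tokens):
        fail(f"trailing token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def format_gpr(rule: GPRRule) -> str:
    """Serialize a GPR tree; ``parse_gpr(format_gpr(t))`` equals ``t`` up to
    associativity/commutativity (compare via :func:`canonical_gpr`)."""
    if rule.op == "gene":
        return rule.gene  # type: ignore[return-value]
    parts = []
    for child in rule.children:
        text = format_gpr(child)
        if rule.op == "and" and child.op == "or":
            text = f"({text})"
        parts.append(text)
    return f" {rule.op} ".join(parts)


def canonical_gpr(rule: GPRRule) -> GPRRule:
    """Canonical form: same-operator nesting flattened, children sorted."""
    if rule.op == "gene":
        return rule
    flat: list[GPRRule] = []
    for child in rule.children:
        c = canonical_gpr(child)
        if c.op == rule.op:
            flat.extend(c.children)
        else:
            flat.append(c)
    flat.sort(key=_gpr_sort_key)
    return GPRRule(rule.op, children=tuple(flat))


def _gpr_sort_key(rule: GPRRule) -> str:
    return format_gpr(rule)


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """A reaction: bounds, stoichiometry column, optional GPR and subsystem.

    Flux units are mmol/gDW/h for real reconstructions and dimensionless in
    toy models.  A missing subsystem annotation is replaced by the sentinel
    ``"unassigned"`` so subsystem-wise statistics are total.
    """

    reaction_id: str
    lower_bound: float
    upper_bound: float
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    gpr: GPRRule | None = None
    subsystem: str = UNASSIGNED_SUBSYSTEM

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.reaction_id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if not self.subsystem:
            object.__setattr__(self, "subsystem", UNASSIGNED_SUBSYSTEM)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    model_id : str
    metabolites : list of metabolite ids (row order of ``S``)
    reactions : list of :class:`Reaction` (column order of ``S``)
    objective_reaction : reaction id of the objective (typically biomass), or
        ``None`` for models without a declared objective.
    """

    model_id: str
    metabolites: list[str]
    reactions: list[Reaction]
    objective_reaction: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.reaction_id in seen:
                raise ModelError(f"duplicate reaction id {rxn.reaction_id!r}")
            seen.add(rxn.reaction_id)
        met_set = set(self.metabolites)
        if len(met_set) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    raise ModelError(
                        f"reaction {rxn.reaction_id!r} references undeclared "
                        f"metabolite {met!r}"
                    )
        if self.objective_reaction is not None and self.objective_reaction not in seen:
            raise ModelError(
                f"objective reaction {self.objective_reaction!r} is not in the model"
            )

    # -- indexing ----------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    def reaction(self, reaction_id: str) -> Reaction:
        idx = self.reaction_index(reaction_id)
        return self.reactions[idx]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except AttributeError:
            self._rxn_index = {r.reaction_id: i for i, r in enumerate(self.reactions)}
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r} in model {self.model_id!r}")

    @property
    def gene_ids(self) -> frozenset[str]:
        genes: set[str] = set()
        for rxn in self.reactions:
            genes |= rxn.genes()
        return frozenset(genes)

    @property
    def stoichiometry(self) -> sparse.csc_matrix:
        """Sparse S matrix, metabolites x reactions."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                if coef != 0:
                    rows.append(met_index[met])
                    cols.append(j)
                    data.append(float(coef))
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def subsystems(self) -> dict[str, list[str]]:
        """Map subsystem label -> reaction ids (every reaction appears once)."""
        out: dict[str, list[str]] = {}
        for rxn in self.reactions:
            out.setdefault(rxn.subsystem, []).append(rxn.reaction_id)
        return out

    def genes_of(self, reaction_ids: Iterable[str]) -> frozenset[str]:
        genes: set[str] = set()
        for rid in reaction_ids:
            genes |= self.reaction(rid).genes()
        return frozenset(genes)

    def submodel(self, kept_reactions: Iterable[str], model_id: str | None = None) -> "MetabolicModel":
        """Induced submodel: keep the given reactions, drop orphaned metabolites.

        The objective reaction is preserved when kept, otherwise unset.
        """
        kept = set(kept_reactions)
        missing = kept - set(self.reaction_ids)
        if missing:
            raise KeyError(f"unknown reactions in submodel request: {sorted(missing)}")
        reactions = [r for r in self.reactions if r.reaction_id in kept]
        used_mets = {m for r in reactions for m in r.stoichiometry}
        metabolites = [m for m in self.metabolites if m in used_mets]
        objective = self.objective_reaction if self.objective_reaction in kept else None
        return MetabolicModel(
            model_id=model_id or f"{self.model_id}_sub",
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction=objective,
        )


def protect_reactions(model: MetabolicModel, ids: Iterable[str]) -> frozenset[str]:
    """Validate and freeze a set of reactions that extraction must never remove."""
    ids = set(ids)
    missing = ids - set(model.reaction_ids)
    if missing:
        raise KeyError(
            f"protected reactions not in model {model.model_id!r}: {sorted(missing)}"
        )
    return frozenset(ids)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".tsv":
        return "tsv"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        _save_json(model, path)
    elif fmt == "tsv":
        _save_tsv(model, path)
    elif fmt == "sbml":
        _save_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        return _load_json(path)
    if fmt == "tsv":
        return _load_tsv(path)
    if fmt == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def _reaction_to_dict(rxn: Reaction) -> dict:
    return {
        "id": rxn.reaction_id,
        "lower_bound": rxn.lower_bound,
        "upper_bound": rxn.upper_bound,
        "metabolites": {m: c for m, c in sorted(rxn.stoichiometry.items())},
        "gpr": format_gpr(rxn.gpr) if rxn.gpr is not None else None,
        "subsystem": rxn.subsystem,
    }


def _reaction_from_dict(entry: Mapping) -> Reaction:
    gpr_text = entry.get("gpr")
    try:
        gpr = parse_gpr(gpr_text) if gpr_text else None
    except GPRParseError as exc:
        raise ModelError(f"reaction {entry.get('id')!r}: {exc}") from exc
    return Reaction(
        reaction_id=entry["id"],
        lower_bound=float(entry["lower_bound"]),
        upper_bound=float(entry["upper_bound"]),
        stoichiometry={m: float(c) for m, c in entry.get("metabolites", {}).items()},
        gpr=gpr,
        subsystem=entry.get("subsystem") or UNASSIGNED_SUBSYSTEM,
    )


def _save_json(model: MetabolicModel, path: Path) -> None:
    payload = {
        "model_id": model.model_id,
        "objective_reaction": model.objective_reaction,
        "metabolites": list(model.metabolites),
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _load_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path.name}: malformed JSON model ({exc})") from exc
    reactions = [_reaction_from_dict(entry) for entry in payload["reactions"]]
    metabolites = payload.get("metabolites")
    if metabolites is None:
        seen: list[str] = []
        for rxn in reactions:
            for met in rxn.stoichiometry:
                if met not in seen:
                    seen.append(met)
        metabolites = seen
    return MetabolicModel(
        model_id=payload.get("model_id", path.stem),
        metabolites=list(metabolites),
        reactions=reactions,
        objective_reaction=payload.get("objective_reaction"),
    )


_STOICH_ITEM_RE = re.compile(r"^(?P<met>.+):(?P<coef>[-+0-9.eE]+)$")


def _format_stoichiometry(stoich: Mapping[str, float]) -> str:
    # repr round-trips doubles exactly; %g would truncate
    return ";".join(f"{m}:{float(c)!r}" for m, c in sorted(stoich.items()))


def _parse_stoichiometry(text: str, reaction_id: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    if not text.strip():
        return stoich
    for item in text.split(";"):
        m = _STOICH_ITEM_RE.match(item.strip())
        if m is None:
            raise ModelError(
                f"reaction {reaction_id!r}: malformed stoichiometry item {item!r}"
            )
        coef = float(m.group("coef"))
        if not math.isfinite(coef):
            raise ModelError(
                f"reaction {reaction_id!r}: non-finite coefficient in {item!r}"
            )
        stoich[m.group("met")] = coef
    return stoich


_TSV_COLUMNS = ["id", "lower_bound", "upper_bound", "gpr", "subsystem", "stoichiometry"]


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [
        f"# model_id={model.model_id}",
        f"# objective={model.objective_reaction or ''}",
        "\t".join(_TSV_COLUMNS),
    ]
    for rxn in model.reactions:
        lines.append(
            "\t".join(
                [
                    rxn.reaction_id,
                    repr(float(rxn.lower_bound)),
                    repr(float(rxn.upper_bound)),
                    format_gpr(rxn.gpr) if rxn.gpr is not None else "",
                    rxn.subsystem,
                    _format_stoichiometry(rxn.stoichiometry),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _load_tsv(path: Path) -> MetabolicModel:
    model_id, objective = path.stem, None
    reactions: list[Reaction] = []
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        if not raw.strip():
            continue
        if raw.startswith("#"):
            body = raw.lstrip("# ").strip()
            if body.startswith("model_id="):
                model_id = body.split("=", 1)[1]
            elif body.startswith("objective="):
                objective = body.split("=", 1)[1] or None
            continue
        fields = raw.split("\t")
        if header is None:
            header = fields
            if header != _TSV_COLUMNS:
                raise ModelError(
                    f"{path.name}: expected TSV header {_TSV_COLUMNS}, got {header}"
                )
            continue
        if len(fields) != len(_TSV_COLUMNS):
            raise ModelError(f"{path.name}: malformed row {raw!r}")
        rid, lb, ub, gpr_text, subsystem, stoich_text = fields
        reactions.append(
            _reaction_from_dict(
                {
                    "id": rid,
                    "lower_bound": lb,
                    "upper_bound": ub,
                    "gpr": gpr_text or None,
                    "subsystem": subsystem or None,
                    "metabolites": _parse_stoichiometry(stoich_text, rid),
                }
            )
        )
    seen: list[str] = []
    for rxn in reactions:
        for met in rxn.stoichiometry:
            if met not in seen:
                seen.append(met)
    return MetabolicModel(
        model_id=model_id, metabolites=seen, reactions=reactions,
        objective_reaction=objective,
    )


# -- SBML via cobrapy -------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.model_id)
    # libsbml requires a compartment on every species
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions:
        crxn = cobra.Reaction(rxn.reaction_id)
        crxn.lower_bound = rxn.lower_bound
        crxn.upper_bound = rxn.upper_bound
        crxn.subsystem = rxn.subsystem
        rxns.append(crxn)
    cmodel.add_reactions(rxns)
    for rxn, crxn in zip(model.reactions, rxns):
        crxn.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr is not None:
            crxn.gene_reaction_rule = format_gpr(rxn.gpr)
    if model.objective_reaction is not None:
        cmodel.objective = model.objective_reaction
    # subsystems as SBML groups so they round-trip through L3 files
    import cobra.core.group

    by_subsystem: dict[str, list] = {}
    for rxn, crxn in zip(model.reactions, rxns):
        by_subsystem.setdefault(rxn.subsystem, []).append(crxn)
    for name, members in by_subsystem.items():
        group = cobra.core.group.Group(
            _group_id(name), name=name, members=members, kind="partonomy"
        )
        cmodel.add_groups([group])
    return cmodel


def _group_id(name: str) -> str:
    return "g_" + re.sub(r"[^A-Za-z0-9_]", "_", name)


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a cobrapy model (e.g. read from SBML L3-FBC) to the native type."""
    subsystem_of: dict[str, str] = {}
    for group in getattr(cmodel, "groups", []):
        for member in group.members:
            rid = getattr(member, "id", None)
            if rid is not None and rid in {r.id for r in cmodel.reactions}:
                subsystem_of[rid] = group.name or group.id
    reactions = []
    for crxn in cmodel.reactions:
        rule = crxn.gene_reaction_rule
        subsystem = crxn.subsystem or subsystem_of.get(crxn.id)
        reactions.append(
            Reaction(
                reaction_id=crxn.id,
                lower_bound=float(crxn.lower_bound),
                upper_bound=float(crxn.upper_bound),
                stoichiometry={m.id: float(c) for m, c in crxn.metabolites.items()},
                gpr=parse_gpr(rule) if rule else None,
                subsystem=subsystem or UNASSIGNED_SUBSYSTEM,
            )
        )
    objective = None
    for variable, coef in cmodel.objective.get_linear_coefficients(
        cmodel.variables
    ).items():  # pragma: no cover - exercised via SBML round-trip
        if coef != 0 and not variable.name.endswith("_reverse"):
            objective = variable.name
            break
    if objective is None:
        obj_rxns = [r.id for r in cmodel.reactions if r.objective_coefficient]
        objective = obj_rxns[0] if obj_rxns else None
    return MetabolicModel(
        model_id=cmodel.id or "model",
        metabolites=[m.id for m in cmodel.metabolites],
        reactions=reactions,
        objective_reaction=objective,
    )


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


def _load_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))
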