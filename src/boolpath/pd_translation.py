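"""Reduce process-description reaction graphs to activity-flow Boolean networks.

A process-description (PD) diagram describes mechanistic reactions —
complex associations, state transitions, transports — among species that
may exist in several modified forms.  The translation collapses that
mechanism into a causal activity-flow model by four rewriting rules and
then infers one Boolean function per remaining species:

* Rule 1 — in a receptor–ligand association the receptor reactant is
  removed (receptor availability is assumed).
* Rule 2 — in a protein–protein association the reactants are removed and
  the reaction's modifiers act directly on the complex product.
* Rule 3 — an inactive species participating in exactly one reaction is
  removed (it only represents the pre-activation form).
* Rule 4 — in a transport reaction moving one biomolecule between
  compartments the reactant is removed and every other reaction touching
  it is re-linked to the product.

Rules are applied in order 1..4 and iterated to a fixpoint.  Logic
inference then treats each producing reaction as an AND of its remaining
reactants and positive modifiers, ORs the producing reactions together,
and lets negative modifiers veto the result (dominant-inhibitor
combination; a per-route alternative is available via ``inhibitor_mode``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from .expr import Expr, Var, and_all, or_all
from .network import BooleanNetwork
from .model_io import ModelSyntaxError, normalize_identifier

__all__ = [
    "Species", "Reaction", "PDGraph", "TranslationTrace",
    "apply_reduction_rules", "infer_logic", "translate",
    "read_pd_text", "write_pd_text",
]

REACTION_TYPES = ("state_transition", "association", "transport")


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    compartment: str = ""
    active: bool = True
    receptor: bool = False
    modifications: tuple[str, ...] = ()

    @property
    def base_name(self) -> str:
        """Biomolecule identity ignoring compartment/state decoration."""
        return self.name or self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    type: str
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modifiers: tuple[tuple[str, str], ...] = ()  # (species id, '+' or '-')

    def participants(self) -> set[str]:
        return (set(self.reactants) | set(self.products)
                | {sid for sid, _ in self.modifiers})


@dataclass
class PDGraph:
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        declared = set(ids)
        for r in self.reactions:
            if r.type not in REACTION_TYPES:
                raise ValueError(f"reaction {r.id}: unknown type {r.type!r}")
            if not r.products:
                raise ValueError(f"reaction {r.id}: no products")
            undeclared = r.participants() - declared
            if undeclared:
                raise ValueError(
                    f"reaction {r.id}: undeclared species {sorted(undeclared)}")
            for _, sign in r.modifiers:
                if sign not in ("+", "-"):
                    raise ValueError(f"reaction {r.id}: modifier sign {sign!r}")

    def get(self, sid: str) -> Species:
        return next(s for s in self.species if s.id == sid)

    def reactions_with(self, sid: str) -> list[Reaction]:
        return [r for r in self.reactions if sid in r.participants()]

    def copy(self) -> "PDGraph":
        return PDGraph(list(self.species), list(self.reactions))


@dataclass
class TranslationTrace:
    """Audit log of the reduction: (rule id, reaction id, removed species,
    rewired (old id -> new id) links), in application order."""
    applied: list[tuple[int, str, tuple[str, ...], tuple[tuple[str, str], ...]]] = \
        field(default_factory=list)

    def removed_species(self) -> list[str]:
        return [sid for _, _, removed, _ in self.applied for sid in removed]


# ---------------------------------------------------------------------------
# reduction

def apply_reduction_rules(pd: PDGraph) -> tuple[PDGraph, TranslationTrace]:
    """Iterate rules 1..4 to a fixpoint (cap 10·|reactions| sweeps)."""
    g = pd.copy()
    trace = TranslationTrace()
    cap = max(1, 10 * len(pd.reactions))
    for _ in range(cap):
        changed = (_rule1(g, trace) or _rule2(g, trace)
                   or _rule3(g, trace) or _rule4(g, trace))
        if not changed:
            return g, trace
    raise RuntimeError("reduction did not reach a fixpoint within the "
                       f"iteration cap ({cap})")


def _drop_species_if_unused(g: PDGraph, sid: str) -> bool:
    if any(sid in r.participants() for r in g.reactions):
        return False
    g.species = [s for s in g.species if s.id != sid]
    return True


def _rule1(g: PDGraph, trace: TranslationTrace) -> bool:
    """Receptor–ligand association: drop the receptor reactant."""
    for i, r in enumerate(g.reactions):
        if r.type != "association" or len(r.reactants) < 2:
            continue
        receptors = [sid for sid in r.reactants if g.get(sid).receptor]
        if not receptors or len(receptors) == len(r.reactants):
            continue
        rec = receptors[0]
        g.reactions[i] = replace(
            r, reactants=tuple(s for s in r.reactants if s != rec))
        removed = (rec,) if _drop_species_if_unused(g, rec) else ()
        trace.applied.append((1, r.id, removed, ()))
        return True
    return False


def _rule2(g: PDGraph, trace: TranslationTrace) -> bool:
    """Protein association: drop all reactants; modifiers already point at
    the product through the reaction."""
    for i, r in enumerate(g.reactions):
        if r.type != "association" or len(r.reactants) < 2:
            continue
        if any(g.get(sid).receptor for sid in r.reactants):
            continue
        reactants = r.reactants
        g.reactions[i] = replace(r, reactants=())
        removed = tuple(sid for sid in reactants
                        if _drop_species_if_unused(g, sid))
        trace.applied.append((2, r.id, removed, ()))
        return True
    return False


def _rule3(g: PDGraph, trace: TranslationTrace) -> bool:
    """Inactive single-reaction species are removed."""
    for s in g.species:
        if s.active:
            continue
        touching = g.reactions_with(s.id)
        if len(touching) != 1:
            continue
        r = touching[0]
        if s.id in r.products:
            continue  # an inactive product is still this reaction's outcome
        idx = g.reactions.index(r)
        g.reactions[idx] = replace(
            r,
            reactants=tuple(x for x in r.reactants if x != s.id),
            modifiers=tuple((m, sgn) for m, sgn in r.modifiers if m != s.id))
        g.species = [sp for sp in g.species if sp.id != s.id]
        trace.applied.append((3, r.id, (s.id,), ()))
        return True
    return False


def _rule4(g: PDGraph, trace: TranslationTrace) -> bool:
    """Transport of one biomolecule between compartments: keep the product,
    re-link every other reaction from the reactant to the product."""
    for i, r in enumerate(g.reactions):
        if r.type != "transport":
            continue
        if len(r.reactants) != 1 or len(r.products) != 1:
            continue
        src, dst = r.reactants[0], r.products[0]
        if src == dst:
            continue
        if g.get(src).base_name != g.get(dst).base_name:
            continue
        rewired: list[tuple[str, str]] = []
        for j, other in enumerate(g.reactions):
            if j == i:
                continue
            if src in other.participants():
                g.reactions[j] = _substitute(other, src, dst)
                rewired.append((src, dst))
        del g.reactions[i]
        g.species = [sp for sp in g.species if sp.id != src]
        trace.applied.append((4, r.id, (src,), tuple(rewired)))
        return True
    return False


def _substitute(r: Reaction, old: str, new: str) -> Reaction:
    sub = lambda xs: tuple(new if x == old else x for x in xs)
    return replace(
        r, reactants=sub(r.reactants), products=sub(r.products),
        modifiers=tuple((new if m == old else m, sgn) for m, sgn in r.modifiers))


# ---------------------------------------------------------------------------
# logic inference

def infer_logic(pd: PDGraph, inhibitor_mode: str = "dominant") -> BooleanNetwork:
    """Infer one Boolean function per species of a reduced PD graph.

    A producing reaction contributes the conjunction of its reactants and
    positive modifiers.  Contributions are OR-ed over producing reactions.
    Negative modifiers veto: globally (``inhibitor_mode='dominant'``,
    default — any inhibitor of any producing reaction turns the node off)
    or per producing route (``'or'``).  Species never produced become free
    inputs, as does a produced species whose regulators all vanished in
    reduction (with a warning).
    """
    if inhibitor_mode not in ("dominant", "or"):
        raise ValueError(f"unknown inhibitor_mode {inhibitor_mode!r}")
    ident = {s.id: normalize_identifier(s.id) for s in pd.species}
    if len(set(ident.values())) != len(ident):
        raise ValueError("species ids collide after identifier normalization")

    functions: dict[str, Expr] = {}
    metadata: dict[str, str] = {}
    for s in pd.species:
        node = ident[s.id]
        if node != s.id:
            metadata[f"display:{node}"] = s.id
        producing = [r for r in pd.reactions if s.id in r.products]
        if not producing:
            functions[node] = Var(node)  # free input
            continue
        routes: list[Expr] = []
        all_negative: list[Expr] = []
        for r in producing:
            positives = [Var(ident[x]) for x in r.reactants]
            positives += [Var(ident[m]) for m, sgn in r.modifiers if sgn == "+"]
            negatives = [Var(ident[m]) for m, sgn in r.modifiers if sgn == "-"]
            all_negative.extend(negatives)
            if inhibitor_mode == "or" and negatives:
                routes.append(and_all(positives + [~or_all(negatives)]))
            elif positives:
                routes.append(and_all(positives))
        if not routes and not all_negative:
            warnings.warn(f"species {s.id!r} is produced but has no "
                          "regulators after reduction; treated as free input")
            functions[node] = Var(node)
            continue
        body = or_all(routes) if routes else ~or_all(all_negative)
        if inhibitor_mode == "dominant" and all_negative and routes:
            body = body & ~or_all(all_negative)
        functions[node] = body
    return BooleanNetwork(functions, metadata)


def translate(pd: PDGraph, inhibitor_mode: str = "dominant",
              ) -> tuple[BooleanNetwork, TranslationTrace]:
    """Full PD → activity-flow translation: reduce, then infer logic."""
    reduced, trace = apply_reduction_rules(pd)
    return infer_logic(reduced, inhibitor_mode=inhibitor_mode), trace


# ---------------------------------------------------------------------------
# text exchange format

def read_pd_text(text: str) -> PDGraph:
    """Parse the block-structured PD exchange format.

    One block per entity::

        species <id>
          name: TH
          compartment: cytosol
          active: false
          receptor: true
          modifications: phosphorylated

        reaction <id>
          type: association
          reactants: A B
          products: A_B
          modifiers: +M -I
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    block: dict[str, str] | None = None
    kind = ""

    def flush() -> None:
        nonlocal block
        if block is None:
            return
        if kind == "species":
            species.append(Species(
                id=block["id"],
                name=block.get("name", ""),
                compartment=block.get("compartment", ""),
                active=block.get("active", "true").lower() != "false",
                receptor=block.get("receptor", "false").lower() == "true",
                modifications=tuple(block.get("modifications", "").split()),
            ))
        else:
            mods = []
            for tok in block.get("modifiers", "").split():
                if tok[0] not in "+-":
                    raise ModelSyntaxError(
                        f"modifier {tok!r} must be signed (+X or -X)")
                mods.append((tok[1:], tok[0]))
            reactions.append(Reaction(
                id=block["id"],
                type=block.get("type", "state_transition"),
                reactants=tuple(block.get("reactants", "").split()),
                products=tuple(block.get("products", "").split()),
                modifiers=tuple(mods),
            ))
        block = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = re.fullmatch(r"(species|reaction)\s+(\S+)", line.strip())
        if m and not line.startswith((" ", "\t")):
            flush()
            kind = m.group(1)
            block = {"id": m.group(2)}
            continue
        if block is None or ":" not in line:
            raise ModelSyntaxError(f"line {lineno}: expected 'key: value' "
                                   "inside a species/reaction block")
        key, value = line.split(":", 1)
        block[key.strip()] = value.strip()
    flush()
    return PDGraph(species, reactions)


def write_pd_text(pd: PDGraph) -> str:
    out: list[str] = []
    for s in pd.species:
        out.append(f"species {s.id}")
        if s.name:
            out.append(f"  name: {s.name}")
        if s.compartment:
            out.append(f"  compartment: {s.compartment}")
        if not s.active:
            out.append("  active: false")
        if s.receptor:
            out.append("  receptor: true")
        if s.modifications:
            out.append(f"  modifications: {' '.join(s.modifications)}")
        out.append("")
    for r in pd.reactions:
        out.append(f"reaction {r.id}")
        out.append(f"  type: {r.type}")
        if r.reactants:
            out.append(f"  reactants: {' '.join(r.reactants)}")
        out.append(f"  products: {' '.join(r.products)}")
        if r.modifiers:
            mods = " ".join(f"{sgn}{m}" for m, sgn in r.modifiers)
            out.append(f"  modifiers: {mods}")
        out.append("")
    return "\n".join(out)
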