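"""Read and write logical models: rule text, SBML-qual, and SIF.

Formats
-------
* Rule text: one ``target, expression`` line per node with ``& | !`` and
  parentheses; ``#`` comments and blank lines allowed.  A node whose
  expression is its own name is a free input.
* SBML-qual: the SBML Level 3 qualitative-models package, restricted to
  binary species (maxLevel 1), one transition per target, and MathML over
  and/or/not/eq at levels 0/1.  Species without a transition are free
  inputs.
* SIF: tab-separated ``source relation target`` with the relation
  vocabulary {activates, inhibits, interacts}.

Node order is first appearance in the source document so that state bit
vectors match the file layout.  Species names containing spaces or colons
are normalized to underscores on read; the original display names are kept
in ``network.metadata["display:<id>"]``.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

from .expr import (And, Const, Expr, ExprSyntaxError, Not, Or, Var,
                   parse_expr)
from .network import BooleanNetwork

__all__ = [
    "read_rules", "write_rules",
    "read_sbml_qual", "write_sbml_qual",
    "write_sif", "read_sif",
    "ModelSyntaxError",
]

SIF_RELATIONS = ("activates", "inhibits", "interacts")


class ModelSyntaxError(ValueError):
    """Malformed model document."""


def normalize_identifier(name: str) -> str:
    """Map a display name to a grammar-safe identifier."""
    ident = re.sub(r"[\s:]+", "_", name.strip())
    if ident and ident[0].isdigit():
        ident = "_" + ident
    return ident


# ---------------------------------------------------------------------------
# rule text

def read_rules(text: str) -> BooleanNetwork:
    """Parse a rule document into a Boolean network.

    Raises :class:`ModelSyntaxError` (with a line number) on bad syntax,
    duplicate targets, or references to undeclared nodes.
    """
    functions: dict[str, Expr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise ModelSyntaxError(f"line {lineno}: expected 'target, expression'")
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
            raise ModelSyntaxError(f"line {lineno}: invalid target {target!r}")
        if target in functions:
            raise ModelSyntaxError(f"line {lineno}: duplicate target {target!r}")
        try:
            functions[target] = parse_expr(expr_text)
        except ExprSyntaxError as exc:
            raise ModelSyntaxError(f"line {lineno}: {exc}") from exc
    declared = set(functions)
    for target, fn in functions.items():
        missing = fn.variables() - declared
        if missing:
            raise ModelSyntaxError(
                f"function of {target!r} references undeclared node(s) "
                f"{sorted(missing)}")
    return BooleanNetwork(functions)


def write_rules(network: BooleanNetwork) -> str:
    """Serialize to rule text, one line per node in node order."""
    lines = [f"{node}, {network.functions[node]}" for node in network.nodes]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SIF

def write_sif(network: BooleanNetwork) -> str:
    """Pairwise-interaction export: one edge per (regulator, target) pair.

    The relation is 'activates' when the regulator occurs only un-negated
    in the target's function, 'inhibits' when only negated, 'interacts'
    when both polarities occur.  Deterministically sorted.
    """
    lines = [f"{s}\t{rel}\t{t}" for s, rel, t in network.interaction_edges()]
    return "\n".join(lines) + ("\n" if lines else "")


def read_sif(text: str) -> list[tuple[str, str, str]]:
    """Parse SIF text into (source, relation, target) triples."""
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t|\s{2,}| ", line)
        parts = [p for p in parts if p]
        if len(parts) != 3:
            raise ModelSyntaxError(f"line {lineno}: expected 3 columns")
        src, rel, tgt = parts
        if rel not in SIF_RELATIONS:
            raise ModelSyntaxError(f"line {lineno}: unknown relation {rel!r}")
        edges.append((src, rel, tgt))
    return edges


# ---------------------------------------------------------------------------
# SBML-qual

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _q(tag: str) -> str:
    return f"{{{_QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{_MATH_NS}}}{tag}"


def read_sbml_qual(document: str) -> BooleanNetwork:
    """Compile an SBML-qual document into a Boolean network.

    Only binary models are supported: any species with maxLevel > 1 is a
    hard error, as is math outside and/or/not/eq over levels 0/1 or a
    transition without a default term.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ModelSyntaxError(f"invalid XML: {exc}") from exc
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise ModelSyntaxError("no <model> element")

    species_order: list[str] = []
    display: dict[str, str] = {}
    constant_species: dict[str, bool] = {}
    lqs = model.find(_q("listOfQualitativeSpecies"))
    if lqs is None:
        raise ModelSyntaxError("no listOfQualitativeSpecies")
    for sp in lqs.findall(_q("qualitativeSpecies")):
        sid = sp.get(_q("id")) or sp.get("id")
        if sid is None:
            raise ModelSyntaxError("qualitativeSpecies without id")
        max_level = sp.get(_q("maxLevel")) or sp.get("maxLevel")
        if max_level is not None and int(max_level) > 1:
            raise ModelSyntaxError(
                f"species {sid!r} has maxLevel {max_level}; only binary "
                "models are supported")
        name = sp.get(_q("name")) or sp.get("name")
        ident = normalize_identifier(sid)
        species_order.append(ident)
        if name and name != ident:
            display[ident] = name
        constant_species[ident] = (
            (sp.get(_q("constant")) or sp.get("constant") or "false") == "true")

    id_map = {normalize_identifier(s): s for s in species_order}
    del id_map  # ids already normalized above

    functions: dict[str, Expr] = {n: Var(n) for n in species_order}
    lot = model.find(_q("listOfTransitions"))
    seen_targets: set[str] = set()
    if lot is not None:
        for tr in lot.findall(_q("transition")):
            target, expr = _read_transition(tr, set(species_order))
            if target in seen_targets:
                raise ModelSyntaxError(
                    f"multiple transitions target species {target!r}")
            seen_targets.add(target)
            functions[target] = expr

    metadata = {f"display:{k}": v for k, v in display.items()}
    mid = model.get("id") or model.get("name")
    if mid:
        metadata["name"] = mid
    return BooleanNetwork(functions, metadata)


def _read_transition(tr: ET.Element, declared: set[str]) -> tuple[str, Expr]:
    outs = tr.find(_q("listOfOutputs"))
    if outs is None:
        raise ModelSyntaxError("transition without outputs")
    out_species = [o.get(_q("qualitativeSpecies")) or o.get("qualitativeSpecies")
                   for o in outs.findall(_q("output"))]
    if len(out_species) != 1 or out_species[0] is None:
        raise ModelSyntaxError("transition must have exactly one output")
    target = normalize_identifier(out_species[0])
    if target not in declared:
        raise ModelSyntaxError(f"transition targets undeclared species "
                               f"{out_species[0]!r}")

    lft = tr.find(_q("listOfFunctionTerms"))
    if lft is None:
        raise ModelSyntaxError(f"transition for {target!r} has no function terms")
    default = lft.find(_q("defaultTerm"))
    if default is None:
        raise ModelSyntaxError(f"transition for {target!r} lacks a default term")
    default_level = int(default.get(_q("resultLevel"))
                        or default.get("resultLevel") or 0)

    terms: list[Expr] = []
    for ft in lft.findall(_q("functionTerm")):
        level = int(ft.get(_q("resultLevel")) or ft.get("resultLevel") or 0)
        math = ft.find(_m("math"))
        if math is None or len(math) == 0:
            raise ModelSyntaxError(f"function term for {target!r} has no math")
        expr = _math_to_expr(math[0], declared)
        if level == 1:
            terms.append(expr)
        else:
            # level-0 term: contributes NOT expr when the default is 1
            terms.append(Not(expr))
    if not terms:
        return target, Const(default_level)
    if default_level == 0:
        from .expr import or_all
        return target, or_all(terms)
    # default 1: ON unless some level-0 term fires; terms were pre-negated
    from .expr import and_all
    return target, and_all(terms)


def _math_to_expr(el: ET.Element, declared: set[str]) -> Expr:
    tag = el.tag
    if tag == _m("apply"):
        children = list(el)
        op, args = children[0], children[1:]
        if op.tag == _m("and"):
            return And(tuple(_math_to_expr(a, declared) for a in args))
        if op.tag == _m("or"):
            return Or(tuple(_math_to_expr(a, declared) for a in args))
        if op.tag == _m("not"):
            if len(args) != 1:
                raise ModelSyntaxError("<not> takes one argument")
            return Not(_math_to_expr(args[0], declared))
        if op.tag == _m("eq"):
            if len(args) != 2:
                raise ModelSyntaxError("<eq> takes two arguments")
            ci = next((a for a in args if a.tag == _m("ci")), None)
            cn = next((a for a in args if a.tag == _m("cn")), None)
            if ci is None or cn is None:
                raise ModelSyntaxError("<eq> must compare a species to a level")
            name = normalize_identifier((ci.text or "").strip())
            if name not in declared:
                raise ModelSyntaxError(f"math references undeclared species "
                                       f"{ci.text!r}")
            level = int(float((cn.text or "").strip()))
            if level not in (0, 1):
                raise ModelSyntaxError(f"unsupported level {level} in math")
            return Var(name) if level == 1 else Not(Var(name))
        raise ModelSyntaxError(f"unsupported MathML operator {op.tag!r}")
    if tag == _m("ci"):
        name = normalize_identifier((el.text or "").strip())
        if name not in declared:
            raise ModelSyntaxError(f"math references undeclared species "
                                   f"{el.text!r}")
        return Var(name)
    if tag == _m("true"):
        return Const(1)
    if tag == _m("false"):
        return Const(0)
    raise ModelSyntaxError(f"unsupported MathML element {tag!r}")


def write_sbml_qual(network: BooleanNetwork) -> str:
    """Serialize to an SBML-qual document (binary levels, one transition per
    non-input node).  Inverse of :func:`read_sbml_qual` up to truth-table
    equivalence."""
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("qual", _QUAL_NS)
    ET.register_namespace("math", _MATH_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {
        "level": "3", "version": "1",
        f"{{{_QUAL_NS}}}required": "true",
    })
    model_id = network.metadata.get("name", "model")
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", {"id": model_id})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  {"id": "default", "constant": "true"})

    inputs = set(network.inputs)
    lqs = ET.SubElement(model, _q("listOfQualitativeSpecies"))
    for node in network.nodes:
        attrs = {
            _q("id"): node,
            _q("compartment"): "default",
            _q("constant"): "false",
            _q("maxLevel"): "1",
        }
        display = network.metadata.get(f"display:{node}")
        if display:
            attrs[_q("name")] = display
        ET.SubElement(lqs, _q("qualitativeSpecies"), attrs)

    lot = ET.SubElement(model, _q("listOfTransitions"))
    for node in network.nodes:
        if node in inputs:
            continue
        fn = network.functions[node]
        tr = ET.SubElement(lot, _q("transition"), {_q("id"): f"tr_{node}"})
        regs = network.regulators(node)
        if regs:
            lin = ET.SubElement(tr, _q("listOfInputs"))
            for reg in regs:
                ET.SubElement(lin, _q("input"), {
                    _q("qualitativeSpecies"): reg,
                    _q("transitionEffect"): "none",
                    _q("sign"): "unknown",
                })
        lout = ET.SubElement(tr, _q("listOfOutputs"))
        ET.SubElement(lout, _q("output"), {
            _q("qualitativeSpecies"): node,
            _q("transitionEffect"): "assignmentLevel",
        })
        lft = ET.SubElement(tr, _q("listOfFunctionTerms"))
        if isinstance(fn, Const):
            ET.SubElement(lft, _q("defaultTerm"),
                          {_q("resultLevel"): str(fn.value)})
        else:
            ft = ET.SubElement(lft, _q("functionTerm"),
                               {_q("resultLevel"): "1"})
            math = ET.SubElement(ft, _m("math"))
            math.append(_expr_to_math(fn))
            ET.SubElement(lft, _q("defaultTerm"), {_q("resultLevel"): "0"})

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True) + "\n"


def _expr_to_math(expr: Expr) -> ET.Element:
    if isinstance(expr, Var):
        apply = ET.Element(_m("apply"))
        ET.SubElement(apply, _m("eq"))
        ci = ET.SubElement(apply, _m("ci"))
        ci.text = expr.name
        cn = ET.SubElement(apply, _m("cn"), {"type": "integer"})
        cn.text = "1"
        return apply
    if isinstance(expr, Const):
        return ET.Element(_m("true") if expr.value else _m("false"))
    if isinstance(expr, Not):
        apply = ET.Element(_m("apply"))
        ET.SubElement(apply, _m("not"))
        apply.append(_expr_to_math(expr.operand))
        return apply
    if isinstance(expr, (And, Or)):
        apply = ET.Element(_m("apply"))
        ET.SubElement(apply, _m("and") if isinstance(expr, And) else _m("or"))
        for op in expr.operands:
            apply.append(_expr_to_math(op))
        return apply
    raise TypeError(f"unknown expression node {expr!r}")
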