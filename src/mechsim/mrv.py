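"""Best-effort reader for a subset of Marvin document (.mrv) XML.

Curly-arrow diagrams of enzyme mechanisms are commonly deposited as
Marvin documents — an XML schema whose bulk is sketch metadata.  This
reader accepts a documented subset sufficient to recover a catalytic
step:

* one ``<molecule>`` block with atoms (``elementType``, optional
  ``formalCharge``), in either nested ``<atom>`` element syntax or the
  whitespace-separated attribute-array syntax;
* ``<bond atomRefs2="a1 a2" order="..."/>`` with orders ``1``, ``2``,
  ``3`` or ``A`` (aromatic, kept distinct — no kekulization);
* electron-flow arrows as ``<MEFlow>`` elements with two child set
  points (source first, then sink): ``<atomSetPoint atomRefs="a1"/>``
  for a single atom, ``<atomSetPoint atomRefs="a1 a2"/>`` for an atom
  pair (an existing bond if the atoms are bonded, otherwise an incipient
  bond), or ``<bondSetPoint atomRefs="a1 a2"/>``/``bondRefs="b1"`` for an
  existing bond.  The optional ``electronCount`` attribute defaults
  to 2.

Everything else (coordinates, sketch decorations, unknown elements) is
ignored; each ignored feature is reported through the module logger.
"""

from __future__ import annotations

import logging

from lxml import etree
from rdkit import Chem

from .errors import MechanismValidationError, MrvParseError
from .model import (
    ActiveSiteState,
    ArrowEndpoint,
    AtomNode,
    BondEdge,
    BondOrder,
    CatalyticStep,
    CurlyArrow,
    validate_mechanism,
    Mechanism,
)

logger = logging.getLogger(__name__)

_ORDER_MAP = {
    "1": BondOrder.SINGLE,
    "2": BondOrder.DOUBLE,
    "3": BondOrder.TRIPLE,
    "A": BondOrder.AROMATIC,
}

_KNOWN_TAGS = {
    "cml", "MDocument", "MChemicalStruct", "molecule", "atomArray", "atom",
    "bondArray", "bond", "MEFlow", "atomSetPoint", "bondSetPoint",
}

# Marvin stores element *symbols*, not atomic numbers
_PT = Chem.GetPeriodicTable()


def _localname(el) -> str:
    return etree.QName(el).localname


def _parse_atoms(mol) -> tuple[dict[str, int], list[AtomNode]]:
    """Return (mrv id -> numeric id, atom list)."""
    id_map: dict[str, int] = {}
    atoms: list[AtomNode] = []

    def add(mrv_id: str, symbol: str, charge: int) -> None:
        if mrv_id in id_map:
            raise MrvParseError(f"duplicate atom id {mrv_id!r}")
        try:
            element = _PT.GetAtomicNumber(symbol)
        except Exception:
            element = 0
        if element < 1:
            raise MrvParseError(f"unknown elementType {symbol!r}")
        num = len(atoms) + 1
        id_map[mrv_id] = num
        atoms.append(AtomNode(num, element, charge))

    for arr in mol.iter():
        if _localname(arr) != "atomArray":
            continue
        nested = [el for el in arr if _localname(el) == "atom"]
        if nested:
            for el in nested:
                mrv_id = el.get("id")
                symbol = el.get("elementType")
                if mrv_id is None or symbol is None:
                    raise MrvParseError("atom element missing id/elementType")
                add(mrv_id, symbol, int(el.get("formalCharge", "0")))
        else:
            ids = (arr.get("atomID") or "").split()
            symbols = (arr.get("elementType") or "").split()
            if not ids:
                continue
            if len(symbols) != len(ids):
                raise MrvParseError("atomArray id/elementType length mismatch")
            charges = (arr.get("formalCharge") or "").split()
            if charges and len(charges) != len(ids):
                raise MrvParseError("atomArray formalCharge length mismatch")
            for k, mrv_id in enumerate(ids):
                add(mrv_id, symbols[k], int(charges[k]) if charges else 0)
    if not atoms:
        raise MrvParseError("no atoms found in document")
    return id_map, atoms


def _parse_bonds(mol, id_map) -> tuple[dict[str, tuple[int, int]], list[BondEdge]]:
    bond_ids: dict[str, tuple[int, int]] = {}
    bonds: list[BondEdge] = []
    for el in mol.iter():
        if _localname(el) != "bond":
            continue
        refs = (el.get("atomRefs2") or "").split()
        if len(refs) != 2:
            raise MrvParseError(f"bond with malformed atomRefs2 {el.get('atomRefs2')!r}")
        order_sym = el.get("order", "1")
        if order_sym not in _ORDER_MAP:
            raise MrvParseError(f"unsupported bond order symbol {order_sym!r}")
        for r in refs:
            if r not in id_map:
                raise MrvParseError(f"bond references undeclared atom {r!r}")
        a, b = id_map[refs[0]], id_map[refs[1]]
        bonds.append(BondEdge(a, b, _ORDER_MAP[order_sym]))
        if el.get("id"):
            bond_ids[el.get("id")] = (min(a, b), max(a, b))
    return bond_ids, bonds


def _parse_setpoint(el, id_map, bond_ids, state, is_source) -> ArrowEndpoint:
    tag = _localname(el)
    if tag == "bondSetPoint":
        if el.get("bondRefs"):
            ref = el.get("bondRefs").split()[0]
            if ref not in bond_ids:
                raise MrvParseError(f"MEFlow references undeclared bond {ref!r}")
            return ArrowEndpoint.bond(*bond_ids[ref])
        refs = (el.get("atomRefs") or "").split()
        if len(refs) != 2:
            raise MrvParseError("bondSetPoint needs bondRefs or two atomRefs")
        nums = [_resolve_atom(r, id_map) for r in refs]
        if not state.has_bond(*nums):
            raise MrvParseError(f"bondSetPoint references non-bonded atoms {refs}")
        return ArrowEndpoint.bond(*nums)
    if tag == "atomSetPoint":
        refs = (el.get("atomRefs") or "").split()
        if len(refs) == 1:
            return ArrowEndpoint.atom(_resolve_atom(refs[0], id_map))
        if len(refs) == 2:
            nums = [_resolve_atom(r, id_map) for r in refs]
            if state.has_bond(*nums):
                return ArrowEndpoint.bond(*nums)
            if is_source:
                raise MrvParseError(
                    f"MEFlow source references non-bonded atom pair {refs}"
                )
            return ArrowEndpoint.incipient(*nums)
        raise MrvParseError(f"atomSetPoint with {len(refs)} atomRefs")
    raise MrvParseError(f"unsupported MEFlow set point element <{tag}>")


def _resolve_atom(ref: str, id_map) -> int:
    if ref not in id_map:
        raise MrvParseError(f"MEFlow references undeclared atom {ref!r}")
    return id_map[ref]


def parse_mrv_step(xml: str | bytes, step_index: int = 1) -> CatalyticStep:
    """Parse one catalytic step from an MRV document.

    Raises :class:`MrvParseError` for out-of-subset content and
    :class:`MechanismValidationError` when the recovered step violates
    domain invariants (e.g. no electron-flow arrows at all).
    """
    if isinstance(xml, str):
        xml = xml.encode()
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as e:
        raise MrvParseError(f"invalid XML: {e}") from None

    ignored = sorted(
        {_localname(el) for el in root.iter() if _localname(el) not in _KNOWN_TAGS}
    )
    if ignored:
        logger.warning("ignoring unsupported MRV elements: %s", ", ".join(ignored))

    id_map, atoms = _parse_atoms(root)
    bond_ids, bonds = _parse_bonds(root, id_map)
    state = ActiveSiteState(tuple(atoms), tuple(bonds))

    arrows: list[CurlyArrow] = []
    for flow in root.iter():
        if _localname(flow) != "MEFlow":
            continue
        points = [
            el for el in flow if _localname(el) in ("atomSetPoint", "bondSetPoint")
        ]
        if len(points) != 2:
            raise MrvParseError(
                f"MEFlow needs exactly 2 set points, found {len(points)}"
            )
        electrons = int(flow.get("electronCount", "2"))
        source = _parse_setpoint(points[0], id_map, bond_ids, state, True)
        sink = _parse_setpoint(points[1], id_map, bond_ids, state, False)
        arrows.append(CurlyArrow(electrons, source, sink))

    step = CatalyticStep(step_index, state, tuple(arrows))
    violations = validate_mechanism(Mechanism("mrv", (step,)))
    if violations:
        raise MechanismValidationError(violations)
    return step
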