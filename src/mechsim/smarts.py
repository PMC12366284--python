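"""SMARTS serialization of arrow-envs.

Arrow-envs are written in a restricted SMARTS dialect:

* atoms as ``[#<element>]``, e.g. ``[#8]``; equivalence classes as an
  alternation in atomic-number-descending order, e.g. ``[#6,#1]``;
* non-zero formal charges appended as ``&-``, ``&+``, ``&-2``, ...;
* the arrow position as a two-digit atom map ``:ED`` where ``E`` is the
  number of moving electrons (1 or 2) and ``D`` marks the atom as touched
  by the arrow's tail (1), tip (2) or both (3);
* explicit bond symbols ``-`` ``=`` ``#`` ``:``; fragments joined with
  ``.``; rings closed with numeric ring-bond labels.

The rendering is canonical: envs with equal canonical keys produce
byte-identical strings, independent of input atom ids or fragment order.
ASCII hyphen-minus is always emitted (typeset text sometimes prints
Unicode hyphens; compare after normalization).
"""

from __future__ import annotations

import re
from typing import Sequence

from rdkit import Chem

from .arrowenv import ArrowEnv, ArrowEnvDefinition, EnvAtom, TWO_AWAY
from .errors import SmartsParseError
from .model import BondEdge, BondOrder

_PT = Chem.GetPeriodicTable()

_BOND_TO_SYM = {
    BondOrder.SINGLE: "-",
    BondOrder.DOUBLE: "=",
    BondOrder.TRIPLE: "#",
    BondOrder.AROMATIC: ":",
}
_SYM_TO_BOND = {v: k for k, v in _BOND_TO_SYM.items()}


def _render_elements(atom: EnvAtom) -> tuple[int, ...]:
    # alternations print highest atomic number first: [#6,#1]
    return tuple(sorted(atom.elements, reverse=True))


def _symbols(atom: EnvAtom) -> tuple[str, ...]:
    return tuple(_PT.GetElementSymbol(int(z)) for z in _render_elements(atom))


def _atom_token(atom: EnvAtom) -> str:
    body = ",".join(f"#{z}" for z in _render_elements(atom))
    q = atom.formal_charge
    if q:
        sign = "-" if q < 0 else "+"
        body += "&" + sign + (str(abs(q)) if abs(q) != 1 else "")
    if atom.digits is not None:
        body += f":{atom.digits[0]}{atom.digits[1]}"
    return f"[{body}]"


def _ring_digit(n: int) -> str:
    return str(n) if n < 10 else f"%{n:02d}"


def to_smarts(env: ArrowEnv) -> str:
    """Serialize an arrow-env to its canonical SMARTS string.

    One dot-separated fragment per connected component, fragments sorted
    lexicographically.  Within a fragment the walk starts at the preferred
    atom (unmapped before mapped, then element symbol descending, then
    canonical rank) and visits neighbours in symbol-descending order, the
    last one continuing the main chain.
    """
    atoms = env.atoms
    adj = env.adjacency
    ranks = env.canonical_ranks

    def nbr_sorted(indices: Sequence[int]) -> list[int]:
        ns = sorted(indices, key=lambda v: ranks[v])
        ns.sort(key=lambda v: _symbols(atoms[v]), reverse=True)
        return ns

    # connected components over atom indices
    seen_global: set[int] = set()
    fragments: list[str] = []
    for root in range(len(atoms)):
        if root in seen_global:
            continue
        comp = []
        stack = [root]
        seen_global.add(root)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen_global:
                    seen_global.add(v)
                    stack.append(v)
        fragments.append(_render_fragment(comp, atoms, adj, ranks, nbr_sorted))
    return ".".join(sorted(fragments))


def _render_fragment(comp, atoms, adj, ranks, nbr_sorted) -> str:
    cand = sorted(comp, key=lambda i: ranks[i])
    cand.sort(key=lambda i: _symbols(atoms[i]), reverse=True)
    cand.sort(key=lambda i: atoms[i].digits is not None)
    start = cand[0]

    order_index: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    back_edges: list[tuple[int, int]] = []
    seen_pairs: set[frozenset[int]] = set()

    def walk(u: int, parent: int | None) -> None:
        order_index[u] = len(order_index)
        children[u] = []
        for v in nbr_sorted(adj[u]):
            if v == parent:
                continue
            if v in order_index:
                pair = frozenset((u, v))
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    back_edges.append((u, v))
            else:
                children[u].append(v)
                walk(v, u)

    walk(start, None)

    ring_marks: dict[int, list[str]] = {u: [] for u in comp}
    for num, (u, v) in enumerate(back_edges, start=1):
        first, second = sorted((u, v), key=order_index.__getitem__)
        sym = _BOND_TO_SYM[BondOrder(adj[first][second])]
        ring_marks[first].append(_ring_digit(num))
        ring_marks[second].append(sym + _ring_digit(num))

    def emit(u: int) -> str:
        s = _atom_token(atoms[u]) + "".join(ring_marks[u])
        kids = children[u]
        for v in kids[:-1]:
            s += "(" + _BOND_TO_SYM[BondOrder(adj[u][v])] + emit(v) + ")"
        if kids:
            v = kids[-1]
            s += _BOND_TO_SYM[BondOrder(adj[u][v])] + emit(v)
        return s

    return emit(start)


_ATOM_RE = re.compile(
    r"\[(#\d+(?:,#\d+)*)(?:&([+-])(\d*))?(?::(\d)(\d))?\]"
)


def parse_smarts_env(
    smarts: str, definition: ArrowEnvDefinition = TWO_AWAY
) -> ArrowEnv:
    """Parse a string of the emitted dialect back into an :class:`ArrowEnv`.

    Inverse of :func:`to_smarts` up to canonical form.  The shell
    structure cannot be recomputed without the originating state, so the
    env is taken as given; ``definition`` names the definition the string
    was produced under.  Out-of-dialect input raises
    :class:`SmartsParseError`.
    """
    smarts = smarts.strip()
    if not smarts:
        raise SmartsParseError("empty SMARTS string")
    atoms: list[EnvAtom] = []
    bonds: list[BondEdge] = []
    for frag in smarts.split("."):
        _parse_fragment(frag, atoms, bonds)
    return ArrowEnv(tuple(atoms), tuple(bonds), definition)


def _parse_fragment(frag: str, atoms: list[EnvAtom], bonds: list[BondEdge]) -> None:
    i = 0
    prev: int | None = None  # atom_id of the previous atom in the walk
    pending: str | None = None
    stack: list[int | None] = []
    ring_open: dict[int, tuple[int, str | None]] = {}

    def add_bond(a: int, b: int, sym: str | None) -> None:
        order = _SYM_TO_BOND[sym or "-"]
        bonds.append(BondEdge(a, b, order))

    while i < len(frag):
        c = frag[i]
        if c == "(":
            if prev is None:
                raise SmartsParseError(f"branch with no preceding atom at {i}: {frag}")
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise SmartsParseError(f"unbalanced ')' at {i}: {frag}")
            prev = stack.pop()
            i += 1
        elif c in _SYM_TO_BOND:
            if pending is not None:
                raise SmartsParseError(f"two bond symbols in a row at {i}: {frag}")
            pending = c
            i += 1
        elif c == "[":
            m = _ATOM_RE.match(frag, i)
            if not m:
                raise SmartsParseError(f"unparsable atom at {i}: {frag}")
            atom = _make_atom(m, len(atoms) + 1)
            atoms.append(atom)
            if prev is not None:
                add_bond(prev, atom.atom_id, pending)
            pending = None
            prev = atom.atom_id
            i = m.end()
            # ring-closure digits, optionally preceded by a bond symbol
            while i < len(frag):
                sym: str | None = None
                j = i
                if frag[j] in _SYM_TO_BOND and j + 1 < len(frag) and (
                    frag[j + 1].isdigit() or frag[j + 1] == "%"
                ):
                    sym = frag[j]
                    j += 1
                if j < len(frag) and frag[j] == "%":
                    if j + 2 >= len(frag) or not frag[j + 1 : j + 3].isdigit():
                        raise SmartsParseError(f"bad ring label at {j}: {frag}")
                    num = int(frag[j + 1 : j + 3])
                    j += 3
                elif j < len(frag) and frag[j].isdigit():
                    num = int(frag[j])
                    j += 1
                else:
                    break
                if num in ring_open:
                    other, other_sym = ring_open.pop(num)
                    use = sym or other_sym
                    if sym and other_sym and sym != other_sym:
                        raise SmartsParseError(
                            f"conflicting bond symbols on ring closure {num}"
                        )
                    add_bond(other, atom.atom_id, use)
                else:
                    ring_open[num] = (atom.atom_id, sym)
                i = j
        else:
            raise SmartsParseError(f"unexpected character {c!r} at {i}: {frag}")
    if stack:
        raise SmartsParseError(f"unbalanced '(' in fragment: {frag}")
    if pending is not None:
        raise SmartsParseError(f"dangling bond symbol in fragment: {frag}")
    if ring_open:
        raise SmartsParseError(f"unclosed ring labels {sorted(ring_open)}: {frag}")


def _make_atom(m: re.Match, atom_id: int) -> EnvAtom:
    elements = tuple(int(tok[1:]) for tok in m.group(1).split(","))
    for z in elements:
        if not (1 <= z <= 118):
            raise SmartsParseError(f"element {z} outside 1..118")
    charge = 0
    if m.group(2):
        mag = int(m.group(3)) if m.group(3) else 1
        charge = -mag if m.group(2) == "-" else mag
    digits = None
    if m.group(4):
        electrons, role = int(m.group(4)), int(m.group(5))
        if electrons not in (1, 2) or role not in (1, 2, 3):
            raise SmartsParseError(
                f"atom map :{electrons}{role} is not a valid (electrons, role) pair"
            )
        digits = (electrons, role)
    equivalence = tuple(sorted(elements)) if len(elements) > 1 else None
    return EnvAtom(
        atom_id=atom_id,
        element=max(elements),
        formal_charge=charge,
        equivalence=equivalence,
        digits=digits,
    )
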