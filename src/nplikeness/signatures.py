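"""Canonical circular atom signatures.

An *atom signature* of height ``h`` is a canonical string describing the
environment of one atom: the subgraph induced on all heavy atoms within graph
distance ``h`` of the root, with element, formal charge, aromaticity and bond
orders, but without stereochemistry, isotopes or hydrogen counts.  Two atoms
get the same text if and only if their rooted height-``h`` environments are
isomorphic, and the text never depends on the input atom order.  The multiset
of the signatures of every heavy atom is the *molecular signature*; its size
always equals the heavy-atom count.

Construction
------------
The environment is unfolded into a layered tree rooted at the query atom:

* layer ``k`` holds atoms at BFS distance ``k`` (``k <= h``);
* a tree node for atom ``a`` at layer ``k`` has a child node for **every**
  neighbour of ``a`` at layer ``k+1`` — an atom reachable by several shortest
  paths therefore occurs in several tree nodes;
* a bond between two atoms of the *same* layer appears as a pair of
  non-expanding "closure" leaves, one under each endpoint.

Atoms occurring in more than one tree node are tagged with an occurrence
number so cycles survive serialization; merging equally-numbered nodes
recovers the induced environment subgraph exactly, which is what
:func:`decode_signature` does.

Grammar
-------
::

    signature := node                      (root carries no bond symbol)
    node      := '[' label ']' [ '(' child+ ')' ]
    child     := bond node
    bond      := '-' | '=' | '#' | ':'
    label     := element [charge] [',' number]
    element   := e.g. 'C', 'Cl', 'Se'; lowercase ('c', 'n', 'se', ...) if aromatic
    charge    := '+' | '-' | '+'digits | '-'digits

Children of a node are serialized in canonical order: primarily the
lexicographic order of their number-free subtree strings; where equal subtree
strings hide different atom identities (only possible in cycles), every
admissible ordering is tried and the lexicographically smallest complete
serialization wins.  Any two isomorphic rooted environments therefore yield
byte-identical text.
"""

from __future__ import annotations

import itertools
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import NPLikenessError, SignatureParseError
from .records import (
    AROMATIC,
    BOND_ORDERS,
    BOND_VALENCE,
    Atom,
    Bond,
    MoleculeRecord,
    SignatureFileRecord,
)

DEFAULT_HEIGHT = 2

#: default valences used to fill open valences of decoded fragments
_DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "P": 3, "S": 2, "F": 1, "Cl": 1, "Br": 1,
    "I": 1, "B": 3, "As": 3, "Se": 2,
}

# aromatic (lowercase) element tokens, longest first so 'se' beats 's'
_AROMATIC_ELEMS = ("as", "se", "te", "b", "c", "n", "o", "p", "s")


@dataclass(frozen=True)
class AtomSignature:
    """Canonical signature of one atom's height-``h`` environment."""

    text: str
    height: int
    uuid: str
    root_atom: int


@dataclass(frozen=True)
class MolecularSignature:
    """Multiset of all atom signatures of one molecule."""

    uuid: str
    signatures: tuple[str, ...]  # one text per heavy atom, sorted

    def as_multiset(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.signatures:
            out[s] = out.get(s, 0) + 1
        return out


@dataclass(frozen=True)
class DecodedSignature:
    """A signature decoded back to its environment subgraph."""

    record: MoleculeRecord
    root: int
    height: int


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _atom_label(atom: Atom) -> str:
    sym = atom.symbol.lower() if atom.aromatic else atom.symbol
    if atom.charge == 1:
        sym += "+"
    elif atom.charge == -1:
        sym += "-"
    elif atom.charge > 1:
        sym += f"+{atom.charge}"
    elif atom.charge < -1:
        sym += f"-{-atom.charge}"
    return sym


@dataclass
class _Node:
    atom: int
    bond: str | None            # bond symbol towards the parent; None at root
    children: list["_Node"] = field(default_factory=list)
    # filled during canonicalization
    plain: str = ""             # number-free canonical subtree string
    sensitive: bool = False     # subtree touches an atom that occurs elsewhere too


def _build_tree(
    adj: Sequence[Sequence[tuple[int, str]]],
    dist: dict[int, int],
    atom: int,
    layer: int,
    bond: str | None,
) -> _Node:
    node = _Node(atom=atom, bond=bond)
    for nbr, order in adj[atom]:
        d = dist.get(nbr)
        if d == layer + 1:
            node.children.append(_build_tree(adj, dist, nbr, layer + 1, order))
        elif d == layer:
            # same-layer ring bond: closure leaf (mirrored under the other endpoint)
            node.children.append(_Node(atom=nbr, bond=order))
    return node


def _bfs_distances(
    adj: Sequence[Sequence[tuple[int, str]]], root: int, height: int
) -> dict[int, int]:
    dist = {root: 0}
    queue = deque([root])
    while queue:
        a = queue.popleft()
        if dist[a] == height:
            continue
        for b, _ in adj[a]:
            if b not in dist:
                dist[b] = dist[a] + 1
                queue.append(b)
    return dist


def _prepare(node: _Node, labels: Sequence[str], duplicated: set[int]) -> None:
    """Bottom-up: canonical number-free strings, child sort, sensitivity flags."""
    for child in node.children:
        _prepare(child, labels, duplicated)
    node.children.sort(key=lambda c: c.plain)
    s = (node.bond or "") + "[" + labels[node.atom] + "]"
    if node.children:
        s += "(" + "".join(c.plain for c in node.children) + ")"
    node.plain = s
    node.sensitive = node.atom in duplicated or any(
        c.sensitive for c in node.children
    )


def _tie_groups(node: _Node, out: list[list[_Node]]) -> None:
    """Collect sibling groups with equal number-free strings whose ordering
    can still influence occurrence numbering."""
    for _, grp in itertools.groupby(node.children, key=lambda c: c.plain):
        g = list(grp)
        if len(g) > 1 and any(c.sensitive for c in g):
            out.append(g)
    for child in node.children:
        _tie_groups(child, out)


_MAX_ORDERINGS = 100_000


def atom_signature(mol: MoleculeRecord, root: int, height: int = DEFAULT_HEIGHT) -> AtomSignature:
    """Canonical signature of ``root``'s height-``height`` environment."""
    if not (0 <= root < mol.num_atoms):
        raise NPLikenessError(f"root atom index {root} out of range")
    if height < 0:
        raise NPLikenessError("height must be >= 0")
    adj = mol.adjacency()
    dist = _bfs_distances(adj, root, height)
    tree = _build_tree(adj, dist, root, 0, None)

    # occurrence counts over the whole tree
    counts: dict[int, int] = {}
    stack = [tree]
    while stack:
        n = stack.pop()
        counts[n.atom] = counts.get(n.atom, 0) + 1
        stack.extend(n.children)
    duplicated = {a for a, c in counts.items() if c > 1}

    labels = [_atom_label(a) for a in mol.atoms]
    _prepare(tree, labels, duplicated)

    if not duplicated:
        text = tree.plain
    else:
        groups: list[list[_Node]] = []
        _tie_groups(tree, groups)
        total = 1
        for g in groups:
            for k in range(2, len(g) + 1):
                total *= k
            if total > _MAX_ORDERINGS:
                raise NPLikenessError(
                    "environment too symmetric to canonicalize "
                    f"({total}+ candidate orderings)"
                )
        best: str | None = None
        group_keys = [_group_key(g) for g in groups]
        for perms in itertools.product(
            *[list(itertools.permutations(g)) for g in groups]
        ):
            candidate = _serialize_with_group_perms(
                tree, labels, duplicated, dict(zip(group_keys, perms))
            )
            if best is None or candidate < best:
                best = candidate
        text = best  # type: ignore[assignment]

    return AtomSignature(text=text, height=height, uuid=mol.uuid, root_atom=root)


def _group_key(group: list[_Node]) -> tuple[int, ...]:
    return tuple(sorted(id(n) for n in group))


def _serialize_with_group_perms(
    node: _Node,
    labels: Sequence[str],
    duplicated: set[int],
    perms: dict[tuple[int, ...], tuple[_Node, ...]],
    numbers: dict[int, int] | None = None,
) -> str:
    if numbers is None:
        numbers = {}
    label = labels[node.atom]
    if node.atom in duplicated:
        if node.atom not in numbers:
            numbers[node.atom] = len(numbers) + 1
        label += f",{numbers[node.atom]}"
    s = (node.bond or "") + "[" + label + "]"
    if node.children:
        ordered: list[_Node] = []
        for _, grp in itertools.groupby(node.children, key=lambda c: c.plain):
            g = list(grp)
            key = _group_key(g)
            ordered.extend(perms.get(key, tuple(g)))
        s += "(" + "".join(
            _serialize_with_group_perms(c, labels, duplicated, perms, numbers)
            for c in ordered
        ) + ")"
    return s


def molecular_signature(mol: MoleculeRecord, height: int = DEFAULT_HEIGHT) -> MolecularSignature:
    """One signature per heavy atom, as an order-independent sorted tuple."""
    if mol.num_atoms == 0:
        raise NPLikenessError("cannot sign an empty molecule")
    texts = sorted(
        atom_signature(mol, i, height).text for i in range(mol.num_atoms)
    )
    return MolecularSignature(uuid=mol.uuid, signatures=tuple(texts))


def sign_batch(
    mols: Iterable[MoleculeRecord], height: int = DEFAULT_HEIGHT
) -> list[SignatureFileRecord]:
    """Signatures for every atom of every molecule, tagged with each record's
    uuid, in input order.  Fragments sharing a uuid pool under that uuid."""
    out: list[SignatureFileRecord] = []
    for mol in mols:
        for i in range(mol.num_atoms):
            out.append(
                SignatureFileRecord(mol.uuid, atom_signature(mol, i, height).text)
            )
    return out


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

_CHARGE_RE = re.compile(r"([+-])(\d*)")
_UPPER_ELEM_RE = re.compile(r"[A-Z][a-z]?")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> SignatureParseError:
        return SignatureParseError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def parse_label(self) -> tuple[str, int, bool, int | None]:
        """-> (symbol, charge, aromatic, occurrence-number or None)"""
        t = self.text
        aromatic = False
        symbol = ""
        for tok in _AROMATIC_ELEMS:
            if t.startswith(tok, self.pos):
                symbol, aromatic = tok.capitalize(), True
                self.pos += len(tok)
                break
        if not symbol:
            m = _UPPER_ELEM_RE.match(t, self.pos)
            if not m:
                raise self.error("expected element symbol")
            symbol = m.group(0)
            self.pos = m.end()
        charge = 0
        if self.peek() in "+-":
            m = _CHARGE_RE.match(t, self.pos)
            assert m is not None
            magnitude = int(m.group(2)) if m.group(2) else 1
            charge = magnitude if m.group(1) == "+" else -magnitude
            self.pos = m.end()
        number: int | None = None
        if self.peek() == ",":
            self.pos += 1
            start = self.pos
            while self.peek().isdigit():
                self.pos += 1
            if self.pos == start:
                raise self.error("expected occurrence number after ','")
            number = int(t[start:self.pos])
        return symbol, charge, aromatic, number

    def parse_node(self, bond: str | None, depth: int, sink: "_GraphSink") -> int:
        self.expect("[")
        symbol, charge, aromatic, number = self.parse_label()
        self.expect("]")
        atom_id = sink.add_occurrence(symbol, charge, aromatic, number, self)
        sink.note_depth(atom_id, depth)
        if self.peek() == "(":
            self.pos += 1
            saw_child = False
            while self.peek() in BOND_ORDERS:
                child_bond = self.peek()
                self.pos += 1
                child_id = self.parse_node(child_bond, depth + 1, sink)
                sink.add_bond(atom_id, child_id, child_bond, self)
                saw_child = True
            if not saw_child:
                raise self.error("empty child list")
            self.expect(")")
        return atom_id


class _GraphSink:
    """Accumulates parsed occurrences, merging equally-numbered ones."""

    def __init__(self) -> None:
        self.atoms: list[tuple[str, int, bool]] = []
        self.by_number: dict[int, int] = {}
        self.bonds: dict[tuple[int, int], str] = {}
        self.depth: dict[int, int] = {}

    def add_occurrence(
        self, symbol: str, charge: int, aromatic: bool,
        number: int | None, parser: _Parser,
    ) -> int:
        if number is not None and number in self.by_number:
            idx = self.by_number[number]
            if self.atoms[idx] != (symbol, charge, aromatic):
                raise parser.error(
                    f"occurrence ,{number} re-used with a different atom label"
                )
            return idx
        self.atoms.append((symbol, charge, aromatic))
        idx = len(self.atoms) - 1
        if number is not None:
            self.by_number[number] = idx
        return idx

    def note_depth(self, atom_id: int, depth: int) -> None:
        self.depth[atom_id] = min(self.depth.get(atom_id, depth), depth)

    def add_bond(self, i: int, j: int, order: str, parser: _Parser) -> None:
        if i == j:
            raise parser.error("self-bond in signature")
        key = (min(i, j), max(i, j))
        prev = self.bonds.get(key)
        if prev is not None and prev != order:
            raise parser.error("conflicting bond orders for one atom pair")
        self.bonds[key] = order


def _fill_hydrogens(symbol: str, charge: int, aromatic: bool, bond_sum: float) -> int:
    valence = _DEFAULT_VALENCE.get(symbol)
    if valence is None:
        return 0
    if symbol in ("N", "O", "S", "P", "C", "B"):
        valence += charge  # cations gain a bond slot, anions lose one
    return max(0, int(valence - bond_sum))


def decode_signature(text: str) -> DecodedSignature:
    """Rebuild the environment subgraph a signature describes.

    The returned record's root re-encodes to exactly ``text`` at the decoded
    height.  Open valences are filled with implicit hydrogens from default
    valences (aromatic bonds counting 1.5).
    """
    parser = _Parser(text)
    sink = _GraphSink()
    if parser.peek() != "[":
        raise parser.error("signature must start with '['")
    root = parser.parse_node(None, 0, sink)
    if parser.pos != len(text):
        raise parser.error("trailing characters after signature")

    bond_sum = [0.0] * len(sink.atoms)
    bonds = []
    for (i, j), order in sorted(sink.bonds.items()):
        bonds.append(Bond(i, j, order))
        bond_sum[i] += BOND_VALENCE[order]
        bond_sum[j] += BOND_VALENCE[order]
    atoms = [
        Atom(sym, chg, _fill_hydrogens(sym, chg, arom, bond_sum[k]), arom)
        for k, (sym, chg, arom) in enumerate(sink.atoms)
    ]
    record = MoleculeRecord(uuid="decoded", atoms=atoms, bonds=bonds)
    record.validate()
    height = max(sink.depth[a] for a in range(len(atoms)))
    return DecodedSignature(record=record, root=root, height=height)


def reencode(decoded: DecodedSignature) -> str:
    """Signature of a decoded fragment's root at its decoded height."""
    return atom_signature(decoded.record, decoded.root, decoded.height).text
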