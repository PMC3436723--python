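"""Core in-memory containers: molecule graphs and the flat-file record types.

A :class:`MoleculeRecord` is a plain heavy-atom graph: element / formal charge /
implicit-hydrogen-count per atom, and typed bonds (single, double, triple,
aromatic).  Hydrogens are always implicit; explicit hydrogens from input files
are folded into the counts at parse time.  Every record carries a UUID which
survives curation: fragments split from one parent share the parent's UUID so
they are pooled back into one molecule when scored.

Bond orders are stored as their one-character serialization symbols
(``-``, ``=``, ``#``, ``:``), which double as the bond tokens of the signature
grammar.
"""

from __future__ import annotations

import uuid as _uuid
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from .errors import NPLikenessError

# Bond-order symbols (also the grammar's bond tokens).
SINGLE = "-"
DOUBLE = "="
TRIPLE = "#"
AROMATIC = ":"
BOND_ORDERS = (SINGLE, DOUBLE, TRIPLE, AROMATIC)

#: numeric valence contribution of each bond symbol
BOND_VALENCE = {SINGLE: 1.0, DOUBLE: 2.0, TRIPLE: 3.0, AROMATIC: 1.5}


class Atom(NamedTuple):
    symbol: str
    charge: int = 0
    hcount: int = 0
    aromatic: bool = False


class Bond(NamedTuple):
    i: int
    j: int
    order: str = SINGLE


def new_uuid() -> str:
    """A fresh RFC-4122 version-4 identifier string."""
    return str(_uuid.uuid4())


def deterministic_uuid_factory(seed: int):
    """Return a callable producing reproducible version-4-shaped UUIDs.

    Successive calls yield the same sequence for the same seed, so pipelines
    can be replayed byte-for-byte.
    """
    import random

    rng = random.Random(seed)

    def factory() -> str:
        return str(_uuid.UUID(int=rng.getrandbits(128), version=4))

    return factory


@dataclass
class MoleculeRecord:
    """A heavy-atom molecular graph with provenance.

    Invariants: bond endpoints are valid 0-based atom indices, no self-bonds,
    no duplicate bonds.  ``validate()`` enforces them.
    """

    uuid: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str | None = None
    origin: str | None = None

    # -- basic graph accessors -------------------------------------------------

    @property
    def num_atoms(self) -> int:
        """Heavy-atom count."""
        return len(self.atoms)

    def adjacency(self) -> list[list[tuple[int, str]]]:
        """Neighbour list: ``adj[i]`` holds ``(j, bond_symbol)`` pairs."""
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append((b.j, b.order))
            adj[b.j].append((b.i, b.order))
        return adj

    def aromatic_flags(self) -> list[bool]:
        return [a.aromatic for a in self.atoms]

    def validate(self) -> None:
        n = len(self.atoms)
        if not self.uuid:
            raise NPLikenessError("record has an empty uuid")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise NPLikenessError(f"bond {b} endpoint out of range (n={n})")
            if b.i == b.j:
                raise NPLikenessError(f"self-bond on atom {b.i}")
            if b.order not in BOND_ORDERS:
                raise NPLikenessError(f"unknown bond order {b.order!r}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise NPLikenessError(f"duplicate bond between {key}")
            seen.add(key)

    # -- derived graphs --------------------------------------------------------

    def subgraph(self, keep: Iterable[int]) -> "MoleculeRecord":
        """Record induced on the given atom indices; uuid/name/origin retained."""
        keep_sorted = sorted(set(keep))
        remap = {old: new for new, old in enumerate(keep_sorted)}
        atoms = [self.atoms[i] for i in keep_sorted]
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in self.bonds
            if b.i in remap and b.j in remap
        ]
        return replace(self, atoms=atoms, bonds=bonds)

    def permuted(self, perm: list[int]) -> "MoleculeRecord":
        """Record with atoms reordered: new index ``k`` holds old atom ``perm[k]``."""
        inv = {old: new for new, old in enumerate(perm)}
        atoms = [self.atoms[old] for old in perm]
        bonds = [Bond(inv[b.i], inv[b.j], b.order) for b in self.bonds]
        return replace(self, atoms=atoms, bonds=bonds)

    def connected_components(self) -> list[list[int]]:
        """Connected components as sorted atom-index lists, in order of smallest member."""
        adj = self.adjacency()
        seen: set[int] = set()
        comps: list[list[int]] = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                a = stack.pop()
                comp.append(a)
                for b, _ in adj[a]:
                    if b not in seen:
                        seen.add(b)
                        stack.append(b)
            comps.append(sorted(comp))
        return comps


class SignatureFileRecord(NamedTuple):
    """One line of a signature file: ``<uuid>\\t<signature>``."""

    uuid: str
    signature: str


class ScoreFileRecord(NamedTuple):
    """One line of a score file: ``<uuid>\\t<score>``."""

    uuid: str
    score: float
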