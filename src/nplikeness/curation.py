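"""Molecule standardisation ahead of signature generation.

Pipeline (fixed order):

1. **Small-component filter** — disconnected components with fewer than
   ``min_fragment_atoms`` heavy atoms (default 6) are deleted; this strips
   counter-ions and solvates before the element filter can see them.
2. **Element whitelist** — molecules containing any element outside
   C, H, N, O, P, S, F, Cl, Br, I, As, Se, B are discarded whole.
3. **Sugar removal** — glycosidically linked ring and linear sugar units are
   deleted iteratively, outermost first, so oligosaccharide chains strip
   completely and a sugar bridging two scaffolds splits the molecule.
4. **Final size filter** — components shrunk below the cutoff by
   deglycosylation are deleted.

Fragments surviving from one parent keep the parent's UUID, so the scorer
later pools them back into a single molecule.

Sugar definitions (heuristic, in the spirit of classic toolkit
deglycosylation):

* *Ring sugar*: a 5- or 6-membered ring with exactly one ring oxygen, all
  other ring atoms carbon, no ring C=C double bond, and at least
  ``ring_size - 3`` ring carbons bearing an exocyclic single-bonded oxygen
  (furanoses and pyranoses match; THF/pyran ethers do not).
* *Linear sugar*: an acyclic chain of >= 3 contiguous sp3 carbons, each
  bearing exactly one single-bonded oxygen, none in a ring.

A sugar *unit* is the matched atoms plus their terminal oxygen substituents
and CH2OH-type appendages.  A unit is removed when every bond leaving it runs
through an exocyclic bridging oxygen (a glycosidic/ether link — C-glycosides
are kept) and at most one of those links leads to another sugar unit
(outside-in removal).  Bridging oxygens are deleted with the sugar, leaving a
clean aglycone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .records import DOUBLE, SINGLE, Bond, MoleculeRecord

DEFAULT_MIN_FRAGMENT_ATOMS = 6
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I", "As", "Se", "B"}
)

REASON_METAL = "metal_element"
REASON_EMPTY = "empty_after_curation"
REASON_TOO_SMALL = "too_small"


@dataclass(frozen=True)
class CurationConfig:
    min_fragment_atoms: int = DEFAULT_MIN_FRAGMENT_ATOMS
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    remove_sugars: bool = True

    def __post_init__(self) -> None:
        if self.min_fragment_atoms < 1:
            raise ValueError("min_fragment_atoms must be >= 1")
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")


@dataclass
class CurationOutcome:
    kept: list[MoleculeRecord] = field(default_factory=list)
    discarded: list[tuple[str, str]] = field(default_factory=list)  # (uuid, reason)
    stats: Counter = field(default_factory=Counter)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_small_components(
    mol: MoleculeRecord, min_fragment_atoms: int = DEFAULT_MIN_FRAGMENT_ATOMS
) -> MoleculeRecord | None:
    """Delete connected components below the heavy-atom cutoff.

    Survivors stay in one record under the original uuid; ``None`` means the
    whole molecule fell below the cutoff.
    """
    keep: list[int] = []
    for comp in mol.connected_components():
        if len(comp) >= min_fragment_atoms:
            keep.extend(comp)
    if not keep:
        return None
    if len(keep) == mol.num_atoms:
        return mol
    return mol.subgraph(keep)


def filter_elements(
    mol: MoleculeRecord,
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS,
) -> bool:
    """True if every atom's element is whitelisted (molecule is kept)."""
    return all(a.symbol in allowed_elements for a in mol.atoms)


# -- sugar perception --------------------------------------------------------

def _graph(mol: MoleculeRecord) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.num_atoms))
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    return g


def _ring_atoms(g: nx.Graph) -> set[int]:
    out: set[int] = set()
    for cyc in nx.cycle_basis(g):
        out.update(cyc)
    return out


def _is_sp3_carbon(mol: MoleculeRecord, adj, i: int) -> bool:
    return mol.atoms[i].symbol == "C" and all(o == SINGLE for _, o in adj[i])


def find_ring_sugars(mol: MoleculeRecord) -> list[set[int]]:
    """Atom-index sets of rings matching the ring-sugar definition.

    Fused matches are merged into one set.
    """
    g = _graph(mol)
    adj = mol.adjacency()
    matches: list[set[int]] = []
    for cycle in nx.simple_cycles(g, length_bound=6):
        size = len(cycle)
        if size not in (5, 6):
            continue
        ring = set(cycle)
        oxygens = [i for i in ring if mol.atoms[i].symbol == "O"]
        carbons = [i for i in ring if mol.atoms[i].symbol == "C"]
        if len(oxygens) != 1 or len(carbons) != size - 1:
            continue
        # no in-ring C=C (or aromatic ring)
        if any(
            g.edges[i, j]["order"] != SINGLE
            for i, j in zip(cycle, cycle[1:] + cycle[:1])
        ):
            continue
        exo_oxy_carbons = sum(
            1
            for c in carbons
            if any(
                o == SINGLE and n not in ring and mol.atoms[n].symbol == "O"
                for n, o in adj[c]
            )
        )
        if exo_oxy_carbons < size - 3:
            continue
        matches.append(ring)
    # merge fused rings sharing atoms
    merged: list[set[int]] = []
    for ring in matches:
        for m in merged:
            if m & ring:
                m |= ring
                break
        else:
            merged.append(set(ring))
    return merged


def find_linear_sugars(mol: MoleculeRecord) -> list[set[int]]:
    """Maximal acyclic chains of >= 3 contiguous sp3 carbons, each with
    exactly one single-bonded oxygen substituent."""
    g = _graph(mol)
    in_ring = _ring_atoms(g)
    adj = mol.adjacency()

    def qualifies(i: int) -> bool:
        if i in in_ring or not _is_sp3_carbon(mol, adj, i):
            return False
        oxy = [n for n, o in adj[i] if o == SINGLE and mol.atoms[n].symbol == "O"]
        return len(oxy) == 1 and all(n not in in_ring for n in oxy)

    candidates = {i for i in range(mol.num_atoms) if qualifies(i)}
    sub = g.subgraph(candidates)
    chains: list[set[int]] = []
    for comp in nx.connected_components(sub):
        if len(comp) >= 3:
            chains.append(set(comp))
    return chains


def _sugar_unit(mol: MoleculeRecord, core: set[int], adj) -> set[int]:
    """Core atoms plus terminal O substituents and CH2OH-type appendages."""
    unit = set(core)
    for c in core:
        if mol.atoms[c].symbol != "C":
            continue
        for n, o in adj[c]:
            if n in unit or o != SINGLE:
                continue
            if mol.atoms[n].symbol == "O" and len(adj[n]) == 1:
                unit.add(n)  # terminal hydroxyl
            elif mol.atoms[n].symbol == "C":
                # CH2OH-style appendage: exocyclic carbon whose only other
                # heavy neighbours are terminal oxygens
                others = [(m, oo) for m, oo in adj[n] if m != c]
                if others and all(
                    mol.atoms[m].symbol == "O" and oo == SINGLE and len(adj[m]) == 1
                    for m, oo in others
                ):
                    unit.add(n)
                    unit.update(m for m, _ in others)
    return unit


def remove_sugars(
    mol: MoleculeRecord,
    min_fragment_atoms: int = DEFAULT_MIN_FRAGMENT_ATOMS,
) -> MoleculeRecord | None:
    """Iteratively delete glycosidically linked sugar units.

    Per round: perceive ring and linear sugars, extend each to its unit, and
    delete every unit whose external attachments all run through bridging
    oxygens and that touches at most one other sugar unit; bridging oxygens
    go with it.  Repeats until no unit is removable, then deletes components
    below the size cutoff.  ``None`` means nothing survived.
    """
    current: MoleculeRecord | None = mol
    while current is not None and current.num_atoms:
        adj = current.adjacency()
        cores = find_ring_sugars(current) + find_linear_sugars(current)
        if not cores:
            break
        units = [_sugar_unit(current, core, adj) for core in cores]

        # External profile of each unit: which bonds leave it, and whether
        # they all run through bridging oxygens (glycosidic/ether links).
        profiles = []
        for unit in units:
            bridges: set[int] = set()
            removable = True
            for a in unit:
                for n, o in adj[a]:
                    if n in unit:
                        continue
                    if o == SINGLE and current.atoms[n].symbol == "O":
                        bridges.add(n)
                    else:
                        removable = False
            profiles.append((unit, bridges, removable))

        # Peel terminal units against the fixed unit list (perceived while all
        # oxygens were still present), outermost first, so whole
        # oligosaccharide chains come off in one round.
        remaining = list(range(len(units)))
        removed: set[int] = set()
        to_delete: set[int] = set()
        changed = True
        while changed:
            changed = False
            for k in list(remaining):
                unit, bridges, removable = profiles[k]
                if not removable:
                    continue
                sugar_links = 0
                for n in bridges:
                    for m, _ in adj[n]:
                        if m in unit:
                            continue
                        if any(
                            m in profiles[j][0]
                            for j in remaining
                            if j != k and j not in removed
                        ):
                            sugar_links += 1
                            break
                if sugar_links <= 1:
                    removed.add(k)
                    remaining.remove(k)
                    to_delete |= unit
                    to_delete |= bridges
                    changed = True
        if not to_delete:
            break
        keep = [i for i in range(current.num_atoms) if i not in to_delete]
        current = current.subgraph(keep) if keep else None

    if current is None or current.num_atoms == 0:
        return None
    return filter_small_components(current, min_fragment_atoms)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def curate(
    mols: Iterable[MoleculeRecord], config: CurationConfig | None = None
) -> CurationOutcome:
    """Run the full curation pipeline over a batch.

    Kept entries are connected records; a parent split by sugar removal
    yields several kept records sharing the parent uuid.  Every input uuid
    lands in exactly one of kept / discarded.
    """
    config = config or CurationConfig()
    outcome = CurationOutcome()
    for mol in mols:
        trimmed = filter_small_components(mol, config.min_fragment_atoms)
        if trimmed is None:
            outcome.discarded.append((mol.uuid, REASON_TOO_SMALL))
            outcome.stats[REASON_TOO_SMALL] += 1
            continue
        if not filter_elements(trimmed, config.allowed_elements):
            outcome.discarded.append((mol.uuid, REASON_METAL))
            outcome.stats[REASON_METAL] += 1
            continue
        if config.remove_sugars:
            trimmed = remove_sugars(trimmed, config.min_fragment_atoms)
        else:
            trimmed = filter_small_components(trimmed, config.min_fragment_atoms)
        if trimmed is None or trimmed.num_atoms == 0:
            outcome.discarded.append((mol.uuid, REASON_EMPTY))
            outcome.stats[REASON_EMPTY] += 1
            continue
        # split surviving disconnected components into records sharing the uuid
        comps = trimmed.connected_components()
        if len(comps) == 1:
            outcome.kept.append(trimmed)
        else:
            for comp in comps:
                outcome.kept.append(trimmed.subgraph(comp))
        outcome.stats["kept"] += 1
    return outcome
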