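"""Atom signatures: canonicality, soundness against an isomorphism oracle,
count conservation, and decode round trips."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from nplikeness.errors import NPLikenessError, SignatureParseError
from nplikeness.records import Atom, Bond, MoleculeRecord, BOND_ORDERS
from nplikeness.signatures import (
    atom_signature,
    decode_signature,
    molecular_signature,
    reencode,
    sign_batch,
)

from conftest import record_from_smiles as rec


# --- independent oracle: rooted neighbourhood isomorphism -------------------

def neighborhood_graph(mol: MoleculeRecord, root: int, height: int) -> nx.Graph:
    """Induced subgraph on atoms within `height` bonds of root, labelled."""
    g = nx.Graph()
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    g.add_nodes_from(range(mol.num_atoms))
    dist = nx.single_source_shortest_path_length(g, root, cutoff=height)
    sub = g.subgraph(dist).copy()
    for i in sub.nodes:
        a = mol.atoms[i]
        sub.nodes[i]["label"] = (a.symbol, a.charge, a.aromatic)
        sub.nodes[i]["is_root"] = i == root
    return sub


def rooted_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["label", "is_root"], [None, None]
    )
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


SMALL_PANEL = [
    "CCO", "CCC", "C1CC1", "c1ccccc1", "c1ccncc1", "C1CCOC1", "CC(=O)O",
    "C1CC2CCC1C2", "[NH4+]", "ClCCl", "C1CCC1", "CC(C)(C)C", "OCC(O)CO",
]


class TestBasics:
    def test_height_zero_is_root_label(self):
        assert atom_signature(rec("C"), 0, 0).text == "[C]"
        assert atom_signature(rec("[NH4+]"), 0, 0).text == "[N+]"
        assert atom_signature(rec("[Cl-]"), 0, 0).text == "[Cl-]"

    def test_ethane_carbons_identical(self):
        ethane = rec("CC")
        for h in (0, 1, 2, 5):
            assert atom_signature(ethane, 0, h).text == atom_signature(ethane, 1, h).text

    def test_benzene_one_equivalence_class(self):
        benzene = rec("c1ccccc1")
        texts = {atom_signature(benzene, i, 2).text for i in range(6)}
        assert len(texts) == 1

    def test_ethanol_three_distinct_environments(self):
        ms = molecular_signature(rec("CCO"), 2)
        assert len(ms.signatures) == 3
        assert len(set(ms.signatures)) == 3

    def test_single_atom_molecule(self):
        ms = molecular_signature(rec("[Cl-]"), 2)
        assert ms.signatures == ("[Cl-]",)

    def test_invalid_root_raises(self):
        with pytest.raises(NPLikenessError):
            atom_signature(rec("CC"), 5, 2)

    def test_ring_bond_distinguished_from_chain(self):
        """Cyclopropane's ring closure must not collapse onto the linear chain."""
        cyclo = atom_signature(rec("C1CC1"), 0, 1).text
        chain = atom_signature(rec("CCC"), 1, 1).text
        assert cyclo != chain


class TestBatch:
    def test_count_conservation(self, mixed_50):
        records = sign_batch(mixed_50, 2)
        assert len(records) == sum(m.num_atoms for m in mixed_50)

    def test_shared_uuid_pools(self, rec):
        a, b = rec("CCO", uuid="U"), rec("CCCC", uuid="U")
        records = sign_batch([a, b], 2)
        assert len(records) == 7
        assert {r.uuid for r in records} == {"U"}

    def test_empty_batch(self):
        assert sign_batch([], 2) == []


class TestCanonicality:
    def test_permutation_invariance(self, mixed_50):
        rng = random.Random(202)
        for mol in mixed_50[:20]:
            reference = molecular_signature(mol, 2).signatures
            for _ in range(5):
                perm = list(range(mol.num_atoms))
                rng.shuffle(perm)
                assert molecular_signature(mol.permuted(perm), 2).signatures == reference

    def test_isomorphism_soundness_small_molecules(self):
        """Equal text at height h <=> rooted h-neighbourhoods isomorphic,
        checked exhaustively over a panel of molecules <= 12 heavy atoms."""
        mols = [rec(s) for s in SMALL_PANEL]
        for h in (0, 1, 2):
            entries = [
                (atom_signature(m, i, h).text, neighborhood_graph(m, i, h))
                for m in mols
                for i in range(m.num_atoms)
            ]
            for x in range(len(entries)):
                for y in range(x + 1, len(entries)):
                    tx, gx = entries[x]
                    ty, gy = entries[y]
                    if gx.number_of_nodes() != gy.number_of_nodes():
                        assert tx != ty
                        continue
                    assert (tx == ty) == rooted_isomorphic(gx, gy)

    def test_height_monotonicity(self):
        """Once two atoms' signatures differ, they differ at all greater heights."""
        mols = [rec(s) for s in SMALL_PANEL]
        atoms = [(m, i) for m in mols for i in range(m.num_atoms)]
        diverged: set[tuple[int, int]] = set()
        for h in range(0, 4):
            texts = [atom_signature(m, i, h).text for m, i in atoms]
            for x in range(len(atoms)):
                for y in range(x + 1, len(atoms)):
                    if (x, y) in diverged:
                        assert texts[x] != texts[y]
                    elif texts[x] != texts[y]:
                        diverged.add((x, y))


class TestDecode:
    def test_roundtrip_on_fixture_signatures(self, mixed_50):
        texts = {r.signature for r in sign_batch(mixed_50, 2)}
        for text in texts:
            assert reencode(decode_signature(text)) == text

    def test_height_zero_decode(self):
        decoded = decode_signature("[N+]")
        assert decoded.record.atoms[0].symbol == "N"
        assert decoded.record.atoms[0].charge == 1
        assert decoded.height == 0

    def test_decoded_root_environment(self):
        text = atom_signature(rec("CCO"), 2, 2).text  # the oxygen
        decoded = decode_signature(text)
        assert decoded.record.atoms[decoded.root].symbol == "O"
        assert decoded.record.num_atoms == 3

    def test_open_valences_filled_with_hydrogens(self):
        decoded = decode_signature("[C](-[C]-[O])")
        hs = {a.symbol: a.hcount for a in decoded.record.atoms}
        assert hs["O"] == 1  # terminal O gets one H

    @pytest.mark.parametrize(
        "bad", ["", "C", "[C](", "[C]()", "[Xx~]", "[C](-[C]))", "[C,]", "[C]extra"]
    )
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(SignatureParseError) as err:
            decode_signature(bad)
        assert err.value.position is not None


# --- property tests over random labelled graphs ----------------------------

@st.composite
def random_molecule(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    symbols = draw(st.lists(st.sampled_from(["C", "N", "O", "S"]), min_size=n, max_size=n))
    charges = draw(st.lists(st.sampled_from([0, 0, 0, 1, -1]), min_size=n, max_size=n))
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = draw(st.lists(st.sampled_from(possible), unique=True, max_size=len(possible))) if possible else []
    orders = draw(st.lists(st.sampled_from(BOND_ORDERS), min_size=len(chosen), max_size=len(chosen)))
    # aromatic flags: mark endpoints of aromatic bonds
    aromatic = [False] * n
    for (i, j), o in zip(chosen, orders):
        if o == ":":
            aromatic[i] = aromatic[j] = True
    atoms = [Atom(s, c, 0, a) for s, c, a in zip(symbols, charges, aromatic)]
    bonds = [Bond(i, j, o) for (i, j), o in zip(chosen, orders)]
    return MoleculeRecord(uuid="h", atoms=atoms, bonds=bonds)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(mol=random_molecule(), data=st.data())
def test_signature_invariants_on_random_graphs(mol, data):
    """Permutation invariance and decode round trip hold on arbitrary
    labelled graphs, not just chemically sensible ones."""
    mol.validate()
    height = data.draw(st.integers(min_value=0, max_value=3))
    root = data.draw(st.integers(min_value=0, max_value=mol.num_atoms - 1))
    text = atom_signature(mol, root, height).text
    assert reencode(decode_signature(text)) == text
    perm = data.draw(st.permutations(range(mol.num_atoms)))
    permuted = mol.permuted(list(perm))
    new_root = list(perm).index(root)
    assert atom_signature(permuted, new_root, height).text == text
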