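"""Molecule and flat-file I/O.

Molecules are read and written through RDKit in two dialects:

* **SDF (V2000 only).**  The molecule UUID is stored in an ``NPL_UUID`` data
  field and picked back up on read, so curated/discarded dumps stay traceable.
  V3000 connection tables are rejected with a clear error rather than silently
  half-supported.
* **SMILES files.**  One SMILES per line with an optional tab-separated name;
  blank lines and lines starting with ``#`` are ignored (fixture files carry
  their generator seed in such a comment header).

Unparsable records are skipped and counted, never fatal: batch screening has
to survive the odd broken entry.  A file yielding *zero* parsable molecules is
an error.

The module also owns the two tab-separated text dialects used between
pipeline stages: signature files (``uuid\\tsignature``) and score files
(``uuid\\tscore`` with six decimal places).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    EmptyInputError,
    InputError,
    OutputError,
    UnsupportedFormatError,
)
from .records import (
    AROMATIC,
    DOUBLE,
    SINGLE,
    TRIPLE,
    Atom,
    Bond,
    MoleculeRecord,
    ScoreFileRecord,
    SignatureFileRecord,
    new_uuid,
)

logger = logging.getLogger(__name__)

# RDKit is chatty about every rejected record; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

UUID_FIELD = "NPL_UUID"
FRAGMENT_SCORE_FIELD = "NPL_FRAGMENT_SCORE"

_RDKIT_TO_ORDER = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
    Chem.BondType.AROMATIC: AROMATIC,
}
_ORDER_TO_RDKIT = {v: k for k, v in _RDKIT_TO_ORDER.items()}


# ---------------------------------------------------------------------------
# RDKit <-> MoleculeRecord
# ---------------------------------------------------------------------------

def from_rdkit(
    mol: Chem.Mol,
    uuid: str | None = None,
    name: str | None = None,
    origin: str | None = None,
) -> MoleculeRecord:
    """Convert a (sanitized) RDKit molecule to a heavy-atom record.

    Explicit hydrogens are folded into per-atom implicit counts.
    """
    if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        mol = Chem.RemoveHs(mol)
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_TO_ORDER.get(b.GetBondType())
        if order is None:
            raise InputError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MoleculeRecord(
        uuid=uuid or new_uuid(), atoms=atoms, bonds=bonds, name=name, origin=origin
    )


def to_rdkit(record: MoleculeRecord, sanitize: bool = True) -> Chem.Mol:
    """Rebuild an RDKit molecule from a record.

    With ``sanitize=True`` implicit hydrogens and aromaticity bookkeeping are
    recomputed by RDKit from the graph (suitable for records that came from
    valid molecules).  With ``sanitize=False`` the stored aromatic flags and
    hydrogen counts are kept verbatim — used for decoded signature fragments,
    whose partial rings cannot be re-perceived.
    """
    rw = Chem.RWMol()
    aromatic = record.aromatic_flags()
    for idx, atom in enumerate(record.atoms):
        a = Chem.Atom(atom.symbol)
        a.SetFormalCharge(atom.charge)
        if aromatic[idx]:
            a.SetIsAromatic(True)
        # carry the stored hydrogen count: kekulization needs it on aromatic
        # N/O (pyrrole-type H) and decoded fragments keep it verbatim
        a.SetNumExplicitHs(atom.hcount)
        if not sanitize:
            a.SetNoImplicit(True)
        rw.AddAtom(a)
    for b in record.bonds:
        rw.AddBond(b.i, b.j, _ORDER_TO_RDKIT[b.order])
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    else:
        mol.UpdatePropertyCache(strict=False)
    if record.name:
        mol.SetProp("_Name", record.name)
    return mol


# ---------------------------------------------------------------------------
# Molecule files
# ---------------------------------------------------------------------------

def read_molecules(
    path: str | Path,
    format: str = "sdf",
    uuid_factory: Callable[[], str] | None = None,
) -> list[MoleculeRecord]:
    """Read molecules from an SDF (V2000) or SMILES file.

    Every record gets a fresh UUID unless (SDF only) it carries one in the
    ``NPL_UUID`` data field.  Unparsable records are skipped with a logged
    reason.  Raises :class:`InputError` if the file is missing and
    :class:`EmptyInputError` if nothing parses.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    if format not in ("sdf", "smiles"):
        raise InputError(f"unknown molecule format {format!r}")
    make_uuid = uuid_factory or new_uuid

    records: list[MoleculeRecord] = []
    skipped = 0
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i in range(len(supplier)):
            raw = supplier.GetItemText(i)
            if "V3000" in raw:
                raise UnsupportedFormatError(
                    f"{path} record {i + 1} is SDF V3000; only V2000 is supported"
                )
            mol = supplier[i]
            if mol is None:
                skipped += 1
                logger.warning("%s: record %d unparsable, skipped", path, i + 1)
                continue
            uid = mol.GetProp(UUID_FIELD) if mol.HasProp(UUID_FIELD) else make_uuid()
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            records.append(
                from_rdkit(mol, uuid=uid, name=name or None, origin=f"{path}#{i + 1}")
            )
    else:
        with open(path) as fh:
            lineno = 0
            for line in fh:
                lineno += 1
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    skipped += 1
                    logger.warning(
                        "%s: line %d is not valid SMILES, skipped", path, lineno
                    )
                    continue
                name = parts[1] if len(parts) > 1 else None
                records.append(
                    from_rdkit(
                        mol, uuid=make_uuid(), name=name, origin=f"{path}#{lineno}"
                    )
                )
    if not records:
        raise EmptyInputError(f"{path}: no parsable molecule records")
    if skipped:
        logger.info("%s: %d record(s) skipped", path, skipped)
    return records


def write_molecules(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    format: str = "sdf",
    extra_fields: dict[str, dict[str, str]] | None = None,
    sanitize: bool = True,
) -> int:
    """Write records to SDF (UUID in ``NPL_UUID``) or a SMILES file.

    ``extra_fields`` maps uuid -> {field: value} for additional SDF data
    fields (used for fragment scores).  Returns the number written.
    """
    path = Path(path)
    try:
        if format == "sdf":
            writer = Chem.SDWriter(str(path))
            if not sanitize:
                writer.SetKekulize(False)
            n = 0
            for rec in records:
                mol = to_rdkit(rec, sanitize=sanitize)
                mol.SetProp(UUID_FIELD, rec.uuid)
                for k, v in (extra_fields or {}).get(rec.uuid, {}).items():
                    mol.SetProp(k, v)
                writer.write(mol)
                n += 1
            writer.close()
        elif format == "smiles":
            n = 0
            with open(path, "w") as fh:
                for rec in records:
                    smi = Chem.MolToSmiles(to_rdkit(rec, sanitize=sanitize))
                    fh.write(smi + (f"\t{rec.name}" if rec.name else "") + "\n")
                    n += 1
        else:
            raise OutputError(f"unknown molecule format {format!r}")
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc
    return n


# ---------------------------------------------------------------------------
# Signature and score files
# ---------------------------------------------------------------------------

def read_signature_file(path: str | Path) -> list[SignatureFileRecord]:
    """Read ``uuid\\tsignature`` lines; malformed lines are skipped (all
    malformed -> error).  An empty file is a valid empty sequence."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    records: list[SignatureFileRecord] = []
    malformed = 0
    total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            total += 1
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                malformed += 1
                logger.warning("%s: line %d malformed, skipped", path, lineno)
                continue
            records.append(SignatureFileRecord(parts[0], parts[1]))
    if total and not records:
        raise InputError(f"{path}: every line malformed")
    return records


def write_signature_file(
    records: Iterable[SignatureFileRecord], path: str | Path
) -> int:
    path = Path(path)
    n = 0
    try:
        with open(path, "w") as fh:
            for rec in records:
                if "\t" in rec.uuid or "\t" in rec.signature:
                    raise OutputError("uuid/signature may not contain tabs")
                fh.write(f"{rec.uuid}\t{rec.signature}\n")
                n += 1
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc
    return n


def read_score_file(path: str | Path) -> list[ScoreFileRecord]:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    records: list[ScoreFileRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                records.append(ScoreFileRecord(parts[0], float(parts[1])))
            except (IndexError, ValueError):
                logger.warning("%s: line %d malformed, skipped", path, lineno)
    return records


def write_score_file(records: Iterable[ScoreFileRecord], path: str | Path) -> int:
    path = Path(path)
    n = 0
    try:
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.uuid}\t{rec.score:.6f}\n")
                n += 1
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc
    return n
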