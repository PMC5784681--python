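"""File formats and core domain types.

Reads the three pipeline inputs (FASTA sequence, CASP RR contact list,
plain 3-state secondary-structure string) and reads/writes coarse-grained
two-bead (Cα/Cβ) models as single-chain PDB files.  All residue indices
are 1-based externally, matching RR and PDB numbering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


class RangeError(FormatError):
    """Raised when a residue index falls outside [1, L]."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence with one-letter residue codes."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise FormatError("empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise FormatError(f"illegal residue characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Contact:
    """A predicted residue pair: 1-based indices i < j, distance bounds in Å
    and a confidence in [0, 1]."""

    i: int
    j: int
    lower: float
    upper: float
    prob: float

    def __post_init__(self):
        if not (1 <= self.i < self.j):
            raise ValueError(f"contact indices must satisfy 1 <= i < j, got ({self.i}, {self.j})")
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError(f"contact bounds must satisfy 0 <= lower <= upper, got ({self.lower}, {self.upper})")
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError(f"contact prob must be in [0, 1], got {self.prob}")

    @property
    def separation(self) -> int:
        return self.j - self.i

    @property
    def range_class(self) -> str:
        """CASP separation class: long (≥24), medium (12-23), short (6-11)."""
        s = self.separation
        if s >= 24:
            return "long"
        if s >= 12:
            return "medium"
        if s >= 6:
            return "short"
        return "local"


@dataclass(frozen=True)
class SecondaryStructure:
    """3-state secondary structure: one of H/E/C per residue."""

    states: str

    def __post_init__(self):
        bad = set(self.states) - set("HEC")
        if bad:
            raise FormatError(f"illegal secondary-structure characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def runs(self, state: str) -> list[tuple[int, int]]:
        """Maximal runs of `state` as 1-based inclusive (start, end) pairs."""
        out = []
        start = None
        for idx, s in enumerate(self.states, start=1):
            if s == state and start is None:
                start = idx
            elif s != state and start is not None:
                out.append((start, idx - 1))
                start = None
        if start is not None:
            out.append((start, len(self.states)))
        return out


@dataclass
class Model:
    """A coarse-grained model: Cα and Cβ coordinates (Å) per residue.

    Glycine carries no Cβ; its ``cb`` row equals its ``ca`` row so Cβ-Cβ
    contact distances remain evaluable for every pair.
    """

    sequence: SequenceRecord
    ca: np.ndarray
    cb: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float).reshape(len(self.sequence), 3)
        self.cb = np.asarray(self.cb, dtype=float).reshape(len(self.sequence), 3)

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "Model":
        return Model(self.sequence, self.ca.copy(), self.cb.copy(), self.label)


def read_fasta(path: str | os.PathLike) -> SequenceRecord:
    """Read the first record of a FASTA file.

    Residues are uppercased and whitespace is stripped; only the 20
    standard one-letter codes plus X are accepted.
    """
    lines = Path(path).read_text().splitlines()
    header = None
    seq_parts: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is None:
                header = line[1:].split()[0] if line[1:].split() else ""
            else:
                break  # single-target pipeline: first record only
            continue
        if header is None:
            raise FormatError(f"{path}: line {lineno}: sequence data before '>' header")
        chunk = line.upper()
        bad = set(chunk) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"{path}: line {lineno}: illegal residue character(s) {sorted(bad)}"
            )
        seq_parts.append(chunk)
    if header is None:
        raise FormatError(f"{path}: no FASTA header found")
    residues = "".join(seq_parts)
    if not residues:
        raise FormatError(f"{path}: record '{header}' has an empty sequence")
    return SequenceRecord(id=header, residues=residues)


def read_rr(path: str | os.PathLike, L: int) -> list[Contact]:
    """Read a CASP RR contact file.

    Accepts comment lines (``#``), optional header keywords and an optional
    leading sequence line.  Records are 5 whitespace-separated fields
    ``i j d1 d2 p``.  Pairs are normalized to i < j, duplicates collapsed
    keeping the maximum probability, and the result is sorted by
    probability descending with ties broken by (i, j) ascending.
    """
    best: dict[tuple[int, int], Contact] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(">"):
            continue
        fields = line.split()
        first = fields[0]
        # leading sequence line or header keywords (PFRMAT, TARGET, MODEL, END...)
        if not _is_int(first):
            if all(c.isalpha() or c in "-*" for c in first):
                continue
            raise FormatError(f"{path}: line {lineno}: unrecognized record '{line}'")
        if len(fields) != 5:
            raise FormatError(
                f"{path}: line {lineno}: expected 5 fields 'i j d1 d2 p', got {len(fields)}"
            )
        try:
            i, j = int(fields[0]), int(fields[1])
            lower, upper, prob = float(fields[2]), float(fields[3]), float(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if i == j:
            raise FormatError(f"{path}: line {lineno}: self-contact ({i}, {j}) rejected")
        if not (1 <= i <= L) or not (1 <= j <= L):
            raise RangeError(
                f"{path}: line {lineno}: residue index out of range [1, {L}]: ({i}, {j})"
            )
        if i > j:
            i, j = j, i
        try:
            contact = Contact(i=i, j=j, lower=lower, upper=upper, prob=prob)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        key = (i, j)
        if key not in best or contact.prob > best[key].prob:
            best[key] = contact
    return sorted(best.values(), key=lambda c: (-c.prob, c.i, c.j))


def write_rr(contacts: list[Contact], path: str | os.PathLike) -> None:
    """Write contacts as 5-field CASP RR records."""
    with open(path, "w") as fh:
        for c in contacts:
            fh.write(f"{c.i} {c.j} {c.lower:g} {c.upper:g} {c.prob:.6f}\n")


def read_ss(path: str | os.PathLike, L: int) -> SecondaryStructure:
    """Read a 3-state (H/E/C) secondary-structure string of length L.

    A FASTA-style header line is tolerated; the state string may be wrapped
    over several lines.
    """
    parts = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        chunk = line.upper()
        bad = set(chunk) - set("HEC")
        if bad:
            raise FormatError(
                f"{path}: line {lineno}: illegal secondary-structure character(s) {sorted(bad)}"
            )
        parts.append(chunk)
    states = "".join(parts)
    if len(states) != L:
        raise FormatError(
            f"{path}: secondary-structure length {len(states)} does not match sequence length {L}"
        )
    return SecondaryStructure(states=states)


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def _model_to_atoms(model: Model) -> struc.AtomArray:
    L = len(model)
    is_gly = np.array([aa == "G" for aa in model.sequence.residues])
    n_atoms = int(2 * L - is_gly.sum())
    atoms = struc.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    names, res_ids, res_names = [], [], []
    pos = 0
    for idx in range(L):
        aa = model.sequence.residues[idx]
        res3 = _ONE_TO_THREE.get(aa, "UNK")
        coords[pos] = model.ca[idx]
        names.append("CA")
        res_ids.append(idx + 1)
        res_names.append(res3)
        pos += 1
        if aa != "G":
            coords[pos] = model.cb[idx]
            names.append("CB")
            res_ids.append(idx + 1)
            res_names.append(res3)
            pos += 1
    atoms.coord = coords
    atoms.atom_name = np.array(names)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(res_names)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.element = np.full(n_atoms, "C")
    atoms.hetero = np.zeros(n_atoms, bool)
    return atoms


def write_pdb(model: Model, path: str | os.PathLike) -> None:
    """Write a model as standard PDB ATOM records (CA + CB per residue,
    CA only for glycine), chain A, coordinates in 8.3 format."""
    pdb = PDBFile()
    pdb.set_structure(_model_to_atoms(model))
    pdb.write(str(path))


def read_pdb(path: str | os.PathLike) -> Model:
    """Read a coarse-grained model back from PDB.

    Requires a CA atom for every residue; a residue without CB gets its
    Cβ row copied from Cα.
    """
    atoms = PDBFile.read(str(path)).get_structure(model=1)
    atoms = atoms[np.isin(atoms.atom_name, ["CA", "CB"])]
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no CA/CB atoms found")
    res_ids = np.unique(atoms.res_id)
    L = len(res_ids)
    ca = np.full((L, 3), np.nan)
    cb = np.full((L, 3), np.nan)
    letters = []
    for k, rid in enumerate(res_ids):
        sel = atoms[atoms.res_id == rid]
        letters.append(_THREE_TO_ONE.get(sel.res_name[0], "X"))
        for atom_idx in range(sel.array_length()):
            if sel.atom_name[atom_idx] == "CA":
                ca[k] = sel.coord[atom_idx]
            elif sel.atom_name[atom_idx] == "CB":
                cb[k] = sel.coord[atom_idx]
    missing = np.isnan(ca).any(axis=1)
    if missing.any():
        raise FormatError(
            f"{path}: missing CA for residue(s) {res_ids[missing].tolist()}"
        )
    no_cb = np.isnan(cb).any(axis=1)
    cb[no_cb] = ca[no_cb]
    seq = SequenceRecord(id=Path(path).stem, residues="".join(letters))
    return Model(sequence=seq, ca=ca, cb=cb, label=Path(path).stem)
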