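"""Structure and sequence I/O.

A thin, uniform data model over PDB-format coordinate files and FASTA
sequence files.  Author (PDB) residue numbering is the only numbering the
rest of the pipeline ever sees: the literature on the Notch-1 ankyrin
domain cites residues by author number (ASP-1987, GLU-2008, GLN-347 of
RBPJ, ...), so internal indices must never leak.

PDB parsing is delegated to :mod:`gemmi`; the classes here are deliberately
small dataclasses so fixtures can be built by hand in tests and by the
synthetic-structure generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueSequence",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
]

#: Standard 3-letter -> 1-letter mapping.  Non-standard residues (MSE, ...)
#: fall through to "X" by design: the analyses only need the 20-letter
#: alphabet and must not crash on modified residues.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_AND_IONS = {
    "HOH", "DOD", "WAT", "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE",
    "SO4", "PO4", "GOL", "EDO", "ACT",
}


@dataclass
class Atom:
    """A single atom: label, element and Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    """A residue with its author-assigned number.

    ``number`` is the integer author number; ``icode`` carries an optional
    insertion code, appended to the identity but ignored for ordering.
    """

    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def label(self) -> str:
        """Identity label, e.g. ``'1987'`` or ``'52A'`` with insertion code."""
        return f"{self.number}{self.icode}"

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __post_init__(self) -> None:
        if not self.atoms:
            # allow construction then append; validated by StructureModel
            pass


@dataclass
class StructureModel:
    """A parsed multi-chain structure with author residue numbering."""

    source_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None

    def __iter__(self) -> Iterable[Residue]:
        for residues in self.chains.values():
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not in {self.source_id!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.number == number and res.icode == icode:
                return res
        raise KeyError(f"residue {number}{icode} not in chain {chain_id!r}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: positions -> R·x + t.  Used by invariance tests."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = StructureModel(self.source_id, {}, self.resolution)
        for cid, residues in self.chains.items():
            out.chains[cid] = [
                Residue(
                    cid, res.number, res.name,
                    [Atom(a.name, a.element, rotation @ a.position + translation)
                     for a in res.atoms],
                    res.icode,
                )
                for res in residues
            ]
        return out


@dataclass
class ResidueSequence:
    """A 1-letter sequence with a parallel list of author numbers."""

    id: str
    letters: str
    numbering: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.numbering:
            self.numbering = list(range(1, len(self.letters) + 1))
        if len(self.numbering) != len(self.letters):
            raise ValueError(
                f"{self.id!r}: {len(self.letters)} letters but "
                f"{len(self.numbering)} numbers"
            )
        bad = set(self.letters.upper()) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"{self.id!r}: letters outside the amino-acid alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    def subsequence(self, start: int, end: int) -> "ResidueSequence":
        """Slice by author numbers, inclusive on both ends."""
        idx = [i for i, n in enumerate(self.numbering) if start <= n <= end]
        if not idx:
            raise ValueError(f"span {start}..{end} not in {self.id!r}")
        return ResidueSequence(
            f"{self.id}/{start}-{end}",
            "".join(self.letters[i] for i in idx),
            [self.numbering[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# PDB I/O


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc label order ('A' first)
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def read_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Read a PDB-format file into a :class:`StructureModel`.

    Keeps amino-acid HETATM records (MSE etc.), drops waters and ions,
    resolves alternate locations to a single conformer (highest occupancy,
    then altloc label order) and preserves author numbering exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    if not (0 <= model_index < len(st)):
        raise IndexError(f"{path}: model {model_index} out of range (have {len(st)})")
    st.setup_entities()
    gmodel = st[model_index]

    model = StructureModel(
        source_id=path.stem,
        resolution=st.resolution if st.resolution else None,
    )
    n_atoms = 0
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name.strip().upper() in _WATER_AND_IONS:
                continue
            if gres.is_water():
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                el = ga.element.name if ga.element else name[0]
                atoms.append(Atom(name, el, np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
            if not atoms:
                continue
            residues.append(
                Residue(
                    gchain.name,
                    gres.seqid.num,
                    gres.name.strip().upper(),
                    atoms,
                    (gres.seqid.icode or " ").strip(),
                )
            )
            n_atoms += len(atoms)
        if residues:
            residues.sort(key=lambda r: r.number)
            model.chains[gchain.name] = residues
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM records after filtering")
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only) for fixtures and reports."""
    lines = []
    serial = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {cid:1s}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(model: StructureModel, chain_id: str) -> ResidueSequence:
    """1-letter sequence of a chain in author-number order; unknowns -> X."""
    residues = model.chain(chain_id)
    return ResidueSequence(
        f"{model.source_id}:{chain_id}",
        "".join(res.one_letter for res in residues),
        [res.number for res in residues],
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ResidueSequence]:
    """Read FASTA records; sequences uppercased, numbering defaults to 1..n."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [ResidueSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(seqs: Iterable[ResidueSequence], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.letters), id=s.id, description="") for s in seqs],
        str(path),
        "fasta",
    )
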