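"""Geometric hydrogen-bond detection and interface inventories.

Hydrogen bonds are called from heavy-atom geometry: a donor nitrogen,
oxygen (or sulfur) within ``d_max`` of an acceptor, with the angle at the
donor between its covalent antecedent and the acceptor at least
``angle_min`` (so the implied hydrogen can point at the acceptor).  When an
explicit hydrogen is present on the donor the D-H...A angle is used
instead.  Defaults: d_max 3.5 A, angle_min 120 deg — the standard
geometric criteria; both are exposed because published interface counts
depend on them.

The interface inventory groups chains into molecules (e.g. ANK / MAML1 /
RBPJ of the ternary Notch transcription complex) and counts bonds whose
donor and acceptor fall in different groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .structures import Residue, StructureModel

__all__ = ["HBond", "InterfaceInventory", "detect_hbonds", "interface_inventory"]

# donor atom -> covalent antecedent, per residue ("*" = any residue, backbone)
_DONORS: dict[tuple[str, str], str] = {
    ("*", "N"): "CA",
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CE1",
    ("TRP", "NE1"): "CD1",
    ("CYS", "SG"): "CB",
}

_ACCEPTORS: set[tuple[str, str]] = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("MET", "SD"),
}


@dataclass(frozen=True)
class AtomRef:
    chain: str
    number: int
    res_name: str
    atom: str

    @property
    def residue_label(self) -> str:
        return f"{self.chain}:{self.res_name}{self.number}"


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    angle: float | None


@dataclass
class InterfaceInventory:
    pairs: dict[tuple[str, str], list[HBond]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.pairs.items()}

    def count(self, a: str, b: str) -> int:
        return len(self.pairs.get(tuple(sorted((a, b))), []))

    def bonds(self, a: str, b: str) -> list[HBond]:
        return self.pairs.get(tuple(sorted((a, b))), [])

    def residue_subcount(self, a: str, b: str,
                         residue_labels: set[str]) -> int:
        """Bonds between groups a and b touching any of the given residues."""
        return sum(
            1 for hb in self.bonds(a, b)
            if hb.donor.residue_label in residue_labels
            or hb.acceptor.residue_label in residue_labels
        )


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return 180.0
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _donor_hydrogens(res: Residue, donor_name: str,
                     donor_pos: np.ndarray) -> list[np.ndarray]:
    out = []
    for a in res.atoms:
        if a.element.upper() == "H" and np.linalg.norm(a.position - donor_pos) < 1.3:
            out.append(a.position)
    return out


def detect_hbonds(
    model: StructureModel,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """All donor-acceptor pairs passing the geometric criteria.

    Pairs within a single residue are excluded; bifurcated bonds count once
    per donor-acceptor atom pair.
    """
    donors, acceptors = [], []
    for res in model:
        if not res.atoms:
            continue
        for a in res.atoms:
            key = (res.name, a.name)
            wild = ("*", a.name)
            if key in _DONORS or (wild in _DONORS and not (res.name == "PRO" and a.name == "N")):
                ante_name = _DONORS.get(key, _DONORS.get(wild))
                ante = res.atom(ante_name)
                donors.append((res, a, ante))
            if key in _ACCEPTORS or wild in _ACCEPTORS:
                acceptors.append((res, a))
    if not donors or not acceptors:
        return []

    acc_pos = np.array([a.position for _, a in acceptors])
    tree = cKDTree(acc_pos)
    bonds: list[HBond] = []
    for res_d, atom_d, ante in donors:
        for j in tree.query_ball_point(atom_d.position, d_max):
            res_a, atom_a = acceptors[j]
            if res_a is res_d:
                continue
            if atom_a.name == atom_d.name and res_a.chain_id == res_d.chain_id \
                    and res_a.number == res_d.number:
                continue
            d = float(np.linalg.norm(atom_a.position - atom_d.position))
            if d < 1e-6 or d > d_max:
                continue
            hyds = _donor_hydrogens(res_d, atom_d.name, atom_d.position)
            if hyds:
                ang = max(_angle_deg(atom_d.position, h, atom_a.position)
                          for h in hyds)
            elif ante is not None:
                ang = _angle_deg(ante.position, atom_d.position, atom_a.position)
            else:
                ang = None
            if ang is not None and ang < angle_min:
                continue
            bonds.append(HBond(
                AtomRef(res_d.chain_id, res_d.number, res_d.name, atom_d.name),
                AtomRef(res_a.chain_id, res_a.number, res_a.name, atom_a.name),
                d, ang,
            ))
    return bonds


def interface_inventory(
    model: StructureModel,
    groups: dict[str, list[str]],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> InterfaceInventory:
    """Per-molecule-pair hydrogen-bond inventory.

    ``groups`` maps molecule names to chain-id lists (the chain-to-molecule
    assignment of a complex is supplied, never guessed).  Only bonds whose
    donor and acceptor belong to different groups are counted.
    """
    chain_to_group: dict[str, str] = {}
    for gname, chains in groups.items():
        for cid in chains:
            if cid not in model.chains:
                raise ValueError(
                    f"group {gname!r} references unknown chain {cid!r} "
                    f"(model has {sorted(model.chains)})"
                )
            chain_to_group[cid] = gname

    inventory = InterfaceInventory()
    for ga, gb in combinations(sorted(groups), 2):
        inventory.pairs[(ga, gb)] = []
    for hb in detect_hbonds(model, d_max, angle_min):
        ga = chain_to_group.get(hb.donor.chain)
        gb = chain_to_group.get(hb.acceptor.chain)
        if ga is None or gb is None or ga == gb:
            continue
        inventory.pairs[tuple(sorted((ga, gb)))].append(hb)
    return inventory
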