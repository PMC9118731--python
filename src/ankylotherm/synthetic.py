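"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here without downloads:
idealized ankyrin-repeat structures (two antiparallel helices + hairpin per
33-residue module), multi-chain complexes whose hydrogen bonds are planted
at exact geometries, charge-cluster models whose patch memberships are
known, qPCR amplification curves of known efficiency, and diverged
orthologue-like sequence pairs.  The planted truths double as oracles for
the analysis modules: in the noiseless case recovery must be exact.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import AmplificationCurve
from .electropatch import debye_length
from .repeats import CANONICAL_REPEATS, REPEAT_LENGTH
from .structures import Atom, Residue, ResidueSequence, StructureModel

__all__ = [
    "RepeatGeometrySpec",
    "PlantedBond",
    "PlantedComplexSpec",
    "QpcrSimSpec",
    "make_repeat_structure",
    "make_planted_complex",
    "make_charge_fixture",
    "make_qpcr_curves",
    "make_orthologue_pair",
    "notch_ternary_complex",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# Idealized repeat structures


@dataclass
class RepeatGeometrySpec:
    n_repeats: int
    sequence: str | None = None          # 33 * n_repeats letters
    helix_rise: float = 1.5              # A per residue along the helix axis
    helix_turn_deg: float = 100.0
    helix_radius: float = 2.3
    repeat_spacing: float = 10.0         # A between repeat slabs (long axis)
    chain_id: str = "A"
    start_number: int = 1
    acidic_positions: list[tuple[int, int]] = field(default_factory=list)
    # (repeat 1-based, position-in-repeat 1-based) -> residue becomes ASP

    def __post_init__(self) -> None:
        if self.n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")
        if self.sequence is None:
            self.sequence = CANONICAL_REPEATS[0] * self.n_repeats
        self.sequence = self.sequence.upper()
        if len(self.sequence) != REPEAT_LENGTH * self.n_repeats:
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"{REPEAT_LENGTH} * {self.n_repeats}"
            )
        seq = list(self.sequence)
        for rep, pos in self.acidic_positions:
            if not (1 <= rep <= self.n_repeats and 1 <= pos <= REPEAT_LENGTH):
                raise ValueError(f"acidic placement ({rep},{pos}) out of range")
            seq[(rep - 1) * REPEAT_LENGTH + pos - 1] = "D"
        self.sequence = "".join(seq)


def _ca_positions(spec: RepeatGeometrySpec, repeat: int) -> np.ndarray:
    """Cα coordinates of one repeat: α1 (5-12), α2 (15-24), βhp (25-31)."""
    z = repeat * spec.repeat_spacing
    turn = np.radians(spec.helix_turn_deg)
    rise, rad = spec.helix_rise, spec.helix_radius
    pos = np.zeros((REPEAT_LENGTH, 3))

    def helix(i_local: int, x0: float, y0: float, direction: float) -> np.ndarray:
        th = turn * i_local
        return np.array([
            x0 + direction * rise * i_local,
            y0 + rad * np.cos(th),
            z + rad * np.sin(th),
        ])

    # α1: positions 5..12 along +x at y = 0
    for k, p in enumerate(range(5, 13)):
        pos[p - 1] = helix(k, 0.0, 0.0, +1.0)
    # α2: positions 15..24 along -x at y = 8, starting past α1's end
    for k, p in enumerate(range(15, 25)):
        pos[p - 1] = helix(k, 12.0, 8.0, -1.0)
    # βhp: positions 25..31 extended along +y at x = -6 (slight zigzag)
    for k, p in enumerate(range(25, 32)):
        pos[p - 1] = np.array([-6.0 + 0.5 * (k % 2), 14.0 + 3.3 * k, z])
    # leading loop 1..4 approaches α1 start from -x
    for k, p in enumerate(range(1, 5)):
        pos[p - 1] = np.array([-14.0 + 3.5 * k, -4.0, z])
    # trailing loop 32..33 beyond the hairpin
    for k, p in enumerate(range(32, 34)):
        pos[p - 1] = np.array([-10.0 - 3.5 * k, 14.0 + 3.3 * 6, z])
    return pos


def make_repeat_structure(spec: RepeatGeometrySpec) -> StructureModel:
    """Idealized ankyrin-domain model: Cα backbone plus the side-chain
    atoms the analyses touch (carboxyl O pairs for D/E, NZ for K, CZ for R).
    """
    model = StructureModel(source_id=f"synthetic_ank_{spec.n_repeats}x33")
    residues: list[Residue] = []
    for r in range(spec.n_repeats):
        cas = _ca_positions(spec, r)
        for p in range(REPEAT_LENGTH):
            idx = r * REPEAT_LENGTH + p
            letter = spec.sequence[idx]
            name = _ONE_TO_THREE.get(letter, "GLY")
            ca = cas[p]
            atoms = [Atom("CA", "C", ca)]
            if letter == "D":
                atoms += [Atom("OD1", "O", ca + np.array([0.9, 0.9, 1.1])),
                          Atom("OD2", "O", ca + np.array([0.9, 0.9, -1.1]))]
            elif letter == "E":
                atoms += [Atom("OE1", "O", ca + np.array([0.9, 0.9, 1.1])),
                          Atom("OE2", "O", ca + np.array([0.9, 0.9, -1.1]))]
            elif letter == "K":
                atoms.append(Atom("NZ", "N", ca + np.array([1.2, 0.9, 0.0])))
            elif letter == "R":
                atoms.append(Atom("CZ", "C", ca + np.array([1.2, 0.9, 0.0])))
            residues.append(Residue(spec.chain_id, spec.start_number + idx,
                                    name, atoms))
    if residues:
        model.chains[spec.chain_id] = residues
    return model


# ---------------------------------------------------------------------------
# Planted hydrogen-bond complexes


@dataclass(frozen=True)
class PlantedBond:
    donor_chain: str
    donor_number: int
    donor_resname: str
    donor_atom: str
    acceptor_chain: str
    acceptor_number: int
    acceptor_resname: str
    acceptor_atom: str
    distance: float = 2.9
    angle: float = 160.0


@dataclass
class PlantedComplexSpec:
    bonds: list[PlantedBond]
    source_id: str = "synthetic_planted_complex"

    def __post_init__(self) -> None:
        for b in self.bonds:
            if b.distance > 3.5:
                raise ValueError(
                    f"planted distance {b.distance} exceeds the default "
                    "detection maximum 3.5 A"
                )
            if not 90 < b.angle <= 180:
                raise ValueError(f"planted angle {b.angle} not in (90, 180]")


_ANTECEDENT = {
    "N": "CA", "OG": "CB", "OG1": "CB", "OH": "CZ", "ND2": "CG",
    "NE2": "CD", "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "ND1": "CG", "NE1": "CD1", "SG": "CB",
}


def _rot_xy(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


class _ComplexBuilder:
    def __init__(self) -> None:
        self.residues: dict[tuple[str, int], Residue] = {}

    def residue(self, chain: str, number: int, name: str) -> Residue:
        key = (chain, number)
        if key not in self.residues:
            self.residues[key] = Residue(chain, number, name, [])
        res = self.residues[key]
        if res.name != name:
            raise ValueError(f"residue {key} requested as both {res.name} and {name}")
        return res

    def add_atom(self, res: Residue, name: str, element: str,
                 pos: np.ndarray) -> None:
        existing = res.atom(name)
        if existing is not None:
            if not np.allclose(existing.position, pos, atol=1e-6):
                raise ValueError(
                    f"{res.chain_id}:{res.name}{res.number} atom {name} "
                    "placed twice at different positions: unsatisfiable geometry"
                )
            return
        res.atoms.append(Atom(name, element, pos))

    def model(self, source_id: str) -> StructureModel:
        m = StructureModel(source_id)
        for (chain, _), res in sorted(self.residues.items()):
            m.chains.setdefault(chain, []).append(res)
        for chain in m.chains.values():
            chain.sort(key=lambda r: r.number)
        return m


def make_planted_complex(spec: PlantedComplexSpec) -> StructureModel:
    """Build a multi-chain model realizing exactly the planted bonds.

    Bonds sharing a residue are laid out in a common spatial cell around
    that hub residue; cells are 40 A apart so no unplanted polar contact
    can satisfy the detection criteria.  A hub acting simultaneously as
    donor and acceptor is rejected as unsatisfiable.
    """
    bonds = spec.bonds
    if not bonds:
        return StructureModel(spec.source_id, {})

    # union-find clustering on shared residues
    parent = list(range(len(bonds)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    res_seen: dict[tuple[str, int], int] = {}
    for i, b in enumerate(bonds):
        for key in ((b.donor_chain, b.donor_number),
                    (b.acceptor_chain, b.acceptor_number)):
            if key in res_seen:
                parent[find(i)] = find(res_seen[key])
            res_seen[key] = i

    clusters: dict[int, list[PlantedBond]] = {}
    for i, b in enumerate(bonds):
        clusters.setdefault(find(i), []).append(b)

    builder = _ComplexBuilder()
    for m, cluster in enumerate(clusters.values()):
        origin = np.array([40.0 * m, 0.0, 0.0])
        counts: dict[tuple[str, int], int] = {}
        for b in cluster:
            for key in ((b.donor_chain, b.donor_number),
                        (b.acceptor_chain, b.acceptor_number)):
                counts[key] = counts.get(key, 0) + 1
        hub = max(counts, key=counts.get)
        shared = counts[hub] > 1
        hub_is_donor = shared and all(
            (b.donor_chain, b.donor_number) == hub for b in cluster
        )
        hub_is_acceptor = shared and all(
            (b.acceptor_chain, b.acceptor_number) == hub for b in cluster
        )
        if shared and not (hub_is_donor or hub_is_acceptor):
            raise ValueError(
                "hub residue participates as both donor and acceptor "
                "across the cluster: unsatisfiable planted geometry"
            )

        if len(cluster) > 1 and hub_is_donor:
            # one donor atom fanning out to several acceptors
            b0 = cluster[0]
            donor_res = builder.residue(b0.donor_chain, b0.donor_number,
                                        b0.donor_resname)
            donor_pos = origin
            builder.add_atom(donor_res, b0.donor_atom, b0.donor_atom[0], donor_pos)
            ante = _ANTECEDENT.get(b0.donor_atom, "CA")
            builder.add_atom(donor_res, ante, "C",
                             donor_pos + np.array([0.0, -1.45, 0.0]))
            spread = np.linspace(-15, 15, len(cluster))
            for b, az in zip(cluster, spread):
                if b.donor_atom != b0.donor_atom or \
                        (b.donor_chain, b.donor_number) != hub:
                    raise ValueError("donor-hub cluster must share one donor atom")
                direction = _rot_xy(np.array([0.0, 1.0, 0.0]), az)
                acc_res = builder.residue(b.acceptor_chain, b.acceptor_number,
                                          b.acceptor_resname)
                builder.add_atom(acc_res, b.acceptor_atom, b.acceptor_atom[0],
                                 donor_pos + b.distance * direction)
        else:
            # acceptor hub (or singleton): donors arranged around their
            # acceptor atoms, which stack 2.4 A apart along z
            acc_atoms: dict[tuple[str, int, str], np.ndarray] = {}
            azimuths = np.linspace(0, 360, len(cluster), endpoint=False)
            for b, az in zip(cluster, azimuths):
                acc_res = builder.residue(b.acceptor_chain, b.acceptor_number,
                                          b.acceptor_resname)
                akey = (b.acceptor_chain, b.acceptor_number, b.acceptor_atom)
                if akey not in acc_atoms:
                    acc_atoms[akey] = origin + np.array([0, 0, 2.4 * len(acc_atoms)])
                    builder.add_atom(acc_res, b.acceptor_atom,
                                     b.acceptor_atom[0], acc_atoms[akey])
                apos = acc_atoms[akey]
                direction = _rot_xy(np.array([1.0, 0.0, 0.0]), az)
                dpos = apos + b.distance * direction
                donor_res = builder.residue(b.donor_chain, b.donor_number,
                                            b.donor_resname)
                builder.add_atom(donor_res, b.donor_atom, b.donor_atom[0], dpos)
                # antecedent set so the acceptor-donor-antecedent angle
                # equals the planted angle
                v = (apos - dpos) / np.linalg.norm(apos - dpos)
                u = _rot_xy(v, b.angle)
                ante = _ANTECEDENT.get(b.donor_atom, "CA")
                builder.add_atom(donor_res, ante, "C", dpos + 1.45 * u)
    return builder.model(spec.source_id)


def notch_ternary_complex() -> StructureModel:
    """SYNTHETIC stand-in for the ternary Notch transcription complex.

    A planted-geometry model (not the crystal structure) reproducing the
    reported interface topology: 8 hydrogen bonds between the ankyrin
    domain (chain A, Notch-1 author numbering) and MAML-1 (chain B), of
    which 5 involve GLU-2008 or ASP-1972, and 2 bonds from GLN-347 of RBPJ
    (chain C) to ASP-1994.  It exercises the same inventory contract the
    crystal complex would.
    """
    A, B, C = "A", "B", "C"
    bonds = [
        # five bonds involving GLU-2008 (ANK4) / ASP-1972 (ANK3) with MAML-1
        PlantedBond(B, 13, "ALA", "N", A, 2008, "GLU", "OE1"),
        PlantedBond(B, 14, "ALA", "N", A, 2008, "GLU", "OE2"),
        PlantedBond(B, 15, "ALA", "N", A, 2008, "GLU", "OE1"),
        PlantedBond(B, 16, "ALA", "N", A, 1972, "ASP", "OD1"),
        PlantedBond(B, 17, "ALA", "N", A, 1972, "ASP", "OD2"),
        # three further ANK-MAML-1 backbone/side-chain bonds
        PlantedBond(B, 18, "ALA", "N", A, 1975, "SER", "OG"),
        PlantedBond(B, 19, "ALA", "N", A, 2011, "ASN", "OD1"),
        PlantedBond(B, 20, "ALA", "N", A, 2014, "ALA", "O"),
        # GLN-347 of RBPJ donates twice to the ASP-1994 carboxyl
        PlantedBond(C, 347, "GLN", "NE2", A, 1994, "ASP", "OD1"),
        PlantedBond(C, 347, "GLN", "NE2", A, 1994, "ASP", "OD2"),
    ]
    return make_planted_complex(
        PlantedComplexSpec(bonds, source_id="synthetic_notch_ternary")
    )


# ---------------------------------------------------------------------------
# Charge-cluster fixtures


def make_charge_fixture(
    clusters: list[tuple[np.ndarray, int, int]],
    ionic_strength: float = 0.15,
) -> tuple[StructureModel, list[set[str]]]:
    """Charged residue clusters with known patch membership.

    ``clusters`` is a list of (center xyz, n_charges, sign).  Each cluster
    is a tight vertical stack of ASP (sign < 0) or LYS (sign > 0) residues
    whose union surface forms one connected super-threshold zone.  Cluster
    centers must be separated by more than 3 Debye lengths so zones cannot
    merge.  Returns the model and the expected member-residue label set
    per cluster.
    """
    lam = debye_length(ionic_strength)
    centers = [np.asarray(c, float) for c, _, _ in clusters]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.linalg.norm(centers[i] - centers[j])
            if d <= 3 * lam:
                raise ValueError(
                    f"clusters {i} and {j} are {d:.1f} A apart; need "
                    f"> {3 * lam:.1f} A (3 Debye lengths)"
                )
    model = StructureModel("synthetic_charge_fixture")
    chain = "Z"
    residues: list[Residue] = []
    expected: list[set[str]] = []
    for ci, (center, n_charges, sign) in enumerate(clusters):
        if n_charges < 1:
            raise ValueError("each cluster needs at least one charge")
        members: set[str] = set()
        for k in range(n_charges):
            num = 100 * (ci + 1) + k
            ca = centers[ci] + np.array([0.0, 0.0, 2.8 * (k - (n_charges - 1) / 2)])
            if sign < 0:
                atoms = [
                    Atom("CA", "C", ca),
                    Atom("OD1", "O", ca + np.array([0.9, 0.0, 1.0])),
                    Atom("OD2", "O", ca + np.array([0.9, 0.0, -1.0])),
                ]
                res = Residue(chain, num, "ASP", atoms)
            else:
                atoms = [Atom("CA", "C", ca),
                         Atom("NZ", "N", ca + np.array([0.9, 0.0, 0.0]))]
                res = Residue(chain, num, "LYS", atoms)
            residues.append(res)
            members.add(f"{chain}:{res.name}{res.label}")
        expected.append(members)
    model.chains[chain] = residues
    return model, expected


# ---------------------------------------------------------------------------
# qPCR curves


@dataclass
class QpcrSimSpec:
    true_efficiency: float
    cycles: int = 30
    noise_sd: float = 0.0
    seed: int = 0
    amplitude: float = 1e-6
    baseline: float = 0.0
    plateau_cycle: int | None = None

    def __post_init__(self) -> None:
        if not 1 < self.true_efficiency <= 2:
            raise ValueError("efficiency must lie in (1, 2] fold/cycle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_qpcr_curves(spec: QpcrSimSpec) -> AmplificationCurve:
    """Exponential amplification with optional plateau and relative noise."""
    cycles = np.arange(1, spec.cycles + 1)
    f = spec.amplitude * spec.true_efficiency ** cycles.astype(float)
    if spec.plateau_cycle is not None:
        cap = spec.amplitude * spec.true_efficiency ** float(spec.plateau_cycle)
        f = np.minimum(f, cap)
    if spec.noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(spec.seed))
        f = f * (1.0 + spec.noise_sd * rng.standard_normal(len(f)))
        f = np.maximum(f, spec.amplitude * 1e-6)
    return AmplificationCurve(cycles, spec.baseline + f)


# ---------------------------------------------------------------------------
# Diverged sequence pairs


def make_orthologue_pair(
    n_repeats: int = 7,
    divergence: float = 0.15,
    seed: int = 0,
) -> tuple[ResidueSequence, ResidueSequence]:
    """SYNTHETIC orthologue-like ankyrin-domain pair.

    Two descendants of a common consensus-tiled ancestor, each with
    positions substituted independently at rate ``divergence``/2, emulate
    a conserved domain pair (not the real human/fly Notch sequences).
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.Generator(np.random.Philox(seed))
    rows = [CANONICAL_REPEATS[i % len(CANONICAL_REPEATS)] for i in range(n_repeats)]
    ancestor = "".join(rows)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"

    def descend(tag: str) -> ResidueSequence:
        letters = list(ancestor)
        for i in range(len(letters)):
            if rng.random() < divergence / 2:
                choices = [a for a in alphabet if a != letters[i]]
                letters[i] = choices[rng.integers(len(choices))]
        return ResidueSequence(f"synthetic_ank_orthologue_{tag}", "".join(letters))

    return descend("a"), descend("b")
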