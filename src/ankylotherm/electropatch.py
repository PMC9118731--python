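"""Surface electrostatics: formal charges, dot surface, screened potential,
charged-zone detection, and acidic-residue geometry.

The physics is a deliberate single-dielectric stand-in for a full
two-dielectric Poisson-Boltzmann solve: point formal charges at side-chain
charge centres, a Shrake-Rupley dot surface, and the Debye-Hueckel screened
Coulomb potential

    phi(r) = sum_i C q_i exp(-|r - r_i| / lambda_D) / (eps |r - r_i|)

with C the Coulomb constant in kJ*A/(mol*e^2) and lambda_D the Debye
length of the electrolyte.  Absolute zone areas from this stand-in are
comparative only; the testable claim is zone identity — which acidic
residues form the connected negative patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as const
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures import Residue, StructureModel

__all__ = [
    "ChargeSite",
    "ChargeModel",
    "SurfacePotentialMap",
    "ChargedPatch",
    "COULOMB_KJ_A",
    "debye_length",
    "assign_charges",
    "sample_surface",
    "screened_potential",
    "detect_patches",
    "carboxyl_distance_matrix",
    "charge_anisotropy",
]

#: N_A e^2 / (4 pi eps_0) in kJ * Angstrom / (mol * e^2)
COULOMB_KJ_A = (
    const.Avogadro * const.e**2 / (4 * np.pi * const.epsilon_0)
    * 1e10 / 1000.0
)

#: Van der Waals radii (A) by element; fallback 1.7.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

#: Side-chain charge centres: residue -> (charge, atoms averaged for the site)
_CHARGE_SITES = {
    "ASP": (-1.0, ("OD1", "OD2")),
    "GLU": (-1.0, ("OE1", "OE2")),
    "LYS": (+1.0, ("NZ",)),
    "ARG": (+1.0, ("CZ",)),
}


@dataclass
class ChargeSite:
    label: str               # e.g. "A:ASP1987"
    chain_id: str
    number: int
    res_name: str
    position: np.ndarray     # A
    charge: float            # e


@dataclass
class ChargeModel:
    sites: list[ChargeSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])

    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    def negated(self) -> "ChargeModel":
        return ChargeModel([
            ChargeSite(s.label, s.chain_id, s.number, s.res_name,
                       s.position.copy(), -s.charge)
            for s in self.sites
        ])


@dataclass
class SurfacePotentialMap:
    points: np.ndarray            # (N, 3) A
    areas: np.ndarray             # (N,) A^2
    potentials: np.ndarray        # (N,) kJ/(mol*e)
    nearest_residue: list[str]    # residue label per point
    ionic_strength: float
    eps_solvent: float
    temperature: float

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class ChargedPatch:
    member_points: np.ndarray
    area: float
    mean_potential: float
    sign: str
    member_residues: list[str]


# ---------------------------------------------------------------------------


def debye_length(ionic_strength: float, eps: float = 78.0,
                 temperature: float = 298.15) -> float:
    """Debye screening length in Angstrom; inf at zero ionic strength."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return np.inf
    i_m3 = ionic_strength * 1000.0 * const.Avogadro  # ions / m^3
    lam = np.sqrt(
        const.epsilon_0 * eps * const.Boltzmann * temperature
        / (2.0 * i_m3 * const.e**2)
    )
    return lam * 1e10


def assign_charges(model: StructureModel,
                   his_charge: float = 0.0) -> ChargeModel:
    """Formal side-chain charges at their geometric charge centres.

    ASP/GLU contribute -1 e at the carboxyl-oxygen midpoint, LYS +1 e at
    NZ, ARG +1 e at CZ.  Histidine is neutral by default (pH 7); a nonzero
    ``his_charge`` is placed at the ND1/NE2 midpoint.  Residues missing
    the needed side-chain atoms are skipped with a warning.
    """
    sites: list[ChargeSite] = []
    table = dict(_CHARGE_SITES)
    if his_charge != 0.0:
        table["HIS"] = (his_charge, ("ND1", "NE2"))
    for res in model:
        entry = table.get(res.name)
        if entry is None:
            continue
        charge, atom_names = entry
        atoms = [res.atom(a) for a in atom_names]
        if any(a is None for a in atoms):
            warnings.warn(
                f"{res.chain_id}:{res.name}{res.label}: missing side-chain "
                f"atoms {[n for n, a in zip(atom_names, atoms) if a is None]}; "
                "charge skipped"
            )
            continue
        pos = np.mean([a.position for a in atoms], axis=0)
        sites.append(ChargeSite(
            f"{res.chain_id}:{res.name}{res.label}",
            res.chain_id, res.number, res.name, pos, charge,
        ))
    return ChargeModel(sites)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sample_surface(
    model: StructureModel,
    probe: float = 1.4,
    dots_per_atom: int = 256,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Shrake-Rupley dot sampling of the solvent-accessible surface.

    Returns (points, areas, residue_labels): accessible dots on each atom's
    expanded sphere (radius + probe), each carrying area 4*pi*(r+probe)^2 /
    dots_per_atom, labelled with the residue that owns the atom.
    """
    atoms: list[tuple[np.ndarray, float, str]] = []
    for res in model:
        label = f"{res.chain_id}:{res.name}{res.label}"
        for a in res.atoms:
            r = VDW_RADII.get(a.element.upper(), 1.7)
            atoms.append((a.position, r + probe, label))
    if not atoms:
        raise ValueError(f"{model.source_id!r}: no atoms to sample")

    centers = np.array([a[0] for a in atoms])
    radii = np.array([a[1] for a in atoms])
    labels = [a[2] for a in atoms]
    tree = cKDTree(centers)
    unit = _fibonacci_sphere(dots_per_atom)

    pts, areas, owners = [], [], []
    r_max = radii.max()
    for i, (c, r, lab) in enumerate(zip(centers, radii, labels)):
        dots = c + r * unit
        neigh = [j for j in tree.query_ball_point(c, r + r_max) if j != i]
        keep = np.ones(len(dots), bool)
        for j in neigh:
            keep &= np.linalg.norm(dots - centers[j], axis=1) >= radii[j]
            if not keep.any():
                break
        if keep.any():
            kept = dots[keep]
            pts.append(kept)
            areas.append(np.full(len(kept), 4 * np.pi * r**2 / dots_per_atom))
            owners.extend([lab] * len(kept))
    if not pts:
        return np.empty((0, 3)), np.empty(0), []
    return np.vstack(pts), np.concatenate(areas), owners


def screened_potential(
    charges: ChargeModel,
    points: np.ndarray,
    areas: np.ndarray | None = None,
    residue_labels: list[str] | None = None,
    ionic_strength: float = 0.15,
    eps: float = 78.0,
    temperature: float = 298.15,
) -> SurfacePotentialMap:
    """Debye-Hueckel potential (kJ/(mol*e)) at each surface point.

    Zero ionic strength recovers the unscreened Coulomb potential exactly.
    Points coincident with a charge site are excluded with a warning.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    points = np.asarray(points, float).reshape(-1, 3)
    n = len(points)
    areas = np.ones(n) if areas is None else np.asarray(areas, float)
    residue_labels = residue_labels or [""] * n

    lam = debye_length(ionic_strength, eps, temperature)
    phi = np.zeros(n)
    ok = np.ones(n, bool)
    if len(charges):
        d = np.linalg.norm(points[:, None, :] - charges.positions[None, :, :], axis=2)
        coincident = (d < 1e-9).any(axis=1)
        if coincident.any():
            warnings.warn(f"{int(coincident.sum())} surface points coincide "
                          "with charge sites; excluded")
            ok &= ~coincident
        with np.errstate(divide="ignore", invalid="ignore"):
            decay = np.exp(-d / lam) if np.isfinite(lam) else 1.0
            contrib = COULOMB_KJ_A * charges.charges[None, :] * decay / (eps * d)
        phi[ok] = contrib[ok].sum(axis=1)
    return SurfacePotentialMap(
        points[ok], areas[ok], phi[ok],
        [residue_labels[i] for i in np.flatnonzero(ok)],
        ionic_strength, eps, temperature,
    )


def detect_patches(
    pmap: SurfacePotentialMap,
    threshold: float = -5.0,
    sign: str = "neg",
    adjacency: float | None = None,
) -> list[ChargedPatch]:
    """Connected super-threshold zones of the surface-potential map.

    Points beyond the threshold (below it for negative patches, above for
    positive) are linked when within ``adjacency`` Angstrom (default: twice
    the mean dot spacing); each connected component becomes a patch, sorted
    by area descending.
    """
    if sign not in ("neg", "pos"):
        raise ValueError("sign must be 'neg' or 'pos'")
    if sign == "neg" and threshold > 0 or sign == "pos" and threshold < 0:
        raise ValueError(f"threshold {threshold} inconsistent with sign {sign!r}")
    mask = pmap.potentials <= threshold if sign == "neg" else pmap.potentials >= threshold
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    pts = pmap.points[idx]
    if adjacency is None:
        tree_all = cKDTree(pmap.points)
        dists, _ = tree_all.query(pmap.points, k=min(2, len(pmap.points)))
        spacing = float(np.mean(dists[:, -1])) if len(pmap.points) > 1 else 1.0
        adjacency = 2.0 * spacing
    tree = cKDTree(pts)
    pairs = tree.query_pairs(adjacency, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        g = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        g = coo_matrix((n, n))
    n_comp, comp = connected_components(g, directed=False)
    patches = []
    for c in range(n_comp):
        members = idx[comp == c]
        patches.append(ChargedPatch(
            member_points=members,
            area=float(pmap.areas[members].sum()),
            mean_potential=float(pmap.potentials[members].mean()),
            sign="-" if sign == "neg" else "+",
            member_residues=sorted({pmap.nearest_residue[m] for m in members}),
        ))
    patches.sort(key=lambda p: -p.area)
    return patches


# ---------------------------------------------------------------------------


def _carboxyl_midpoint(res: Residue) -> np.ndarray:
    names = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}.get(res.name)
    if names is None:
        raise ValueError(
            f"{res.chain_id}:{res.name}{res.label} is not an acidic residue "
            "with a carboxyl group"
        )
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        raise ValueError(
            f"{res.chain_id}:{res.name}{res.label}: carboxyl atoms missing"
        )
    return np.mean([a.position for a in atoms], axis=0)


def carboxyl_distance_matrix(
    model: StructureModel,
    residues: list[tuple[str, int]],
) -> pd.DataFrame:
    """Pairwise distances (A) between side-chain carboxyl midpoints.

    ``residues`` is a list of (chain_id, author_number) for ASP/GLU residues.
    """
    labels, mids = [], []
    for chain_id, number in residues:
        res = model.residue(chain_id, number)
        mids.append(_carboxyl_midpoint(res))
        labels.append(f"{res.name}{res.number}")
    mids = np.array(mids)
    d = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=2)
    return pd.DataFrame(d, index=labels, columns=labels)


def charge_anisotropy(
    charges: ChargeModel,
    centroid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Dipole moment of the charge distribution: |sum q_i (r_i - c)|, e*A.

    ``centroid`` defaults to the unweighted mean of the charge sites; pass
    the molecular centroid to measure anisotropy about the whole body.
    Returns (magnitude, unit_vector); the unit vector is zero for a
    vanishing dipole.
    """
    if len(charges) == 0:
        raise ValueError("charge model is empty")
    pos = charges.positions
    c = pos.mean(axis=0) if centroid is None else np.asarray(centroid, float)
    dip = (charges.charges[:, None] * (pos - c)).sum(axis=0)
    mag = float(np.linalg.norm(dip))
    unit = dip / mag if mag > 1e-12 else np.zeros(3)
    return mag, unit
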