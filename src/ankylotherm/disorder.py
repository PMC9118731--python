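"""Intrinsic-disorder scoring from Boltzmann-inverted pair statistics.

The disorder argument rests on an energy-like pairwise potential obtained
by Boltzmann inversion of amino-acid pairing statistics,

    E_ij = -ln(rho_ij / rho*_ij),

where rho_ij is the observed frequency of residue types i and j occurring
within a contact window of one another and rho*_ij is the product of the
marginal frequencies (the no-interaction reference).  A residue whose
sequence neighbourhood offers mostly favourable (negative) interaction
energy is predicted ordered; an unfavourable neighbourhood is predicted
disordered.  Scores are mapped to [0, 1] by a logistic transform whose
midpoint is anchored on a packaged ordered/disordered benchmark pair.

The published per-domain score averages (Notch-1 ANK 0.37, other human ANK
0.22, yeast ANK 0.21, A. thaliana ANK 0.16) depend on the published tool's
proprietary parameter fit; they are accepted verbatim as inputs to the
downstream thermodynamics (see :mod:`ankylotherm.thermo`), while this
scorer is validated on ordering and range properties.

Also here: the charge/hydrophobicity plane used to flag "natively
unfolded" character — mean net charge against mean Kyte-Doolittle
hydrophobicity, split by the canonical boundary line R = 2.785 H - 1.151.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .structures import ResidueSequence

__all__ = [
    "PairPotential",
    "DisorderProfile",
    "ChargeHydroPoint",
    "estimate_pair_potential",
    "disorder_profile",
    "domain_mean",
    "charge_hydrophobicity",
    "read_scores_tsv",
    "read_potential_tsv",
    "BENCHMARK_ORDERED",
    "BENCHMARK_DISORDERED",
]

#: Synthetic calibration benchmarks: a hydrophobic-core-like ordered
#: sequence and a polar/charged low-complexity disordered one.  They anchor
#: the logistic midpoint so that ordered scores fall below 0.5 and
#: disordered ones above it under any corpus-derived potential.
BENCHMARK_ORDERED = "MKVLILACLVALALAWQYNVKAGHFDLVNEIILGAVLWFIVTAMVLGIKA"
BENCHMARK_DISORDERED = "MSEDSSKEEGKPSEESKDEEQSPKESEEGNKSDEESKEQPSGESEEKKSP"

DEFAULT_CHARGES = {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": +0.1}

_HYDROPHOBIC = "AVILMFWC"
_POLAR = "GSTNQDEKRHPY"


def _quasi_globular_corpus(n_seqs: int = 30, length: int = 240,
                           seed: int = 20) -> list[ResidueSequence]:
    """Synthetic corpus emulating the pairing statistics of folded proteins.

    Folded chains cluster hydrophobic residues (the buried core) while
    isolating polar residues between them (the exposed surface), so
    hydrophobic-hydrophobic pairings are over-represented relative to
    composition while specific polar-polar pairings fall below their
    marginal product.  The corpus encodes exactly that: runs of 4-8 core
    residues separated by 1-3 scattered polar residues.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    out = []
    for s in range(n_seqs):
        letters: list[str] = []
        while len(letters) < length:
            run = rng.integers(4, 9)
            letters.extend(rng.choice(list(_HYDROPHOBIC), run))
            gap = rng.integers(1, 4)
            letters.extend(rng.choice(list(_POLAR), gap))
        out.append(ResidueSequence(f"globular_like_{s}", "".join(letters[:length])))
    return out


_DEFAULT_POTENTIAL: "PairPotential | None" = None


def default_potential(contact_window: int = 4) -> "PairPotential":
    """Pair potential Boltzmann-inverted from the packaged synthetic
    quasi-globular corpus (cached)."""
    global _DEFAULT_POTENTIAL
    if _DEFAULT_POTENTIAL is None:
        _DEFAULT_POTENTIAL = estimate_pair_potential(
            _quasi_globular_corpus(), contact_window
        )
    return _DEFAULT_POTENTIAL


@dataclass
class PairPotential:
    """Symmetric dimensionless interaction energies E_ij with provenance."""

    energies: pd.DataFrame          # letters x letters; NaN where undefined
    observed: pd.DataFrame          # rho_ij (symmetric, sums to 1)
    reference: pd.DataFrame         # rho*_ij = f_i f_j

    @property
    def letters(self) -> list[str]:
        return list(self.energies.index)

    def energy(self, i: str, j: str) -> float:
        return float(self.energies.loc[i, j])

    def imputed(self) -> pd.DataFrame:
        """Energies with undefined cells filled by row maximum + 1.

        An unseen pairing carries no evidence of attraction; it is treated
        as at least as unfavourable as the worst observed pairing so that
        NaNs never propagate into profiles.
        """
        e = self.energies.copy()
        fill = np.nanmax(e.values) + 1.0 if np.isfinite(e.values).any() else 1.0
        return e.fillna(fill)

    def shifted(self, delta: float) -> "PairPotential":
        return PairPotential(self.energies + delta, self.observed, self.reference)

    def swapped(self) -> "PairPotential":
        """Exchange observed and reference distributions (negates energies)."""
        e = -self.energies
        return PairPotential(e, self.reference, self.observed)


@dataclass
class DisorderProfile:
    scores: np.ndarray
    numbering: list[int]
    window: int
    midpoint: float
    slope: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))


@dataclass
class ChargeHydroPoint:
    mean_net_charge: float
    mean_hydrophobicity: float
    classification: str  # "ordered-side" | "disordered-side"


# ---------------------------------------------------------------------------


def estimate_pair_potential(
    corpus: list[ResidueSequence],
    contact_window: int = 2,
) -> PairPotential:
    """Boltzmann-invert pairing statistics of a sequence corpus.

    Ordered pairs (s[p], s[p+d]) for 1 <= d <= contact_window are counted in
    both orders, so rho is symmetric and sums to 1; the reference is the
    outer product of marginal residue frequencies.  Cells never observed
    are left NaN in the energy table (flagged, not fabricated).
    """
    if contact_window < 1:
        raise ValueError("contact_window must be >= 1")
    seqs = [s.letters.upper().replace("X", "") for s in corpus]
    total_res = sum(len(s) for s in seqs)
    if total_res < 2:
        raise ValueError("corpus must contain at least 2 residues")
    letters = sorted(set("".join(seqs)))
    li = {aa: k for k, aa in enumerate(letters)}
    n = len(letters)

    counts = np.zeros((n, n))
    marg = np.zeros(n)
    for s in seqs:
        for p, aa in enumerate(s):
            marg[li[aa]] += 1
            for d in range(1, contact_window + 1):
                if p + d < len(s):
                    a, b = li[aa], li[s[p + d]]
                    counts[a, b] += 1
                    counts[b, a] += 1
    if counts.sum() == 0:
        raise ValueError("corpus yields no residue pairs at this window")
    rho = counts / counts.sum()
    f = marg / marg.sum()
    rho_star = np.outer(f, f)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = -np.log(rho / rho_star)
    e[rho == 0] = np.nan

    idx = pd.Index(letters)
    return PairPotential(
        pd.DataFrame(e, index=idx, columns=idx),
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(rho_star, index=idx, columns=idx),
    )


def _window_energies(letters: str, e: pd.DataFrame, window: int) -> np.ndarray:
    """Mean interaction energy of each residue with its window composition."""
    missing = sorted(set(letters) - set(e.index) - {"X"})
    if missing:
        raise KeyError(
            f"potential lacks energies for letters {missing}; supply a potential "
            "covering the sequence alphabet"
        )
    half = window // 2
    n = len(letters)
    emat = e.values
    li = {aa: k for k, aa in enumerate(e.index)}
    out = np.zeros(n)
    for p in range(n):
        lo, hi = max(0, p - half), min(n, p + half + 1)
        acc, cnt = 0.0, 0
        kp = li.get(letters[p])
        if kp is None:  # X scores as the neutral mid-energy 0
            out[p] = 0.0
            continue
        for q in range(lo, hi):
            if q == p:
                continue
            kq = li.get(letters[q])
            if kq is None:
                continue
            acc += emat[kp, kq]
            cnt += 1
        out[p] = acc / cnt if cnt else 0.0
    return out


def disorder_profile(
    seq: ResidueSequence,
    potential: PairPotential | None = None,
    window: int = 21,
    midpoint: float | None = None,
    slope: float | None = None,
) -> DisorderProfile:
    """Per-residue disorder scores in [0, 1].

    Each residue's estimated interaction energy is the composition-weighted
    mean of E over a centred window (truncated at the termini); the logistic
    map score = 1 / (1 + exp(-(e - m)/s)) sends favourable (low) energies to
    low scores.  When ``midpoint``/``slope`` are omitted they are anchored
    so the packaged ordered/disordered benchmark pair straddles 0.5.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    if potential is None:
        potential = default_potential()
    e = potential.imputed()
    energies = _window_energies(seq.letters.upper(), e, window)
    if midpoint is None or slope is None:
        try:
            e_ord = _window_energies(BENCHMARK_ORDERED, e, window).mean()
            e_dis = _window_energies(BENCHMARK_DISORDERED, e, window).mean()
        except KeyError:
            # toy potentials over restricted alphabets: neutral transform
            e_ord, e_dis = -2.0, 2.0
        if midpoint is None:
            midpoint = 0.5 * (e_ord + e_dis)
        if slope is None:
            gap = abs(e_dis - e_ord)
            slope = gap / 4.0 if gap > 1e-12 else 1.0
    scores = 1.0 / (1.0 + np.exp(-(energies - midpoint) / slope))
    return DisorderProfile(scores, list(seq.numbering), window, midpoint, slope)


def domain_mean(profile: DisorderProfile, span: tuple[int, int] | None = None) -> float:
    """Arithmetic mean of scores over an author-number span."""
    if span is None:
        return profile.mean
    lo, hi = span
    idx = [i for i, n in enumerate(profile.numbering) if lo <= n <= hi]
    if not idx:
        raise ValueError(f"span {lo}..{hi} selects no residues")
    return float(np.mean(profile.scores[idx]))


# ---------------------------------------------------------------------------


def charge_hydrophobicity(
    seq: ResidueSequence,
    charges: dict[str, float] | None = None,
    window: int = 5,
    boundary: tuple[float, float] = (2.785, -1.151),
) -> ChargeHydroPoint:
    """Locate a sequence on the charge/hydrophobicity plane.

    Mean net charge is |average signed side-chain charge per residue|
    (D, E = -1; K, R = +1; H = +0.1 by default).  Hydrophobicity is the
    Kyte-Doolittle scale min-max normalised to [0, 1], averaged over
    ``window``-residue sliding windows.  The classification boundary is
    the line R = a*H + b; points above it (charge high for their
    hydrophobicity) fall on the natively-unfolded, disordered side.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    charges = DEFAULT_CHARGES if charges is None else charges
    letters = seq.letters.upper()
    net = abs(float(np.mean([charges.get(aa, 0.0) for aa in letters])))

    kd_min, kd_max = min(KYTE_DOOLITTLE.values()), max(KYTE_DOOLITTLE.values())
    vals = np.array([
        (KYTE_DOOLITTLE.get(aa, 0.0) - kd_min) / (kd_max - kd_min)
        for aa in letters
    ])
    w = min(window, len(vals))
    smoothed = np.convolve(vals, np.ones(w) / w, mode="valid")
    hydro = float(np.mean(smoothed))

    a, b = boundary
    side = "disordered-side" if net > a * hydro + b else "ordered-side"
    return ChargeHydroPoint(net, hydro, side)


# ---------------------------------------------------------------------------
# TSV ingestion (externally computed scores / potentials)


def read_scores_tsv(path: str | Path) -> DisorderProfile:
    """Read per-residue scores from a 2-column TSV (residue_number, score)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (residue number, score)")
    scores = df.iloc[:, 1].to_numpy(float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError(f"{path}: scores must lie in [0, 1]")
    return DisorderProfile(scores, df.iloc[:, 0].astype(int).tolist(), 0, 0.0, 1.0)


def read_potential_tsv(path: str | Path) -> PairPotential:
    """Read a square energy table from TSV (letters as header and index)."""
    e = pd.read_csv(path, sep="\t", index_col=0)
    e.columns = [str(c) for c in e.columns]
    if list(e.index) != list(e.columns):
        raise ValueError(f"{path}: energy table must be square and symmetric-labelled")
    placeholder = pd.DataFrame(np.nan, index=e.index, columns=e.columns)
    return PairPotential(e, placeholder, placeholder)
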