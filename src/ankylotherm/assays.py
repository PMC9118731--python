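"""qPCR and molecular-beacon arithmetic.

Three small, exactly-specified computations used around the wet-lab
readouts:

* the Pfaffl efficiency-corrected relative-expression ratio
  ``Eff_tar^dct_tar / Eff_ref^dct_ref`` with dct = control - test;
* amplification-efficiency estimation as the antilog of the slope of
  log10(fluorescence) vs cycle over the best window-of-linearity;
* a unimolecular two-state melting temperature for stem-loop (molecular
  beacon) hairpins, Tm = dH/dS, with nearest-neighbour stem sums, a
  loop-closure entropy penalty, and a salt correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt
from scipy import stats

__all__ = [
    "QpcrRecord",
    "AmplificationCurve",
    "BeaconSpec",
    "pfaffl_ratio",
    "amplification_efficiency",
    "hairpin_tm",
    "MB4_SEQUENCE",
    "MB5_SEQUENCE",
]

#: The two L-DNA thermometer beacons (fluorophore/quencher ends omitted).
MB4_SEQUENCE = "CGAGTTTTTTTTTTTTTTTCTCG"   # 4-bp stem, Tm anchor 36 C
MB5_SEQUENCE = "GCGAGTTTTTTTTTTTTTTTCTCGC"  # 5-bp stem, Tm anchor 50 C

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Loop-closure entropy at the reference loop size (cal/(mol*K), negative:
#: closing the loop is entropically costly).  Anchored once on the printed
#: beacon melting temperatures (36/50 C, +/- 3 C); other loop sizes follow
#: the Jacobson-Stockmayer 1.75*R*ln(n/n0) extrapolation.
_LOOP_REF_SIZE = 15
_LOOP_REF_DS = -14.0
_R_CAL = 1.987


@dataclass
class QpcrRecord:
    """Efficiencies (fold/cycle) and delta-ct values (control - test)."""

    eff_tar: float
    dct_tar: float
    eff_ref: float
    dct_ref: float

    def __post_init__(self) -> None:
        if self.eff_tar <= 1 or self.eff_ref <= 1:
            raise ValueError("amplification efficiencies must exceed 1 fold/cycle")

    def swapped(self) -> "QpcrRecord":
        """Exchange test and control roles (negates both delta-ct)."""
        return QpcrRecord(self.eff_tar, -self.dct_tar, self.eff_ref, -self.dct_ref)


@dataclass
class AmplificationCurve:
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 6:
            raise ValueError("need at least 6 points to locate a linear window")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be non-negative")


@dataclass
class BeaconSpec:
    sequence: str
    stem_length: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError("beacon sequence must be DNA (ACGT)")
        k = self.stem_length
        if k < 2:
            raise ValueError("stem must be at least 2 bp")
        head, tail = seq[:k], seq[-k:]
        if head != tail.translate(_COMPLEMENT)[::-1]:
            raise ValueError(
                f"termini {head}/{tail} are not reverse-complementary: "
                "not a hairpin stem"
            )
        if len(seq) - 2 * k < 3:
            raise ValueError("hairpin loop must be at least 3 nt")
        self.sequence = seq

    @property
    def loop_length(self) -> int:
        return len(self.sequence) - 2 * self.stem_length


def pfaffl_ratio(r: QpcrRecord) -> float:
    """Relative expression of target vs reference gene (dimensionless)."""
    if r.eff_tar <= 0 or r.eff_ref <= 0:
        raise ValueError("efficiencies must be positive")
    return r.eff_tar ** r.dct_tar / r.eff_ref ** r.dct_ref


def amplification_efficiency(
    curve: AmplificationCurve,
    window: int = 5,
) -> float:
    """Fold-per-cycle efficiency from the window of linearity.

    Fits log10(F) vs cycle over every ``window``-point stretch of strictly
    positive fluorescence, keeps the window with the best coefficient of
    determination among positive-slope fits (ties to the earliest cycles),
    and returns 10**slope.  Scale-invariant by construction.
    """
    c = np.asarray(curve.cycles, float)
    f = curve.fluorescence
    n = len(c)
    if window < 3 or window > n:
        raise ValueError(f"window must be in 3..{n}")
    best: tuple[float, int] | None = None
    best_slope = None
    for i in range(n - window + 1):
        fw = f[i:i + window]
        if np.any(fw <= 0):
            continue
        res = stats.linregress(c[i:i + window], np.log10(fw))
        if res.slope <= 0:
            continue
        r2 = res.rvalue ** 2
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, i)
            best_slope = res.slope
    if best_slope is None:
        raise ValueError("no positive-slope window of linearity found")
    return float(10.0 ** best_slope)


def _stack_params(stack: str, table: dict) -> tuple[float, float]:
    """(dH kcal, dS cal/K) for a 2-nt stack, trying both table orientations."""
    comp = stack.translate(_COMPLEMENT)
    keys = (stack, f"{stack}/{comp}", f"{comp[::-1]}/{stack[::-1]}")
    for key in keys:
        if key in table:
            v = table[key]
            return float(v[0]), float(v[1])
    raise KeyError(f"no nearest-neighbour parameters for stack {stack!r}")


def hairpin_tm(
    beacon: BeaconSpec,
    nn_params: dict | None = None,
    na_molar: float = 0.135,
) -> float:
    """Two-state unimolecular melting temperature in Celsius.

    Tm = dH / dS - 273.15 with dH, dS summed over the stem's
    nearest-neighbour stacks (SantaLucia unified DNA parameters by
    default), a loop-closure entropy penalty extrapolated from the
    calibrated reference loop, and the entropic salt correction
    0.368 * n_stacks * ln[Na+].  Being unimolecular, there is no
    concentration term.
    """
    if na_molar <= 0:
        raise ValueError("na_molar must be positive")
    table = nn_params if nn_params is not None else _mt.DNA_NN4
    stem = beacon.sequence[: beacon.stem_length]
    dh = ds = 0.0
    for i in range(len(stem) - 1):
        h, s = _stack_params(stem[i:i + 2], table)
        dh += h
        ds += s
    ds_loop = _LOOP_REF_DS - 1.75 * _R_CAL * np.log(
        beacon.loop_length / _LOOP_REF_SIZE
    )
    n_stacks = len(stem) - 1
    ds_salt = 0.368 * n_stacks * np.log(na_molar)
    ds_total = ds + ds_loop + ds_salt
    if dh >= 0 or ds_total >= 0:
        raise ValueError("stem does not form a stable hairpin (dH or dS >= 0)")
    return dh * 1000.0 / ds_total - 273.15
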