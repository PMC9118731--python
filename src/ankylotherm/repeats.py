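"""Ankyrin-repeat anatomy.

The ankyrin (ANK) module is a 33-residue unit folding into two antiparallel
α-helices (α1, α2) followed by a β-hairpin (βhp); tandem copies stack into
the ankyrin domain.  This module segments a domain sequence into 33-residue
repeats against a position-weight profile of the canonical repeat, labels
the secondary-structure elements (from a fixed positional template, or
geometrically when coordinates are available), and quantifies per-element
composition enrichment — the route by which alanine enrichment in the
helices and acidic-residue enrichment on the hairpin surface are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structures import ResidueSequence, StructureModel

__all__ = [
    "AnkRepeat",
    "RepeatAnnotation",
    "CompositionProfile",
    "EnrichmentTable",
    "REPEAT_LENGTH",
    "CANONICAL_REPEATS",
    "consensus_pwm",
    "segment_repeats",
    "assign_elements",
    "composition_profile",
    "enrichment",
    "percent_similarity",
]

REPEAT_LENGTH = 33
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Small curated alignment of canonical 33-residue ankyrin repeats built
#: around the invariant TPLH tetrapeptide and the GH/GADVNA motifs shared by
#: designed consensus repeats and natural ANK families.  The default
#: position-weight profile is estimated from these rows; any alignment of
#: 33-column rows can be supplied instead.
CANONICAL_REPEATS: tuple[str, ...] = (
    "DKDGNTPLHLAARNGHLEVVKLLLEAGADVNAK",
    "DNEGNTPLHLAAKEGHLEIVQLLLKAGADVNAR",
    "DKNGRTPLHLAAENGHLEVVRLLLEHGADVNAK",
    "NADGNTPLHIAAREGHLEIVEVLLKYGADVNAQ",
    "DSDGNTPLHLAIKNGHLEVVKLLVEAGADVNAK",
    "DEEGNTALHIAAGNGHLEVVQLLLDAGADVNLQ",
    "DKDGDTPLHLAARNGHAEVVRLLLSAGADVNAK",
    "NNDGNTPLHEAASNGHAEVVELLLKHGADVNAK",
)

# Positional element template (1-based positions within a repeat):
# 5-12 -> α1, 15-24 -> α2, 25-31 -> βhp, everything else loop.
_TEMPLATE_SPANS = {"a1": (5, 12), "a2": (15, 24), "bhp": (25, 31)}

ELEMENT_CLASSES = {
    "α-helix": {"a1", "a2"},
    "helix": {"a1", "a2"},
    "β-hairpin": {"bhp"},
    "hairpin": {"bhp"},
    "loop": {"loop"},
    "all": {"a1", "a2", "bhp", "loop"},
}


@dataclass
class AnkRepeat:
    """One 33-residue repeat: 1-based index, author-number span, labels."""

    index: int
    span: tuple[int, int]
    element_labels: list[str] = field(default_factory=list)
    score: float = 0.0


@dataclass
class RepeatAnnotation:
    domain_span: tuple[int, int]
    repeats: list[AnkRepeat] = field(default_factory=list)
    residual: list[int] = field(default_factory=list)
    sequence: ResidueSequence | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass
class CompositionProfile:
    element_class: str
    frequencies: dict[str, float]
    n: int


@dataclass
class EnrichmentTable:
    element_class: str
    entries: dict[str, float]
    pseudocount: float


def template_labels() -> list[str]:
    """Per-position element labels of the fixed 33-residue template."""
    labels = ["loop"] * REPEAT_LENGTH
    for name, (lo, hi) in _TEMPLATE_SPANS.items():
        for p in range(lo, hi + 1):
            labels[p - 1] = name
    return labels


def consensus_pwm(alignment: tuple[str, ...] = CANONICAL_REPEATS,
                  pseudocount: float = 0.5) -> np.ndarray:
    """Position-weight matrix (log2-odds vs uniform background), 33 x 20."""
    rows = [r.upper() for r in alignment]
    if not rows or any(len(r) != REPEAT_LENGTH for r in rows):
        raise ValueError(f"consensus alignment rows must all have length {REPEAT_LENGTH}")
    counts = np.full((REPEAT_LENGTH, len(AMINO_ACIDS)), pseudocount)
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for row in rows:
        for p, aa in enumerate(row):
            if aa in idx:
                counts[p, idx[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log2(freqs / (1.0 / len(AMINO_ACIDS)))


def _window_scores(letters: str, pwm: np.ndarray) -> np.ndarray:
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    n = len(letters)
    scores = np.full(max(n - REPEAT_LENGTH + 1, 0), -np.inf)
    for off in range(len(scores)):
        s = 0.0
        for p in range(REPEAT_LENGTH):
            k = idx.get(letters[off + p])
            if k is not None:
                s += pwm[p, k]
            # X contributes 0 (uninformative)
        scores[off] = s
    return scores


def segment_repeats(
    seq: ResidueSequence,
    consensus: np.ndarray | None = None,
    n_expected: int | None = None,
    threshold: float = 0.0,
) -> RepeatAnnotation:
    """Tile a domain with non-overlapping 33-residue repeats.

    Dynamic programming selects the non-overlapping set of 33-mers scoring
    above ``threshold`` (summed log2-odds against the consensus profile)
    that maximises first the repeat count, then the total score; ties are
    broken leftmost.  With ``n_expected`` the threshold is relaxed until at
    least that many windows qualify, and the best ``n_expected`` are kept.
    """
    if consensus is None:
        consensus = consensus_pwm()
    if consensus.shape != (REPEAT_LENGTH, len(AMINO_ACIDS)):
        raise ValueError(
            f"consensus profile must be {REPEAT_LENGTH}x{len(AMINO_ACIDS)}, "
            f"got {consensus.shape}"
        )
    letters = seq.letters.upper()
    n = len(letters)
    if n == 0:
        return RepeatAnnotation((0, -1), [], [], seq)
    domain_span = (seq.numbering[0], seq.numbering[-1])
    if n < REPEAT_LENGTH:
        return RepeatAnnotation(domain_span, [], list(seq.numbering), seq)

    scores = _window_scores(letters, consensus)
    eligible = scores >= threshold
    if n_expected is not None and int(eligible.sum()) < n_expected:
        eligible = np.ones_like(eligible, dtype=bool)

    # Weighted-interval DP over equal-length windows.
    # best[i] = (count, total score, -leftmost tie) achievable from offset i.
    NEG = (-1, -np.inf)
    m = len(scores)
    best: list[tuple[int, float]] = [(0, 0.0)] * (m + REPEAT_LENGTH)
    take: list[bool] = [False] * m
    for i in range(m - 1, -1, -1):
        skip = best[i + 1]
        if eligible[i]:
            nxt = best[i + REPEAT_LENGTH] if i + REPEAT_LENGTH <= m else (0, 0.0)
            cand = (nxt[0] + 1, nxt[1] + scores[i])
        else:
            cand = NEG
        # prefer taking on exact ties -> leftmost placement
        if cand >= skip:
            best[i], take[i] = cand, True
        else:
            best[i], take[i] = skip, False

    offsets: list[int] = []
    i = 0
    while i < m:
        if take[i]:
            offsets.append(i)
            i += REPEAT_LENGTH
        else:
            i += 1
    if n_expected is not None and len(offsets) > n_expected:
        keep = sorted(sorted(offsets, key=lambda o: (-scores[o], o))[:n_expected])
        offsets = keep

    repeats = []
    covered: set[int] = set()
    for k, off in enumerate(offsets, start=1):
        span = (seq.numbering[off], seq.numbering[off + REPEAT_LENGTH - 1])
        repeats.append(AnkRepeat(k, span, template_labels(), float(scores[off])))
        covered.update(range(off, off + REPEAT_LENGTH))
    residual = [seq.numbering[i] for i in range(n) if i not in covered]
    return RepeatAnnotation(domain_span, repeats, residual, seq)


# ---------------------------------------------------------------------------
# Element assignment


def _helical_mask(ca: np.ndarray) -> np.ndarray:
    """Geometric helix detection from Cα positions: i..i+3 chord length.

    An ideal α-helix (1.5 Å rise, ~100° turn) places Cα(i) and Cα(i+3)
    ~5.0-5.5 Å apart; extended strands put them near 10 Å.
    """
    n = len(ca)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        d = np.linalg.norm(ca[i + 3] - ca[i])
        if 4.0 < d < 6.5:
            mask[i:i + 4] = True
    return mask


def assign_elements(
    annotation: RepeatAnnotation,
    model: StructureModel | None = None,
    chain_id: str | None = None,
) -> RepeatAnnotation:
    """Label each repeat position α1/α2/βhp/loop.

    Without coordinates the fixed positional template applies.  With a
    structure, helical stretches are detected geometrically; the first
    helical run in a repeat becomes α1, the second α2, and the trailing
    non-helical stretch before the repeat boundary becomes the β-hairpin.
    """
    if not annotation.repeats:
        raise ValueError("annotation has no repeats to label")
    if model is None:
        for rep in annotation.repeats:
            rep.element_labels = template_labels()
        return annotation

    if chain_id is None:
        chain_id = next(iter(model.chains))
    residues = {res.number: res for res in model.chain(chain_id)}
    for rep in annotation.repeats:
        numbers = list(range(rep.span[0], rep.span[1] + 1))
        ca = []
        for num in numbers:
            res = residues.get(num)
            a = res.atom("CA") if res else None
            if a is None:
                raise ValueError(
                    f"repeat {rep.index}: residue {num} missing from chain "
                    f"{chain_id!r} of {model.source_id!r}"
                )
            ca.append(a.position)
        mask = _helical_mask(np.asarray(ca))
        labels = ["loop"] * len(numbers)
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                if j - i + 1 >= 4:
                    runs.append((i, j))
                i = j + 1
            else:
                i += 1
        for name, run in zip(("a1", "a2"), runs[:2]):
            for p in range(run[0], run[1] + 1):
                labels[p] = name
        if len(runs) >= 2:
            # hairpin: the stretch after α2, excluding the final connector
            start = runs[1][1] + 1
            end = len(labels) - 2
            for p in range(start, max(start, end) + 1):
                if p < len(labels) and labels[p] == "loop":
                    labels[p] = "bhp"
        rep.element_labels = labels
    return annotation


# ---------------------------------------------------------------------------
# Composition and enrichment


def composition_profile(
    seq: ResidueSequence,
    labels: list[str],
    element_class: str,
) -> CompositionProfile:
    """Amino-acid frequencies over residues whose label is in the class."""
    if len(labels) != len(seq):
        raise ValueError(f"{len(labels)} labels for {len(seq)} residues")
    if element_class not in ELEMENT_CLASSES:
        raise ValueError(f"unknown element class {element_class!r} "
                         f"(choose from {sorted(ELEMENT_CLASSES)})")
    wanted = ELEMENT_CLASSES[element_class]
    selected = [aa for aa, lab in zip(seq.letters.upper(), labels) if lab in wanted]
    n = len(selected)
    if n == 0:
        return CompositionProfile(element_class, {}, 0)
    freqs = {aa: selected.count(aa) / n for aa in set(selected)}
    return CompositionProfile(element_class, freqs, n)


def enrichment(
    target: CompositionProfile,
    reference: CompositionProfile,
    pseudocount: float = 0.01,
) -> EnrichmentTable:
    """log2((f_target + p) / (f_reference + p)) per amino acid."""
    if target.element_class != reference.element_class:
        raise ValueError(
            f"element classes differ: {target.element_class!r} vs "
            f"{reference.element_class!r}"
        )
    if pseudocount < 0 or (pseudocount == 0 and (
            set(target.frequencies) ^ set(reference.frequencies))):
        raise ValueError("pseudocount must be > 0 unless supports coincide")
    entries = {}
    for aa in sorted(set(AMINO_ACIDS) | set(target.frequencies) | set(reference.frequencies)):
        ft = target.frequencies.get(aa, 0.0)
        fr = reference.frequencies.get(aa, 0.0)
        if ft + pseudocount <= 0 or fr + pseudocount <= 0:
            continue
        entries[aa] = float(np.log2((ft + pseudocount) / (fr + pseudocount)))
    return EnrichmentTable(target.element_class, entries, pseudocount)


# ---------------------------------------------------------------------------
# Similarity


def percent_similarity(
    a: ResidueSequence,
    b: ResidueSequence,
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Global-alignment similarity percentage.

    Aligns globally with affine gap penalties, then reports the fraction of
    alignment columns (terminal gaps excluded) whose residue pair has a
    positive substitution score, as a percentage.  Columns containing a gap
    count toward the denominator.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("percent_similarity requires non-empty sequences")
    subst = substitution_matrices.load(matrix) if isinstance(matrix, str) else matrix
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a.letters.upper(), b.letters.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    # strip terminal-gap columns
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns == 0:
        return 0.0
    similar = 0
    for x, y in zip(row_a[start:end], row_b[start:end]):
        if x != "-" and y != "-" and subst[x, y] > 0:
            similar += 1
    return 100.0 * similar / columns


def alignment_score(
    a: str,
    b: str,
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Raw global affine-gap alignment score (exposed for oracle checks)."""
    subst = substitution_matrices.load(matrix) if isinstance(matrix, str) else matrix
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return float(aligner.score(a.upper(), b.upper()))
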