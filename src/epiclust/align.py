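"""Bisulfite-aware local alignment of read pairs to amplicon references.

Each mate is aligned independently to every reference with an affine-gap
Smith–Waterman (via Biopython's pairwise aligner) under an asymmetric
substitution matrix: on the converted strand an unmethylated reference C is
read as T, so reference-C versus read-T scores as a match, while
reference-T versus read-C stays a mismatch.  Mate 2 is sequenced from the
reverse complement of the converted strand and is reverse-complemented
before alignment.  A pair is retained only when both mates' best alignments
hit the same reference (a "coherent" pair); ties between references are
broken toward the lowest reference index.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .amplicons import AmpliconReference
from .readsim import ReadPair, reverse_complement

__all__ = [
    "BisulfiteScoring",
    "MateAlignment",
    "PairAlignment",
    "Rejection",
    "bisulfite_align_pair",
]


@dataclass(frozen=True)
class BisulfiteScoring:
    """Affine-gap local-alignment scoring.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  With
    ``bisulfite_rule`` on, read T against reference C scores as a match.
    ``min_score_frac`` sets the retention threshold at
    ``min_score_frac * read_len * match``; pairs scoring below it on their
    best reference are rejected rather than force-assigned.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    bisulfite_rule: bool = True
    min_score_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be at least as costly as gap_extend")


@lru_cache(maxsize=8)
def _aligner(scoring: BisulfiteScoring) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array("ACGT", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = scoring.match if a == b else scoring.mismatch
    if scoring.bisulfite_rule:
        mat["C", "T"] = scoring.match  # reference C read as T after conversion
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


@dataclass(frozen=True)
class MateAlignment:
    """One mate's local alignment against the assigned reference.

    ``blocks`` pairs aligned reference/read intervals (0-based half-open),
    in the CIGAR sense: gaps fall between consecutive blocks.  ``read`` is
    the aligned read sequence in reference (top-strand) orientation.
    """

    score: float
    ref_start: int
    ref_end: int
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    read: str


@dataclass(frozen=True)
class PairAlignment:
    ref_name: str
    ref_index: int
    mate1: MateAlignment
    mate2: MateAlignment


@dataclass(frozen=True)
class Rejection:
    reason: str  # "discordant" | "low_score"
    detail: str = ""


def _best_ref(
    read: str, refs: list[AmpliconReference], aligner: Align.PairwiseAligner
) -> tuple[int, float]:
    scores = [aligner.score(r.sequence, read) for r in refs]
    best = int(np.argmax(scores))  # argmax takes the first (lowest index) on ties
    return best, float(scores[best])


def _full_alignment(
    read: str, ref: AmpliconReference, aligner: Align.PairwiseAligner
) -> MateAlignment:
    aln = aligner.align(ref.sequence, read)[0]
    tblocks, qblocks = aln.aligned
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks)
    )
    return MateAlignment(
        score=float(aln.score),
        ref_start=int(tblocks[0][0]),
        ref_end=int(tblocks[-1][1]),
        blocks=blocks,
        read=read,
    )


def bisulfite_align_pair(
    pair: ReadPair,
    refs: list[AmpliconReference],
    scoring: BisulfiteScoring = BisulfiteScoring(),
) -> PairAlignment | Rejection:
    """Align a read pair to all references; retain only coherent pairs.

    Returns a :class:`PairAlignment` when both mates' best-scoring
    reference agrees and both scores clear the retention threshold,
    otherwise a :class:`Rejection` with a reason code.
    """
    if not refs:
        raise ValueError("refs must be nonempty")
    if not pair.mate1 or not pair.mate2:
        raise ValueError("mate sequences must be nonempty")
    aligner = _aligner(scoring)
    read1 = pair.mate1
    read2 = reverse_complement(pair.mate2)  # back to top-strand orientation

    i1, s1 = _best_ref(read1, refs, aligner)
    i2, s2 = _best_ref(read2, refs, aligner)
    if i1 != i2:
        return Rejection(
            "discordant", f"mate1→{refs[i1].name}, mate2→{refs[i2].name}"
        )
    thr1 = scoring.min_score_frac * len(read1) * scoring.match
    thr2 = scoring.min_score_frac * len(read2) * scoring.match
    if s1 < thr1 or s2 < thr2:
        return Rejection("low_score", f"scores ({s1}, {s2}) below ({thr1}, {thr2})")
    ref = refs[i1]
    return PairAlignment(
        ref_name=ref.name,
        ref_index=i1,
        mate1=_full_alignment(read1, ref, aligner),
        mate2=_full_alignment(read2, ref, aligner),
    )
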