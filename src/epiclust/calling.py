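"""Per-CpG methylation quantification and sample QC.

From retained coherent pair alignments, the caller tallies the four base
frequencies at every CpG cytosine of the reference and reports the
methylation percentage 100·C/(C+T) per site.  Bisulfite conversion
efficiency is estimated from non-CpG cytosines, which should read T in a
fully converted library: efficiency = 100·T/(C+T) pooled over all non-CpG
C positions.  A sample passes QC only if every analyzed CpG reaches the
coverage floor (default 100x) and conversion efficiency exceeds the
threshold (default: strictly greater than 99%).

Overlapping mates of one pair are a single template molecule, so each
reference position is counted at most once per pair; where the mates
disagree, mate 1 wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicons import AmpliconReference
from .align import PairAlignment, Rejection, BisulfiteScoring, bisulfite_align_pair
from .readsim import ReadPair

__all__ = [
    "BaseCounts",
    "MethylationProfile",
    "QCResult",
    "tally_cpg_bases",
    "methylation_percentages",
    "conversion_efficiency",
    "qc_sample",
    "call_sample",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class BaseCounts:
    """A/C/G/T counts observed at each CpG cytosine position.

    ``counts`` has shape (n_cpg, 4) in A, C, G, T order.
    """

    amplicon: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 4 or (c < 0).any():
            raise ValueError("counts must be (n_cpg, 4) and non-negative")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class MethylationProfile:
    """Called methylation for one sample x amplicon."""

    amplicon: str
    counts: BaseCounts
    meth_pct: np.ndarray  # NaN where C+T == 0
    coverage: np.ndarray
    conversion_pct: float
    analyzed_cpgs: tuple[int, ...]
    n_pairs_retained: int = 0
    n_pairs_rejected: int = 0
    qc: "QCResult | None" = None


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def _per_pair_bases(aln: PairAlignment) -> dict[int, str]:
    """Reference position → observed base for one pair, mate 1 winning."""
    bases: dict[int, str] = {}
    for mate in (aln.mate2, aln.mate1):  # mate1 written last, wins overlaps
        for (t0, t1), (q0, q1) in mate.blocks:
            for k in range(t1 - t0):
                bases[t0 + k] = mate.read[q0 + k]
    return bases


def _tally_positions(
    alignments: list[PairAlignment], positions: np.ndarray
) -> np.ndarray:
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    index = {int(p): i for i, p in enumerate(positions)}
    for aln in alignments:
        for pos, base in _per_pair_bases(aln).items():
            i = index.get(pos)
            j = _BASE_INDEX.get(base)
            if i is not None and j is not None:
                counts[i, j] += 1
    return counts


def tally_cpg_bases(
    alignments: list[PairAlignment], ref: AmpliconReference
) -> BaseCounts:
    """Tally the four base frequencies at each CpG cytosine of ``ref``."""
    for aln in alignments:
        if aln.ref_name != ref.name:
            raise ValueError(f"alignment targets {aln.ref_name}, not {ref.name}")
    counts = _tally_positions(alignments, np.asarray(ref.cpg_positions, int))
    return BaseCounts(amplicon=ref.name, counts=counts)


def methylation_percentages(counts: BaseCounts) -> np.ndarray:
    """Per-site methylation percent, 100·C/(C+T); NaN where C+T = 0.

    A and G observations are excluded from the denominator (they reflect
    sequencing error or variation, not conversion state) but remain in the
    base-count report.
    """
    c = counts.counts[:, _BASE_INDEX["C"]].astype(float)
    t = counts.counts[:, _BASE_INDEX["T"]].astype(float)
    denom = c + t
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, 100.0 * c / denom, np.nan)
    return pct


def conversion_efficiency(
    alignments: list[PairAlignment], ref: AmpliconReference
) -> float:
    """Percent of non-CpG cytosines read as T, pooled over the amplicon."""
    positions = np.asarray(ref.non_cpg_c_positions, int)
    if positions.size == 0:
        raise ValueError(f"{ref.name} has no non-CpG cytosine")
    counts = _tally_positions(alignments, positions)
    c = counts[:, _BASE_INDEX["C"]].sum()
    t = counts[:, _BASE_INDEX["T"]].sum()
    if c + t == 0:
        raise ValueError("no covered non-CpG cytosine; conversion not computable")
    return float(100.0 * t / (c + t))


def qc_sample(
    profile: MethylationProfile,
    min_coverage: int = 100,
    min_conversion: float = 99.0,
) -> QCResult:
    """Coverage and conversion QC.

    Fails when any analyzed CpG is below ``min_coverage``x, or when
    conversion efficiency is not strictly greater than ``min_conversion``.
    """
    reasons = []
    for i in profile.analyzed_cpgs:
        if profile.coverage[i] < min_coverage:
            reasons.append(
                f"CpG{i + 1} coverage {profile.coverage[i]} < {min_coverage}"
            )
    if not profile.conversion_pct > min_conversion:
        reasons.append(
            f"conversion {profile.conversion_pct:.2f}% <= {min_conversion}%"
        )
    return QCResult(passed=not reasons, reasons=reasons)


def call_sample(
    pairs: list[ReadPair],
    refs: list[AmpliconReference],
    scoring: BisulfiteScoring = BisulfiteScoring(),
    min_coverage: int = 100,
    min_conversion: float = 99.0,
) -> tuple[dict[str, MethylationProfile], list[Rejection]]:
    """Align, tally, and QC one sample's read pairs against all references.

    Returns per-amplicon profiles (for amplicons with >= 1 retained pair)
    and the list of rejections.
    """
    by_ref: dict[str, list[PairAlignment]] = {}
    rejections: list[Rejection] = []
    for pair in pairs:
        res = bisulfite_align_pair(pair, refs, scoring)
        if isinstance(res, Rejection):
            rejections.append(res)
        else:
            by_ref.setdefault(res.ref_name, []).append(res)

    profiles: dict[str, MethylationProfile] = {}
    for ref in refs:
        alns = by_ref.get(ref.name, [])
        if not alns:
            continue
        counts = tally_cpg_bases(alns, ref)
        pct = methylation_percentages(counts)
        conv = conversion_efficiency(alns, ref)
        prof = MethylationProfile(
            amplicon=ref.name,
            counts=counts,
            meth_pct=pct,
            coverage=counts.coverage,
            conversion_pct=conv,
            analyzed_cpgs=ref.analyzed_cpgs,
            n_pairs_retained=len(alns),
            n_pairs_rejected=0,
        )
        prof.qc = qc_sample(prof, min_coverage, min_conversion)
        profiles[ref.name] = prof
    return profiles, rejections


def profiles_to_frame(
    sample: str, profiles: dict[str, MethylationProfile],
    refs: list[AmpliconReference],
) -> pd.DataFrame:
    """Long-format per-CpG call table (one row per analyzed CpG)."""
    ref_by_name = {r.name: r for r in refs}
    rows = []
    for name, prof in profiles.items():
        ref = ref_by_name[name]
        for i in prof.analyzed_cpgs:
            rows.append(
                {
                    "sample": sample,
                    "amplicon": name,
                    "cpg_index": i + 1,
                    "genomic_pos": ref.start + ref.cpg_positions[i],
                    "A": int(prof.counts.counts[i, 0]),
                    "C": int(prof.counts.counts[i, 1]),
                    "G": int(prof.counts.counts[i, 2]),
                    "T": int(prof.counts.counts[i, 3]),
                    "coverage": int(prof.coverage[i]),
                    "meth_pct": float(prof.meth_pct[i]),
                    "conversion_pct": prof.conversion_pct,
                    "qc_pass": bool(prof.qc.passed) if prof.qc else None,
                }
            )
    return pd.DataFrame(rows)
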