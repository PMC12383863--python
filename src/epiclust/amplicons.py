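"""Amplicon reference sequences and their CpG maps.

A targeted bisulfite-sequencing experiment amplifies a handful of short
genomic regions; methylation is quantified only at the CpG dinucleotides
inside each amplicon.  This module models one such region
(:class:`AmpliconReference`), generates synthetic references with an exact,
known CpG layout, and reads/writes them as FASTA plus a JSON sidecar
carrying the CpG coordinates and genome metadata.

The six study regions (intron 1 of *BDNF*, intron 7 of *FKBP5*, the *IGF2*
differentially methylated region, and the promoter, intron 1, and exon 3 of
*OXTR*) are available via :func:`study_references`.  Regions are keyed by
their hg19 coordinates; the exon-3 region carries 15 CpGs, intron 1 carries
13, and the promoter carries 9 of which 7 are analyzed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconReference",
    "make_amplicon_reference",
    "study_references",
    "find_cpg_sites",
    "write_references",
    "read_references",
    "STUDY_REGIONS",
]


def find_cpg_sites(sequence: str) -> list[int]:
    """Return 0-based offsets of the C of every CG dinucleotide."""
    out = []
    pos = sequence.find("CG")
    while pos != -1:
        out.append(pos)
        pos = sequence.find("CG", pos + 1)
    return out


@dataclass(frozen=True)
class AmpliconReference:
    """One amplified target region with its CpG site map.

    Parameters
    ----------
    name
        Short label, e.g. ``"BDNF"``.
    chrom, start, end
        Genomic metadata, 1-based inclusive as conventionally printed.
    sequence
        Uppercase A/C/G/T reference (bisulfite-unconverted top strand).
    cpg_positions
        Strictly increasing 0-based offsets of the C of each CG.
    analyzed_cpgs
        Indices (into ``cpg_positions``) of the CpGs included in analysis.
        Defaults to all sites; lets a region carry more CpGs than are
        reported (e.g. 7 of 9 in the OXTR promoter).
    """

    name: str
    chrom: str
    start: int
    end: int
    sequence: str
    cpg_positions: tuple[int, ...]
    analyzed_cpgs: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.name}: sequence must be uppercase A/C/G/T")
        found = tuple(find_cpg_sites(self.sequence))
        if found != tuple(self.cpg_positions):
            raise ValueError(
                f"{self.name}: declared cpg_positions {self.cpg_positions} "
                f"do not match the sequence's CG sites {found}"
            )
        if not self.analyzed_cpgs:
            object.__setattr__(
                self, "analyzed_cpgs", tuple(range(len(self.cpg_positions)))
            )
        if any(i < 0 or i >= len(self.cpg_positions) for i in self.analyzed_cpgs):
            raise ValueError(f"{self.name}: analyzed_cpgs out of range")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Offsets of cytosines outside CpG context (conversion controls)."""
        cpg = set(self.cpg_positions)
        return tuple(
            i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg
        )


def make_amplicon_reference(
    length: int,
    n_cpg: int,
    gc_frac: float = 0.5,
    seed: int = 0,
    name: str = "amplicon",
    chrom: str = "chrU",
    start: int = 1,
) -> AmpliconReference:
    """Generate a random amplicon with exactly ``n_cpg`` CG dinucleotides.

    CpG sites are placed uniformly at random (non-overlapping); the
    remaining positions are filled from a background with G+C fraction
    ``gc_frac``, then any accidental CG created by the fill is destroyed by
    mutating its G to A.  Deterministic given ``seed``.
    """
    if n_cpg < 0 or length < 2 * n_cpg:
        raise ValueError(f"cannot fit {n_cpg} CpGs in {length} bp")
    if not 0.0 <= gc_frac <= 1.0:
        raise ValueError("gc_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # Draw non-overlapping CpG start positions: stars-and-bars — choose
    # n_cpg sorted slots in [0, length - n_cpg) and shift each by its rank
    # so every CG block occupies two dedicated bases.
    if n_cpg:
        slots = np.sort(rng.choice(length - n_cpg, size=n_cpg, replace=False))
        cpg_pos = slots + np.arange(n_cpg)
    else:
        cpg_pos = np.array([], dtype=int)

    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    seq = rng.choice(bases, size=length, p=p)
    for pos in cpg_pos:
        seq[pos], seq[pos + 1] = "C", "G"

    # Destroy accidental CGs; repeat until the scan is clean because a fix
    # can in principle be adjacent to another C.
    reserved = set(int(x) for x in cpg_pos)
    for _ in range(length):
        dirty = [q for q in find_cpg_sites("".join(seq)) if q not in reserved]
        if not dirty:
            break
        for q in dirty:
            seq[q + 1] = "A"
    sequence = "".join(seq)

    return AmpliconReference(
        name=name,
        chrom=chrom,
        start=start,
        end=start + length - 1,
        sequence=sequence,
        cpg_positions=tuple(int(x) for x in cpg_pos),
    )


# Study regions (hg19), keyed by coordinates. Each entry:
# (label, chrom, start, end, total CpGs, analyzed CpG count)
STUDY_REGIONS: tuple[tuple[str, str, int, int, int, int], ...] = (
    ("BDNF", "chr11", 27723077, 27723244, 11, 11),      # intron 1
    ("FKBP5", "chr6", 35558405, 35558550, 3, 3),        # intron 7
    ("IGF2", "chr11", 2169373, 2169658, 5, 5),          # DMR
    ("OXTR_PR", "chr3", 8811488, 8811837, 9, 7),        # promoter, 7 of 9
    ("OXTR_I1", "chr3", 8810654, 8810919, 13, 13),      # intron 1
    ("OXTR_E3", "chr3", 8809340, 8809530, 15, 15),      # exon 3
)


def study_references(seed: int = 20_25) -> list[AmpliconReference]:
    """Synthetic stand-ins for the six study amplicons.

    Sequences are generated (the true genomic sequences are not bundled)
    but lengths, CpG counts, and genome coordinates match the study design.
    For the promoter region the first 7 of its 9 CpGs are analyzed.
    """
    refs = []
    for i, (label, chrom, start, end, n_cpg, n_analyzed) in enumerate(STUDY_REGIONS):
        ref = make_amplicon_reference(
            length=end - start + 1,
            n_cpg=n_cpg,
            gc_frac=0.5,
            seed=seed + i,
            name=label,
            chrom=chrom,
            start=start,
        )
        if n_analyzed < n_cpg:
            ref = AmpliconReference(
                name=ref.name, chrom=ref.chrom, start=ref.start, end=ref.end,
                sequence=ref.sequence, cpg_positions=ref.cpg_positions,
                analyzed_cpgs=tuple(range(n_analyzed)),
            )
        refs.append(ref)
    return refs


def write_references(refs: list[AmpliconReference], fasta: str | Path, sidecar: str | Path) -> None:
    """Write references as FASTA plus a JSON sidecar with CpG maps."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description=f"{r.chrom}:{r.start}-{r.end}")
        for r in refs
    ]
    SeqIO.write(records, str(fasta), "fasta")
    meta = {
        r.name: {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "cpg_positions": list(r.cpg_positions),
            "analyzed_cpgs": list(r.analyzed_cpgs),
        }
        for r in refs
    }
    Path(sidecar).write_text(json.dumps(meta, indent=1))


def read_references(fasta: str | Path, sidecar: str | Path) -> list[AmpliconReference]:
    meta = json.loads(Path(sidecar).read_text())
    refs = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        m = meta[rec.id]
        refs.append(
            AmpliconReference(
                name=rec.id,
                chrom=m["chrom"],
                start=m["start"],
                end=m["end"],
                sequence=str(rec.seq).upper(),
                cpg_positions=tuple(m["cpg_positions"]),
                analyzed_cpgs=tuple(m["analyzed_cpgs"]),
            )
        )
    return refs
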