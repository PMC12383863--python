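"""Simulation of paired-end reads from bisulfite-converted amplicons.

Each simulated template molecule is a full copy of one amplicon on the
original top strand.  Bisulfite chemistry is applied per molecule: a
methylated CpG cytosine is protected and stays C; an unmethylated cytosine
(CpG or not) is converted C→T with probability ``conversion_eff``.  Mate 1
is read from the 5' end of the converted strand, mate 2 from the 5' end of
its reverse complement, so with the default full-length insert the mates
overlap the whole amplicon.  Uniform substitution errors are applied last.
The per-molecule methylation states drawn are kept as a truth record so a
caller's output can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .amplicons import AmpliconReference

__all__ = ["ReadPair", "ReadPairSet", "simulate_bisulfite_pairs", "write_fastq_pairs"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
PHRED40 = "I"  # constant base quality, Phred+33


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str


@dataclass
class ReadPairSet:
    """Simulated pairs plus their per-molecule ground truth.

    ``truth_states`` has shape (n_pairs, n_cpg): the methylated/unmethylated
    state drawn for each CpG of each template molecule.
    """

    amplicon: str
    pairs: list[ReadPair]
    truth_states: np.ndarray
    truth_offsets: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __len__(self) -> int:
        return len(self.pairs)

    def truth_methylation_pct(self) -> np.ndarray:
        """Realized per-CpG methylation of the drawn molecules, in percent."""
        n = self.truth_states.shape[0]
        return 100.0 * self.truth_states.sum(axis=0) / n


def simulate_bisulfite_pairs(
    ref: AmpliconReference,
    meth: np.ndarray,
    conversion_eff: float = 1.0,
    error_rate: float = 0.0,
    n_pairs: int = 100,
    read_len: int | None = None,
    seed: int = 0,
    name_prefix: str | None = None,
) -> ReadPairSet:
    """Simulate ``n_pairs`` paired-end reads from one amplicon.

    Parameters
    ----------
    meth
        Per-CpG methylation probability, one entry per CpG of ``ref``.
    conversion_eff
        Probability that an unprotected cytosine is converted to T.
    error_rate
        Per-base probability of a uniform substitution error.
    read_len
        Mate length; defaults to the full amplicon length (overlapping
        mates). Must not exceed the amplicon length.
    """
    meth = np.asarray(meth, float)
    if meth.shape != (ref.n_cpg,):
        raise ValueError(f"meth must have one probability per CpG ({ref.n_cpg})")
    for val, label in ((conversion_eff, "conversion_eff"), (error_rate, "error_rate")):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1]")
    if ((meth < 0) | (meth > 1)).any():
        raise ValueError("meth probabilities must lie in [0, 1]")
    L = len(ref)
    if read_len is None:
        read_len = L
    if not 0 < read_len <= L:
        raise ValueError(f"read_len must lie in (0, {L}]")

    rng = np.random.default_rng(seed)
    seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
    cpg = np.asarray(ref.cpg_positions, int)
    is_c = seq == b"C"
    non_cpg_c = is_c.copy()
    non_cpg_c[cpg] = False

    states = rng.random((n_pairs, ref.n_cpg)) < meth  # True = methylated
    pairs: list[ReadPair] = []
    prefix = name_prefix or ref.name
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i in range(n_pairs):
        mol = seq.copy()
        # unprotected cytosines: all non-CpG Cs, plus unmethylated CpG Cs
        convert = non_cpg_c.copy()
        convert[cpg[~states[i]]] = True
        converted = convert & (rng.random(L) < conversion_eff)
        mol[converted] = b"T"

        m1 = mol[:read_len].copy()
        m2 = np.frombuffer(
            reverse_complement(mol.tobytes().decode())[:read_len].encode(), dtype="S1"
        ).copy()
        for mate in (m1, m2):
            err = rng.random(read_len) < error_rate
            if err.any():
                idx = np.flatnonzero(err)
                # substitute with a uniformly chosen different base
                shift = rng.integers(1, 4, size=idx.size)
                cur = np.searchsorted(bases, mate[idx])
                mate[idx] = bases[(cur + shift) % 4]
        pairs.append(
            ReadPair(
                name=f"{prefix}:{i}",
                mate1=m1.tobytes().decode(),
                qual1=PHRED40 * read_len,
                mate2=m2.tobytes().decode(),
                qual2=PHRED40 * read_len,
            )
        )
    return ReadPairSet(
        amplicon=ref.name,
        pairs=pairs,
        truth_states=states,
        truth_offsets=np.zeros(n_pairs, int),
    )


def write_fastq_pairs(
    sets: list[ReadPairSet],
    fastq1: str | Path,
    fastq2: str | Path,
    truth: str | Path | None = None,
) -> None:
    """Write mate-1/mate-2 FASTQ files (Phred+33) and an optional truth JSON."""
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for ps in sets:
            for p in ps.pairs:
                f1.write(f"@{p.name}/1\n{p.mate1}\n+\n{p.qual1}\n")
                f2.write(f"@{p.name}/2\n{p.mate2}\n+\n{p.qual2}\n")
    if truth is not None:
        payload = {
            ps.amplicon: {
                "states": ps.truth_states.astype(int).tolist(),
                "offsets": ps.truth_offsets.tolist(),
            }
            for ps in sets
        }
        Path(truth).write_text(json.dumps(payload))


def read_fastq_pairs(fastq1: str | Path, fastq2: str | Path) -> list[ReadPair]:
    """Read paired FASTQ files produced by :func:`write_fastq_pairs`."""

    def _records(path):
        out = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            out.append((lines[i][1:].rsplit("/", 1)[0], lines[i + 1], lines[i + 3]))
        return out

    r1, r2 = _records(fastq1), _records(fastq2)
    if len(r1) != len(r2):
        raise ValueError("mate files differ in record count")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(r1, r2):
        if n1 != n2:
            raise ValueError(f"mate name mismatch: {n1!r} vs {n2!r}")
        pairs.append(ReadPair(name=n1, mate1=s1, qual1=q1, mate2=s2, qual2=q2))
    return pairs
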