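"""Pileup construction, masked consensus calling and assembly statistics.

The consensus semantics re-implement the reference-guided assembly model:
per-position base tallies over {A,C,G,T,N}, a majority-base consensus that
can be masked on coverage depth and majority proportion, and an optional
second layer of SNP masking when the minor base exceeds a user proportion.
Contigs are maximal runs of covered positions; zero-depth positions split
contigs.  N read bases count toward depth but are excluded from majority
(and, downstream, discordance) denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ReadPlacement
from .records import SequenceRecord, encode, revcomp

__all__ = [
    "Pileup",
    "PileupColumn",
    "MaskPolicy",
    "ConsensusContig",
    "build_pileup",
    "call_consensus",
    "consensus_string",
    "assembly_stats",
]

_BASES = "ACGTN"

# IUPAC two-base ambiguity codes, used when snp_mask_mode == "IUPAC"
_IUPAC2 = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}


@dataclass
class PileupColumn:
    """Per-position tallies; a convenience view into a Pileup."""

    ref_id: str
    pos: int
    counts: dict
    depth: int
    consensus_base: str | None = None


class Pileup:
    """Base tallies for one reference: a 5 x L count matrix (ACGTN rows)."""

    def __init__(self, ref_id: str, length: int):
        self.ref_id = ref_id
        self.counts = np.zeros((5, length), dtype=np.int64)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        """Total depth per position (N read bases included)."""
        return self.counts.sum(axis=0)

    @property
    def acgt_counts(self) -> np.ndarray:
        return self.counts[:4]

    def column(self, pos: int) -> PileupColumn:
        col = self.counts[:, pos]
        return PileupColumn(
            ref_id=self.ref_id,
            pos=pos,
            counts={b: int(col[i]) for i, b in enumerate(_BASES)},
            depth=int(col.sum()),
        )


@dataclass
class MaskPolicy:
    """Masking thresholds for consensus calling.

    A position is masked to N when its depth is below ``min_depth`` or the
    majority base holds less than ``min_major_proportion`` of the non-N
    calls.  With SNP masking on, a second base at proportion
    ``snp_min_minor_proportion`` or more masks the position to N
    (``snp_mask_mode='N'``) or to the two-base IUPAC code (``'IUPAC'``).
    """

    min_depth: int = 3
    min_major_proportion: float = 0.7
    snp_min_minor_proportion: float = 0.2
    snp_mask_mode: str = "N"  # N | IUPAC | off

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("min_major_proportion", "snp_min_minor_proportion"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.snp_mask_mode not in ("N", "IUPAC", "off"):
            raise ValueError("snp_mask_mode must be 'N', 'IUPAC' or 'off'")


@dataclass
class ConsensusContig:
    """A maximal run of covered positions with its masked consensus."""

    ref_id: str
    start: int
    end: int  # half-open
    sequence: str
    median_depth: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("contig end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length != span length")

    def __len__(self) -> int:
        return self.end - self.start


def build_pileup(
    placements: Iterable[ReadPlacement],
    reads: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    reference: SequenceRecord,
) -> Pileup:
    """Tally aligned read bases per reference position.

    Each aligned base (reverse-complemented for minus-strand placements)
    increments exactly one column.  Positions wrap modulo the reference
    length for circular references; on a linear reference a placement
    overrunning the end is an error.
    """
    if not isinstance(reads, Mapping):
        reads = {r.id: r for r in reads}
    L = len(reference.bases)
    pileup = Pileup(reference.id, L)
    for p in placements:
        if p.ref_id != reference.id:
            raise ValueError(f"placement on {p.ref_id!r}, expected {reference.id!r}")
        rec = reads[p.read_id]
        oriented = rec.bases if p.strand == "+" else revcomp(rec.bases)
        seg = oriented[p.read_start : p.read_start + p.aligned_length]
        codes = encode(seg)
        if reference.circular:
            pos = (p.ref_start + np.arange(p.aligned_length)) % L
        else:
            if p.ref_start + p.aligned_length > L:
                raise ValueError(
                    f"placement of {p.read_id!r} overruns linear reference end"
                )
            pos = np.arange(p.ref_start, p.ref_start + p.aligned_length)
        np.add.at(pileup.counts, (codes, pos), 1)
    return pileup


def _consensus_chars(pileup: Pileup, policy: MaskPolicy):
    """Per-position consensus characters plus covered/tie flags."""
    acgt = pileup.acgt_counts
    depth = pileup.depth
    covered = depth > 0
    acgt_sum = acgt.sum(axis=0)

    order = np.argsort(-acgt, axis=0, kind="stable")  # stable: A<C<G<T tie-break
    major_idx = order[0]
    second_idx = order[1]
    major_count = np.take_along_axis(acgt, major_idx[None, :], axis=0)[0]
    second_count = np.take_along_axis(acgt, second_idx[None, :], axis=0)[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        major_prop = np.where(acgt_sum > 0, major_count / np.maximum(acgt_sum, 1), 0.0)
        minor_prop = np.where(acgt_sum > 0, second_count / np.maximum(acgt_sum, 1), 0.0)

    chars = np.full(pileup.length, "N", dtype="<U1")
    base_arr = np.array(list("ACGT"))
    chars[covered & (acgt_sum > 0)] = base_arr[major_idx[covered & (acgt_sum > 0)]]

    masked = (depth < policy.min_depth) | (major_prop < policy.min_major_proportion)
    chars[covered & masked] = "N"

    if policy.snp_mask_mode != "off":
        snp = covered & ~masked & (minor_prop >= policy.snp_min_minor_proportion)
        if policy.snp_mask_mode == "N":
            chars[snp] = "N"
        else:
            for i in np.flatnonzero(snp):
                pair = frozenset((base_arr[major_idx[i]], base_arr[second_idx[i]]))
                chars[i] = _IUPAC2[pair]

    ties = covered & (major_count == second_count) & (acgt_sum > 0)
    return chars, covered, ties


def call_consensus(pileup: Pileup, policy: MaskPolicy) -> list[ConsensusContig]:
    """Masked consensus over maximal runs of covered positions."""
    chars, covered, _ = _consensus_chars(pileup, policy)
    depth = pileup.depth
    contigs: list[ConsensusContig] = []
    if not covered.any():
        return contigs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        contigs.append(
            ConsensusContig(
                ref_id=pileup.ref_id,
                start=int(start),
                end=int(end),
                sequence="".join(chars[start:end]),
                median_depth=float(np.median(depth[start:end])),
            )
        )
    return contigs


def consensus_string(pileup: Pileup, policy: MaskPolicy | None = None) -> str:
    """Full-length consensus (uncovered positions as N).

    With ``policy=None`` this is the plain majority consensus with no
    masking, which is what the discordance computation measures against.
    """
    if policy is None:
        policy = MaskPolicy(min_depth=1, min_major_proportion=1e-9,
                            snp_mask_mode="off")
    chars, _, _ = _consensus_chars(pileup, policy)
    return "".join(chars)


def assembly_stats(contigs: Sequence[ConsensusContig], pileup: Pileup) -> dict:
    """Contig count, N50, longest contig, and median covered-position depth.

    N50 is the length L such that contigs of length >= L together hold at
    least half of the total contig length (descending cumulative sum).
    """
    if not contigs:
        raise ValueError("no contigs")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for length in lengths:
        acc += length
        if acc * 2 >= total:
            n50 = length
            break
    depth = pileup.depth
    covered = depth > 0
    return {
        "n_contigs": len(contigs),
        "n50": int(n50),
        "longest": int(lengths[0]),
        "median_depth": float(np.median(depth[covered])),
    }
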