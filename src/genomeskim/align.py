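"""Ungapped seed-and-extend placement of short reads on references.

The matcher indexes exact k-mers of the reference(s), collects candidate
diagonals from seed hits on both strands, and scores each diagonal by
gapless extension over the full read.  Placements at or above the identity
cutoff are reported best-first, with ties broken by (lower reference
position, + strand).  There is no gapped or banded alignment: at 40 nt
read lengths a placement spanning a true indel simply fails the identity
threshold, which is the intended behavior for consensus work.

Circular references are handled by doubling the encoded sequence; seed
positions are restricted to the first copy and reported positions are
modulo the reference length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import SequenceRecord, encode, revcomp

__all__ = ["ReadPlacement", "ReferenceIndex", "place_reads"]

_N_CODE = 4


@dataclass
class ReadPlacement:
    """A read's gapless mapping to a reference.

    ``ref_start`` is 0-based; ``read_start`` is the offset of the aligned
    block within the read *in reference orientation* (nonzero only when a
    read overhangs a linear reference end).  Identity counts N bases on
    either side as mismatches.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    aligned_length: int
    matches: int
    identity: float
    read_start: int = 0

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError("ref_start must be >= 0")
        if self.matches > self.aligned_length:
            raise ValueError("matches cannot exceed aligned_length")


class ReferenceIndex:
    """Exact k-mer index over one or more reference sequences.

    Parameters
    ----------
    references : sequence of SequenceRecord
    seed_len : int
        k-mer size; must be >= 4 (smaller seeds make the index degenerate).
    honor_soft_mask : bool
        Skip seeds overlapping soft-masked (lower-case-in-source) or N
        positions when building the index.  Extension still uses the full
        upper-case sequence, so masking suppresses seeding only.
    """

    def __init__(
        self,
        references: Sequence[SequenceRecord],
        seed_len: int = 11,
        honor_soft_mask: bool = False,
    ) -> None:
        if seed_len < 4:
            raise ValueError("seed_len < 4: degenerate index")
        self.references = list(references)
        self.seed_len = seed_len
        self._enc: list[np.ndarray] = []
        self._reflen: list[int] = []
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        k = seed_len
        for ri, rec in enumerate(self.references):
            L = len(rec.bases)
            seq = rec.bases + rec.bases if rec.circular else rec.bases
            self._enc.append(encode(seq))
            self._reflen.append(L)
            raw = rec.bases.encode("ascii")
            n_pos = {i for i, b in enumerate(rec.bases) if b == "N"}
            masked = set()
            if honor_soft_mask and rec.soft_mask is not None:
                masked = set(np.flatnonzero(rec.soft_mask).tolist())
            limit = L if rec.circular else L - k + 1
            doubled = raw + raw if rec.circular else raw
            for i in range(max(limit, 0)):
                window = range(i, i + k)
                if any((j % L) in n_pos or (j % L) in masked for j in window):
                    continue
                kmer = doubled[i : i + k]
                self._index.setdefault(kmer, []).append((ri, i))

    # -- mapping ----------------------------------------------------------

    def _extend(self, ri: int, diag: int, enc_read: np.ndarray):
        """Gapless extension of the full read along one diagonal."""
        L = self._reflen[ri]
        Lr = len(enc_read)
        ref = self._enc[ri]
        if self.references[ri].circular:
            d = diag % L
            ref_seg = ref[d : d + Lr]
            read_seg = enc_read
            ref_start, read_start = d, 0
        else:
            s = max(diag, 0)
            e = min(diag + Lr, L)
            if e - s < self.seed_len:
                return None
            ref_seg = ref[s:e]
            read_seg = enc_read[s - diag : e - diag]
            ref_start, read_start = s, s - diag
        valid = (ref_seg != _N_CODE) & (read_seg != _N_CODE)
        matches = int(np.count_nonzero((ref_seg == read_seg) & valid))
        aligned = len(read_seg)
        return ref_start, read_start, aligned, matches

    def map_read(
        self,
        bases: str,
        min_identity: float = 0.85,
        max_hits: int = 1,
        read_id: str = "",
    ) -> list[ReadPlacement]:
        k = self.seed_len
        L = len(bases)
        if L < k:
            return []
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        candidates = []
        seen: set[tuple[int, int, str]] = set()
        for strand in "+-":
            s = bases if strand == "+" else revcomp(bases)
            raw = s.encode("ascii")
            enc_read = encode(s)
            for o in offsets:
                hits = self._index.get(raw[o : o + k])
                if not hits:
                    continue
                for ri, p in hits:
                    diag = p - o
                    norm = diag % self._reflen[ri] if self.references[ri].circular else diag
                    key = (ri, norm, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    ext = self._extend(ri, diag, enc_read)
                    if ext is None:
                        continue
                    ref_start, read_start, aligned, matches = ext
                    identity = matches / aligned
                    if identity >= min_identity:
                        candidates.append(
                            ReadPlacement(
                                read_id=read_id,
                                ref_id=self.references[ri].id,
                                ref_start=ref_start,
                                strand=strand,
                                aligned_length=aligned,
                                matches=matches,
                                identity=identity,
                                read_start=read_start,
                            )
                        )
        candidates.sort(
            key=lambda p: (-p.identity, p.ref_start, 0 if p.strand == "+" else 1, p.ref_id)
        )
        return candidates[:max_hits]


def place_reads(
    reads: Iterable[SequenceRecord],
    reference: SequenceRecord,
    seed_len: int = 11,
    min_identity: float = 0.85,
    max_hits_per_read: int = 1,
) -> list[ReadPlacement]:
    """Place reads on a single reference; see ReferenceIndex.map_read."""
    index = ReferenceIndex([reference], seed_len=seed_len)
    placements = []
    for rec in reads:
        placements.extend(
            index.map_read(
                rec.bases,
                min_identity=min_identity,
                max_hits=max_hits_per_read,
                read_id=rec.id,
            )
        )
    return placements
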