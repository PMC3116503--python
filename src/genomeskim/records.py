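"""Core sequence containers and nucleotide utilities.

All sequences are held as upper-case strings over the 5-letter alphabet
{A, C, G, T, N}.  Anything else (IUPAC ambiguity codes, gaps that slipped
through) is mapped to N; a module-level counter records how often that
happened so callers can warn.  Internal coordinates are 0-based half-open
throughout the package; human-readable reports convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceRecord",
    "revcomp",
    "encode",
    "decode",
    "ambiguous_replaced_count",
    "reset_ambiguous_counter",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = set("ACGTN")

# base -> small integer code; everything non-ACGT is 4 (N)
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# counts characters outside {A,C,G,T,N} replaced by N on ingestion
_ambiguous_replaced = 0


def ambiguous_replaced_count() -> int:
    return _ambiguous_replaced


def reset_ambiguous_counter() -> None:
    global _ambiguous_replaced
    _ambiguous_replaced = 0


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode bases as uint8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence with optional per-base Phred scores.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA/FASTQ header token up to first whitespace).
    bases : str
        Nucleotides; normalized to upper-case ACGTN on construction.
    quality : list of int, optional
        Phred scores, one per base.
    circular : bool
        Whether the sequence is a circular molecule (plastome-style).
    soft_mask : numpy bool array, optional
        True at positions that were lower-case in the source file
        (RepeatMasker-style soft masking); honored by seeding, not extension.
    """

    id: str
    bases: str
    quality: list[int] | None = None
    circular: bool = False
    soft_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        global _ambiguous_replaced
        s = self.bases
        if s != s.upper():
            if self.soft_mask is None:
                arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                self.soft_mask = (arr >= ord("a")) & (arr <= ord("z"))
            s = s.upper()
        if not set(s) <= _VALID:
            cleaned = []
            for ch in s:
                if ch in _VALID:
                    cleaned.append(ch)
                else:
                    cleaned.append("N")
                    _ambiguous_replaced += 1
            s = "".join(cleaned)
        self.bases = s
        if self.quality is not None:
            if len(self.quality) != len(self.bases):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if any(q < 0 for q in self.quality):
                raise ValueError(
                    f"record {self.id!r}: negative Phred score "
                    "(wrong FASTQ offset?)"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.quality is None else list(reversed(self.quality))
        mask = None if self.soft_mask is None else self.soft_mask[::-1].copy()
        return SequenceRecord(
            self.id, revcomp(self.bases), qual, self.circular, mask
        )
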