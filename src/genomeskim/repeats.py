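"""SSR detection, genomic repeat pairs, plastome IR structure, repeat-library hits.

The microsatellite scanner reports maximal *perfect* tandem repeats of
2-6 nt motifs: di- and trinucleotide runs of >= 4 units, tetra- through
hexanucleotide runs of >= 3 units.  A run is attributed to its shortest
period ((TA)6 is a dinucleotide locus, never a hexanucleotide one) and
mononucleotide runs are never SSRs.  Reported motifs preserve the
observed strand; the lexicographically-least rotation is kept alongside
for class bookkeeping.

Genomic repeats (direct and inverted self-matches above a length and
identity threshold) are found by exact seeding and gapless X-drop
extension of the sequence against itself and its reverse complement.
The quadripartite plastome structure (LSC / IRa / SSC / IRb) falls out
as the longest high-identity inverted self-match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ReferenceIndex
from .records import SequenceRecord, encode, revcomp

__all__ = [
    "SsrLocus",
    "RepeatPair",
    "QuadripartiteStructure",
    "DEFAULT_MIN_UNITS",
    "scan_ssrs",
    "ssr_primer_feasibility",
    "find_repeats",
    "detect_quadripartite",
    "classify_vs_repeat_library",
    "pairwise_identity",
]

#: minimum repeat units per motif length: di/tri >= 4, tetra/penta/hexa >= 3
DEFAULT_MIN_UNITS = {2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


def _min_period(motif: str) -> int:
    for q in range(1, len(motif) + 1):
        if all(motif[i] == motif[i - q] for i in range(q, len(motif))):
            return q
    return len(motif)


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


@dataclass
class SsrLocus:
    """A perfect microsatellite: span = n_units full copies of the motif."""

    contig_id: str
    start: int
    end: int  # half-open
    motif: str  # canonical (lexicographically least rotation)
    motif_observed: str  # as read off the contig at `start`
    n_units: int
    perfect: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif_observed) * self.n_units:
            raise ValueError("span length != motif length x n_units")


def scan_ssrs(
    contigs: list[SequenceRecord],
    min_units: dict[int, int] | None = None,
    min_contig_len: int = 150,
) -> list[SsrLocus]:
    """Maximal perfect tandem repeats in contigs of at least min_contig_len.

    The per-contig result is independent of contig order; loci are
    reported per occurrence (several per contig allowed, e.g. compound
    TC4...TA4 arrangements come out as two loci).
    """
    min_units = dict(DEFAULT_MIN_UNITS if min_units is None else min_units)
    loci: list[SsrLocus] = []
    for rec in contigs:
        if len(rec.bases) < min_contig_len:
            continue
        s = rec.bases
        a = encode(s)
        for p, need in sorted(min_units.items()):
            if len(s) < 2 * p:
                continue
            eq = (a[:-p] == a[p:]) & (a[:-p] != 4)
            if not eq.any():
                continue
            padded = np.concatenate(([0], eq.view(np.int8), [0]))
            edges = np.flatnonzero(np.diff(padded))
            for i0, i1 in zip(edges[::2], edges[1::2]):
                region_len = int(i1 - i0) + p
                n = region_len // p
                if n < need:
                    continue
                motif = s[i0 : i0 + p]
                if _min_period(motif) != p:
                    continue
                loci.append(
                    SsrLocus(
                        contig_id=rec.id,
                        start=int(i0),
                        end=int(i0) + n * p,
                        motif=_canonical_rotation(motif),
                        motif_observed=motif,
                        n_units=n,
                    )
                )
    loci.sort(key=lambda l: (l.contig_id, l.start, len(l.motif_observed)))
    return loci


def ssr_primer_feasibility(
    locus: SsrLocus,
    contig: SequenceRecord,
    product_range: tuple[int, int] = (100, 450),
    min_flank: int = 18,
) -> bool:
    """Whether a PCR window of product_range length can contain the locus.

    Feasible iff some window whose total length lies in ``product_range``
    fits inside the contig, contains the locus, and leaves at least
    ``min_flank`` nt of flank on each side (room for a primer).  No primer
    design is attempted.
    """
    L = len(contig.bases)
    if not (0 <= locus.start and locus.end <= L):
        raise ValueError("locus lies outside contig")
    if locus.start < min_flank or L - locus.end < min_flank:
        return False
    needed = max(product_range[0], (locus.end - locus.start) + 2 * min_flank)
    return needed <= min(product_range[1], L)


@dataclass
class RepeatPair:
    """Two high-identity spans of one sequence (direct or inverted)."""

    kind: str  # direct | inverted
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise ValueError("kind must be 'direct' or 'inverted'")
        if self.span_a == self.span_b:
            raise ValueError("repeat spans must differ")


def _xdrop_extend(match: np.ndarray, lo: int, hi: int,
                  mismatch_penalty: int = 3, xdrop: int = 12):
    """Extend [lo, hi) over a boolean match vector, trimming to best score."""
    # right
    best, score, end = 0, 0, hi
    i = hi
    n = len(match)
    while i < n:
        score += 1 if match[i] else -mismatch_penalty
        if score > best:
            best, end = score, i + 1
        if best - score > xdrop:
            break
        i += 1
    # left
    best, score, start = 0, 0, lo
    i = lo - 1
    while i >= 0:
        score += 1 if match[i] else -mismatch_penalty
        if score > best:
            best, start = score, i
        if best - score > xdrop:
            break
        i -= 1
    return start, end


def _diag_seeds(seq: str, other: str, k: int) -> dict[int, list[int]]:
    """Seed offsets per diagonal for seq vs other (exact k-mer matches)."""
    pos: dict[str, list[int]] = {}
    for j in range(len(other) - k + 1):
        kmer = other[j : j + k]
        if "N" in kmer:
            continue
        pos.setdefault(kmer, []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        hits = pos.get(kmer)
        if not hits:
            continue
        for j in hits:
            diags.setdefault(j - i, []).append(i)
    return diags


def find_repeats(
    sequence: SequenceRecord | str,
    min_len: int = 30,
    min_identity: float = 0.85,
    kinds: tuple = ("direct", "inverted"),
    seed_len: int = 12,
    strict_greater: bool = True,
) -> list[RepeatPair]:
    """Maximal gapless self-matches above the length/identity thresholds.

    The length rule follows the "greater than min_len" wording strictly
    by default; set ``strict_greater=False`` for >=.  The self-diagonal is
    excluded and mirrored duplicates are collapsed.
    """
    s = sequence.bases if isinstance(sequence, SequenceRecord) else sequence
    if len(s) < 2 * min_len:
        raise ValueError("sequence shorter than twice min_len")
    a = encode(s)
    n = len(s)
    results: dict[tuple, RepeatPair] = {}

    def _harvest(diags: dict[int, list[int]], arr_b: np.ndarray, kind: str):
        for d, seeds in diags.items():
            if kind == "direct" and d <= 0:
                continue  # self-diagonal and mirrored (negative) diagonals
            base = max(0, -d)  # first valid position in `a` on this diagonal
            span = min(n, len(arr_b) - d)  # one past the last valid position
            if span - base < seed_len:
                continue
            seg_a = a[base:span]
            seg_b = arr_b[base + d : span + d]
            m = (seg_a == seg_b) & (seg_a != 4) & (seg_b != 4)
            seeds = sorted(x - base for x in seeds)
            covered_to = -1
            for off in seeds:
                if off < covered_to:
                    continue
                st, en = _xdrop_extend(m, off, off + seed_len)
                covered_to = en
                length = en - st
                ok_len = length > min_len if strict_greater else length >= min_len
                if not ok_len:
                    continue
                identity = float(np.count_nonzero(m[st:en])) / length
                if identity < min_identity:
                    continue
                a_span = (base + st, base + en)
                if kind == "direct":
                    b_span = (a_span[0] + d, a_span[1] + d)
                else:
                    jb = (base + st + d, base + en + d)  # coords in revcomp
                    b_span = (n - jb[1], n - jb[0])
                if a_span == b_span:
                    continue
                x_span, y_span = sorted((a_span, b_span))
                key = (kind, x_span, y_span)
                prev = results.get(key)
                if prev is None or length > prev.length:
                    results[key] = RepeatPair(kind, x_span, y_span, length, identity)

    if "direct" in kinds:
        _harvest(_diag_seeds(s, s, seed_len), a, "direct")
    if "inverted" in kinds:
        rc = revcomp(s)
        _harvest(_diag_seeds(s, rc, seed_len), encode(rc), "inverted")

    pairs = list(results.values())
    # drop pairs fully contained in a longer pair of the same kind
    pairs.sort(key=lambda r: -r.length)
    kept: list[RepeatPair] = []
    for r in pairs:
        contained = any(
            k.kind == r.kind
            and k.span_a[0] <= r.span_a[0] and r.span_a[1] <= k.span_a[1]
            and k.span_b[0] <= r.span_b[0] and r.span_b[1] <= k.span_b[1]
            for k in kept
        )
        if not contained:
            kept.append(r)
    kept.sort(key=lambda r: (r.span_a, r.span_b, r.kind))
    return kept


@dataclass
class QuadripartiteStructure:
    """LSC / IR / SSC arc lengths of a circular plastome."""

    lsc_len: int
    ir_len: int
    ssc_len: int
    has_ir: bool
    boundaries: dict = field(default_factory=dict)


def detect_quadripartite(
    plastome: SequenceRecord,
    min_ir_len: int = 1000,
    min_ir_identity: float = 0.99,
    seed_len: int = 20,
) -> QuadripartiteStructure:
    """Resolve the quadripartite structure from the longest inverted repeat.

    The two arcs between the IR arms are labeled LSC (longer) and SSC
    (shorter).  With no inverted self-match of at least ``min_ir_len`` the
    result reports ``has_ir=False`` rather than raising.  The sequence is
    expected to be circular-flagged and linearized outside the IR (an IR
    arm crossing the chosen origin is not resolved).
    """
    if not plastome.circular:
        raise ValueError("plastome must be circular-flagged")
    L = len(plastome.bases)
    pairs = [
        p
        for p in find_repeats(
            plastome,
            min_len=min_ir_len - 1,
            min_identity=min_ir_identity,
            kinds=("inverted",),
            seed_len=seed_len,
        )
        if p.length >= min_ir_len
    ]
    if not pairs:
        return QuadripartiteStructure(0, 0, 0, has_ir=False)
    best = max(pairs, key=lambda p: p.length)
    (a0, a1), (b0, b1) = sorted((best.span_a, best.span_b))
    ir_len = best.length
    inner = b0 - a1
    outer = L - b1 + a0
    lsc, ssc = max(inner, outer), min(inner, outer)
    return QuadripartiteStructure(
        lsc_len=lsc,
        ir_len=ir_len,
        ssc_len=ssc,
        has_ir=True,
        boundaries={"ira": (a0, a1), "irb": (b0, b1)},
    )


def _family(ref_id: str) -> str:
    if ":" in ref_id:
        return ref_id.split(":", 1)[0]
    return ref_id


def classify_vs_repeat_library(
    queries: list[SequenceRecord],
    library: list[SequenceRecord],
    min_identity: float = 0.70,
    seed_len: int = 11,
):
    """Fraction of queries hitting a repeat library, plus per-family counts.

    A query counts once toward the overall fraction however many elements
    it hits, and once per family it touches (library ids follow the
    ``family:element`` label convention).
    """
    if not library:
        raise ValueError("repeat library must be non-empty")
    index = ReferenceIndex(library, seed_len=seed_len)
    n_hit = 0
    per_family: dict[str, int] = {}
    for rec in queries:
        hits = index.map_read(
            rec.bases, min_identity=min_identity, max_hits=len(library)
        )
        if not hits:
            continue
        n_hit += 1
        for fam in {_family(h.ref_id) for h in hits}:
            per_family[fam] = per_family.get(fam, 0) + 1
    fraction = n_hit / len(queries) if queries else 0.0
    return fraction, per_family


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity between two aligned sequences with gapped columns removed."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    matches = 0
    cols = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        raise ValueError("no ungapped columns: identity undefined")
    return matches / cols
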