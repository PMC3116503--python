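"""Read cleaning: N-read removal, adapter-read removal, unscorable-tail trimming.

The cleaning model is the two-pool scheme used for GAII-era skims: a
"cleaned" pool (N-containing and adapter-matching reads removed) feeds
de-novo-style analyses, and a "cleaned and trimmed" pool additionally
truncates each read at its first unscorable base (Illumina quality "B",
generalized here to quality <= Q2) and everything after it.  Reads
truncated to nothing are dropped and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SequenceRecord, encode, revcomp

__all__ = ["QcReport", "remove_n_and_adapter", "trim_quality_tails", "run_qc"]


@dataclass
class QcReport:
    n_input: int = 0
    n_removed_N: int = 0
    n_removed_adapter: int = 0
    n_emptied_by_trimming: int = 0
    retained_fraction_after_trimming: float = 1.0
    bases_in: int = 0
    bases_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _matches_adapter(bases: str, adapter: str, min_match: int, min_identity: float) -> bool:
    """True if any ungapped overlap of >= min_match nt reaches min_identity.

    Both read orientations are checked.  Overlaps slide the adapter across
    the read at every offset (adapter may hang off either end).
    """
    enc_ad = encode(adapter)
    la = len(adapter)
    for oriented in (bases, revcomp(bases)):
        enc_rd = encode(oriented)
        lr = len(oriented)
        for shift in range(-(la - min_match), lr - min_match + 1):
            a0 = max(0, -shift)
            r0 = max(0, shift)
            n = min(la - a0, lr - r0)
            if n < min_match:
                continue
            seg_a = enc_ad[a0 : a0 + n]
            seg_r = enc_rd[r0 : r0 + n]
            matches = int(np.count_nonzero((seg_a == seg_r) & (seg_a != 4) & (seg_r != 4)))
            if matches / n >= min_identity:
                return True
    return False


def remove_n_and_adapter(
    reads: list[SequenceRecord],
    adapter: str | None = "AGATCGGAAGAGC",
    adapter_min_match: int = 10,
    adapter_min_identity: float = 0.9,
) -> tuple[list[SequenceRecord], QcReport]:
    """Drop reads containing any N, then reads matching the adapter.

    Survivor order is preserved; reads are never modified.  Pass
    ``adapter=None`` to disable adapter filtering.
    """
    report = QcReport(n_input=len(reads))
    kept = []
    for rec in reads:
        report.bases_in += len(rec.bases)
        if "N" in rec.bases:
            report.n_removed_N += 1
            continue
        if adapter and _matches_adapter(
            rec.bases, adapter, adapter_min_match, adapter_min_identity
        ):
            report.n_removed_adapter += 1
            continue
        kept.append(rec)
        report.bases_out += len(rec.bases)
    return kept, report


def trim_quality_tails(
    reads: list[SequenceRecord], unscorable_q: int = 2
) -> tuple[list[SequenceRecord], QcReport]:
    """Truncate each read at its first quality <= unscorable_q base.

    All bases from the first unscorable position onward are removed.
    Reads reduced to length zero are dropped and counted as emptied.
    ``retained_fraction_after_trimming`` is bases_out / bases_in over the
    input pool.
    """
    report = QcReport(n_input=len(reads))
    kept = []
    for rec in reads:
        if rec.quality is None:
            raise ValueError(
                f"read {rec.id!r} carries no qualities; skip quality trimming "
                "for quality-less pools"
            )
        report.bases_in += len(rec.bases)
        cut = len(rec.bases)
        for i, q in enumerate(rec.quality):
            if q <= unscorable_q:
                cut = i
                break
        if cut == 0:
            report.n_emptied_by_trimming += 1
            continue
        if cut == len(rec.bases):
            kept.append(rec)
        else:
            kept.append(SequenceRecord(rec.id, rec.bases[:cut], rec.quality[:cut]))
        report.bases_out += cut
    report.retained_fraction_after_trimming = (
        report.bases_out / report.bases_in if report.bases_in else 1.0
    )
    return kept, report


def run_qc(reads, adapter="AGATCGGAAGAGC", adapter_min_match=10,
           adapter_min_identity=0.9, unscorable_q=2):
    """Full cleaning: returns (cleaned, cleaned_and_trimmed, merged report)."""
    cleaned, rep1 = remove_n_and_adapter(
        reads, adapter, adapter_min_match, adapter_min_identity
    )
    trimmed, rep2 = trim_quality_tails(cleaned, unscorable_q)
    report = QcReport(
        n_input=rep1.n_input,
        n_removed_N=rep1.n_removed_N,
        n_removed_adapter=rep1.n_removed_adapter,
        n_emptied_by_trimming=rep2.n_emptied_by_trimming,
        retained_fraction_after_trimming=rep2.retained_fraction_after_trimming,
        bases_in=rep1.bases_in,
        bases_out=rep2.bases_out,
    )
    return cleaned, trimmed, report
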