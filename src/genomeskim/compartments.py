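"""Compartment classification, genome coverage and copy-number arithmetic.

A genome skim saturates only the high-copy fraction: organellar genomes
and rDNA arrays.  Classifying reads against labeled reference sets gives
the per-compartment read fractions; combined with the sequencing yield and
a flow-cytometry genome size those fractions give overall and nuclear
coverage, and the ratio of a repeat's median read depth to the nuclear
coverage estimates its copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import ReferenceIndex
from .records import SequenceRecord

__all__ = [
    "CompartmentSummary",
    "CoverageEstimate",
    "classify_reads",
    "estimate_genome_coverage",
    "estimate_copy_number",
    "pg_to_mbp",
]

#: 1 pg of DNA corresponds to 978 Mbp
PG_TO_MBP = 978.0

#: fixed classification priority: organelles first, then rDNA, then control;
#: anything unmatched is nuclear/unclassified
PRIORITY = ("chloroplast", "mitochondrial", "rdna", "control")


@dataclass
class CompartmentSummary:
    per_compartment: dict  # label -> {"n_reads", "fraction", "bases"}
    total_reads: int
    total_bases: int
    assignments: list = field(default_factory=list, repr=False)

    def fraction(self, label: str) -> float:
        return self.per_compartment.get(label, {}).get("fraction", 0.0)


def classify_reads(
    reads: list[SequenceRecord],
    compartment_refs: dict,
    seed_len: int = 11,
    min_identity: float = 0.90,
) -> CompartmentSummary:
    """Assign each read to the first compartment where it places.

    ``compartment_refs`` maps label -> list of reference SequenceRecords.
    Labels are tried in the fixed priority order (chloroplast,
    mitochondrial, rDNA, control, then any extra labels such as a
    contaminant set, in insertion order); a read matching several
    compartments keeps the first, mirroring sequential read removal and
    resolving e.g. plastid-derived mitochondrial insertions
    deterministically.  Unmatched reads are 'nuclear'.
    """
    if not compartment_refs:
        raise ValueError("at least one labeled reference set is required")
    ordered = [c for c in PRIORITY if c in compartment_refs]
    ordered += [c for c in compartment_refs if c not in PRIORITY]
    indexes = {
        label: ReferenceIndex(refs, seed_len=seed_len)
        for label, refs in compartment_refs.items()
    }
    counts = {label: {"n_reads": 0, "bases": 0} for label in ordered}
    counts["nuclear"] = {"n_reads": 0, "bases": 0}
    assignments = []
    total_bases = 0
    for rec in reads:
        total_bases += len(rec.bases)
        assigned = "nuclear"
        for label in ordered:
            if indexes[label].map_read(rec.bases, min_identity=min_identity, max_hits=1):
                assigned = label
                break
        counts[assigned]["n_reads"] += 1
        counts[assigned]["bases"] += len(rec.bases)
        assignments.append((rec.id, assigned))
    n = len(reads)
    per = {
        label: {
            "n_reads": c["n_reads"],
            "fraction": c["n_reads"] / n if n else 0.0,
            "bases": c["bases"],
        }
        for label, c in counts.items()
    }
    return CompartmentSummary(
        per_compartment=per,
        total_reads=n,
        total_bases=total_bases,
        assignments=assignments,
    )


@dataclass
class CoverageEstimate:
    overall_coverage: float
    nuclear_coverage: float
    overall_coverage_rounded: float
    nuclear_coverage_rounded: float
    genome_size: float
    total_bases: float
    organellar_fraction: float


def estimate_genome_coverage(
    total_bases: float,
    genome_size: float,
    fractions: dict | None = None,
) -> CoverageEstimate:
    """Overall and nuclear fold coverage from yield, genome size, fractions.

    overall = total_bases / genome_size; nuclear removes the organellar and
    rDNA read fractions from the yield first.  Both are also reported
    rounded to one decimal (the precision the estimates warrant at skim
    depth).
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    fractions = fractions or {}
    organellar = sum(fractions.values())
    if not 0.0 <= organellar < 1.0:
        raise ValueError("compartment fractions must sum to [0, 1)")
    overall = total_bases / genome_size
    nuclear = total_bases * (1.0 - organellar) / genome_size
    return CoverageEstimate(
        overall_coverage=overall,
        nuclear_coverage=nuclear,
        overall_coverage_rounded=round(overall, 1),
        nuclear_coverage_rounded=round(nuclear, 1),
        genome_size=genome_size,
        total_bases=total_bases,
        organellar_fraction=organellar,
    )


def estimate_copy_number(median_depth: float, nuclear_coverage: float):
    """Repeat copy number as median read depth / single-copy coverage.

    A repeat sequenced to depth d in a genome whose single-copy fraction
    sits at coverage c must be present in about d / c copies.  Returns
    ``(raw, rounded_to_integer)``.
    """
    if nuclear_coverage <= 0:
        raise ValueError("nuclear coverage must be positive")
    raw = median_depth / nuclear_coverage
    return raw, int(round(raw))


def pg_to_mbp(two_c_picograms: float):
    """Convert a 2C flow-cytometry value (pg) to a 1C genome size in Mbp.

    1C Mbp = (2C pg / 2) x 978.  Returns ``(raw, rounded)`` with the
    rounded value at the nearest 5 Mbp, the precision such estimates are
    quoted at.
    """
    if two_c_picograms <= 0:
        raise ValueError("2C value must be positive")
    raw = (two_c_picograms / 2.0) * PG_TO_MBP
    return raw, int(round(raw / 5.0) * 5)
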