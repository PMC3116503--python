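"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA and FASTQ parsing is delegated to Biopython's low-level iterators
(`SimpleFastaParser`, `FastqGeneralIterator`); quality decoding and the
offset contract live here.  SAM ingestion uses pysam and is read-only:
the internal matcher reports its own placement table, but pre-computed
alignments can be fed into the pileup machinery through `ingest_sam`.

Phred offsets 33 and 64 are both supported (GAII-era data is offset 64,
where quality character ``B`` decodes to Q2, the "unscorable" value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import SequenceRecord, revcomp

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "ingest_sam",
    "write_sam",
    "RunConfig",
    "report_metadata",
]

__version__ = "0.1.0"


class FormatError(ValueError):
    """Malformed input file."""


def _check_fasta_shape(path: Path) -> None:
    """Fail early, naming a line number, on empty or headerless files."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>'"
                )
            return
    raise FormatError(f"{path}: empty FASTA file")


def read_fasta(path, keep_soft_mask: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    ids are the header token up to the first whitespace.  With
    ``keep_soft_mask`` the lower-case (soft-masked) positions of each
    sequence are recorded on the returned records.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise FormatError(f"{path}: record with empty header")
            if not keep_soft_mask:
                seq = seq.upper()
            records.append(SequenceRecord(name, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def read_fastq(path, phred_offset: int = 33) -> list[SequenceRecord]:
    """Read FASTQ; qualities decoded as ``ord(char) - phred_offset``.

    A decoded quality below zero means the file uses the other offset and
    raises a FormatError.
    """
    if phred_offset not in (33, 64):
        raise ValueError("phred_offset must be 33 or 64")
    path = Path(path)
    records = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            name = title.split()[0]
            scores = [ord(c) - phred_offset for c in qual]
            if any(q < 0 for q in scores):
                raise FormatError(
                    f"{path}: record {name!r}: negative quality decoded "
                    f"with offset {phred_offset} (wrong offset?)"
                )
            records.append(SequenceRecord(name, seq, scores))
    return records


def write_fastq(records: Iterable[SequenceRecord], path, phred_offset: int = 33) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + phred_offset) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def ingest_sam(path):
    """Read primary mapped records from a SAM file as ReadPlacements.

    Returns ``(placements, n_skipped)`` where unmapped, secondary and
    supplementary records are skipped and counted.  Identity is derived
    from the NM tag when present (gapless alignments assumed, matching
    the internal matcher's model).
    """
    import pysam

    from .align import ReadPlacement

    placements: list[ReadPlacement] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if not sam.header.get("SQ"):
            raise FormatError(f"{path}: SAM header lacks reference (@SQ) lines")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            aligned = rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            matches = aligned - int(nm)
            placements.append(
                ReadPlacement(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=aligned,
                    matches=matches,
                    identity=matches / aligned if aligned else 0.0,
                    read_start=rec.query_alignment_start,
                )
            )
    return placements, n_skipped


def write_sam(placements, reads, references, path) -> None:
    """Write gapless placements as a minimal text SAM file.

    The stored SEQ is the read in reference orientation (reverse strand
    placements carry FLAG 16 and the reverse-complemented sequence), with
    soft clips for any unaligned prefix/suffix, so a round trip through
    `ingest_sam` reproduces the placement table.
    """
    by_id = {r.id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref.bases)}\n")
        for p in placements:
            rec = by_id[p.read_id]
            oriented = rec.bases if p.strand == "+" else revcomp(rec.bases)
            lead = p.read_start
            trail = len(oriented) - lead - p.aligned_length
            cigar = ""
            if lead:
                cigar += f"{lead}S"
            cigar += f"{p.aligned_length}M"
            if trail:
                cigar += f"{trail}S"
            flag = 0 if p.strand == "+" else 16
            nm = p.aligned_length - p.matches
            fh.write(
                f"{p.read_id}\t{flag}\t{p.ref_id}\t{p.ref_start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{oriented}\t*\tNM:i:{nm}\n"
            )


# ---------------------------------------------------------------------------
# run configuration

#: Stage parameters as a flat namespace.  Defaults mirror the study values
#: where the study states one; the rest are the package's documented choices.
DEFAULTS: dict = {
    "seed": 0,
    "read_length": 40,  # 40 nt short reads
    "phred_offset": 33,
    # read QC
    "adapter": "AGATCGGAAGAGC",
    "adapter_min_match": 10,
    "adapter_min_identity": 0.9,
    "unscorable_q": 2,  # Illumina "B" tail value
    # consensus calling
    "seed_len": 11,
    "min_identity": 0.85,
    "min_depth": 3,
    "min_major_proportion": 0.7,
    "snp_min_minor_proportion": 0.2,
    "snp_mask_mode": "N",
    # rDNA polymorphism
    "poly_min_avg_q": 20,
    "poly_min_base_q": 20,
    "poly_threshold": 0.02,
    # compartment classification
    "compartment_seed_len": 11,
    "compartment_min_identity": 0.90,
    # gene coverage (tile size 7 / 80% identity regime)
    "gene_seed_len": 7,
    "gene_min_identity": 0.80,
    "bootstrap_iterations": 1000,
    "bootstrap_level": 0.95,
    # repeats / SSRs
    "repeat_min_len": 30,
    "repeat_min_identity": 0.85,
    "repeat_library_min_identity": 0.70,
    "ssr_min_contig_len": 150,
    "ssr_product_range": (100, 450),
}

_PROPORTION_KEYS = {
    "adapter_min_identity",
    "min_identity",
    "min_major_proportion",
    "snp_min_minor_proportion",
    "poly_threshold",
    "compartment_min_identity",
    "gene_min_identity",
    "bootstrap_level",
    "repeat_min_identity",
    "repeat_library_min_identity",
}

_POSITIVE_INT_KEYS = {
    "read_length",
    "adapter_min_match",
    "seed_len",
    "min_depth",
    "compartment_seed_len",
    "gene_seed_len",
    "bootstrap_iterations",
    "repeat_min_len",
    "ssr_min_contig_len",
}


@dataclass
class RunConfig:
    """Flat key = value configuration with validated defaults."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged
        self.validate()

    def validate(self) -> None:
        for key in _PROPORTION_KEYS:
            v = self.params[key]
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{key} = {v}: must be in [0, 1]")
        for key in _POSITIVE_INT_KEYS:
            v = self.params[key]
            if int(v) != v or int(v) <= 0:
                raise ValueError(f"{key} = {v}: must be a positive integer")

    def __getitem__(self, key):
        return self.params[key]

    def __setitem__(self, key, value):
        self.params[key] = value
        self.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        params = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}: line {lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in DEFAULTS:
                    raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
                default = DEFAULTS[key]
                if isinstance(default, bool):
                    params[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    params[key] = int(value)
                elif isinstance(default, float):
                    params[key] = float(value)
                elif isinstance(default, tuple):
                    params[key] = tuple(int(x) for x in value.split(","))
                else:
                    params[key] = value
        return cls(params)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.params.items()):
                if isinstance(value, tuple):
                    value = ",".join(str(x) for x in value)
                fh.write(f"{key} = {value}\n")


def report_metadata(config: RunConfig | None = None, **extra) -> dict:
    """Common metadata block every report carries: config, seed, version."""
    config = config or RunConfig()
    meta = {
        "tool": "genomeskim",
        "version": __version__,
        "seed": config["seed"],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sorted(config.params.items())
        },
    }
    meta.update(extra)
    return meta


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
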