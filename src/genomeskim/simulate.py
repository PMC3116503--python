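"""Synthetic genome-skim generator with ground truth.

The simulator emulates the statistical structure of a low-coverage
(~0.4-0.5x) plant genome skim of 40 nt reads:

* a multi-compartment genome -- random nuclear background, a circular
  quadripartite plastome (LSC + IRa + SSC + IRb), linear mitochondrial
  contigs, and two tandem-repeat rDNA families (an 18S-5.8S-26S-like
  cistron and a 5S-like unit) instantiated as many near-identical copies;
* controlled intragenomic polymorphism among rDNA copies: each designated
  polymorphic site carries a minor base in ``round(f * n_copies)`` copies,
  so the truth fraction is exact and recoverable;
* planted SSR loci and dispersed repeat families in the nuclear background;
* an error-calibration control sequence (PhiX-style), excluded from the
  genomic read pool by default and sequenced separately;
* read sampling with per-compartment read fractions (default 11.8% / 3.4%
  / 1.8% for chloroplast / mitochondrial / rDNA), uniform start positions
  (circular wrap on the plastome), substitution errors, and planted QC
  artifacts (N bases, adapter read-through, unscorable Q2 tails).

All randomness flows from one seeded generator in documented order, so a
given (spec, params, seed) is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SequenceRecord, revcomp

__all__ = [
    "RdnaSpec",
    "GenomeSpec",
    "ReadSimParams",
    "PolymorphicSite",
    "MockGenomeTruth",
    "build_mock_genome",
    "simulate_reads",
]

CHLOROPLAST = "chloroplast"
MITOCHONDRIAL = "mitochondrial"
RDNA = "rdna"
NUCLEAR = "nuclear"
CONTROL = "control"

_ALPHABET = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=length)])


@dataclass
class RdnaSpec:
    """One tandem rDNA family: unit template and its intragenomic variation."""

    unit_len: int
    n_copies: int
    poly_site_rate: float
    minor_copy_fraction_range: tuple[float, float]
    #: plant exactly this many sites instead of a Binomial(unit_len, rate) draw
    n_poly_sites: int | None = None

    def __post_init__(self) -> None:
        if self.unit_len <= 0 or self.n_copies <= 0:
            raise ValueError("unit_len and n_copies must be positive")
        if not 0.0 <= self.poly_site_rate <= 1.0:
            raise ValueError("poly_site_rate must be in [0, 1]")
        if self.n_poly_sites is not None and not 0 <= self.n_poly_sites <= self.unit_len:
            raise ValueError("n_poly_sites must be in [0, unit_len]")
        lo, hi = self.minor_copy_fraction_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("minor_copy_fraction_range must lie within (0, 0.5]")


@dataclass
class GenomeSpec:
    """Blueprint for a scaled-down multi-compartment mock genome.

    Defaults are chosen to mirror the study conditions at desk scale: the
    cistron-like unit keeps its real 7,541 bp length and a 0.00252 per-site
    polymorphism rate (expectation ~19 sites), the 5S-like unit is 120 bp
    at a 0.267 rate (expectation ~32 sites), and the per-compartment read
    fractions default to 11.8% / 3.4% / 1.8%.
    """

    nuclear_length: int = 100_000
    plastome: dict = field(
        default_factory=lambda: {"lsc_len": 6000, "ir_len": 1700, "ssc_len": 1200}
    )
    mito_contig_lengths: tuple = (4000, 3000, 2000)
    rdna_cistron: RdnaSpec = field(
        default_factory=lambda: RdnaSpec(7541, 200, 0.00252, (0.04, 0.17))
    )
    rdna_5s: RdnaSpec = field(
        default_factory=lambda: RdnaSpec(120, 500, 0.267, (0.02, 0.14))
    )
    ssr_plan: tuple = (
        ("TA", 6, 2),
        ("GA", 5, 2),
        ("ATTC", 4, 1),
        ("CCT", 4, 1),
    )
    repeat_families: tuple = (("copia", 300, 5), ("gypsy", 250, 4))
    control_sequence_length: int = 1000
    compartment_read_fractions: dict = field(
        default_factory=lambda: {CHLOROPLAST: 0.118, MITOCHONDRIAL: 0.034, RDNA: 0.018}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("lsc_len", "ir_len", "ssc_len"):
            if self.plastome[key] <= 0:
                raise ValueError(f"plastome {key} must be positive")
        if self.nuclear_length <= 0 or self.control_sequence_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if any(l <= 0 for l in self.mito_contig_lengths):
            raise ValueError("mitochondrial contig lengths must be positive")
        if sum(self.compartment_read_fractions.values()) >= 1.0:
            raise ValueError("compartment read fractions must sum to < 1")


@dataclass
class ReadSimParams:
    """Read pool parameters (40 nt reads, skim depth by default)."""

    read_length: int = 40
    total_bases: int | None = None
    mean_coverage: float | None = 0.5
    error_rate: float = 0.004  # constant per-base substitution rate
    base_quality: int = 24
    tail_quality: int = 2  # the "B"/unscorable value
    low_quality_tail_fraction: float = 0.0
    n_read_fraction: float = 0.0
    adapter_fraction: float = 0.0
    adapter: str = "AGATCGGAAGAGC"
    min_read_length: int = 20  # truncation floor at linear sequence ends
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for name in ("low_quality_tail_fraction", "n_read_fraction", "adapter_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length < self.min_read_length:
            raise ValueError("read_length must be >= min_read_length")


@dataclass
class PolymorphicSite:
    """Ground truth for one intragenomic polymorphism in an rDNA template."""

    pos: int
    major_base: str
    minor_base: str
    target_fraction: float
    realized_fraction: float
    minor_copies: np.ndarray = field(repr=False)  # bool per copy


@dataclass
class MockGenomeTruth:
    """Ground truth emitted alongside the mock genome."""

    compartments: dict  # seq_id -> compartment label
    seq_lengths: dict
    copy_numbers: dict  # seq_id -> tandem copy count (1 for single-copy)
    circular: dict  # seq_id -> bool
    poly_sites: dict  # seq_id -> list[PolymorphicSite]
    ssr_loci: list  # (seq_id, start, end, motif, n_units)
    repeat_pairs: list  # (family, seq_id, start_a, start_b, length)
    read_fractions: dict  # compartment -> expected read fraction
    ir_span: dict  # plastome IRa/IRb spans

    def intervals(self):
        """Whole-sequence compartment intervals (they tile trivially)."""
        return [
            (sid, 0, self.seq_lengths[sid], label)
            for sid, label in self.compartments.items()
        ]


def _plant_ssrs(nuclear: list, plan, rng, truth_loci, seq_id):
    """Overwrite nuclear background with perfect tandem repeats.

    Flanking bases are forced to break the repeat period so the planted
    locus is maximal by construction.
    """
    L = len(nuclear)
    used: list[tuple[int, int]] = []
    for motif, n_units, count in plan:
        p = len(motif)
        span = p * n_units
        for _ in range(count):
            for _attempt in range(100):
                start = int(rng.integers(1, L - span - 1))
                if all(start + span + 1 <= a or start - 1 >= b for a, b in used):
                    break
            else:
                raise ValueError("ssr_plan exceeds nuclear sequence capacity")
            nuclear[start : start + span] = list(motif * n_units)
            # break period on both flanks
            left_choices = [b for b in "ACGT" if b != motif[-1]]
            right_choices = [b for b in "ACGT" if b != motif[0]]
            nuclear[start - 1] = left_choices[int(rng.integers(len(left_choices)))]
            nuclear[start + span] = right_choices[int(rng.integers(len(right_choices)))]
            used.append((start - 1, start + span + 1))
            truth_loci.append((seq_id, start, start + span, motif, n_units))


def _plant_repeats(nuclear: list, families, rng, truth_pairs, used, seq_id):
    for family, elem_len, n_copies in families:
        element = _random_seq(rng, elem_len)
        starts = []
        for _ in range(n_copies):
            for _attempt in range(200):
                start = int(rng.integers(0, len(nuclear) - elem_len))
                if all(start + elem_len <= a or start >= b for a, b in used):
                    break
            else:
                raise ValueError("repeat_families plan exceeds sequence capacity")
            nuclear[start : start + elem_len] = list(element)
            used.append((start, start + elem_len))
            starts.append(start)
        starts.sort()
        for i in range(len(starts)):
            for j in range(i + 1, len(starts)):
                truth_pairs.append((family, seq_id, starts[i], starts[j], elem_len))


def _rdna_truth(template: str, spec: RdnaSpec, rng) -> list[PolymorphicSite]:
    """Designate polymorphic sites; assign each minor base to round(f*n) copies."""
    if spec.n_poly_sites is not None:
        n_sites = spec.n_poly_sites
    else:
        n_sites = int(rng.binomial(spec.unit_len, spec.poly_site_rate))
    positions = np.sort(rng.choice(spec.unit_len, size=n_sites, replace=False))
    lo, hi = spec.minor_copy_fraction_range
    sites = []
    for pos in positions:
        major = template[pos]
        minor = rng.choice([b for b in "ACGT" if b != major])
        f = float(rng.uniform(lo, hi))
        n_minor = int(round(f * spec.n_copies))
        if n_minor == 0:
            n_minor = 1
        order = rng.permutation(spec.n_copies)
        mask = np.zeros(spec.n_copies, dtype=bool)
        mask[order[:n_minor]] = True
        sites.append(
            PolymorphicSite(
                pos=int(pos),
                major_base=major,
                minor_base=str(minor),
                target_fraction=f,
                realized_fraction=n_minor / spec.n_copies,
                minor_copies=mask,
            )
        )
    return sites


def build_mock_genome(spec: GenomeSpec):
    """Build the mock genome and its ground truth.

    Returns ``(records, truth)``.  The plastome is emitted as one
    circular-flagged sequence LSC + IRa + SSC + IRb where IRb is the
    reverse complement of IRa.  rDNA families are emitted as one template
    sequence each, with the copy count and per-copy minor-allele
    assignments recorded in the truth (copies are instantiated lazily at
    read-simulation time).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth = MockGenomeTruth(
        compartments={},
        seq_lengths={},
        copy_numbers={},
        circular={},
        poly_sites={},
        ssr_loci=[],
        repeat_pairs=[],
        read_fractions={},
        ir_span={},
    )

    # 1. nuclear background with planted SSRs and repeat families
    nuclear = list(_random_seq(rng, spec.nuclear_length))
    _plant_ssrs(nuclear, spec.ssr_plan, rng, truth.ssr_loci, "nuclear_1")
    used = [(s - 1, e + 1) for (_, s, e, _, _) in truth.ssr_loci]
    _plant_repeats(nuclear, spec.repeat_families, rng, truth.repeat_pairs, used, "nuclear_1")
    records.append(SequenceRecord("nuclear_1", "".join(nuclear)))
    truth.compartments["nuclear_1"] = NUCLEAR

    # 2. plastome: LSC + IRa + SSC + IRb (reverse complement of IRa), circular
    lsc = _random_seq(rng, spec.plastome["lsc_len"])
    ira = _random_seq(rng, spec.plastome["ir_len"])
    ssc = _random_seq(rng, spec.plastome["ssc_len"])
    plastome = lsc + ira + ssc + revcomp(ira)
    records.append(SequenceRecord("plastome", plastome, circular=True))
    truth.compartments["plastome"] = CHLOROPLAST
    a0 = len(lsc)
    b0 = len(lsc) + len(ira) + len(ssc)
    truth.ir_span["plastome"] = ((a0, a0 + len(ira)), (b0, b0 + len(ira)))

    # 3. mitochondrial contigs
    for i, L in enumerate(spec.mito_contig_lengths, start=1):
        rec = SequenceRecord(f"mito_{i}", _random_seq(rng, L))
        records.append(rec)
        truth.compartments[rec.id] = MITOCHONDRIAL

    # 4. rDNA templates with polymorphism truth; a unit of a tandem array is
    # locally periodic, so the template is circular (reads span unit joins)
    for sid, sub in (("rdna_cistron", spec.rdna_cistron), ("rdna_5S", spec.rdna_5s)):
        template = _random_seq(rng, sub.unit_len)
        records.append(SequenceRecord(sid, template, circular=True))
        truth.compartments[sid] = RDNA
        truth.copy_numbers[sid] = sub.n_copies
        truth.poly_sites[sid] = _rdna_truth(template, sub, rng)

    # 5. control sequence (separate calibration lane; weight 0 in the pool);
    # circular, like the phage genome it stands in for
    records.append(
        SequenceRecord("control", _random_seq(rng, spec.control_sequence_length),
                       circular=True)
    )
    truth.compartments["control"] = CONTROL

    for rec in records:
        truth.seq_lengths[rec.id] = len(rec.bases)
        truth.copy_numbers.setdefault(rec.id, 1)
        truth.circular[rec.id] = rec.circular

    fractions = dict(spec.compartment_read_fractions)
    fractions[NUCLEAR] = 1.0 - sum(fractions.values())
    fractions[CONTROL] = 0.0
    truth.read_fractions = fractions
    return records, truth


def _apply_rdna_alleles(bases: list, sid: str, start: int, copy: int, truth) -> None:
    L = truth.seq_lengths[sid]
    circular = truth.circular.get(sid, False)
    for site in truth.poly_sites.get(sid, ()):
        off = (site.pos - start) % L if circular else site.pos - start
        if 0 <= off < len(bases) and site.minor_copies[copy]:
            bases[off] = site.minor_base


def simulate_reads(
    genome: list[SequenceRecord],
    truth: MockGenomeTruth,
    params: ReadSimParams,
    fractions: dict | None = None,
):
    """Simulate a shotgun read pool with provenance.

    ``fractions`` overrides the per-compartment read fractions (only
    compartments present among ``genome`` are used; weights renormalize).
    Within a compartment, the source sequence is chosen proportional to
    length x copy number.  Returns ``(reads, provenance)`` where the
    provenance DataFrame maps read id -> (source, position, strand,
    compartment, copy index, planted artifacts).
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    rng = np.random.default_rng(params.seed)
    rl = params.read_length

    fractions = dict(fractions if fractions is not None else truth.read_fractions)
    comps = sorted({truth.compartments[rec.id] for rec in genome})
    weights = np.array([max(fractions.get(c, 0.0), 0.0) for c in comps], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(comps))
    weights /= weights.sum()

    by_comp: dict[str, list[SequenceRecord]] = {c: [] for c in comps}
    for rec in genome:
        by_comp[truth.compartments[rec.id]].append(rec)
    seq_weights = {
        c: np.array(
            [len(r.bases) * truth.copy_numbers[r.id] for r in recs], dtype=float
        )
        for c, recs in by_comp.items()
    }
    for c in comps:
        seq_weights[c] = seq_weights[c] / seq_weights[c].sum()

    template_bases = sum(len(rec.bases) for rec in genome)
    if params.total_bases is not None:
        n_reads = int(round(params.total_bases / rl))
    elif params.mean_coverage is not None:
        n_reads = int(round(params.mean_coverage * template_bases / rl))
    else:
        raise ValueError("one of total_bases or mean_coverage is required")
    if n_reads == 0:
        import warnings

        warnings.warn("requested coverage yields an empty read pool")
        return [], pd.DataFrame(
            columns=["read_id", "source", "start", "strand", "compartment",
                     "copy", "artifact", "tail_start", "length"]
        )

    # draw order: compartment, sequence, position, strand, copy, artifact
    comp_idx = rng.choice(len(comps), size=n_reads, p=weights)
    seq_u = rng.random(n_reads)
    pos_u = rng.random(n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    copy_u = rng.random(n_reads)
    artifact_u = rng.random(n_reads)
    tail_starts = rng.integers(0, rl, size=n_reads)
    n_positions = rng.integers(0, rl, size=n_reads)
    err_mask = rng.random((n_reads, rl)) < params.error_rate
    err_shift = rng.integers(1, 4, size=int(err_mask.sum()))

    f_n = params.n_read_fraction
    f_ad = f_n + params.adapter_fraction
    f_tail = f_ad + params.low_quality_tail_fraction

    doubled = {
        rec.id: rec.bases + rec.bases if rec.circular else rec.bases
        for rec in genome
    }

    reads: list[SequenceRecord] = []
    rows = []
    err_cursor = 0
    for i in range(n_reads):
        comp = comps[comp_idx[i]]
        recs = by_comp[comp]
        cw = seq_weights[comp]
        si = int(np.searchsorted(np.cumsum(cw), seq_u[i], side="right"))
        si = min(si, len(recs) - 1)
        rec = recs[si]
        sid = rec.id
        L = len(rec.bases)
        if rec.circular:
            start = int(pos_u[i] * L)
            bases = list(doubled[sid][start : start + rl])
        else:
            hi = max(L - params.min_read_length, 0)
            start = int(pos_u[i] * (hi + 1))
            start = min(start, hi)
            bases = list(rec.bases[start : start + rl])
        copy = 0
        if truth.copy_numbers[sid] > 1:
            copy = int(copy_u[i] * truth.copy_numbers[sid])
            _apply_rdna_alleles(bases, sid, start, copy, truth)

        # substitution errors (cyclic shift among ACGT; N untouched)
        row_err = np.flatnonzero(err_mask[i, : len(bases)])
        for j in row_err:
            b = bases[j]
            if b in "ACGT":
                bases[j] = "ACGT"[("ACGT".index(b) + err_shift[err_cursor]) % 4]
            err_cursor += 1
        err_cursor += int(err_mask[i, len(bases):].sum())

        strand = "+" if strands[i] == 0 else "-"
        seq = "".join(bases)
        if strand == "-":
            seq = revcomp(seq)
        quality = [params.base_quality] * len(seq)

        artifact = "none"
        tail_start = -1
        u = artifact_u[i]
        if u < f_n:
            artifact = "n_base"
            seq = seq[: n_positions[i] % len(seq)] + "N" + seq[n_positions[i] % len(seq) + 1 :]
        elif u < f_ad:
            artifact = "adapter"
            # read-through into adapter: at least 10 nt of adapter in the read
            pos = int(n_positions[i] % max(len(seq) - 10 + 1, 1))
            ad = params.adapter
            tiled = (ad * (len(seq) // len(ad) + 1))[: len(seq) - pos]
            seq = seq[:pos] + tiled
        elif u < f_tail:
            artifact = "tail"
            tail_start = int(tail_starts[i] % len(seq))
            quality = quality[:tail_start] + [params.tail_quality] * (len(seq) - tail_start)

        rid = f"r{i:07d}"
        reads.append(SequenceRecord(rid, seq, quality))
        rows.append(
            (rid, sid, start % L if rec.circular else start, strand, comp,
             copy, artifact, tail_start, len(seq))
        )

    provenance = pd.DataFrame(
        rows,
        columns=["read_id", "source", "start", "strand", "compartment",
                 "copy", "artifact", "tail_start", "length"],
    )
    return reads, provenance
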