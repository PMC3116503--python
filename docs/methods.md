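# Methods

This note documents the models, parameter choices and numerical
conventions behind `genomeskim`, and what the simulation-based tests do
and do not establish about real data.

## Coordinates, alphabets, formats

Internal coordinates are 0-based, half-open; human-readable reports are
1-based inclusive.  Sequences are upper-cased to the 5-letter alphabet
{A,C,G,T,N}; any other character is mapped to N and counted.  Lower-case
(soft-masked) reference positions are remembered separately and excluded
from seeding only.  FASTQ offsets 33 and 64 are both supported (the
default is 33; GAII-era data is 64, where quality character "B" decodes
to Q2).  SAM is ingested read-only via pysam; the internal matcher writes
its own placement table.

## Read placement

The matcher is deliberately simple: exact k-mer seeds (default k = 11 for
consensus work; k = 7 with 80% identity for gene-space counting, k = 11
with 90% for compartment classification) propose diagonals on both
strands; each diagonal is scored by gapless extension over the full read;
candidates at or above the identity threshold are reported best-first
with ties broken by (lower reference position, then + strand).  Seeds are
taken at non-overlapping offsets plus the final position, which detects
any placement whose errors leave one clean k-window — ample at 40 nt and
sub-percent error.  N bases count as mismatches on either side.  There is
no gapped alignment: at these read lengths a placement spanning a true
indel fails the identity threshold and the region is left to masking,
which is the behavior reference-guided consensus needs.  Circular
references are indexed over a doubled sequence with positions reported
modulo length.

Each read contributes at most one placement (its best) to any pileup, so
depth is never double-counted.  One visible consequence, reproduced
deliberately: reads from the second inverted-repeat arm of a plastome are
exact reverse complements of the first arm, tie on identity, and collapse
onto the lower-coordinate arm — the familiar one-IR-copy assembly
behavior (`analysis/03`).  Per-target multi-placement is used only where
the quantity is defined per target (gene hits, repeat-library hits).

## Consensus and masking

Consensus is the majority base over A/C/G/T counts (N counts toward depth
but not majority; majority ties break alphabetically and are flagged).  A
position is masked to N when depth < `min_depth` (default 3) or the
majority proportion < `min_major_proportion` (default 0.7); when SNP
masking is on, a second base at ≥ `snp_min_minor_proportion` (default
0.2) masks to N or to the two-base IUPAC code.  The defaults are
documented package choices — masking is intrinsically a user-specified
operation — and masking is monotone: raising the majority threshold can
only mask further (property-tested).  Contigs are maximal runs of covered
positions; N50 is computed by descending cumulative sum; median depth is
taken over covered positions.

## rDNA intragenomic polymorphism

Reads with mean Phred < 20 are discarded; surviving bases under Q20 are
masked to N (length-preserving).  Discordance at a position is
`n_discordant / depth_effective` where the denominator counts non-N read
bases only — masked bases carry no evidence, so they are excluded from
both numerator and denominator.  Zero-effective-depth positions are
missing, not zero.  Positions at ≥ 2% discordance are called polymorphic;
the threshold is a parameter, deliberately conservative relative to the
control-lane error floor, and the calls are monotone in it.  Percent
polymorphic per annotated region is `100 × calls / region length` to one
decimal; region annotation is supplied as a BED-style interval list, not
computed.  The control profile reports the mean discordance, the
worst position (systematic-error sites are reported, never auto-removed)
and exceedance counts at user cutoffs.

The consensus used for discordance defaults to the self-consensus of the
same filtered pool; a supplied reference is also accepted.

## Compartments, coverage, copy number

Classification tries labeled reference sets in a fixed priority order —
chloroplast, mitochondrial, rDNA, control, then any extra sets (e.g. a
contaminant screen), with unmatched reads labeled nuclear.  The order
resolves reads matching several compartments (plastid-derived
mitochondrial insertions) deterministically, mirroring sequential read
removal.  Fractions are per read; bases are also tracked for coverage.

Coverage: `overall = yield / genome size`;
`nuclear = yield × (1 − Σ organellar fractions) / genome size`.  Copy
number: `median depth / nuclear coverage` (scale-invariant).  Rounding
conventions for "approximately" reports: coverage to one decimal, copies
to integer, genome sizes to the nearest 5 Mbp; the 2C→1C conversion is
`(pg / 2) × 978 Mbp/pg`.

## Gene-space coverage

A hit is a qualifying placement of a read on a gene; each read counts at
most once per gene however many places it hits that gene, and may hit
several genes.  `hits/kb = hits/(length/1000)`;
`coverage = hits/kb × read length / 1000`.  The estimator is upward
biased: overlapping reads (PCR duplicates, edge overhangs) inflate it,
and this is asserted as a property rather than corrected.  Genes with
zero hits are excluded from medians and reported separately.  Bootstrap
CIs are percentile intervals over 1,000 median resamples from one seeded
generator, with values sorted first so the interval is order-invariant;
empirical coverage of the 95% interval is checked at 95% ± 3 points.
Quartiles for the outlier rule (Q3 + 1.5·IQR, strictly above) use linear
interpolation between order statistics, oracle-tested.

## SSRs and repeats

An SSR locus is a maximal perfect tandem run of a 2–6 nt motif meeting
the unit minimum (di/tri ≥ 4, tetra/penta/hexa ≥ 3), attributed to its
shortest period — (TA)₆ is a dinucleotide locus, and mononucleotide runs
are never SSRs.  The reported motif preserves the observed strand; the
lexicographically least rotation is kept for class bookkeeping.  Compound
arrangements come out as separate perfect loci.  The scanner is tested
for exact set equality against an independent brute-force enumeration; in
adversarial strings two same-period runs can share up to period−1 bases,
which the enumeration reproduces.  Contigs under 150 bp are skipped (too
little flank for primers); PCR feasibility asks whether a window of
100–450 bp can contain the locus with ≥ 18 nt of flank on each side — no
primer chemistry is modeled.

Genomic repeats are maximal gapless self-matches (sequence vs itself and
vs its reverse complement) from 12-mer seeds with X-drop extension
(match +1, mismatch −3, drop 12), trimmed to the best-scoring endpoints;
pairs need length > 30 bp (strictly, per the wording; a flag switches to
≥) and identity ≥ 85%, with the self-diagonal excluded and mirrored
duplicates collapsed.  The quadripartite plastome structure takes the
longest inverted self-match at ≥ 99% identity and ≥ 1 kb (both
configurable package choices) as the IR; the longer remaining arc is the
LSC; lsc + 2·ir + ssc equals the genome length by construction.  An IR
arm crossing the chosen linearization origin is not resolved.

## The simulator

The mock genome is a scaled-down version of the study system: a random
nuclear background (default 100 kb) with planted SSRs and two dispersed
repeat families; a circular plastome LSC + IRa + SSC + IRb (6,000 / 1,700
/ 1,200 bp; IRb the exact reverse complement of IRa); three mitochondrial
contigs; two rDNA families — a cistron-like unit kept at its real 7,541 bp
with a 0.00252 per-site polymorphism rate (expectation ≈ 19 sites, minor
fractions 4–17%) and a 120 bp 5S-like unit at rate 0.267 (expectation
≈ 32 sites, minor fractions 2–14%); and a 1 kb control sequence.  rDNA
templates and the control are circular: a unit inside a tandem array is
locally periodic (reads span unit joints), and the control stands in for
a circular phage genome — this also keeps their depth uniform, which the
copy-number and error-calibration arithmetic assumes.  An exact-count
option plants a specified number of polymorphic sites instead of the
binomial draw, for tests pinned to printed site counts.

Minor alleles are assigned deterministically: each site's minor base goes
to `round(f × n_copies)` copies chosen by one seeded shuffle, so the
truth fraction is exact.  Read sampling draws a compartment per read at
the configured fractions (defaults 11.8% / 3.4% / 1.8% for chloroplast /
mitochondrial / rDNA — the published mix), then a sequence within the
compartment proportional to length × copy number, then a uniform start
(circular wrap where flagged; linear reads truncate at ends, floor 20
nt).  Errors are uniform substitutions (default 0.4%, a deliberate
overstatement of post-filter error so filtering has work to do) with flat
Q24 qualities; QC artifacts (an N base, adapter read-through with ≥ 10 nt
of adapter, an unscorable Q2 tail) are planted in disjoint read subsets
and recorded in the provenance table.  All randomness flows from one
seeded generator in documented order; identical inputs give byte-identical
FASTQ and truth outputs.

What the simulator does not model — and hence what passing tests do not
establish about real data: indels and structural divergence from the
reference, position- and context-dependent error, quality-score miscalibration,
GC and coverage bias, PCR duplicates, paired ends, real repeat taxonomy,
and nuclear insertions of organellar DNA.  The recovery tests show the
estimators are correct under their own assumptions at the study's stated
conditions, not that those assumptions hold for any particular dataset.

## Problem sizes

The default conditions are desk-scale by design: a ~128 kb template set,
a ~1,600-read skim, deep pools of 400–1,000× only over the short rDNA and
control templates, 100 random 10 kb sequences for the scanner oracle, 20
seeds for calibration checks and 500 repetitions for bootstrap coverage.
These sizes make every stage's statistical claim testable while keeping
the full suite in the order of a minute of compute.
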