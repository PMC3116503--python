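#!/usr/bin/env python
"""Build the mock multi-compartment genome and the ~0.5x skim read pool.

Writes the genome FASTA, the read FASTQ, the control-lane FASTQ, and the
ground-truth tables under results/sim/.  Downstream scripts regenerate the
same data from the same seeds, so each stage also runs standalone.
"""

from pathlib import Path

from genomeskim.io import write_fasta, write_fastq, write_json
from genomeskim.simulate import (
    GenomeSpec,
    ReadSimParams,
    build_mock_genome,
    simulate_reads,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

GENOME_SEED = 101
READS_SEED = 102
CONTROL_SEED = 103

#: the genomic lane: skim depth with QC artifacts to exercise cleaning
READ_PARAMS = ReadSimParams(
    mean_coverage=0.5,
    seed=READS_SEED,
    n_read_fraction=0.005,
    adapter_fraction=0.005,
    low_quality_tail_fraction=0.03,
)

#: the deep, clean control lane used for error calibration
CONTROL_PARAMS = ReadSimParams(mean_coverage=1000, seed=CONTROL_SEED,
                               error_rate=0.0004)


def build_all():
    records, truth = build_mock_genome(GenomeSpec(seed=GENOME_SEED))
    reads, provenance = simulate_reads(records, truth, READ_PARAMS)
    control = next(r for r in records if r.id == "control")
    control_reads, _ = simulate_reads([control], truth, CONTROL_PARAMS,
                                      fractions={"control": 1.0})
    return records, truth, reads, provenance, control_reads


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    records, truth, reads, provenance, control_reads = build_all()
    write_fasta(records, OUT / "genome.fasta")
    write_fastq(reads, OUT / "reads.fastq")
    write_fastq(control_reads, OUT / "control_reads.fastq")
    provenance.to_csv(OUT / "provenance.tsv", sep="\t", index=False)
    write_json(
        {
            "seed_genome": GENOME_SEED,
            "seed_reads": READS_SEED,
            "n_reads": len(reads),
            "n_control_reads": len(control_reads),
            "expected_read_fractions": truth.read_fractions,
            "poly_sites": {k: len(v) for k, v in truth.poly_sites.items()},
            "ssr_loci_planted": len(truth.ssr_loci),
            "repeat_pairs_planted": len(truth.repeat_pairs),
        },
        OUT / "truth_summary.json",
    )
    print(f"simulated {len(reads)} skim reads over "
          f"{sum(len(r.bases) for r in records)} bp of templates; "
          f"{len(control_reads)} control reads; outputs in {OUT}")


if __name__ == "__main__":
    main()
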