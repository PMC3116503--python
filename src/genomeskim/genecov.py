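"""Gene-space coverage from unique read hits on a reference gene set.

At skim depth single-copy genes are far from assembled, but the fraction
of a related species' gene set hit by at least one read, and the per-gene
hit density, measure how much of the gene space the skim touched.  The
coverage estimator is

    hits_per_kb = n_unique_hits / (gene_length / 1000)
    coverage    = hits_per_kb * read_length / 1000

("unique" = each read counts at most once per gene, however many places it
hits that gene; a read may hit several genes).  Coverage is overestimated
when reads overlap (PCR duplicates), which is a property of the estimator,
not a bug.  Medians get percentile-bootstrap confidence intervals; genes
above Q3 + 1.5 IQR are flagged as outliers (multigene families, unmasked
low-complexity sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import ReferenceIndex
from .records import SequenceRecord

__all__ = [
    "GeneCoverageRecord",
    "CoverageSummary",
    "count_unique_hits",
    "coverage_from_hits",
    "bootstrap_median_ci",
    "flag_outliers",
    "summarize_gene_coverage",
]


@dataclass
class GeneCoverageRecord:
    gene_id: str
    gene_length: int
    n_unique_hits: int
    hits_per_kb: float
    coverage: float


@dataclass
class CoverageSummary:
    n_genes_with_hits: int
    n_genes_zero_hits: int
    median_hits_per_kb: float
    hits_per_kb_ci: tuple[float, float]
    median_coverage: float
    coverage_ci: tuple[float, float]
    outlier_threshold: float
    n_outliers: int
    bootstrap_iterations: int
    seed: int


def count_unique_hits(
    reads: list[SequenceRecord],
    genes: list[SequenceRecord],
    seed_len: int = 7,
    min_identity: float = 0.80,
) -> dict[str, int]:
    """Unique read hits per gene (tile-7 / 80%-identity regime).

    Soft-masked gene regions (lower-case in the source FASTA) are excluded
    from seeding, so repeat-masked genes behave as masked.  Returns a
    count for every gene, zeros included.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    index = ReferenceIndex(genes, seed_len=seed_len, honor_soft_mask=True)
    counts = {g.id: 0 for g in genes}
    for rec in reads:
        hits = index.map_read(
            rec.bases, min_identity=min_identity, max_hits=len(genes) * 4
        )
        for gene_id in {h.ref_id for h in hits}:
            counts[gene_id] += 1
    return counts


def coverage_from_hits(n_hits: int, gene_length: int, read_length: int):
    """(hits_per_kb, coverage) for one gene; values also usable pre-rounded.

    coverage = hits_per_kb x read_length / 1000.
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    hits_per_kb = n_hits / (gene_length / 1000.0)
    coverage = hits_per_kb * read_length / 1000.0
    return hits_per_kb, coverage


def bootstrap_median_ci(
    values,
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the median.

    Values are sorted internally before resampling so the interval is
    invariant to input order for a fixed seed.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(iterations, n))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(medians, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def flag_outliers(values):
    """Box-plot upper-whisker rule: flag values above Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics.  Returns
    ``(threshold, flags)`` with flags True for values strictly above the
    threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(values, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    return float(threshold), values > threshold


def summarize_gene_coverage(
    records: list[GeneCoverageRecord],
    iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CoverageSummary:
    """Medians with bootstrap CIs and outlier flags over genes with hits.

    Zero-hit genes are excluded from the medians and reported separately.
    """
    with_hits = [r for r in records if r.n_unique_hits > 0]
    zero = len(records) - len(with_hits)
    if len(with_hits) < 4:
        raise ValueError("too few genes with hits to summarize")
    hk = np.array([r.hits_per_kb for r in with_hits])
    cov = np.array([r.coverage for r in with_hits])
    threshold, flags = flag_outliers(cov)
    return CoverageSummary(
        n_genes_with_hits=len(with_hits),
        n_genes_zero_hits=zero,
        median_hits_per_kb=float(np.median(hk)),
        hits_per_kb_ci=bootstrap_median_ci(hk, iterations, level, seed),
        median_coverage=float(np.median(cov)),
        coverage_ci=bootstrap_median_ci(cov, iterations, level, seed),
        outlier_threshold=threshold,
        n_outliers=int(flags.sum()),
        bootstrap_iterations=iterations,
        seed=seed,
    )
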