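"""Intragenomic rDNA polymorphism from per-position read discordance.

Tandem rDNA arrays collapse onto a single template during reference-guided
assembly, so variation among the hundreds-to-thousands of copies shows up
as a stable fraction of reads disagreeing with the consensus at a site.
This module implements the quantification: quality filtering (reads with
mean Phred < 20 discarded, sub-Q20 bases masked to N), per-position
discordance proportions against a consensus with N bases excluded from
both numerator and denominator, a polymorphism call at >= 2% discordance
by default, and a control-lane error profile that calibrates the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import Pileup
from .records import SequenceRecord, encode

__all__ = [
    "DiscordanceProfile",
    "ControlErrorProfile",
    "quality_filter_for_polymorphism",
    "discordance_profile",
    "call_polymorphic",
    "control_error_profile",
]


def quality_filter_for_polymorphism(
    reads: list[SequenceRecord],
    min_avg_q: int = 20,
    min_base_q: int = 20,
) -> list[SequenceRecord]:
    """Discard reads with mean Phred < min_avg_q; mask sub-threshold bases to N.

    Lengths are preserved; only base identities change.  Reads must carry
    qualities.
    """
    out = []
    for rec in reads:
        if rec.quality is None:
            raise ValueError(f"read {rec.id!r} carries no qualities")
        qual = np.asarray(rec.quality)
        if qual.mean() < min_avg_q:
            continue
        if (qual < min_base_q).any():
            bases = "".join(
                "N" if q < min_base_q else b for b, q in zip(rec.bases, rec.quality)
            )
            out.append(SequenceRecord(rec.id, bases, rec.quality))
        else:
            out.append(rec)
    return out


@dataclass
class DiscordanceProfile:
    """Per-position discordance against a consensus.

    ``proportion`` is NaN where the effective (non-N) depth is zero: such
    positions are missing, not zero.  ``calls`` is populated by
    `call_polymorphic`.
    """

    ref_id: str
    pos: np.ndarray
    depth_effective: np.ndarray
    n_discordant: np.ndarray
    proportion: np.ndarray
    threshold: float | None = None
    calls: set = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pos": self.pos,
                "depth_effective": self.depth_effective,
                "n_discordant": self.n_discordant,
                "proportion": self.proportion,
            }
        )
        if self.threshold is not None:
            df["call"] = [int(p) in self.calls for p in self.pos]
        return df


def discordance_profile(pileup: Pileup, consensus: str) -> DiscordanceProfile:
    """Proportion of reads differing from the consensus at each position.

    N read bases are excluded from numerator and denominator; positions
    where the consensus itself is N (masked/uncalled) are reported missing.
    """
    if len(consensus) != pileup.length:
        raise ValueError(
            f"consensus length {len(consensus)} != pileup length {pileup.length}"
        )
    cons_codes = encode(consensus)
    acgt = pileup.acgt_counts
    eff_depth = acgt.sum(axis=0)
    pos_idx = np.arange(pileup.length)
    concordant = np.where(
        cons_codes < 4,
        acgt[np.minimum(cons_codes, 3), pos_idx],
        0,
    )
    n_disc = eff_depth - concordant
    with np.errstate(divide="ignore", invalid="ignore"):
        proportion = np.where(eff_depth > 0, n_disc / np.maximum(eff_depth, 1), np.nan)
    proportion = np.where(cons_codes < 4, proportion, np.nan)
    return DiscordanceProfile(
        ref_id=pileup.ref_id,
        pos=pos_idx,
        depth_effective=eff_depth,
        n_discordant=n_disc,
        proportion=proportion,
    )


def call_polymorphic(
    profile: DiscordanceProfile,
    threshold: float = 0.02,
    regions: list[tuple[str, int, int]] | None = None,
):
    """Call positions with discordance >= threshold as polymorphic.

    ``regions`` is a BED-style list of (name, start, end) intervals
    (0-based half-open); per-region percent polymorphic is 100 x calls /
    region length, reported to one decimal.  Without regions a single
    whole-profile region is used.  Returns ``(positions, percents)``.
    """
    valid = ~np.isnan(profile.proportion)
    called = valid & (profile.proportion >= threshold)
    positions = sorted(int(p) for p in profile.pos[called])
    profile.threshold = threshold
    profile.calls = set(positions)
    if regions is None:
        regions = [("all", 0, len(profile.pos))]
    percents = {}
    for name, start, end in regions:
        if end <= start:
            raise ValueError(f"region {name!r}: end must exceed start")
        n_called = sum(1 for p in positions if start <= p < end)
        percents[name] = round(100.0 * n_called / (end - start), 1)
    return positions, percents


@dataclass
class ControlErrorProfile:
    """Summary of residual discordance on a known control sequence."""

    overall_mean_discordance: float
    max_position: tuple[int, float]
    _proportions: np.ndarray = field(repr=False, default=None)
    _positions: np.ndarray = field(repr=False, default=None)

    def n_positions_above(self, cutoff: float) -> int:
        return int(np.count_nonzero(self._proportions > cutoff))


def control_error_profile(control_profile: DiscordanceProfile) -> ControlErrorProfile:
    """Mean discordance, worst position and exceedance counts on a control.

    Systematic-error positions (the control analogue of a >17% anomaly)
    surface as ``max_position``; they are reported, never auto-removed.
    """
    valid = ~np.isnan(control_profile.proportion)
    props = control_profile.proportion[valid]
    positions = control_profile.pos[valid]
    if props.size == 0:
        raise ValueError("control profile has no covered positions")
    worst = int(np.argmax(props))
    return ControlErrorProfile(
        overall_mean_discordance=float(props.mean()),
        max_position=(int(positions[worst]), float(props[worst])),
        _proportions=props,
        _positions=positions,
    )
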