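"""Confidence filtering of miRNA->target interactions and temporal pairing.

A miRNA DE at time t is paired only with targets DE at the same or a
later time (regulator change precedes target change), through
interactions that are either experimentally observed or predicted with
high confidence (conserved miRNA and a conserved site, or a total
context score of -0.4 or less).  For three time points this yields six
paired datasets per region, named "XhDEmiR/YhDEtargets".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datasets import InteractionRecord

CONTEXT_SCORE_CUTOFF = -0.4
TIME_PAIRS = ((0, 0), (0, 8), (0, 120), (8, 8), (8, 120), (120, 120))


def passes_confidence(rec: InteractionRecord, context_cutoff: float = CONTEXT_SCORE_CUTOFF) -> bool:
    if rec.evidence == "experimental":
        return True
    if rec.evidence == "predicted_high":
        return rec.mirna_conserved and (
            rec.n_conserved_sites >= 1 or rec.context_score <= context_cutoff
        )
    return False


def confidence_filter(
    records: Iterable[InteractionRecord], context_cutoff: float = CONTEXT_SCORE_CUTOFF
) -> list[InteractionRecord]:
    """Keep experimentally observed and high-confidence predicted interactions."""
    return [r for r in records if passes_confidence(r, context_cutoff)]


@dataclass
class PairedDataset:
    """One "XhDEmiR/YhDEtargets" set: miRNAs DE at X h paired with their
    confidence-passing targets DE at Y >= X h."""

    region: str
    mirna_time_h: int
    target_time_h: int
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.target_time_h < self.mirna_time_h:
            raise ValueError("target time must be >= miRNA time")

    @property
    def name(self) -> str:
        return f"{self.mirna_time_h}hDEmiR/{self.target_time_h}hDEtargets"

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {g for _, g in self.pairs}

    @property
    def molecules(self) -> set[str]:
        return self.mirnas | self.targets

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(
            {
                "mirna": [m for m, _ in rows],
                "gene": [g for _, g in rows],
                "mirna_time_h": self.mirna_time_h,
                "target_time_h": self.target_time_h,
            }
        )


def temporal_pairing(
    de_mirnas_by_time: Mapping[int, set[str]],
    de_targets_by_time: Mapping[int, set[str]],
    records: Sequence[InteractionRecord],
    region: str = "",
    time_pairs: Sequence[tuple[int, int]] = TIME_PAIRS,
    prefiltered: bool = False,
) -> list[PairedDataset]:
    """Build the six paired datasets of one region.

    ``records`` are confidence-filtered first unless ``prefiltered``.
    Empty datasets are still emitted under their name, so each region
    always yields exactly ``len(time_pairs)`` datasets.
    """
    if not prefiltered:
        records = confidence_filter(records)
    by_mirna: dict[str, set[str]] = {}
    for r in records:
        by_mirna.setdefault(r.mirna_id, set()).add(r.gene_id)

    out = []
    for t_mir, t_tgt in time_pairs:
        psd = PairedDataset(region=region, mirna_time_h=t_mir, target_time_h=t_tgt)
        mirs = de_mirnas_by_time.get(t_mir, set())
        tgts = de_targets_by_time.get(t_tgt, set())
        for m in mirs:
            for g in by_mirna.get(m, ()):  # only interaction-backed pairs
                if g in tgts:
                    psd.pairs.add((m, g))
        out.append(psd)
    return out


def overlap_proportion(targets_earlier: set[str], targets_later: set[str]) -> float | None:
    """Shared targets as a percentage of the earlier time point's targets.

    Returns None (an absent value) when the earlier set is empty.
    """
    if not targets_earlier:
        return None
    return 100.0 * len(targets_earlier & targets_later) / len(targets_earlier)


def multi_time_targets(
    targets_by_time: Mapping[int, set[str]],
) -> tuple[set[str], set[str]]:
    """Partition 0h-miRNA targets by the exact pattern of DE times.

    Returns (targets DE at 0, 8 and 120 h; targets DE at 0 and 120 h
    only).
    """
    t0 = targets_by_time.get(0, set())
    t8 = targets_by_time.get(8, set())
    t120 = targets_by_time.get(120, set())
    all_three = t0 & t8 & t120
    zero_and_120_only = (t0 & t120) - t8
    return all_three, zero_and_120_only


def region_overlap_summary(sets_by_region: Mapping[str, set[str]]) -> dict[str, int]:
    """Counts of every non-empty intersection class across regions.

    Each probe in the union is assigned to exactly one membership class,
    keyed by the sorted regions it belongs to (e.g. "AMY+PFC").  Class
    counts therefore sum to the size of the union.
    """
    regions = sorted(sets_by_region)
    counts: dict[str, int] = {}
    for k in range(1, len(regions) + 1):
        for combo in combinations(regions, k):
            inside = set.intersection(*(sets_by_region[r] for r in combo)) if combo else set()
            outside = set.union(set(), *(sets_by_region[r] for r in regions if r not in combo))
            n = len(inside - outside)
            if n:
                counts["+".join(combo)] = n
    return counts
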