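"""Split-consensus voting: classification with an explicit *uncertain* class.

For a field with enough years, every admissible calibration-validation year
split produces two stability maps; where the two sides agree a pixel keeps
the agreed class, where they disagree it is marked uncertain.  Exhausting all
splits and taking the per-pixel modal category turns disagreement between
year subsets into a fourth, explicitly uncertain class — pixels whose
stability label depends on which years happen to be observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import YearSplit, enumerate_splits
from .raster_core import (
    CLASS_HIGH_STABLE,
    CLASS_LOW_STABLE,
    CLASS_NODATA,
    CLASS_UNCERTAIN,
    CLASS_UNSTABLE,
    StabilityMap,
    YieldStack,
)
from .stability import ThresholdSet, classify

__all__ = ["VoteTally", "split_consensus_map", "vote_uncertainty", "class_fractions"]

# Modal-vote tie-break, most conservative first: ambiguity is surfaced, not
# hidden behind a stable label.
_TIE_PRIORITY = (CLASS_UNCERTAIN, CLASS_UNSTABLE, CLASS_LOW_STABLE, CLASS_HIGH_STABLE)


@dataclass
class VoteTally:
    """Per-pixel vote counts over the four categories across all splits."""

    counts: dict[int, np.ndarray]
    n_splits: int

    def total(self) -> np.ndarray:
        return sum(self.counts.values())


def split_consensus_map(
    stack: YieldStack, split: YearSplit, thresholds: ThresholdSet
) -> StabilityMap:
    """Classify both sides of one year split; disagreement becomes uncertain."""
    map_a = classify(stack.subset(split.set_a), thresholds)
    map_b = classify(stack.subset(split.set_b), thresholds)
    classes = np.where(
        map_a.classes == map_b.classes, map_a.classes, CLASS_UNCERTAIN
    ).astype(np.uint8)
    classes[~(map_a.valid_mask & map_b.valid_mask)] = CLASS_NODATA
    return StabilityMap(
        classes,
        transform=stack.transform,
        algorithm=thresholds.algorithm + "+consensus",
        thresholds=thresholds,
        years=stack.years,
    )


def vote_uncertainty(
    stack: YieldStack,
    thresholds: ThresholdSet,
    min_years: int = 6,
    min_set_years: int = 3,
    max_splits: int = 500,
    seed: int = 0,
) -> tuple[StabilityMap, VoteTally]:
    """Four-class stability map by voting over all year splits.

    Splits are enumerated exhaustively; fields with very many years are
    guarded by a seeded random subsample capped at ``max_splits``.  Each
    pixel takes its most frequent consensus category, ties resolved by the
    fixed priority uncertain > unstable > low-and-stable > high-and-stable.
    """
    if stack.n_years < min_years:
        raise ValueError(f"need at least {min_years} years, got {stack.n_years}")
    splits = enumerate_splits(stack.years, min_set_years)
    if len(splits) > max_splits:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(splits), size=max_splits, replace=False)
        splits = [splits[i] for i in sorted(idx)]

    counts = {c: np.zeros(stack.shape, dtype=np.int32) for c in _TIE_PRIORITY}
    for split in splits:
        consensus = split_consensus_map(stack, split, thresholds)
        for c in _TIE_PRIORITY:
            counts[c] += consensus.classes == c
    tally = VoteTally(counts, n_splits=len(splits))

    stacked = np.stack([counts[c] for c in _TIE_PRIORITY])  # priority order
    winner_idx = stacked.argmax(axis=0)  # argmax takes the first max => priority tie-break
    classes = np.take(np.array(_TIE_PRIORITY, dtype=np.uint8), winner_idx)
    classes[~stack.joint_mask] = CLASS_NODATA
    voted = StabilityMap(
        classes,
        transform=stack.transform,
        algorithm=thresholds.algorithm + "+voting",
        thresholds=thresholds,
        years=stack.years,
    )
    return voted, tally


def class_fractions(smap: StabilityMap) -> dict[str, float]:
    """Per-category fractions over the map's valid pixels (sum to 1)."""
    valid = smap.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("empty map")
    from .raster_core import CLASS_NAMES

    return {
        CLASS_NAMES[c]: float((smap.classes[valid] == c).sum() / n)
        for c in (CLASS_LOW_STABLE, CLASS_HIGH_STABLE, CLASS_UNSTABLE, CLASS_UNCERTAIN)
    }
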