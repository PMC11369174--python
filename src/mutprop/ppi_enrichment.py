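"""Enrichment of previously reported protein-protein interactions among hits.

The screen's hit list is compared against the searchable background: all
bait x prey protein pairs representable in the library, excluding
self-binding pairs.  The fold enrichment is the ratio of the known-PPI
fraction among observed interactions to the known-PPI fraction in the
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set


@dataclass(frozen=True)
class EnrichmentInput:
    observed_known: int
    observed_total: int
    background_known: int
    background_total: int

    def __post_init__(self) -> None:
        if self.observed_total <= 0 or self.background_total <= 0:
            raise ValueError("totals must be positive")
        if self.observed_known > self.observed_total or self.background_known > self.background_total:
            raise ValueError("known counts cannot exceed totals")
        if min(self.observed_known, self.background_known) < 0:
            raise ValueError("counts must be non-negative")


def enrichment_ratio(inp: EnrichmentInput) -> float:
    """Observed known-PPI fraction over background fraction, 2 decimals."""
    if inp.background_known == 0:
        raise ZeroDivisionError("background has no known interactions; ratio undefined")
    observed = inp.observed_known / inp.observed_total
    background = inp.background_known / inp.background_total
    return round(observed / background, 2)


def background_pairs(baits: Set[str] | Iterable[str], preys: Set[str] | Iterable[str]) -> int:
    """Number of unique bait x prey protein pairs excluding self-binding."""
    baits, preys = set(baits), set(preys)
    if not baits or not preys:
        raise ValueError("bait and prey sets must be non-empty")
    return len(baits) * len(preys) - len(baits & preys)


def count_known(observed_pairs: Iterable[tuple[str, str]],
                known_pairs: Iterable[tuple[str, str]]) -> int:
    """Observed pairs present in a known-PPI list (orientation-insensitive)."""
    known = {frozenset(p) for p in known_pairs}
    return sum(1 for p in {frozenset(q) for q in observed_pairs} if p in known)
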