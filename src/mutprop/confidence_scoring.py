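"""Confidence scoring of enriched peptides.

Each peptide retained after count processing receives one point per
satisfied criterion: (i) occurrence in replicate selections, (ii) overlap
with another enriched peptide from the same protein, (iii) match to the
bait's motif consensus and (iv) count support.  The 0-4 score maps to a
confidence class: 4 = high, 2-3 = medium, otherwise low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_mapping import MotifModel

DEFAULT_MIN_REPLICATES = 2
DEFAULT_MIN_OVERLAP = 4

CLASS_LOW = "low"
CLASS_MEDIUM = "medium"
CLASS_HIGH = "high"


@dataclass(frozen=True)
class PeptideHit:
    bait_id: str
    peptide: str
    protein_id: str
    window_start: int
    window_end: int
    replicate_occurrence: bool
    peptide_overlap: bool
    motif_match: bool
    count_support: bool
    mean_count: float

    @property
    def criteria(self) -> tuple[bool, bool, bool, bool]:
        return (self.replicate_occurrence, self.peptide_overlap,
                self.motif_match, self.count_support)

    @property
    def score(self) -> int:
        return sum(self.criteria)

    @property
    def confidence_class(self) -> str:
        return classify_score(self.score)


def classify_score(score: int) -> str:
    if not 0 <= score <= 4:
        raise ValueError(f"score {score} outside 0-4")
    if score == 4:
        return CLASS_HIGH
    if score in (2, 3):
        return CLASS_MEDIUM
    return CLASS_LOW


def score_hits(
    merged: pd.DataFrame,
    peptide_meta: Mapping[str, tuple[str, int, int]],
    motif: MotifModel | None,
    bait_id: str,
    r_min: int = DEFAULT_MIN_REPLICATES,
    o_min: int = DEFAULT_MIN_OVERLAP,
    c_min: float | None = None,
) -> list[PeptideHit]:
    """Score every enriched peptide of one bait.

    ``merged`` is the peptide x replicate table of normalised average counts;
    ``peptide_meta`` maps a peptide to its (protein_id, window_start,
    window_end).  ``c_min`` defaults to the median mean merged count of the
    retained peptides.  A missing motif model makes criterion (iii) evaluate
    false with a warning rather than failing.
    """
    if motif is None:
        warnings.warn(f"no motif model for bait {bait_id}; motif criterion set to false",
                      stacklevel=2)
    merged = merged.loc[merged.sum(axis=1) > 0]
    if merged.empty:
        return []
    mean_counts = merged.mean(axis=1)
    if c_min is None:
        c_min = float(np.median(mean_counts))
    n_replicates = (merged > 0).sum(axis=1)

    by_protein: dict[str, list[tuple[str, int, int]]] = {}
    for pep in merged.index:
        prot, w0, w1 = peptide_meta[pep]
        by_protein.setdefault(prot, []).append((pep, w0, w1))

    hits: list[PeptideHit] = []
    for pep in merged.index:
        prot, w0, w1 = peptide_meta[pep]
        overlap = any(
            other != pep and min(w1, o1) - max(w0, o0) + 1 >= o_min
            for other, o0, o1 in by_protein[prot]
        )
        hits.append(
            PeptideHit(
                bait_id=bait_id,
                peptide=pep,
                protein_id=prot,
                window_start=w0,
                window_end=w1,
                replicate_occurrence=bool(n_replicates[pep] >= r_min),
                peptide_overlap=overlap,
                motif_match=bool(motif.search(pep)) if motif is not None else False,
                count_support=bool(mean_counts[pep] >= c_min),
                mean_count=float(mean_counts[pep]),
            )
        )
    return hits


def hits_to_frame(hits: Sequence[PeptideHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bait_id": [h.bait_id for h in hits],
            "peptide": [h.peptide for h in hits],
            "protein_id": [h.protein_id for h in hits],
            "window_start": [h.window_start for h in hits],
            "window_end": [h.window_end for h in hits],
            "replicate_occurrence": [h.replicate_occurrence for h in hits],
            "peptide_overlap": [h.peptide_overlap for h in hits],
            "motif_match": [h.motif_match for h in hits],
            "count_support": [h.count_support for h in hits],
            "mean_count": [h.mean_count for h in hits],
            "score": [h.score for h in hits],
            "confidence": [h.confidence_class for h in hits],
        }
    )
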