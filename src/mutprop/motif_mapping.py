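"""Motif consensus mapping and mutation-position classification.

A bait's short linear motif (SLiM) is described by a consensus over residue
classes: fixed ("key") positions restrict the residue (``Y``, ``[FILV]``)
and wild-card positions (``x`` or ``.``) allow any residue.  Each mutation
is classified by where it falls relative to the motif instance found in the
+/-20-residue window around the mutation site:

* ``key``           - a wild-type match covers the site at a fixed position
* ``wildcard``      - a wild-type match covers the site at a wild-card position
* ``motif_created`` - only the mutant window matches at that span and the
  mutated residue occupies a fixed position (the mutation completes the motif)
* ``flanking``      - matches exist in the window but none covers the site
* ``no_motif``      - no match in either window

The physicochemical severity of a substitution is quantified by the Grantham
distance (composition / polarity / volume) with the conventional class
boundaries: conservative (<51), moderately conservative (51-100), moderately
radical (101-150) and radical (>150).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORY_KEY = "key"
CATEGORY_WILDCARD = "wildcard"
CATEGORY_FLANKING = "flanking"
CATEGORY_MOTIF_CREATED = "motif_created"
CATEGORY_NO_MOTIF = "no_motif"

_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPosition:
    allowed: frozenset[str]

    @property
    def is_fixed(self) -> bool:
        return len(self.allowed) < 20


@dataclass(frozen=True)
class MotifModel:
    """Consensus motif of a bait domain (ELM-style regex subset)."""

    bait_id: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError(f"consensus {self.consensus!r} shorter than 2 positions")

    @property
    def positions(self) -> tuple[MotifPosition, ...]:
        return _parse_consensus(self.consensus)

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> list[int]:
        """0-based start offsets of all consensus matches within ``window``."""
        positions = self.positions
        n = len(positions)
        return [
            i
            for i in range(len(window) - n + 1)
            if all(window[i + j] in positions[j].allowed for j in range(n))
        ]

    def search(self, sequence: str) -> bool:
        return bool(self.matches(sequence))


def _parse_consensus(consensus: str) -> tuple[MotifPosition, ...]:
    positions: list[MotifPosition] = []
    i = 0
    while i < len(consensus):
        ch = consensus[i]
        if ch == "[":
            j = consensus.index("]", i)
            allowed = frozenset(consensus[i + 1: j])
            i = j + 1
        elif ch in ("x", "."):
            allowed = frozenset(_ALL_AA)
            i += 1
        elif ch in _ALL_AA:
            allowed = frozenset(ch)
            i += 1
        else:
            raise ValueError(f"unsupported consensus token {ch!r} in {consensus!r}")
        positions.append(MotifPosition(allowed))
    return tuple(positions)


@dataclass(frozen=True)
class PSSM:
    """Optional position-specific scoring matrix with a log-odds match threshold."""

    bait_id: str
    weights: pd.DataFrame  # positions x residues, log-odds
    threshold: float

    def score(self, window: str, offset: int) -> float:
        n = len(self.weights)
        return float(sum(self.weights.iloc[j][window[offset + j]] for j in range(n)))

    def matches(self, window: str) -> list[int]:
        n = len(self.weights)
        return [
            i for i in range(len(window) - n + 1) if self.score(window, i) >= self.threshold
        ]


@dataclass
class MutationMotifAnnotation:
    bait_id: str
    protein_id: str
    mutation: str
    category: str
    motif_span: tuple[int, int] | None  # 1-based inclusive protein coordinates
    distance_to_motif: int | None
    grantham: float | None
    grantham_class: str | None


def extract_window(protein_seq: str, position: int, mut_aa: str,
                   flank: int = 20) -> tuple[str, str, int]:
    """+/-``flank`` residue windows around a 1-based mutation position.

    Returns (wt_window, mut_window, offset) where ``offset`` is the 1-based
    protein position of the window's first residue; windows are truncated at
    the sequence termini.
    """
    if not 1 <= position <= len(protein_seq):
        raise ValueError(f"position {position} outside sequence of length {len(protein_seq)}")
    lo = max(1, position - flank)
    hi = min(len(protein_seq), position + flank)
    wt_window = protein_seq[lo - 1: hi]
    k = position - lo
    mut_window = wt_window[:k] + mut_aa + wt_window[k + 1:]
    return wt_window, mut_window, lo


def classify_mutation(
    wt_window: str,
    mut_window: str,
    pos_in_window: int,
    motif: MotifModel,
    *,
    bait_id: str | None = None,
    protein_id: str = "",
    mutation: str = "",
    window_offset: int = 1,
    known_spans: Sequence[tuple[int, int]] | None = None,
) -> MutationMotifAnnotation:
    """Classify a mutation's position relative to the bait's motif.

    ``pos_in_window`` is the 0-based index of the mutated residue in the
    windows.  ``known_spans`` (0-based inclusive window coordinates) are
    curated motif instances that take precedence over de novo scanning.
    Ties between overlapping matches are broken toward the match covering
    the mutation, then leftmost.
    """
    if len(wt_window) != len(mut_window):
        raise ValueError("wild-type and mutant windows differ in length")
    n = len(motif)
    wt_aa, mut_aa = wt_window[pos_in_window], mut_window[pos_in_window]
    g = grantham(wt_aa, mut_aa) if wt_aa != mut_aa else 0.0

    if known_spans:
        spans = [(s, e) for s, e in known_spans]
        wt_starts = [s for s, _ in spans]
        mut_starts: list[int] = []
    else:
        wt_starts = motif.matches(wt_window)
        mut_starts = motif.matches(mut_window)

    def covering(starts: Sequence[int]) -> list[int]:
        return [s for s in starts if s <= pos_in_window <= s + n - 1]

    def annotate(category: str, span_start: int | None, distance: int | None
                 ) -> MutationMotifAnnotation:
        span = None
        if span_start is not None:
            span = (window_offset + span_start, window_offset + span_start + n - 1)
        return MutationMotifAnnotation(
            bait_id=bait_id or motif.bait_id,
            protein_id=protein_id,
            mutation=mutation or f"{wt_aa}{window_offset + pos_in_window}{mut_aa}",
            category=category,
            motif_span=span,
            distance_to_motif=distance,
            grantham=g,
            grantham_class=grantham_class(g),
        )

    wt_cover = covering(wt_starts)
    if wt_cover:
        s = wt_cover[0]
        fixed = motif.positions[pos_in_window - s].is_fixed
        return annotate(CATEGORY_KEY if fixed else CATEGORY_WILDCARD, s, 0)

    mut_cover = [
        s for s in covering(mut_starts)
        if s not in wt_starts and motif.positions[pos_in_window - s].is_fixed
    ]
    if mut_cover:
        return annotate(CATEGORY_MOTIF_CREATED, mut_cover[0], 0)

    away = sorted(set(wt_starts) | set(mut_starts))
    if away:
        def dist(s: int) -> int:
            if s > pos_in_window:
                return s - pos_in_window
            return pos_in_window - (s + n - 1)
        nearest = min(away, key=lambda s: (dist(s), s))
        return annotate(CATEGORY_FLANKING, nearest, dist(nearest))
    return annotate(CATEGORY_NO_MOTIF, None, None)


# --- Grantham distance -----------------------------------------------------

#: Composition (c), polarity (p) and molecular volume (v) per residue.
_GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0.0, 4.9, 111),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0.0, 8.1, 31),
    "V": (0.0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0.0, 5.2, 111),
    "F": (0.0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
    "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
    "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
    "M": (0.0, 5.7, 105), "W": (0.13, 5.4, 170),
}
_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399


def _grantham_raw(a: str, b: str) -> float:
    c1, p1, v1 = _GRANTHAM_PROPERTIES[a]
    c2, p2, v2 = _GRANTHAM_PROPERTIES[b]
    return math.sqrt(
        _ALPHA * (c1 - c2) ** 2 + _BETA * (p1 - p2) ** 2 + _GAMMA * (v1 - v2) ** 2
    )


def _build_grantham_matrix() -> dict[tuple[str, str], int]:
    pairs = list(itertools.combinations(_GRANTHAM_PROPERTIES, 2))
    rho = 100.0 / (sum(_grantham_raw(a, b) for a, b in pairs) / len(pairs))
    matrix: dict[tuple[str, str], int] = {}
    for a, b in pairs:
        d = round(rho * _grantham_raw(a, b))
        matrix[(a, b)] = d
        matrix[(b, a)] = d
    for a in _GRANTHAM_PROPERTIES:
        matrix[(a, a)] = 0
    return matrix


GRANTHAM_MATRIX: dict[tuple[str, str], int] = _build_grantham_matrix()


def grantham(aa_from: str, aa_to: str) -> float:
    """Grantham distance between two residues (0 iff identical; symmetric)."""
    try:
        return float(GRANTHAM_MATRIX[(aa_from, aa_to)])
    except KeyError:
        raise ValueError(f"non-canonical residue pair ({aa_from!r}, {aa_to!r})") from None


def grantham_class(score: float) -> str:
    """Severity class: <51 / 51-100 / 101-150 / >150 (closed named ranges)."""
    if score < 51:
        return "conservative"
    if score <= 100:
        return "moderately_conservative"
    if score <= 150:
        return "moderately_radical"
    return "radical"


def annotations_to_frame(annotations: Sequence[MutationMotifAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bait_id": [a.bait_id for a in annotations],
            "protein_id": [a.protein_id for a in annotations],
            "mutation": [a.mutation for a in annotations],
            "category": [a.category for a in annotations],
            "motif_start": [a.motif_span[0] if a.motif_span else np.nan for a in annotations],
            "motif_end": [a.motif_span[1] if a.motif_span else np.nan for a in annotations],
            "distance": [a.distance_to_motif for a in annotations],
            "grantham": [a.grantham for a in annotations],
            "grantham_class": [a.grantham_class for a in annotations],
        }
    )
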