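"""Mutation-centred analysis of phage selection counts.

All wild-type/mutant peptide pairs reporting on the same mutation site are
collapsed into a single domain-mutation pair per bait.  Two statistics are
computed over the collapsed observations (one observation = one overlapping
peptide pair in one selection replicate, with normalised counts nc_wt and
nc_mut):

* the mutation enrichment score
      sum_i nc_mut_i / (nc_wt_i + nc_mut_i)  -  sum_i nc_wt_i / (nc_wt_i + nc_mut_i)
  bounded by +/-n; positive = the mutation enhances binding, negative =
  the mutation diminishes binding;
* a two-sided Mann-Whitney U p-value comparing the vector of wild-type
  counts against the vector of mutant counts.

Pairs with p below the cut-off (default 0.001) are classified as enhancing
or diminishing by the sign of the score; the rest are neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_design import PeptidePairDesign

DEFAULT_P_CUTOFF = 0.001

#: Cut-off for the per-window (individual peptide pair) Mann-Whitney test.
#: With a handful of replicates per window the exact-test p floor
#: (2 / C(2r, r), e.g. ~0.008 at 5 vs 5) sits above the collapsed-pair
#: cut-off, so the window-level call uses a conventional 0.05.
DEFAULT_INDIVIDUAL_P_CUTOFF = 0.05

DIRECTION_ENHANCING = "enhancing"
DIRECTION_DIMINISHING = "diminishing"
DIRECTION_NEUTRAL = "neutral"

#: Above this combined sample size the Mann-Whitney p switches from the
#: exact distribution to the tie-corrected normal approximation.
EXACT_N_MAX = 20


@dataclass(frozen=True)
class PairObservation:
    """Counts of one wild-type/mutant peptide pair in one replicate."""

    nc_wt: float
    nc_mut: float
    window: int
    replicate: str

    def __post_init__(self) -> None:
        if self.nc_wt < 0 or self.nc_mut < 0:
            raise ValueError("normalised counts must be non-negative")
        if self.nc_wt == 0 and self.nc_mut == 0:
            raise ValueError("zero/zero observations are excluded before scoring")


@dataclass
class DomainMutationPair:
    bait_id: str
    protein_id: str
    mutation: str
    n_obs: int
    enrichment_score: float
    p_value: float
    direction: str
    n_significant_individual_pairs: int


def collapse_pairs(
    merged: pd.DataFrame,
    designs: Sequence[PeptidePairDesign],
    min_count: float = 0.0,
) -> dict[tuple[str, str], list[PairObservation]]:
    """Collapse per-peptide counts into per-mutation observation lists.

    ``merged`` is the peptide x replicate table of normalised average counts
    for one bait.  For every designed pair and every replicate, one
    observation (nc_wt, nc_mut) is formed; observations where both counts
    are zero (or ``min_count`` or below) on both sides are dropped.  Keys
    are (protein_id, mutation label).
    """
    out: dict[tuple[str, str], list[PairObservation]] = {}
    lut = merged.to_dict(orient="index") if not merged.empty else {}
    replicates = list(merged.columns)
    for d in designs:
        wt_row = lut.get(d.wt_peptide)
        mut_row = lut.get(d.mut_peptide)
        if wt_row is None and mut_row is None:
            continue
        for rep in replicates:
            nc_wt = float(wt_row[rep]) if wt_row else 0.0
            nc_mut = float(mut_row[rep]) if mut_row else 0.0
            if nc_wt <= min_count and nc_mut <= min_count:
                continue
            key = (d.protein_id, d.variant.label)
            out.setdefault(key, []).append(
                PairObservation(nc_wt, nc_mut, d.window_start, str(rep))
            )
    return out


def enrichment_score(obs: Sequence[PairObservation]) -> float:
    """Sum of mutant count fractions minus sum of wild-type count fractions."""
    if not obs:
        raise ValueError("enrichment score undefined for empty observations")
    fracs = np.array([o.nc_mut / (o.nc_wt + o.nc_mut) for o in obs])
    return float(np.sum(fracs) - np.sum(1.0 - fracs))


def mw_test(obs: Sequence[PairObservation]) -> float:
    """Two-sided Mann-Whitney U p-value, wild-type vs mutant count vectors.

    Uses the exact null distribution when the combined sample size is at
    most ``EXACT_N_MAX`` and there are no ties, and the midrank normal
    approximation with tie correction otherwise.  Identical vectors give
    p = 1.
    """
    if not obs:
        raise ValueError("at least one observation required")
    wt = np.array([o.nc_wt for o in obs])
    mut = np.array([o.nc_mut for o in obs])
    return mw_test_vectors(wt, mut)


def mw_test_vectors(wt: np.ndarray, mut: np.ndarray) -> float:
    pooled = np.concatenate([wt, mut])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(wt, mut, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def classify(score: float, p_value: float, p_cutoff: float = DEFAULT_P_CUTOFF) -> str:
    """Direction call: enhancing / diminishing at the cut-off, else neutral."""
    if p_value <= p_cutoff and score > 0:
        return DIRECTION_ENHANCING
    if p_value <= p_cutoff and score < 0:
        return DIRECTION_DIMINISHING
    return DIRECTION_NEUTRAL


def individual_pair_significance(
    obs: Sequence[PairObservation], p_cutoff: float = DEFAULT_INDIVIDUAL_P_CUTOFF
) -> int:
    """Number of peptide windows whose own replicate counts differ significantly."""
    by_window: dict[int, list[PairObservation]] = {}
    for o in obs:
        by_window.setdefault(o.window, []).append(o)
    n_sig = 0
    for window, window_obs in sorted(by_window.items()):
        if len(window_obs) < 2:
            warnings.warn(f"window {window}: fewer than 2 replicates, skipped",
                          stacklevel=2)
            continue
        wt = np.array([o.nc_wt for o in window_obs])
        mut = np.array([o.nc_mut for o in window_obs])
        if mw_test_vectors(wt, mut) <= p_cutoff:
            n_sig += 1
    return n_sig


def analyse_bait(
    merged: pd.DataFrame,
    designs: Sequence[PeptidePairDesign],
    bait_id: str,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    individual_p_cutoff: float = DEFAULT_INDIVIDUAL_P_CUTOFF,
) -> list[DomainMutationPair]:
    """Full mutation-centred analysis for one bait's merged count table."""
    collapsed = collapse_pairs(merged, designs)
    results = []
    for (protein_id, mutation), obs in sorted(collapsed.items()):
        score = enrichment_score(obs)
        p = mw_test(obs)
        results.append(
            DomainMutationPair(
                bait_id=bait_id,
                protein_id=protein_id,
                mutation=mutation,
                n_obs=len(obs),
                enrichment_score=score,
                p_value=p,
                direction=classify(score, p, p_cutoff),
                n_significant_individual_pairs=individual_pair_significance(
                    obs, individual_p_cutoff),
            )
        )
    return results


def pairs_to_frame(pairs: Iterable[DomainMutationPair],
                   fdr_column: bool = True) -> pd.DataFrame:
    """Result table; an optional Benjamini-Hochberg FDR column is reported
    but never used for classification."""
    pairs = list(pairs)
    df = pd.DataFrame(
        {
            "bait_id": [p.bait_id for p in pairs],
            "protein_id": [p.protein_id for p in pairs],
            "mutation": [p.mutation for p in pairs],
            "n_obs": [p.n_obs for p in pairs],
            "enrichment_score": [p.enrichment_score for p in pairs],
            "p_value": [p.p_value for p in pairs],
            "direction": [p.direction for p in pairs],
            "n_significant_windows": [p.n_significant_individual_pairs for p in pairs],
        }
    )
    if fdr_column and len(df):
        df["fdr"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def v_plot(df: pd.DataFrame, path: str, p_cutoff: float = DEFAULT_P_CUTOFF) -> None:
    """V-shaped plot: enrichment score vs -log10 p, coloured by direction."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colours = {DIRECTION_ENHANCING: "#c0392b", DIRECTION_DIMINISHING: "#2980b9",
               DIRECTION_NEUTRAL: "#95a5a6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for direction, sub in df.groupby("direction"):
        ax.scatter(sub["enrichment_score"], -np.log10(sub["p_value"].clip(lower=1e-300)),
                   s=12, c=colours.get(direction, "k"), label=direction, alpha=0.8)
    ax.axhline(-np.log10(p_cutoff), ls="--", lw=0.8, c="k")
    ax.set_xlabel("mutation enrichment score")
    ax.set_ylabel("-log10 p (Mann-Whitney)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
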