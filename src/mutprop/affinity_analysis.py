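"""Fluorescence-polarisation affinity analytics.

Saturation curves (probe + titrated protein) are fitted with the quadratic
ligand-depletion binding model, displacement curves (probe-protein complex +
titrated unlabelled competitor) with a four-parameter logistic on the log10
competitor concentration; IC50 values are converted to competitor K_D by the
competitive-binding correction of Nikolovska-Coleska et al. (free-inhibitor,
probe-occupancy and free-protein terms at the inhibition midpoint).

Wild-type/mutant affinity fold-changes are oriented so that fold > 1 means
the mutant binds tighter, making sign(log2 fold) directly comparable to the
sign of the phage mutation enrichment score.  A pair in which one member
shows no displacement within the titrated range is an unbounded affinity
change; its fold is capped (default cap 20, |log2| = 4.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

#: Sentinel for "no displacement within the titrated concentration range".
NON_BINDER = float("inf")

DEFAULT_FOLD_CAP = 20.0
DEFAULT_AGREEMENT_THRESHOLD = 2.0


# --- forward models --------------------------------------------------------

def bound_fraction_quadratic(protein: np.ndarray, probe_total: float, kd: float) -> np.ndarray:
    """Fraction of probe bound under ligand depletion (physical quadratic root)."""
    protein = np.asarray(protein, dtype=float)
    s = protein + probe_total + kd
    disc = np.clip(s * s - 4.0 * protein * probe_total, 0.0, None)
    return (s - np.sqrt(disc)) / (2.0 * probe_total)


def saturation_model(protein: np.ndarray, kd: float, mp_free: float, mp_max: float,
                     probe_total: float) -> np.ndarray:
    return mp_free + (mp_max - mp_free) * bound_fraction_quadratic(protein, probe_total, kd)


def logistic4(log_conc: np.ndarray, top: float, bottom: float, log_ic50: float,
              hill: float) -> np.ndarray:
    """Sigmoidal dose-response with logarithmic x; decreasing for hill > 0."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.asarray(log_conc) - log_ic50)))


# --- curve containers ------------------------------------------------------

@dataclass
class SaturationCurve:
    probe_conc: float
    protein_concs: np.ndarray
    mp_values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        self.mp_values = np.asarray(self.mp_values, dtype=float)
        if len(self.protein_concs) != len(self.mp_values):
            raise ValueError("concentration and mP series differ in length")
        if np.any(self.protein_concs < 0):
            raise ValueError("negative concentrations")


@dataclass
class DisplacementCurve:
    competitor_concs: np.ndarray
    mp_values: np.ndarray
    probe_conc: float
    protein_conc: float
    probe_kd: float
    label: str = ""

    def __post_init__(self) -> None:
        self.competitor_concs = np.asarray(self.competitor_concs, dtype=float)
        self.mp_values = np.asarray(self.mp_values, dtype=float)
        if len(self.competitor_concs) != len(self.mp_values):
            raise ValueError("concentration and mP series differ in length")


@dataclass
class SaturationFit:
    kd: float
    mp_free: float
    mp_max: float
    ok: bool
    message: str = ""


@dataclass
class DisplacementFit:
    ic50: float  # NON_BINDER when no displacement within range
    non_binder: bool
    anomalous: bool
    top: float = math.nan
    bottom: float = math.nan
    hill: float = math.nan
    message: str = ""


# --- fitters ---------------------------------------------------------------

def fit_saturation(curve: SaturationCurve) -> SaturationFit:
    """Least-squares fit of the quadratic binding model to a saturation series."""
    if len(curve.protein_concs) < 5:
        raise ValueError("at least 5 concentration points required")
    mp = curve.mp_values
    span = float(mp.max() - mp.min())
    noise = float(np.std(np.diff(mp))) if len(mp) > 2 else 0.0
    if span <= max(1e-12, 3.0 * noise / math.sqrt(2.0)) or span < 0.02 * abs(mp.max()):
        return SaturationFit(math.nan, float(mp.mean()), float(mp.mean()), False,
                             "flat mP series: no binding transition")
    p0 = [float(np.median(curve.protein_concs[curve.protein_concs > 0])),
          float(mp.min()), float(mp.max())]
    try:
        popt, _ = curve_fit(
            lambda c, kd, lo, hi: saturation_model(c, kd, lo, hi, curve.probe_conc),
            curve.protein_concs, mp, p0=p0,
            bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return SaturationFit(math.nan, math.nan, math.nan, False, f"no convergence: {exc}")
    kd, mp_free, mp_max = map(float, popt)
    ok = kd > 0 and np.isfinite(kd)
    if kd > 100.0 * curve.protein_concs.max():
        return SaturationFit(kd, mp_free, mp_max, False, "kd beyond titrated range")
    return SaturationFit(kd, mp_free, mp_max, ok)


def fit_displacement(curve: DisplacementCurve) -> DisplacementFit:
    """Four-parameter logistic fit on log10 competitor concentration.

    Returns a NON_BINDER result when the curve shows no displacement plateau
    (flat series, vanishing amplitude, or midpoint outside the titrated
    range); an increasing mP trend is flagged anomalous.
    """
    concs = curve.competitor_concs
    mp = curve.mp_values
    pos = concs > 0
    if pos.sum() < 6:
        raise ValueError("at least 6 positive competitor concentrations required")
    logc = np.log10(concs[pos])
    if logc.max() - logc.min() < 2.0:
        raise ValueError("competitor series must span at least 2 decades")
    y = mp[pos]

    rho = stats.spearmanr(logc, y).statistic if np.ptp(y) > 0 else 0.0
    if rho > 0.5 and (y[np.argmax(logc)] - y[np.argmin(logc)]) > 0.05 * abs(y).max():
        return DisplacementFit(math.nan, False, True, message="mP increases with competitor")

    p0 = [float(y.max()), float(y.min()), float(np.median(logc)), 1.0]
    try:
        popt, _ = curve_fit(logistic4, logc, y, p0=p0,
                            bounds=([-np.inf, -np.inf, logc.min() - 6, 0.1],
                                    [np.inf, np.inf, logc.max() + 6, 10.0]),
                            maxfev=20000)
    except RuntimeError:
        return DisplacementFit(NON_BINDER, True, False, message="fit failed: no displacement")
    top, bottom, log_ic50, hill = map(float, popt)
    resid_sd = float(np.std(y - logistic4(logc, *popt)))
    amplitude = top - bottom
    if amplitude <= max(3.0 * resid_sd, 0.02 * abs(top)):
        return DisplacementFit(NON_BINDER, True, False, top, bottom, hill,
                               "top and bottom plateaus indistinguishable")
    if not logc.min() <= log_ic50 <= logc.max():
        return DisplacementFit(NON_BINDER, True, False, top, bottom, hill,
                               "IC50 outside titrated range")
    return DisplacementFit(10.0 ** log_ic50, False, False, top, bottom, hill)


def ic50_to_kd(ic50: float, probe_conc: float, probe_kd: float,
               protein_conc: float) -> float:
    """Competitor K_D from a displacement IC50 (Nikolovska-Coleska correction).

    Corrects the midpoint for probe occupancy and free protein:
    ``K_i = [I]50 / ([L]50/K_d + [P]0/K_d + 1)`` with [I]50 the free
    competitor at 50% inhibition, [L]50 the free probe at 50% inhibition and
    [P]0 the free protein at 0% inhibition.  Always <= IC50; tends to IC50
    in the dilute limit.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if min(probe_conc, probe_kd, protein_conc) <= 0:
        raise ValueError("probe_conc, probe_kd and protein_conc must be positive")
    s = protein_conc + probe_conc + probe_kd
    pl0 = (s - math.sqrt(s * s - 4.0 * protein_conc * probe_conc)) / 2.0
    p0_free = protein_conc - pl0
    pl50 = pl0 / 2.0
    l50_free = probe_conc - pl50
    p50_free = probe_kd * pl50 / l50_free
    pi50 = protein_conc - pl50 - p50_free
    i50_free = ic50 - pi50
    return i50_free / (l50_free / probe_kd + p0_free / probe_kd + 1.0)


# --- fold changes and agreement -------------------------------------------

@dataclass
class FoldChange:
    fold: float
    log2_fold: float  # rounded to 1 decimal for reporting
    capped: bool


def fold_change(kd_wt: float, kd_mut: float, cap: float = DEFAULT_FOLD_CAP) -> FoldChange:
    """K_D ratio oriented so fold > 1 means the mutant binds tighter.

    A NON_BINDER on either side caps the fold at ``cap`` (or 1/cap); both
    sides NON_BINDER is undefined.
    """
    wt_nb = math.isinf(kd_wt)
    mut_nb = math.isinf(kd_mut)
    if wt_nb and mut_nb:
        raise ValueError("fold change undefined when neither peptide binds")
    if wt_nb:
        fold = cap
    elif mut_nb:
        fold = 1.0 / cap
    else:
        if kd_wt <= 0 or kd_mut <= 0:
            raise ValueError("K_D values must be positive")
        fold = kd_wt / kd_mut
    return FoldChange(fold, round(math.log2(fold), 1), wt_nb or mut_nb)


@dataclass
class AffinityRecord:
    bait_id: str
    label: str
    kd_wt: float  # NON_BINDER when the wild-type peptide shows no displacement
    kd_mut: float
    sem_wt: float = math.nan
    sem_mut: float = math.nan
    enrichment_score: float | None = None
    cap: float = DEFAULT_FOLD_CAP
    fc: FoldChange = field(init=False)

    def __post_init__(self) -> None:
        self.fc = fold_change(self.kd_wt, self.kd_mut, self.cap)

    def agrees(self, threshold: float = DEFAULT_AGREEMENT_THRESHOLD) -> bool | None:
        """Twofold-and-direction agreement with the phage enrichment score."""
        if self.enrichment_score is None:
            return None
        f = self.fc.fold
        if not (self.fc.capped or f >= threshold or f <= 1.0 / threshold):
            return False
        return (f > 1.0) == (self.enrichment_score > 0)


def agreement_table(records: Sequence[AffinityRecord],
                    threshold: float = DEFAULT_AGREEMENT_THRESHOLD
                    ) -> tuple[int, int, int]:
    """(n_agree, n_total, percent agreement) over records carrying a score."""
    scored = [r for r in records if r.enrichment_score is not None]
    if not scored:
        raise ValueError("no records with an enrichment score")
    n_agree = sum(1 for r in scored if r.agrees(threshold))
    pct = round(100.0 * n_agree / len(scored))
    return n_agree, len(scored), int(pct)


def affinity_spearman(records: Sequence[AffinityRecord]) -> float:
    """Spearman correlation of log2 fold-change with the enrichment score."""
    scored = [r for r in records if r.enrichment_score is not None]
    return float(stats.spearmanr(
        [r.fc.log2_fold for r in scored],
        [r.enrichment_score for r in scored],
    ).statistic)


# --- packaged affinity validation table ------------------------------------

def _parse_kd(value: str) -> float:
    value = str(value).strip()
    if value in ("n.b.", "nb", ""):
        return NON_BINDER
    if value.startswith("<"):
        return float(value[1:])
    return float(value)


def load_affinity_table() -> pd.DataFrame:
    """The packaged affinity validation table (K_D in micromolar)."""
    with resources.files("mutprop.data").joinpath("table1_affinity.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def affinity_records_from_table(df: pd.DataFrame | None = None,
                                primary_only: bool = True,
                                cap: float = DEFAULT_FOLD_CAP) -> list[AffinityRecord]:
    if df is None:
        df = load_affinity_table()
    if primary_only:
        df = df[df["agreement_set"] == "1"]
    records = []
    for row in df.itertuples(index=False):
        score = None if str(row.enrichment_score) in ("n.d.", "nan") else float(row.enrichment_score)
        records.append(
            AffinityRecord(
                bait_id=row.domain,
                label=f"{row.gene} {row.mutation}",
                kd_wt=_parse_kd(row.kd_wt),
                kd_mut=_parse_kd(row.kd_mut),
                enrichment_score=score,
                cap=cap,
            )
        )
    return records
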