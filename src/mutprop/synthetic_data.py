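"""Synthetic datasets with known ground truth for the whole pipeline.

The generator emulates a mutational peptide-phage display experiment: a toy
proteome of disordered regions with one planted motif-relevant variant per
protein, replicate/selection-day structured NGS counts with negative-binomial
overdispersion (phage pools are clonal expansions), and noisy fluorescence-
polarisation curves produced by the same forward models the fitters invert.

Variant classes and their planted binding asymmetry (delta = effect size):

* ``motif_breaking_key``  - wild-type window carries the motif, the mutation
  destroys a fixed position: wt propensity b, mutant b*(1-delta)
* ``motif_creating``      - the mutation completes an almost-motif:
  wt b*(1-delta), mutant b
* ``wildcard_neutral``    - mutation at a wild-card position inside a motif:
  symmetric propensities
* ``flanking_neutral``    - mutation outside the motif: symmetric

delta = 0 is an exact null simulation.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library_design import IdrRegion, PeptidePairDesign, VariantRecord
from .motif_mapping import MotifModel
from .ngs_processing import BarcodeScheme, CountTable
from .affinity_analysis import (
    DisplacementCurve,
    SaturationCurve,
    logistic4,
    saturation_model,
)

CLASS_BREAKING = "motif_breaking_key"
CLASS_CREATING = "motif_creating"
CLASS_WILDCARD = "wildcard_neutral"
CLASS_FLANKING = "flanking_neutral"
ALL_CLASSES = (CLASS_BREAKING, CLASS_CREATING, CLASS_WILDCARD, CLASS_FLANKING)

EXPECTED_DIRECTION = {
    CLASS_BREAKING: "diminishing",
    CLASS_CREATING: "enhancing",
    CLASS_WILDCARD: "neutral",
    CLASS_FLANKING: "neutral",
}

#: Planted consensus (WW-domain style): two fixed prolines, a wild-card, a
#: fixed tyrosine.  Background sequences avoid P so no accidental instances.
DEFAULT_MOTIF = MotifModel("SYN_BAIT", "PPxY")

_BACKGROUND_AA = "ADEFGHIKLMNQRSTVW"  # no P (motif), no C (sanitised away), no Y adjacency risk


@dataclass
class SimulationConfig:
    seed: int = 0
    n_variants_per_class: int = 4
    region_length: int = 48
    effect_size: float = 0.9      # delta, wt/mut propensity asymmetry in [0, 1]
    depth: int = 100_000          # reads per (replicate, day)
    n_replicates: int = 5
    n_days: int = 2
    dispersion: float = 10.0      # negative-binomial size; larger = less overdispersed
    baseline_propensity: float = 1.0
    fp_noise_sd: float = 0.0      # mP units
    peptide_len: int = 16
    step: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if min(self.n_variants_per_class, self.region_length, self.depth,
               self.n_replicates, self.n_days) <= 0:
            raise ValueError("all counts must be positive")
        if self.region_length < len(DEFAULT_MOTIF) + 2 * self.peptide_len:
            raise ValueError("region too short to centre a motif away from the ends")


@dataclass
class GroundTruth:
    motif: MotifModel
    bait_id: str
    variant_class: dict[tuple, str] = field(default_factory=dict)
    expected_direction: dict[tuple, str] = field(default_factory=dict)

    def n_planted(self, cls: str) -> int:
        return sum(1 for c in self.variant_class.values() if c == cls)


@dataclass
class SyntheticLibrary:
    proteome: dict[str, str]
    regions: list[IdrRegion]
    variants: list[VariantRecord]
    truth: GroundTruth


def _random_background(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(_BACKGROUND_AA), size=length))


def simulate_library(config: SimulationConfig) -> SyntheticLibrary:
    """Toy proteome: one region and one planted variant per protein."""
    rng = np.random.default_rng(config.seed)
    motif = DEFAULT_MOTIF
    truth = GroundTruth(motif=motif, bait_id=motif.bait_id)
    proteome: dict[str, str] = {}
    regions: list[IdrRegion] = []
    variants: list[VariantRecord] = []
    idx = 0
    for cls in ALL_CLASSES:
        for _ in range(config.n_variants_per_class):
            idx += 1
            pid = f"SYNP{idx:04d}"
            seq = _random_background(rng, config.region_length)
            centre = config.region_length // 2  # 0-based motif start
            if cls == CLASS_BREAKING:
                seq[centre:centre + 4] = ["P", "P", seq[centre + 2], "Y"]
                var_pos0, wt_aa, mut_aa = centre + 3, "Y", "E"
            elif cls == CLASS_CREATING:
                # almost-motif: tyrosine missing; the mutation supplies it
                seq[centre:centre + 4] = ["P", "P", seq[centre + 2], "F"]
                var_pos0, wt_aa, mut_aa = centre + 3, "F", "Y"
            elif cls == CLASS_WILDCARD:
                seq[centre:centre + 4] = ["P", "P", "S", "Y"]
                var_pos0, wt_aa, mut_aa = centre + 2, "S", "G"
            else:  # flanking
                seq[centre:centre + 4] = ["P", "P", seq[centre + 2], "Y"]
                var_pos0 = centre + 4 + int(rng.integers(1, 4))
                wt_aa = seq[var_pos0]
                mut_aa = "G" if wt_aa != "G" else "A"
            seq[var_pos0] = wt_aa
            protein_seq = "".join(seq)
            proteome[pid] = protein_seq
            regions.append(IdrRegion(pid, 1, len(protein_seq), protein_seq))
            v = VariantRecord(pid, var_pos0 + 1, wt_aa, mut_aa,
                              pathogenicity="pathogenic", origin="somatic")
            variants.append(v)
            truth.variant_class[v.key] = cls
            truth.expected_direction[v.key] = EXPECTED_DIRECTION[cls]
    return SyntheticLibrary(proteome, regions, variants, truth)


def _pair_propensities(cls: str, b: float, delta: float) -> tuple[float, float]:
    if cls == CLASS_BREAKING:
        return b, b * (1.0 - delta)
    if cls == CLASS_CREATING:
        return b * (1.0 - delta), b
    return b, b


def simulate_counts(designs: list[PeptidePairDesign], truth: GroundTruth,
                    config: SimulationConfig) -> CountTable:
    """Overdispersed selection counts per (replicate, selection day).

    Counts are negative-binomial with mean proportional to each peptide's
    binding propensity, scaled so each (replicate, day) totals ~``depth``
    reads in expectation.
    """
    rng = np.random.default_rng(config.seed + 1)
    peptides: list[str] = []
    props: list[float] = []
    seen: set[str] = set()
    for d in designs:
        cls = truth.variant_class[d.variant.key]
        p_wt, p_mut = _pair_propensities(cls, config.baseline_propensity, config.effect_size)
        for pep, prop in ((d.wt_peptide, p_wt), (d.mut_peptide, p_mut)):
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
                props.append(prop)
    props_arr = np.array(props)
    if props_arr.sum() <= 0:
        raise ValueError("all propensities are zero; depth cannot be placed")
    means = config.depth * props_arr / props_arr.sum()
    counts: dict[tuple[str, str, str], int] = {}
    size = config.dispersion
    for rep in range(1, config.n_replicates + 1):
        for day in range(1, config.n_days + 1):
            p = size / (size + means)
            draws = rng.negative_binomial(size, p)
            for pep, c in zip(peptides, draws):
                if c > 0:
                    counts[(pep, f"rep{rep}", f"day{day}")] = int(c)
    return CountTable.from_counts(truth.bait_id, counts)


def make_barcode_scheme(n_replicates: int, n_days: int) -> tuple[BarcodeScheme, dict[str, tuple[str, str]]]:
    """Dual-barcode scheme and sample metadata for FASTQ emission."""
    bases = "ACGT"

    def bc(i: int) -> str:
        return "".join(bases[(i >> (2 * k)) & 3] for k in range(4))

    barcodes: dict[str, tuple[str, str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    i = 0
    for rep in range(1, n_replicates + 1):
        for day in range(1, n_days + 1):
            sample = f"rep{rep}:day{day}"
            barcodes[sample] = (bc(i), bc(i + 97))
            meta[sample] = (f"rep{rep}", f"day{day}")
            i += 1
    scheme = BarcodeScheme(barcodes, adapter5="GGATCC", adapter3="GAATTC")
    return scheme, meta


def emit_fastq(table: CountTable, designs: list[PeptidePairDesign],
               scheme: BarcodeScheme, path, quality: int = 30) -> int:
    """Write the count table out as reads (barcodes + adapters + oligo, uniform Q).

    Reads use the design's own reverse-translated oligos so the FASTQ path
    exercises the same inserts the library emits.  Returns reads written.
    """
    oligo: dict[str, str] = {}
    for d in designs:
        oligo[d.wt_peptide] = d.wt_oligo
        oligo[d.mut_peptide] = d.mut_oligo
    qchar = chr(quality + 33)
    n = 0
    with open(path, "w") as fh:
        for row in table.raw.itertuples(index=False):
            sample = f"{row.replicate}:{row.day}"
            bc5, bc3 = scheme.barcodes[sample]
            seq = bc5 + scheme.adapter5 + oligo[row.peptide] + scheme.adapter3 + bc3
            for k in range(row.count):
                fh.write(f"@{sample}|{row.peptide}|{k}\n{seq}\n+\n{qchar * len(seq)}\n")
                n += 1
    return n


@dataclass
class FpGroundTruth:
    saturation_kd: float
    displacement_kds: dict[str, float]  # label -> planted competitor K_D


def simulate_fp_curves(
    config: SimulationConfig,
    saturation_kd: float = 1e-6,
    competitor_kds: dict[str, float] | None = None,
    probe_conc: float = 10e-9,
    mp_free: float = 50.0,
    mp_complex: float = 250.0,
) -> tuple[SaturationCurve, dict[str, DisplacementCurve], FpGroundTruth]:
    """Saturation and displacement curves from the binding forward models.

    The displacement forward model solves the exact three-species
    competitive equilibrium, so planted competitor K_Ds are recoverable by
    the 4-parameter-logistic fit + IC50 conversion to within the fit's
    discretisation error.  Gaussian mP noise with ``config.fp_noise_sd``.
    """
    rng = np.random.default_rng(config.seed + 2)
    if competitor_kds is None:
        competitor_kds = {"wt": 1e-6, "mut": 25e-6}
    protein = saturation_kd * np.logspace(-2, 2.5, 12)
    mp = saturation_model(protein, saturation_kd, mp_free, mp_complex, probe_conc)
    mp = mp + rng.normal(0.0, config.fp_noise_sd, size=mp.shape)
    sat = SaturationCurve(probe_conc, protein, mp, label="saturation")

    protein_conc = 1.5 * saturation_kd  # 1-2x K_D of the probe complex
    curves: dict[str, DisplacementCurve] = {}
    for label, ki in competitor_kds.items():
        concs = np.logspace(-8.5, -3.0, 12)
        mp_d = np.array([
            _displacement_mp(it, protein_conc, probe_conc, saturation_kd, ki,
                             mp_free, mp_complex)
            for it in concs
        ])
        mp_d = mp_d + rng.normal(0.0, config.fp_noise_sd, size=mp_d.shape)
        curves[label] = DisplacementCurve(concs, mp_d, probe_conc, protein_conc,
                                          saturation_kd, label=label)
    return sat, curves, FpGroundTruth(saturation_kd, dict(competitor_kds))


def _displacement_mp(inhibitor_total: float, protein_total: float, probe_total: float,
                     probe_kd: float, ki: float, mp_free: float, mp_complex: float) -> float:
    """Exact competitive-equilibrium mP for one titration point."""
    from scipy.optimize import brentq

    def imbalance(p_free: float) -> float:
        pl = p_free * probe_total / (probe_kd + p_free)
        pi = p_free * inhibitor_total / (ki + p_free)
        return p_free + pl + pi - protein_total

    p_free = brentq(imbalance, 0.0, protein_total, xtol=1e-30, rtol=1e-14)
    bound_frac = p_free / (probe_kd + p_free)
    return mp_free + (mp_complex - mp_free) * bound_frac
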