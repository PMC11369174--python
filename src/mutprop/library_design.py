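"""Design of tiled wild-type/mutant peptide-pair phage libraries.

Disease-associated missense variants falling in intrinsically disordered
regions (IDRs) are represented in the library by *pairs* of peptides: the
wild-type window and the same window carrying exactly one substitution.
Each IDR is tiled with overlapping fixed-length windows so that an interior
variant is covered by several independent peptide pairs.  Peptides are
sanitised (cysteine -> alanine, to avoid disulphide artefacts on the phage
coat) and reverse-translated into oligonucleotides using an E. coli-optimised
codon table while avoiding a forbidden restriction site in the insert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ranked codons per residue (most-used first) for E. coli K-12 expression.
#: Order follows relative codon-usage frequency in highly expressed genes.
ECOLI_CODON_USAGE: dict[str, tuple[str, ...]] = {
    "A": ("GCG", "GCC", "GCA", "GCT"),
    "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
    "N": ("AAC", "AAT"),
    "D": ("GAT", "GAC"),
    "C": ("TGC", "TGT"),
    "Q": ("CAG", "CAA"),
    "E": ("GAA", "GAG"),
    "G": ("GGC", "GGT", "GGG", "GGA"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("CTG", "TTA", "TTG", "CTC", "CTT", "CTA"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "S": ("AGC", "TCT", "TCC", "AGT", "TCG", "TCA"),
    "T": ("ACC", "ACG", "ACT", "ACA"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTG", "GTT", "GTC", "GTA"),
}

#: SmaI recognition site; inserts must not contain it.
DEFAULT_FORBIDDEN_SITES = frozenset({"CCCGGG"})

PATHOGENIC_CLASSES = frozenset({"pathogenic", "likely_pathogenic"})


@dataclass(frozen=True)
class IdrRegion:
    """A disordered region of a protein (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}:{self.start}-{self.end}: interval length "
                f"{self.end - self.start + 1} != sequence length {len(self.sequence)}"
            )
        bad = [(i, aa) for i, aa in enumerate(self.sequence) if aa not in CANONICAL_AA]
        if bad:
            i, aa = bad[0]
            raise ValueError(
                f"{self.protein_id}: non-canonical residue {aa!r} at region offset {i}"
            )

    def residue(self, position: int) -> str:
        """Residue at an absolute (1-based) protein position."""
        return self.sequence[position - self.start]

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level variant (single substitution, or a short delins).

    ``wt_aa``/``mut_aa`` are single residues for SNVs; for multi-residue
    substitutions they are equal-start strings (``wt_aa`` spans
    ``position .. position+len(wt_aa)-1``).
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    pathogenicity: str = "other"
    origin: str = "unknown"
    disease_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.label}: wild-type and mutant residues are equal")
        for s in (self.wt_aa, self.mut_aa):
            if not s or any(aa not in CANONICAL_AA for aa in s):
                raise ValueError(f"{self.label}: non-canonical residue in {s!r}")

    @property
    def span_end(self) -> int:
        return self.position + len(self.wt_aa) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.wt_aa) == 1 and len(self.mut_aa) == 1

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


@dataclass(frozen=True)
class PeptidePairDesign:
    """One wild-type/mutant peptide pair, the library's atomic unit."""

    wt_peptide: str
    mut_peptide: str
    protein_id: str
    window_start: int  # 1-based absolute position of the window's first residue
    variant: VariantRecord
    wt_oligo: str
    mut_oligo: str

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.wt_peptide) - 1

    @property
    def pair_id(self) -> str:
        return f"{self.protein_id}_{self.window_start}-{self.window_end}_{self.variant.label}"


@dataclass
class DesignSummary:
    n_mutations: int
    n_prey_proteins: int
    n_unique_peptides: int
    n_wt_peptides: int
    n_pairs: int
    pct_pathogenic: float
    pct_somatic: float
    disease_category_counts: dict[str, int]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage of ``numerator`` in ``denominator``, rounded for reporting."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def sanitize_peptide(seq: str) -> str:
    """Replace every cysteine by alanine; reject non-canonical residues."""
    if not seq:
        raise ValueError("empty peptide")
    for i, aa in enumerate(seq):
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}")
    return seq.replace("C", "A")


def reverse_translate(
    peptide: str,
    codon_usage: Mapping[str, Sequence[str]] | None = None,
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN_SITES,
) -> str:
    """Deterministic reverse translation avoiding forbidden DNA substrings.

    Greedy highest-ranked codon choice with local backtracking: when
    appending the top codon would create a forbidden site across a codon
    junction, lower-ranked codons are tried at the current position, and if
    all fail the previous position is revisited.
    """
    usage = codon_usage or ECOLI_CODON_USAGE
    max_site = max((len(s) for s in forbidden), default=0)

    def clean(dna: str) -> bool:
        window = dna[-(max_site + 2):] if max_site else dna
        return not any(site in window for site in forbidden)

    chosen: list[int] = []  # codon rank chosen at each peptide position
    dna_parts: list[str] = []
    i = 0
    while i < len(peptide):
        aa = peptide[i]
        if aa not in usage:
            raise ValueError(f"no codons for residue {aa!r}")
        start_rank = chosen[i] + 1 if i < len(chosen) else 0
        placed = False
        for rank in range(start_rank, len(usage[aa])):
            candidate = "".join(dna_parts) + usage[aa][rank]
            if clean(candidate):
                if i < len(chosen):
                    chosen[i] = rank
                else:
                    chosen.append(rank)
                dna_parts.append(usage[aa][rank])
                placed = True
                break
        if placed:
            i += 1
        else:
            # exhaust this position: backtrack
            if i < len(chosen):
                del chosen[i:]
            if not dna_parts:
                raise ValueError(f"cannot reverse-translate {peptide!r} under constraints")
            dna_parts.pop()
            i -= 1
            if i < 0:
                raise ValueError(f"cannot reverse-translate {peptide!r} under constraints")
    dna = "".join(dna_parts)
    if str(Seq(dna).translate()) != peptide:
        raise AssertionError("reverse translation round-trip failed")  # pragma: no cover
    return dna


def _windows(region: IdrRegion, peptide_len: int, step: int) -> list[int]:
    """Absolute start positions of full tiling windows."""
    starts = []
    s = region.start
    while s + peptide_len - 1 <= region.end:
        starts.append(s)
        s += step
    return starts


def _apply_variant(window_seq: str, window_start: int, variant: VariantRecord) -> str:
    off = variant.position - window_start
    return window_seq[:off] + variant.mut_aa + window_seq[off + len(variant.wt_aa):]


def tile_region(
    region: IdrRegion,
    variants: Iterable[VariantRecord],
    peptide_len: int = 16,
    step: int = 4,
    codon_usage: Mapping[str, Sequence[str]] | None = None,
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN_SITES,
) -> list[PeptidePairDesign]:
    """Tile one region and emit a wt/mut pair per (window, overlapping variant).

    Only a single mutation is introduced per designed peptide: several
    variants inside one window yield several mutant peptides sharing the
    same wild-type partner.  If a variant near the region's trailing end is
    not covered by any full-step window, one extra window anchored at the
    region end is added so that terminal variants are not lost.
    """
    if peptide_len <= step:
        raise ValueError("peptide_len must exceed step")
    variants = list(variants)
    for v in variants:
        if v.protein_id != region.protein_id:
            raise ValueError(f"variant {v.label} is not on protein {region.protein_id}")
        if v.position not in region or v.span_end > region.end:
            raise ValueError(
                f"variant {v.protein_id}:{v.label} lies outside region "
                f"{region.start}-{region.end}"
            )
        observed = region.sequence[v.position - region.start: v.span_end - region.start + 1]
        if observed != v.wt_aa:
            raise ValueError(
                f"variant {v.protein_id}:{v.label}: region sequence has "
                f"{observed!r} at position {v.position}, expected {v.wt_aa!r}"
            )
    if region.end - region.start + 1 < peptide_len:
        warnings.warn(
            f"region {region.protein_id}:{region.start}-{region.end} shorter than "
            f"peptide length {peptide_len}; no peptides designed",
            stacklevel=2,
        )
        return []

    starts = _windows(region, peptide_len, step)

    def covered(v: VariantRecord, window_starts: Sequence[int]) -> bool:
        return any(s <= v.position and v.span_end <= s + peptide_len - 1 for s in window_starts)

    if any(not covered(v, starts) for v in variants):
        anchor = region.end - peptide_len + 1
        if anchor not in starts:
            starts.append(anchor)

    designs: list[PeptidePairDesign] = []
    for s in starts:
        window_seq = region.sequence[s - region.start: s - region.start + peptide_len]
        wt_pep = sanitize_peptide(window_seq)
        wt_oligo: str | None = None
        for v in variants:
            if not (s <= v.position and v.span_end <= s + peptide_len - 1):
                continue
            mut_pep = sanitize_peptide(_apply_variant(window_seq, s, v))
            if mut_pep == wt_pep:
                warnings.warn(
                    f"variant {v.protein_id}:{v.label}: wild-type and mutant peptides "
                    "identical after cysteine sanitisation; pair skipped",
                    stacklevel=2,
                )
                continue
            if wt_oligo is None:
                wt_oligo = reverse_translate(wt_pep, codon_usage, forbidden)
            designs.append(
                PeptidePairDesign(
                    wt_peptide=wt_pep,
                    mut_peptide=mut_pep,
                    protein_id=region.protein_id,
                    window_start=s,
                    variant=v,
                    wt_oligo=wt_oligo,
                    mut_oligo=reverse_translate(mut_pep, codon_usage, forbidden),
                )
            )
    return designs


def design_library(
    regions: Iterable[IdrRegion],
    variants: Iterable[VariantRecord],
    peptide_len: int = 16,
    step: int = 4,
    codon_usage: Mapping[str, Sequence[str]] | None = None,
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN_SITES,
) -> list[PeptidePairDesign]:
    """Design the full library: each variant is tiled within its region(s)."""
    by_protein: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_protein.setdefault(v.protein_id, []).append(v)
    designs: list[PeptidePairDesign] = []
    for region in regions:
        inside = [
            v
            for v in by_protein.get(region.protein_id, [])
            if v.position in region and v.span_end <= region.end
        ]
        if inside:
            designs.extend(
                tile_region(region, inside, peptide_len, step, codon_usage, forbidden)
            )
    return designs


def summarize_design(designs: Sequence[PeptidePairDesign]) -> DesignSummary:
    """Deduplicated library summary (percentages over unique mutations)."""
    if not designs:
        raise ValueError("no designs to summarise")
    mutations = {d.variant.key: d.variant for d in designs}
    wt_peptides = {d.wt_peptide for d in designs}
    all_peptides = wt_peptides | {d.mut_peptide for d in designs}
    pairs = {(d.wt_peptide, d.mut_peptide) for d in designs}
    n_mut = len(mutations)
    n_path = sum(1 for v in mutations.values() if v.pathogenicity in PATHOGENIC_CLASSES)
    n_som = sum(1 for v in mutations.values() if v.origin == "somatic")
    cat_counts: dict[str, int] = {}
    for v in mutations.values():
        if len(v.disease_categories) > 1:
            label = "mixed"
        elif v.disease_categories:
            label = next(iter(v.disease_categories))
        else:
            label = "unknown"
        cat_counts[label] = cat_counts.get(label, 0) + 1
    return DesignSummary(
        n_mutations=n_mut,
        n_prey_proteins=len({d.protein_id for d in designs}),
        n_unique_peptides=len(all_peptides),
        n_wt_peptides=len(wt_peptides),
        n_pairs=len(pairs),
        pct_pathogenic=percent(n_path, n_mut),
        pct_somatic=percent(n_som, n_mut),
        disease_category_counts=cat_counts,
    )
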