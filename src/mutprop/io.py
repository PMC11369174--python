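"""Readers and writers for the plain-text formats used across the pipeline.

FASTA goes through Biopython; tabular inputs and outputs are tab-separated
files handled with pandas.  Output tables carry a commented header line
recording the parameters that produced them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_design import IdrRegion, PeptidePairDesign, VariantRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein (or DNA) sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_regions_tsv(path: str | Path, proteome: Mapping[str, str]) -> list[IdrRegion]:
    """Regions table: protein_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    regions = []
    for row in df.itertuples(index=False):
        seq = proteome[row.protein_id][row.start - 1: row.end]
        regions.append(IdrRegion(row.protein_id, int(row.start), int(row.end), seq))
    return regions


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Variants table: protein_id, position, wt, mut, pathogenicity, origin, categories.

    ``categories`` is a semicolon-separated list; missing values are allowed
    for the three annotation columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    variants = []
    for row in df.itertuples(index=False):
        cats = getattr(row, "categories", None)
        variants.append(
            VariantRecord(
                protein_id=row.protein_id,
                position=int(row.position),
                wt_aa=row.wt,
                mut_aa=row.mut,
                pathogenicity=getattr(row, "pathogenicity", None) or "other",
                origin=getattr(row, "origin", None) or "unknown",
                disease_categories=frozenset(
                    c for c in str(cats).split(";") if cats and not pd.isna(cats) and c
                ),
            )
        )
    return variants


def design_to_frame(designs: Sequence[PeptidePairDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [d.pair_id for d in designs],
            "protein_id": [d.protein_id for d in designs],
            "window_start": [d.window_start for d in designs],
            "window_end": [d.window_end for d in designs],
            "mutation": [d.variant.label for d in designs],
            "wt_peptide": [d.wt_peptide for d in designs],
            "mut_peptide": [d.mut_peptide for d in designs],
            "wt_oligo": [d.wt_oligo for d in designs],
            "mut_oligo": [d.mut_oligo for d in designs],
        }
    )


def write_tsv(path: str | Path, df: pd.DataFrame, params: Mapping[str, object] | None = None) -> None:
    """Write a TSV with an optional ``# key=value ...`` parameter header line."""
    path = Path(path)
    with open(path, "w") as fh:
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in params.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_design(path: str | Path, designs: Sequence[PeptidePairDesign],
                 params: Mapping[str, object] | None = None) -> None:
    write_tsv(path, design_to_frame(designs), params)


def write_oligo_fasta(path: str | Path, designs: Iterable[PeptidePairDesign]) -> None:
    seqs: dict[str, str] = {}
    for d in designs:
        seqs.setdefault(f"{d.protein_id}_{d.window_start}_wt", d.wt_oligo)
        seqs[f"{d.pair_id}_mut"] = d.mut_oligo
    write_fasta(path, seqs)
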