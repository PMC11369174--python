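"""From amplicon reads to cleaned, normalised, merged peptide count tables.

Reads carry a 5' barcode + 5' adapter + peptide-coding insert + 3' adapter +
3' barcode.  Demultiplexing requires an exact match of *both* barcodes
(dual-barcode rule); reads with mean base quality below the threshold are
discarded; inserts are translated in the fixed phagemid frame and kept only
when the peptide is part of the library design.  Counts of 1 are treated as
sequencing noise and removed, counts are normalised per (replicate, selection
day) to a fixed scale, and days are merged into a per-peptide, per-replicate
normalised average count.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_MIN_AVG_QUALITY = 20.0
DEFAULT_SCALE = 1_000_000.0

REJECT_NO_ADAPTER = "no-adapter"
REJECT_FRAME_STOP = "frame/stop"
REJECT_NOT_IN_DESIGN = "not-in-design"


@dataclass(frozen=True)
class BarcodeScheme:
    """Dual barcodes per sample plus the constant adapter sequences."""

    barcodes: Mapping[str, tuple[str, str]]
    adapter5: str
    adapter3: str

    def __post_init__(self) -> None:
        pairs = list(self.barcodes.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate 5'/3' barcode pair in scheme")

    def lookup(self) -> dict[tuple[str, str], str]:
        return {pair: sample for sample, pair in self.barcodes.items()}


@dataclass
class CountTable:
    """Per-bait peptide counts with raw, normalised and merged layers.

    ``raw``/``normalised`` are long-form frames with columns
    (peptide, replicate, day, count); ``merged`` is a wide frame of
    per-replicate normalised average counts indexed by peptide.
    """

    bait_id: str
    raw: pd.DataFrame
    normalised: pd.DataFrame | None = None
    merged: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    @staticmethod
    def from_counts(bait_id: str, counts: Mapping[tuple[str, str, str], int]) -> "CountTable":
        """Build from a mapping (peptide, replicate, day) -> raw count."""
        rows = [
            {"peptide": p, "replicate": r, "day": d, "count": int(c)}
            for (p, r, d), c in sorted(counts.items())
        ]
        return CountTable(bait_id, pd.DataFrame(rows, columns=["peptide", "replicate", "day", "count"]))


def quality_filter(qualities: Iterable[int], sequence: str,
                   min_avg_q: float = DEFAULT_MIN_AVG_QUALITY) -> bool:
    """Keep a read iff its arithmetic-mean base quality is >= ``min_avg_q``."""
    quals = list(qualities)
    if len(quals) != len(sequence):
        raise ValueError("quality string length does not match sequence length")
    return sum(quals) / len(quals) >= min_avg_q


def demultiplex(reads: Iterable, scheme: BarcodeScheme) -> tuple[dict[str, list], int]:
    """Assign reads to samples by exact match of both barcodes.

    Returns (sample -> reads, number of unassigned reads).  A read matching
    one sample's 5' barcode but another's 3' barcode is unassigned.
    """
    lookup = scheme.lookup()
    lengths5 = sorted({len(b5) for b5, _ in lookup}, reverse=True)
    lengths3 = sorted({len(b3) for _, b3 in lookup}, reverse=True)
    out: dict[str, list] = {sample: [] for sample in scheme.barcodes}
    unassigned = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        sample = None
        for l5 in lengths5:
            for l3 in lengths3:
                pair = (seq[:l5], seq[len(seq) - l3:])
                if pair in lookup:
                    sample = lookup[pair]
                    break
            if sample:
                break
        if sample is None:
            unassigned += 1
        else:
            out[sample].append(rec)
    return out, unassigned


def trim_translate_match(sequence: str, scheme: BarcodeScheme,
                         design: frozenset[str] | set[str]) -> tuple[str | None, str | None]:
    """Trim adapters, translate the insert in frame, match against the design.

    Returns (peptide, None) on success, or (None, reject_reason).
    Rejections are data, not errors.
    """
    i5 = sequence.find(scheme.adapter5)
    i3 = sequence.rfind(scheme.adapter3)
    if i5 < 0 or i3 < 0 or i3 < i5 + len(scheme.adapter5):
        return None, REJECT_NO_ADAPTER
    insert = sequence[i5 + len(scheme.adapter5): i3]
    if not insert or len(insert) % 3 != 0 or any(b not in "ACGT" for b in insert):
        return None, REJECT_FRAME_STOP
    peptide = str(Seq(insert).translate())
    if "*" in peptide:
        return None, REJECT_FRAME_STOP
    if peptide not in design:
        return None, REJECT_NOT_IN_DESIGN
    return peptide, None


def _open_fastq(path: str | Path) -> Iterator:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fastq")
    else:
        yield from SeqIO.parse(str(path), "fastq")


def count_reads(
    reads: Iterable,
    scheme: BarcodeScheme,
    design: frozenset[str] | set[str],
    sample_meta: Mapping[str, tuple[str, str]],
    min_avg_q: float = DEFAULT_MIN_AVG_QUALITY,
) -> tuple[dict[str, CountTable], Counter]:
    """Full read-to-count path for a pooled run.

    ``sample_meta`` maps sample_id -> (replicate, day); all samples are
    assumed to belong to one bait pool per call.  Returns per-bait count
    tables keyed by ``bait`` parsed from sample ids of the form
    ``bait:replicate:day`` when ``sample_meta`` is None-like, otherwise a
    single table keyed ``"pooled"`` is avoided by the caller grouping.
    """
    fates: Counter = Counter()
    assigned, unassigned = demultiplex(reads, scheme)
    fates["unassigned"] = unassigned
    counts: dict[tuple[str, str, str], int] = {}
    for sample, recs in assigned.items():
        replicate, day = sample_meta[sample]
        for rec in recs:
            fates["assigned"] += 1
            if not quality_filter(rec.letter_annotations["phred_quality"], str(rec.seq), min_avg_q):
                fates["low-quality"] += 1
                continue
            peptide, reason = trim_translate_match(str(rec.seq), scheme, design)
            if peptide is None:
                fates[reason] += 1
                continue
            fates["matched"] += 1
            counts[(peptide, replicate, day)] = counts.get((peptide, replicate, day), 0) + 1
    table = CountTable.from_counts("pooled", counts)
    return {"pooled": table}, fates


def count_fastq(path: str | Path, scheme: BarcodeScheme,
                design: frozenset[str] | set[str],
                sample_meta: Mapping[str, tuple[str, str]],
                min_avg_q: float = DEFAULT_MIN_AVG_QUALITY) -> tuple[CountTable, Counter]:
    tables, fates = count_reads(_open_fastq(path), scheme, design, sample_meta, min_avg_q)
    return tables["pooled"], fates


def clean_counts(table: CountTable) -> CountTable:
    """Remove singleton observations (raw count == 1) within each (replicate, day)."""
    raw = table.raw
    cleaned = raw[raw["count"] != 1].reset_index(drop=True)
    return CountTable(table.bait_id, cleaned, params=dict(table.params, cleaned=True))


def normalise_and_merge(
    table: CountTable,
    scale: float = DEFAULT_SCALE,
    zero_fill: bool = True,
) -> CountTable:
    """Normalise per (replicate, day) to ``scale`` and average days per replicate.

    With ``zero_fill`` (default) a peptide absent on one of a replicate's
    sequenced days contributes 0 to that replicate's average; otherwise the
    average runs over the days the peptide was observed.  Days with zero
    total count are excluded with a warning.
    """
    raw = table.raw
    if raw.empty:
        merged = pd.DataFrame()
        return CountTable(table.bait_id, raw, raw.assign(norm=[]), merged,
                          dict(table.params, scale=scale, zero_fill=zero_fill))
    totals = raw.groupby(["replicate", "day"])["count"].transform("sum")
    group_totals = raw.groupby(["replicate", "day"])["count"].sum()
    dead = group_totals[group_totals == 0]
    if len(dead):
        warnings.warn(f"excluding {len(dead)} (replicate, day) groups with zero total count",
                      stacklevel=2)
    norm = raw.assign(norm=raw["count"] * scale / totals)
    norm = norm[totals > 0]
    if zero_fill:
        n_days = norm.groupby("replicate")["day"].nunique()
        sums = norm.groupby(["peptide", "replicate"])["norm"].sum()
        merged_s = sums / n_days.reindex(sums.index.get_level_values("replicate")).values
    else:
        merged_s = norm.groupby(["peptide", "replicate"])["norm"].mean()
    merged = merged_s.unstack("replicate", fill_value=0.0)
    merged.columns.name = None
    return CountTable(table.bait_id, raw, norm.reset_index(drop=True), merged,
                      dict(table.params, scale=scale, zero_fill=zero_fill))


def process_counts(table: CountTable, scale: float = DEFAULT_SCALE,
                   zero_fill: bool = True) -> CountTable:
    """clean -> normalise -> merge in one call."""
    return normalise_and_merge(clean_counts(table), scale=scale, zero_fill=zero_fill)
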