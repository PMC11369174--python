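# mutprop

Analysis toolkit for **mutational proteomic peptide-phage display (ProP-PD)**:
large-scale screening of how disease-associated missense mutations in
intrinsically disordered regions (IDRs) break, weaken, enhance or create
protein interactions mediated by short linear motifs (SLiMs).

In a mutational ProP-PD experiment every mutation site is represented in the
phage library by *pairs* of overlapping peptides — the wild-type window and
the same window carrying exactly one substitution — so a single selection
against a purified bait domain reports which allele the domain prefers.
`mutprop` implements the complete computational workflow around such screens:

* **library design** — tile IDRs with overlapping wild-type/mutant 16-mer
  pairs (step 4), replace cysteines by alanines, reverse-translate to
  E. coli-optimised oligonucleotides while avoiding the SmaI site;
* **NGS processing** — dual-barcode demultiplexing, mean-Q20 quality
  filtering, adapter trimming, in-frame translation and design matching,
  removal of singleton counts, per-(replicate, day) normalisation and
  per-replicate merging;
* **confidence scoring** — the 0–4 peptide score from replicate occurrence,
  peptide overlap, motif match and count support (4 = high, 2–3 = medium);
* **mutation analysis** — the mutation enrichment score with a two-sided
  Mann–Whitney test per domain–mutation pair;
* **motif mapping** — classification of each mutation as hitting a key or
  wild-card motif position, a flanking position, or creating a new motif
  instance, with Grantham substitution distances;
* **affinity analytics** — fluorescence-polarisation saturation (quadratic
  ligand-depletion model) and displacement fits (4-parameter logistic),
  IC50→K_D conversion, fold-change capping for non-binders, and agreement
  scoring against the phage enrichment scores;
* **synthetic data** — a generator with planted ground truth (motif-breaking,
  motif-creating and neutral variants; overdispersed replicate counts; noisy
  FP curves) used throughout the test suite.

## The core statistic

For one bait domain and one mutation site, all overlapping wild-type/mutant
peptide pairs observed across selection replicates are collapsed into
observations *(nc_wt, nc_mut)* of normalised counts, and scored as

```
score = Σᵢ nc_mutⁱ / (nc_wtⁱ + nc_mutⁱ)  −  Σᵢ nc_wtⁱ / (nc_wtⁱ + nc_mutⁱ)
```

The score is bounded by ±n (the number of observations): positive means the
mutation enhances binding, negative means it diminishes binding, and |score|
= n only when every observation is fully one-sided. Significance comes from
a two-sided Mann–Whitney U test of the wild-type against the mutant count
vector (exact distribution for small tie-free samples, midrank normal
approximation with tie correction otherwise); pairs with p ≤ 0.001 are
classified as enhancing or diminishing by the sign of the score. Plotting
score against −log₁₀ p yields the characteristic V-shaped plot, with the
diminished interactions on the left arm and the enhanced ones on the right.

## Worked example

Simulate a small screen with planted effects and analyse it:

```
mutprop simulate --out-dir demo --seed 7 --n-variants-per-class 2 \
    --depth 20000 --replicates 4 --days 2
```

```python
import pandas as pd
from mutprop import io as mio
from mutprop.library_design import design_library
from mutprop.ngs_processing import CountTable, process_counts
from mutprop.mutation_analysis import analyse_bait, pairs_to_frame

proteome = mio.read_fasta("demo/proteome.fasta")
regions = mio.read_regions_tsv("demo/regions.tsv", proteome)
variants = mio.read_variants_tsv("demo/variants.tsv")
designs = design_library(regions, variants)
raw = pd.read_csv("demo/counts.tsv", sep="\t", comment="#")
merged = process_counts(CountTable("SYN_BAIT", raw)).merged
print(pairs_to_frame(analyse_bait(merged, designs, "SYN_BAIT")).to_string(index=False))
```

```
 bait_id protein_id mutation  n_obs  enrichment_score  p_value   direction  n_significant_windows
SYN_BAIT   SYNP0001     Y28E     16        -13.329341 0.000002 diminishing                      4
SYN_BAIT   SYNP0002     Y28E     16        -12.703182 0.000002 diminishing                      4
SYN_BAIT   SYNP0003     F28Y     16         13.277282 0.000002   enhancing                      4
SYN_BAIT   SYNP0004     F28Y     16         12.859259 0.000002   enhancing                      4
SYN_BAIT   SYNP0005     S27G     16         -0.196936 0.777432     neutral                      0
SYN_BAIT   SYNP0006     S27G     16          0.448422 0.610892     neutral                      0
SYN_BAIT   SYNP0007     E31G     16         -0.178848 0.720310     neutral                      0
SYN_BAIT   SYNP0008     V30G     16          0.297327 0.637561     neutral                      0
```

The two variants planted to destroy the fixed tyrosine of the PPxY motif
(Y28E) come out strongly diminishing, the two that complete the motif (F28Y)
strongly enhancing, and the wild-card/flanking variants are neutral — with
all 4 peptide windows per pair individually significant for the true effects.

The affinity side works from plate-reader tables or the packaged validation
table of 24 wild-type/mutant peptide pairs measured by FP displacement:

```
$ mutprop affinity
19 of 24 pairs agree (79%)
$ mutprop enrich 100 1229 4638 147147
enrichment: 2.58
```

All stages are also available as `mutprop design / count / score / mutscan /
motif / affinity / enrich / simulate`, plus `mutprop run-all --config run.ini`
to execute the pipeline end-to-end with a run report.

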