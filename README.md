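# gliascan

Alpha-gliadins are the gluten proteins chiefly responsible for celiac
disease (CD): their first repetitive domain carries short immunogenic
peptides (epitopes) — the innate p31-43 peptide and the HLA-DQ2.5-presented
9-mers DQ2.5-glia-α1a/α1b/α2/α3, including the notorious 33-mer fragment
with six overlapping copies of the α1/α2 epitopes.  `gliascan` turns
barcoded paired-end amplicon sequencing of this domain (e.g. from *Aegilops*
accessions carrying the wheat D genome) into:

* a **genotype × epitope frequency matrix** — reads are quality-trimmed,
  merged by overlap, demultiplexed by an 8-bp barcode, stripped of
  barcode/primers/signal peptide, translated, purged of pseudogene-derived
  sequences (internal stop codons), deduplicated into 100%-identity protein
  clusters, filtered to clusters with >15 members, and scanned for a panel
  of epitopes with overlap-inclusive counting weighted by cluster size and
  normalised per 10,000 retained coding sequences;
* a **toxicity-weighted immunogenicity load** per genotype
  `L(g) = Σ_e w(e) · f_e(g)` with weights 3 (highly toxic/toxic),
  2 (moderately/reduced toxicity), 1 (low toxicity), reported as a
  percentage of the maximal genotype;
* a **consensus-protein phylogeny** — per-genotype consensus of the ten
  most prevalent clusters, center-star alignment, p-distances with pairwise
  deletion, Saitou–Nei neighbor joining, bootstrap branch support.

A synthetic read generator with a known ground truth emulates the assay
(fusion-primer read anatomy, pseudogene fraction, substitution errors), so
the whole pipeline is testable without the sequencing deposit.

## Worked example

```python
from gliascan.constants import THIRTY_THREE_MER
from gliascan.quantify import count_occurrences

total = sum(count_occurrences(THIRTY_THREE_MER, e)
            for e in ("PFPQPQLPY", "PYPQPQLPY", "PQPQLPYPQ"))
print(total)   # 6 — the 33-mer's six overlapping α1a/α1b/α2 epitope copies
```

End to end, from a shell:

```bash
gliascan simulate --out demo/data --n-genotypes 3 --depth 2000 \
    --error-rate 0 --pseudogene-fraction 0.3 --seed 7
gliascan run --fwd demo/data/reads_R1.fastq --rev demo/data/reads_R2.fastq \
    --sheet demo/data/sample_sheet.tsv --out demo/run --seed 7 --n-reps 50
```

which prints the ranked toxicity report, e.g.

```
                              sum_HT_T     sum_MT_RT       sum_LT  weighted_load  relative_percent  rank
genotype
Ae. juvenalis 'AE 1495'  113262.711864  11299.435028  5296.610169  129858.757062             100.0     1
Ae. juvenalis 'AE 537'    81861.818182  36000.000000  5825.454545  123687.272727              95.2     2
Ae. tauschii 'AE 1600'    83446.286950  27051.189618  5133.381399  115630.857967              89.0     3
```

Here `sum_HT_T` / `sum_MT_RT` / `sum_LT` are the weighted load contributions
of each toxicity group (frequencies are per 10,000 retained CDSs, so values
are large when an epitope occurs about once per read); `relative_percent`
expresses each genotype's load against the most toxic genotype (100%).
`demo/run/` also receives the raw/normalised/log2 frequency matrices, a
presence–absence matrix, per-stage read counts, cluster representatives,
consensus proteins, the bootstrapped Newick tree and a manifest of output
checksums (identical config + seed ⇒ byte-identical bundle).

## Layout

- `src/gliascan/panel.py` — epitope panel, TSV I/O, toxicity weights
- `src/gliascan/simulate.py` — synthetic reads + ground truth
- `src/gliascan/preprocess.py` — trim, merge, demultiplex, strip
- `src/gliascan/cluster.py` — translate, stop filter, identity clustering
- `src/gliascan/quantify.py` — epitope scanning, frequency matrix
- `src/gliascan/toxicity.py` — weighted load and relative percentages
- `src/gliascan/phylo.py` — consensus, alignment, p-distance, NJ, bootstrap
- `src/gliascan/pipeline.py`, `cli.py` — orchestration and the `gliascan` CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
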