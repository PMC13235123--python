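# Methods

## The assay and its in-silico model

The pipeline analyses RNA amplicons of the first variable (repetitive)
domain of alpha-gliadin.  Each sequenced amplicon is, 5'→3' on the coding
strand: an 8-bp genotype barcode, the degenerate forward primer
`atgaaracmtttcycatc` (sitting on the MKTF[LP]I start of the signal
peptide), the remainder of the signal peptide, the variable domain that
carries the celiac-disease (CD) epitopes, and the binding region of the
universal degenerate reverse primer `ctgctgctgtgaaattrgwt` (the PISQQQ
motif).  Reads are modelled post-adapter: the first observable base is the
barcode.  The reading frame is anchored at the forward primer's ATG rather
than by ORF search, because the primer sits on the start codon by design.

## Preprocessing

* **Quality trimming** — sliding window (default 4 bases), truncation at
  the first window with mean Phred < 20, discard below 36 bases.  These are
  conventional short-read trimming defaults; with the generator's Q40/Q10
  quality model a truncation requires a run of low-quality calls, so the
  stage is exercised but rarely destructive at realistic error rates.
* **Merging** — the reverse read is reverse-complemented and every overlap
  length from `min(len_f, len_r)` down to 10 is scored; candidates with
  mismatch density > 0.25 are rejected, the rest ranked by
  `matches − mismatches` (ties to the longer overlap).  The overlap
  consensus takes the higher-quality base (ties to the forward read) and
  the maximum quality.  `N` matches nothing, including another `N`.  The
  implementation counts matches for all overlaps at once by one-hot
  correlation; a literal exhaustive scan serves as the test oracle.
* **Demultiplexing** — exact match of the first 8 bases against the sample
  sheet.  Zero-mismatch matching avoids barcode cross-talk; unmatched reads
  are counted as UNASSIGNED (a warning fires above 10%).
* **Stripping** — barcode removed; forward primer verified immediately
  after it (IUPAC-degenerate match); reverse primer located within the last
  40 bases (rightmost match), everything from it onward truncated; then the
  first `signal_peptide_codons` codons are removed.  The default (20) is
  the length of the generator's signal peptide; the generator and parser
  share the constant, and real data with a different signal-peptide length
  only needs this one knob.

## Translation, clustering, filtering

Translation uses the standard genetic code; any codon containing `N`
becomes `X`, stops become `*`, and a trailing partial codon is dropped.
Sequences containing `*` are removed as pseudogene-derived (their count is
the per-genotype `stop_removed`).  Clustering is **exact string equality
within a genotype** — the meaningful reading of "100% identity" here,
since frequency weighting by cluster size is only well defined when all
members are identical; greedy substring absorption (which some
deduplication tools perform at 100% identity) is deliberately not done.
Clusters with more than 15 members (`size ≥ 16`) are retained, a
confidence filter against sequencing-error and PCR-stochasticity
singletons.

## Quantification

`raw[g, e] = Σ_clusters occurrences(representative, e) × size`, with
overlap-inclusive occurrence counting (forced by the 33-mer, whose six
epitope copies overlap).  Normalisation is `raw × 10000 / depth`, with
`depth` the genotype's retained (stop-free) CDS count by default — the
denominator actually available at this stage — or its merged-read count
via `depth_denominator`.  The log2 display transform uses a +1 pseudocount
because zeros are common in the sparse epitope matrix.  Presence/absence
is `raw > 0`.

## Toxicity load

Each epitope's frequency is multiplied by its class weight — HT/T: 3,
MT/RT: 2, LT: 1; NT and unknown-toxicity epitopes weigh 0 and are excluded
from the load — and summed per genotype; percentages are relative to the
maximal genotype (100%).  The per-epitope weighted **sum** is used (rather
than per-group maxima) because it is the only formulation yielding a single
percentage per genotype; per-group subtotals are emitted alongside so
either reading can be inspected.  The multiplicand defaults to normalised
frequencies (`toxicity_input = raw` is available).  Percentages are
reported to one decimal.

## Consensus phylogeny

The ten largest selected clusters per genotype (ties by lexicographic
representative) are aligned by **center-star**: the center maximises the
summed pairwise global-alignment score (match 1, mismatch −1, linear gap
−2), all others are aligned to it pairwise, and the pairwise alignments are
merged under "once a gap, always a gap".  Center-star replaces a
progressive aligner because it is deterministic and oracle-testable, and
the inputs are near-identical amplicon proteins for which it is adequate.
The consensus takes, per column, the plurality non-gap residue if it
reaches 50% of non-gap rows (ties to the lexicographically smallest
residue), else `X`; columns that are gaps in more than half the rows are
dropped.  `X` columns are then invisible to distances, which use
**p-distance with pairwise deletion** (sites with `-` or `X` in either row
excluded; a pair with no comparable sites is an error naming the pair).

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion; topology ties are broken by the smallest index pair; negative
branch lengths are clamped to zero with the deficit moved to the sister
edge (common practice); two taxa yield a single edge written as two
half-length branches.  Bootstrap support resamples alignment columns with
replacement from one seeded stream (replicate *r* consumes draw *r*, so
identical seed + replicate count ⇒ identical supports); replicates in
which some pair loses all comparable sites contribute no support.  The
default is 1000 replicates.  Tie-breaking inside NJ differs between
implementations, so leaf-for-leaf agreement with any particular external
tool's tree is not expected — an independent NJ implementation is used as
a topology oracle on additive matrices in the tests.

## Synthetic data generator

The generator is the package's study stand-in, not a fixture: ten genotype
specifications carry the published accession names and 8-bp barcodes, with
several transcript profiles each (relative abundances 0.1–0.5) whose
epitope composition loosely mirrors the study narrative (one accession rich
in every toxic epitope, the *Ae. crassa* accessions poor in them).
Back-translation draws codons uniformly over synonymous codons (the least
assumption, since codon usage is unstated) except where the degenerate
primers constrain them.  Study conditions emulated: ~10 genotypes, tens of
thousands of read pairs per genotype (default depth 20,000), merged
amplicons within 250–490 bp, read lengths 250–300 bp, a pseudogene
fraction (default 0.3, reflecting the prevalence of internally-stopped
alpha-gliadin copies) realised as reads whose mature domain carries one
stop codon, and i.i.d. substitution errors (default rate 10⁻³).  Qualities
are Q40, Q10 at injected error sites.  The truth table records expected
per-read epitope occurrences per genotype (occurrences per transcript ×
relative abundance).

Not modelled: indels, chimeras/PCR duplicates, quality-by-cycle decay,
adapter read-through, codon-usage bias, and between-genotype depth
variance.  Passing tests therefore demonstrate correctness of the
algorithms under substitution noise and pseudogene contamination, not
robustness to indel-heavy or chimeric libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 3
genotypes × 20,000 read pairs (error 0.001, pseudogene fraction 0.3) —
large enough that multinomial sampling error is negligible against the
rank structure of the truth (Spearman recovery is 1.0 in practice), small
enough for a desk machine; unit tests use hundreds to thousands of reads.
Bootstrap replicates are reduced (100 or fewer) where only determinism or
a clear split is being checked.  All randomness flows through
`numpy.random.default_rng` seeded from a single integer; rerunning a
pipeline config with the same seed produces byte-identical output bundles
(gzip output is written with a fixed mtime for this reason, and logs carry
no timestamps).

## Packaged data

Two small synthetic fixtures ship with the package: a stand-in epitope
panel (`synthetic_epitope_panel.tsv` — canonical alpha-gliadin epitope
sequences plus constructed variants and toxicity classes, since the full
147-entry panel is user-suppliable) and a toxicity fixture
(`synthetic_toxicity_fixture.tsv`) whose weighted loads are hand-computable
(42 / 21 / 10.5 → 100% / 50% / 25%).  The built-in canonical panel contains
the six epitopes whose sequences are fixed by the assay; p31-43 is a named
placeholder whose sequence must come from a panel file.
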