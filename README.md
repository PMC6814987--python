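# mitocomp

Comparative organellar genome analysis: repeat/single-copy partitioning,
repeat-collapsed genome sizes, plastome-derived insertion (MIPT) detection,
pairwise shared-DNA vs K2P-distance decay, gene/intron content
classification, and horizontal-transfer donor profiling — plus a synthetic
genome-evolution simulator that makes the whole pipeline verifiable
without any downloads.

## Modules

| module | what it does |
|---|---|
| `mitocomp.seqio` | FASTA/BED/GFF3/TSV I/O, interval algebra, multipartite concatenation with coordinate map-back |
| `mitocomp.pairalign` | self-contained seed-and-extend local aligner (exact-word seeds, ungapped X-drop) with Karlin–Altschul E-values, plus an affine-gap global aligner |
| `mitocomp.repeatscan` | dispersed + tandem repeat detection, overlap merging, repetitive/single-copy partition, size-class bins, >1 kb family clustering and collapsing |
| `mitocomp.shareddna` | pairwise shared-DNA matrices (query-side coverage), MIPT scan, decay statistics (correlations, 50% "half-life"), HGT profiling and profile consistency |
| `mitocomp.genecontent` | intact/pseudogene/fragment/absent gene classification, intron lengths, concatenated gene alignments, Kimura 2-parameter distances |
| `mitocomp.simulate` | genome families evolved along a newick tree (K2P substitutions, segmental IGS turnover, planted repeats/MIPTs/HGT tracts) with exact ground truth |
| `mitocomp.cli` | `mitocomp` command: orchestrates the stages, boxplot statistics, report bundle |

## CLI

```sh
# self-contained run: simulate a family, then repeats -> collapse ->
# shared -> mipt -> genes -> report
mitocomp all --seed 1 --out out/

# individual stages on your own FASTA files
mitocomp repeats genomes.fasta --out out/ --word-size 7 --evalue 1e-6
mitocomp collapse genomes.fasta --out collapsed.fasta --large-repeat 1000
mitocomp shared a.fasta b.fasta c.fasta --out out/
mitocomp mipt mito.fasta plastome.fasta --mipt-min 100
mitocomp hgt parasite.fasta donor1.fasta donor2.fasta
mitocomp k2p aligned_pair.fasta
mitocomp boxstats sizes.txt
mitocomp simulate --seed 7 --out sim/
```

Multi-record query FASTAs passed to `mitocomp hgt` are concatenated with
N spacers (multipartite genomes). All report files echo the tool version,
config hash and alignment parameters in `#` header lines; reruns with the
same config are byte-identical.

## Conventions

Coordinates are 0-based half-open internally; emitted files follow each
format's convention (BED 0-based half-open, GFF3/tabular hits 1-based
inclusive). Default alignment scoring is match +1 / mismatch −2, gap open
5 / extend 2, word size 7, E ≤ 1e-6, minimum hit 30 bp; repeats >1 kb are
collapsed to a single (leftmost) copy before shared-DNA estimation.
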