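# contigclust

Cluster de novo assembled transcriptome contigs into gene-level groups using
multi-mapped reads, and emit per-cluster fragment counts ready for
count-based differential-expression tools (edgeR, DESeq2, ...).

De novo assemblers typically output many contigs per gene (redundant copies,
fragments, isoforms, near-paralogues). `contigclust` groups contigs that
share multi-mapped reads by agglomerative hierarchical clustering with the
distance

```
d(a, b) = 1 - R_ab / min(R_a, R_b)     (1 if the expression-ratio test rejects)
```

where `R_a` is the number of fragments mapping to contig `a` and `R_ab` the
number mapping to both. A Poisson likelihood-ratio test keeps apart contig
pairs whose expression ratio changes across condition groups (e.g.
paralogues with reciprocal differential expression), so they remain testable
downstream. After clustering, every fragment is assigned to exactly one
cluster (multi-cluster fragments uniformly at random, seeded), producing a
cluster × sample count matrix.

## Usage

Align reads to the assembled contigs reporting **all** alignments
(e.g. `bowtie --all`), one or more SAM/BAM files per sample (unsorted,
unindexed is fine), then:

```sh
contigclust sample1.bam sample2.bam sample3.bam sample4.bam \
    -f s1,s2,s3,s4 -g ctrl,ctrl,treat,treat -p out
```

This writes `out-clusters.txt` (contig → cluster) and `out-counts.txt`
(cluster × sample count matrix).

Key flags:

| flag | meaning |
|------|---------|
| `-f` | comma-separated sample name per file; files sharing a name form one sample (default: file basenames) |
| `-g` | comma-separated condition-group label per file (default: each sample its own group) |
| `-m` | minimum total fragments for a contig to be kept (default 10; `-m 0` disables) |
| `-d` | distance threshold(s); `-d 0.3,0.5` writes one output pair per value (default 0.3) |
| `--pvalue` / `-D` | p-value (default 1e-5) or explicit statistic threshold for the ratio test |
| `--no-test` | disable the ratio test (isoform-like contigs co-cluster regardless of expression) |
| `--seed` | seed for random assignment of multi-cluster fragments (default 1) |
| `-i` | input format: `bam`, `sam` or `eqclass` (a plain TSV of contig-set, sample, count) |

Evaluate a clustering against gene-level truth labels (pairwise
precision/recall):

```sh
contigclust-eval --clusters out-clusters.txt --truth truth.tsv
# or derive labels from contig-vs-annotation alignment hits
contigclust-eval --clusters out-clusters.txt --hits hits.tsv
```

`truth.tsv` is `contig<TAB>gene`; `hits.tsv` is
`contig gene length identity start end` (0-based half-open footprint of the
gene on the contig). Hits shorter than 200 bases or under 98% identity are
dropped; contigs matching ≥2 genes whose footprints overlap by <100 bases
are flagged chimeric and excluded.

## Library layout

| module | role |
|--------|------|
| `contigclust.alignment_io` | SAM/BAM and equivalence-class TSV parsing; experiment design |
| `contigclust.readmodel` | equivalence-class store, low-coverage filter, super-clusters, shared-count queries, exact inclusion–exclusion merges |
| `contigclust.ratio_test` | closed-form Poisson likelihood-ratio test and rejection thresholds |
| `contigclust.clustering` | per-super-cluster agglomerative clustering engine |
| `contigclust.counting_output` | unique fragment assignment, output files, CLI |
| `contigclust.evaluation` | truth labelling and pairwise precision/recall |
| `contigclust.synthetic` | seed-deterministic synthetic scenarios (redundancy, fragmentation, chimeras, paralogues) with known truth |

## Tests

```sh
python -m pytest tests/
```

The suite includes independent oracles: the closed-form likelihood-ratio
statistic is checked against brute-force numeric likelihood maximisation,
and the clustering engine against a naive reimplementation that recomputes
the full distance matrix from raw equivalence classes at every step.
`tests/test_acceptance.py` runs the acceptance criteria at full scale.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end pipeline smoke check and writes the (empty) numeric
target report — there are no desk-scale reproducible headline numbers, so
acceptance is property/oracle based.
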