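"""Score a clustering against gene-level truth labels.

Truth labels can be built from a tabular contig-vs-annotation alignment
file: hits shorter than 200 bases or below 98% identity are dropped; a
contig whose surviving hits cover two or more genes whose footprints on the
contig overlap by fewer than 100 bases is flagged CHIMERIC (unknown origin);
other multi-gene contigs go to the gene with the longest alignment.

Clustering quality is pairwise precision/recall: over all unordered pairs
of labeled contigs, a true positive is a pair from the same gene placed in
the same cluster, a false positive a pair from different genes placed
together, and a false negative a pair from one gene split apart.
"""

from __future__ import annotations

import math
import sys
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import click

__all__ = [
    "CHIMERIC",
    "UNKNOWN",
    "AlignmentHit",
    "PairwiseScores",
    "label_contigs",
    "label_clusters",
    "pairwise_precision_recall",
    "read_hits_table",
    "read_truth_table",
    "cli",
]

CHIMERIC = "CHIMERIC"
UNKNOWN = "UNKNOWN"
SENTINELS = frozenset({CHIMERIC, UNKNOWN})

MIN_HIT_LENGTH = 200
MIN_HIT_IDENTITY = 0.98
CHIMERA_MAX_OVERLAP = 100


@dataclass(frozen=True)
class AlignmentHit:
    """One contig-vs-gene alignment; interval is the gene's footprint on the contig, 0-based half-open."""

    contig: str
    gene: str
    length: int
    identity: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.start >= self.end:
            raise ValueError(f"malformed interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class PairwiseScores:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int


def _union_length_overlap(
    ivs_a: Sequence[tuple[int, int]], ivs_b: Sequence[tuple[int, int]]
) -> int:
    """Total overlap in bases between two unions of intervals."""
    total = 0
    for a0, a1 in ivs_a:
        for b0, b1 in ivs_b:
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


def label_contigs(
    hits: Iterable[AlignmentHit],
    min_length: int = MIN_HIT_LENGTH,
    min_identity: float = MIN_HIT_IDENTITY,
    chimera_max_overlap: int = CHIMERA_MAX_OVERLAP,
) -> dict[str, str]:
    """Assign each contig a gene label, CHIMERIC or UNKNOWN.

    Contigs present in ``hits`` whose every hit fails the length/identity
    filter come out UNKNOWN.
    """
    by_contig: dict[str, list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        by_contig[hit.contig].append(hit)
    labels: dict[str, str] = {}
    for contig, contig_hits in by_contig.items():
        surviving = [
            h for h in contig_hits if h.length >= min_length and h.identity >= min_identity
        ]
        if not surviving:
            labels[contig] = UNKNOWN
            continue
        genes = sorted({h.gene for h in surviving})
        if len(genes) >= 2:
            footprints = {
                g: [(h.start, h.end) for h in surviving if h.gene == g] for g in genes
            }
            chimeric = any(
                _union_length_overlap(footprints[g1], footprints[g2]) < chimera_max_overlap
                for i, g1 in enumerate(genes)
                for g2 in genes[i + 1 :]
            )
            if chimeric:
                labels[contig] = CHIMERIC
                continue
        # longest alignment wins; ties resolve to the lexicographically first gene
        best_len = max(h.length for h in surviving)
        labels[contig] = min(h.gene for h in surviving if h.length == best_len)
    return labels


def label_clusters(
    contig_to_cluster: Mapping[str, str], labels: Mapping[str, str]
) -> dict[str, str]:
    """Label each cluster with the majority gene of its labeled contigs.

    Sentinel-labeled and unlabeled contigs do not vote; ties break
    lexicographically; clusters with no votes are UNKNOWN.
    """
    votes: dict[str, Counter] = defaultdict(Counter)
    clusters = set(contig_to_cluster.values())
    for contig, cluster in contig_to_cluster.items():
        gene = labels.get(contig, UNKNOWN)
        if gene not in SENTINELS:
            votes[cluster][gene] += 1
    out = {}
    for cluster in clusters:
        if votes[cluster]:
            top = max(votes[cluster].values())
            out[cluster] = min(g for g, n in votes[cluster].items() if n == top)
        else:
            out[cluster] = UNKNOWN
    return out


def pairwise_precision_recall(
    contig_to_cluster: Mapping[str, str], labels: Mapping[str, str]
) -> PairwiseScores:
    """Pairwise precision and recall over all non-sentinel labeled contig pairs.

    Counts are computed from the cluster x gene contingency table, which is
    exactly equivalent to enumerating all C(n, 2) pairs.  A zero denominator
    yields NaN for the corresponding ratio.
    """
    contigs = [
        c
        for c in contig_to_cluster
        if labels.get(c, UNKNOWN) not in SENTINELS and c in labels
    ]
    n = len(contigs)
    if n < 2:
        raise ValueError("need at least two labeled contigs")

    def npairs(k: int) -> int:
        return k * (k - 1) // 2

    cell: Counter = Counter((contig_to_cluster[c], labels[c]) for c in contigs)
    per_cluster: Counter = Counter(contig_to_cluster[c] for c in contigs)
    per_gene: Counter = Counter(labels[c] for c in contigs)
    tp = sum(npairs(k) for k in cell.values())
    same_cluster = sum(npairs(k) for k in per_cluster.values())
    same_gene = sum(npairs(k) for k in per_gene.values())
    fp = same_cluster - tp
    fn = same_gene - tp
    tn = npairs(n) - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    return PairwiseScores(precision, recall, tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_hits_table(path: str | Path) -> list[AlignmentHit]:
    """TSV: contig, gene, length, identity, start, end (0-based half-open)."""
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            contig, gene, length, identity, start, end = parts
            hits.append(
                AlignmentHit(contig, gene, int(length), float(identity), int(start), int(end))
            )
    return hits


def read_truth_table(path: str | Path) -> dict[str, str]:
    """TSV: contig, gene (sentinels CHIMERIC/UNKNOWN allowed)."""
    labels = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            labels[parts[0]] = parts[1]
    return labels


def read_clusters_table(path: str | Path) -> dict[str, str]:
    """The clusters TSV written by the main tool: contig, cluster name."""
    mapping = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            mapping[parts[0]] = parts[1]
    return mapping


@click.command(name="contigclust-eval")
@click.option("--clusters", "clusters_path", required=True, type=click.Path(exists=True), help="Contig-to-cluster TSV from the main tool.")
@click.option("--truth", "truth_path", default=None, type=click.Path(exists=True), help="Truth-label TSV (contig, gene).")
@click.option("--hits", "hits_path", default=None, type=click.Path(exists=True), help="Contig-vs-annotation hits TSV; labels are derived with the standard filters.")
def cli(clusters_path: str, truth_path: str | None, hits_path: str | None) -> None:
    """Print pairwise precision/recall of a clustering as TSV to stdout."""
    if (truth_path is None) == (hits_path is None):
        raise click.UsageError("pass exactly one of --truth or --hits")
    contig_to_cluster = read_clusters_table(clusters_path)
    if truth_path:
        labels = read_truth_table(truth_path)
    else:
        labels = label_contigs(read_hits_table(hits_path))
    scores = pairwise_precision_recall(contig_to_cluster, labels)
    sys.stdout.write("precision\trecall\tTP\tFP\tFN\tTN\n")
    sys.stdout.write(
        f"{scores.precision:.6g}\t{scores.recall:.6g}\t"
        f"{scores.tp}\t{scores.fp}\t{scores.fn}\t{scores.tn}\n"
    )
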