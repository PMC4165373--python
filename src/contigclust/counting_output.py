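"""Unique fragment assignment, output files and the command-line interface.

Every retained fragment is counted exactly once: equivalence classes whose
contigs all fall in one final cluster contribute all their counts there;
classes spanning several clusters have each fragment assigned uniformly at
random (seeded) to one of them.  Per sample, the output counts therefore sum
exactly to the number of retained fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np

from contigclust.alignment_io import (
    ExperimentDesign,
    parse_alignments,
    read_eqclass_table,
)
from contigclust.clustering import ClusterParams, run_all
from contigclust.readmodel import (
    EqClassStore,
    build_eqclasses,
    build_superclusters,
    filter_low_coverage,
)

__all__ = ["ClusterResult", "name_clusters", "assign_fragments", "write_outputs", "cli"]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 1


@dataclass(frozen=True)
class ClusterResult:
    """Final contig->cluster map and cluster x sample count matrix."""

    contig_to_cluster: dict[str, str]
    counts: dict[str, np.ndarray]  # cluster name -> per-sample integer counts
    samples: tuple[str, ...]
    seed: int
    ambiguous_fraction: float


def name_clusters(partition: list[list[frozenset[str]]]) -> dict[str, str]:
    """Assign stable names ``Cluster-<sc>.<i>`` to partition blocks.

    Super-clusters arrive sorted by smallest member contig and blocks within
    each are sorted likewise, so names are deterministic.
    """
    mapping: dict[str, str] = {}
    for sc_idx, blocks in enumerate(partition):
        for blk_idx, block in enumerate(blocks):
            name = f"Cluster-{sc_idx}.{blk_idx}"
            for contig in block:
                mapping[contig] = name
    return mapping


def assign_fragments(
    store: EqClassStore,
    partition: list[list[frozenset[str]]],
    design: ExperimentDesign,
    seed: int = DEFAULT_SEED,
) -> ClusterResult:
    """Uniquely assign every fragment of a filtered store to a final cluster.

    ``store`` must hold original contig keys (pre-merge).  Fragments of a
    class touching k > 1 clusters are split uniformly at random among the k;
    the multinomial draws are taken in sorted class order so a seed fully
    determines the counts matrix.
    """
    contig_to_cluster = name_clusters(partition)
    for contig in store.live_ids:
        if contig not in contig_to_cluster:
            raise KeyError(f"contig {contig!r} missing from partition")
    n_samples = store.n_samples
    counts: dict[str, np.ndarray] = {
        name: np.zeros(n_samples, dtype=np.int64)
        for name in sorted(set(contig_to_cluster.values()))
    }
    rng = np.random.default_rng(seed)
    ambiguous = 0
    total = 0
    for key, vec in sorted(store.items(), key=lambda kv: tuple(sorted(kv[0]))):
        clusters = sorted({contig_to_cluster[c] for c in key})
        total += int(vec.sum())
        if len(clusters) == 1:
            counts[clusters[0]] += vec
            continue
        ambiguous += int(vec.sum())
        probs = np.full(len(clusters), 1.0 / len(clusters))
        for s in range(n_samples):
            n = int(vec[s])
            if n == 0:
                continue
            draw = rng.multinomial(n, probs)
            for name, x in zip(clusters, draw):
                counts[name][s] += x
    frac = ambiguous / total if total else 0.0
    logger.info(
        "assigned %d fragments; %.2f%% mapped to multiple clusters", total, 100 * frac
    )
    return ClusterResult(contig_to_cluster, counts, tuple(design.samples), seed, frac)


def write_outputs(result: ClusterResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>-clusters.txt`` and ``<prefix>-counts.txt``.

    Both files are TSV, LF-terminated, unquoted.  The clusters file is
    sorted by contig id; the counts file has a ``Cluster`` + sample-id
    header and rows sorted by cluster name.
    """
    prefix = str(prefix)
    clusters_path = Path(f"{prefix}-clusters.txt")
    counts_path = Path(f"{prefix}-counts.txt")
    with open(clusters_path, "w", encoding="utf-8", newline="\n") as fh:
        for contig in sorted(result.contig_to_cluster):
            fh.write(f"{contig}\t{result.contig_to_cluster[contig]}\n")
    with open(counts_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Cluster\t" + "\t".join(result.samples) + "\n")
        for name in sorted(result.counts):
            row = "\t".join(str(int(x)) for x in result.counts[name])
            fh.write(f"{name}\t{row}\n")
    return clusters_path, counts_path


# ---------------------------------------------------------------------------
# CLI


def _build_design(
    files: tuple[str, ...],
    sample_names: str | None,
    groups: str | None,
) -> ExperimentDesign:
    if sample_names:
        names = sample_names.split(",")
        if len(names) != len(files):
            raise click.UsageError(
                f"-f lists {len(names)} sample names for {len(files)} files"
            )
    else:
        names = [Path(f).name for f in files]
        if len(set(names)) != len(names):
            raise click.UsageError(
                "file basenames are not unique; pass sample names with -f"
            )
    samples: list[str] = []
    files_per_sample: dict[str, list[str]] = {}
    for name, path in zip(names, files):
        if name not in files_per_sample:
            samples.append(name)
            files_per_sample[name] = []
        files_per_sample[name].append(path)
    if groups:
        labels = groups.split(",")
        if len(labels) != len(files):
            raise click.UsageError(
                f"-g lists {len(labels)} group labels for {len(files)} files"
            )
        group_of_sample: dict[str, str] = {}
        for name, label in zip(names, labels):
            if group_of_sample.setdefault(name, label) != label:
                raise click.UsageError(
                    f"sample {name!r} appears with conflicting group labels"
                )
    else:
        # default: each sample is its own condition group
        group_of_sample = {name: name for name in samples}
    return ExperimentDesign(
        tuple(samples),
        {s: tuple(f) for s, f in files_per_sample.items()},
        group_of_sample,
    )


def _load_eqclass(
    files: tuple[str, ...], sample_names: str | None, groups: str | None
) -> tuple[ExperimentDesign, EqClassStore]:
    """Equivalence-class input: sample ids come from the table rows.

    Each file is read once; ``-f`` (if given) fixes the sample order and
    ``-g`` lists one group label per sample in that order.
    """
    rows: list[tuple[frozenset[str], str, int]] = []
    seen: dict[str, None] = {}
    for path in dict.fromkeys(files):
        for key, sample_id, count in read_eqclass_table(path):
            rows.append((key, sample_id, count))
            seen.setdefault(sample_id)
    samples = sample_names.split(",") if sample_names else list(seen)
    unknown = set(seen) - set(samples)
    if unknown:
        raise click.UsageError(f"samples {sorted(unknown)} in tables but not in -f")
    if groups:
        labels = groups.split(",")
        if len(labels) != len(samples):
            raise click.UsageError(
                f"-g lists {len(labels)} group labels for {len(samples)} samples"
            )
        group_of_sample = dict(zip(samples, labels))
    else:
        group_of_sample = {s: s for s in samples}
    design = ExperimentDesign(
        tuple(samples), {s: tuple(dict.fromkeys(files)) for s in samples}, group_of_sample
    )
    store = EqClassStore(len(samples))
    idx = {s: i for i, s in enumerate(samples)}
    for key, sample_id, count in rows:
        vec = np.zeros(len(samples), dtype=np.int64)
        vec[idx[sample_id]] = count
        store.add(key, vec)
    return design, store


def _load_alignments(design: ExperimentDesign) -> EqClassStore:
    store = EqClassStore(len(design.samples))
    for sample in design.samples:
        frags = parse_alignments(design.files_per_sample[sample], sample)
        sub = build_eqclasses(frags, design)
        for key, vec in sub.items():
            store.add(key, vec)
    return store


@click.command(name="contigclust")
@click.argument("files", nargs=-1, required=True, type=click.Path(exists=True))
@click.option("-f", "--sample-names", default=None, help="Comma-separated sample name per file; files sharing a name form one sample. Default: file basenames.")
@click.option("-g", "--groups", default=None, help="Comma-separated condition-group label per file. Default: each sample is its own group.")
@click.option("-m", "--min-fragments", default=10, show_default=True, help="Remove contigs with fewer total fragments than this; 0 disables filtering.")
@click.option("-d", "--dist-thresholds", default="0.3", show_default=True, help="Comma-separated distance threshold(s); each value yields its own output pair.")
@click.option("-p", "--prefix", default="clusters", show_default=True, help="Output file prefix.")
@click.option("-D", "--stat-threshold", type=float, default=None, help="Explicit rejection threshold on the ratio-test statistic (overrides --pvalue).")
@click.option("--pvalue", default=1e-5, show_default=True, help="P-value for the ratio-test rejection threshold.")
@click.option("--no-test", is_flag=True, help="Disable the expression-ratio test (isoform-like contigs co-cluster).")
@click.option("--seed", default=DEFAULT_SEED, show_default=True, help="Seed for random assignment of multi-cluster fragments.")
@click.option("-i", "--input-format", type=click.Choice(["bam", "sam", "eqclass"]), default="bam", help="Input format; bam/sam are auto-detected, eqclass reads the TSV dialect.")
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(
    files: tuple[str, ...],
    sample_names: str | None,
    groups: str | None,
    min_fragments: int,
    dist_thresholds: str,
    prefix: str,
    stat_threshold: float | None,
    pvalue: float,
    no_test: bool,
    seed: int,
    input_format: str,
    verbose: bool,
) -> None:
    """Cluster contigs from multi-mapped alignments and count fragments per cluster.

    FILES are alignment files (SAM/BAM from report-all mapping) or
    equivalence-class tables, one or more per sample.
    """
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(message)s",
    )
    try:
        thresholds = [float(x) for x in dist_thresholds.split(",")]
    except ValueError:
        raise click.UsageError(f"bad -d value {dist_thresholds!r}")
    if input_format == "eqclass":
        design, store = _load_eqclass(files, sample_names, groups)
    else:
        design = _build_design(files, sample_names, groups)
        store = _load_alignments(design)
    logger.info(
        "%d samples in %d condition groups", len(design.samples), design.n_conditions
    )
    n_contigs = len(store.live_ids)
    totals = store.total_fragments()
    logger.info("%d contigs, %d fragments", n_contigs, int(totals.sum()))
    store, removed = filter_low_coverage(store, min_fragments)
    logger.info(
        "filtered %d contigs below %d fragments; %d retained",
        len(removed), min_fragments, len(store.live_ids),
    )
    superclusters = build_superclusters(store)
    if superclusters:
        sizes = sorted((len(sc.member_ids) for sc in superclusters), reverse=True)
        logger.info(
            "%d super-clusters; largest %d contigs", len(superclusters), sizes[0]
        )
    for d in thresholds:
        params = ClusterParams(
            d_threshold=d,
            test_enabled=not no_test,
            p_value=pvalue,
            D_threshold=stat_threshold,
        )
        partition = run_all(store, design, params)
        result = assign_fragments(store, partition, design, seed)
        out_prefix = prefix if len(thresholds) == 1 else f"{prefix}-d{d:g}"
        clusters_path, counts_path = write_outputs(result, out_prefix)
        logger.info("wrote %s and %s", clusters_path, counts_path)
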