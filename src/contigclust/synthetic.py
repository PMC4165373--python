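"""Desk-scale synthetic fixtures with known gene-level truth.

Genes are abstract base intervals, not nucleotide strings: a contig is a
set of (gene, start, end) segments and a fragment maps to every contig one
of whose segments entirely contains its interval.  This reproduces the
multi-mapping structure the clustering algorithm consumes — redundant
duplicates, fragmented transcripts, chimeric concatenations and paralogous
shared blocks — without simulating sequence or running an aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from contigclust.alignment_io import ExperimentDesign, FragmentRecord
from contigclust.evaluation import CHIMERIC

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "generate_scenario",
    "emit_sam",
    "redundant_config",
    "paralog_config",
    "disjoint_config",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry, artifact rates and expression design of one scenario.

    ``mean_fragments`` is either a scalar (every gene, every condition) or a
    sequence of per-gene sequences of per-condition means.  ``dispersion``
    of 0 draws Poisson counts; > 0 draws negative binomial with variance
    m + dispersion * m^2.
    """

    n_genes: int = 2
    gene_length: int = 1000
    isoforms_per_gene: int = 1
    duplicate_rate: float = 0.0
    fragmentation_rate: float = 0.0
    fragment_overlap: int = 0  # bases shared by the two pieces of a split gene
    chimera_rate: float = 0.0
    paralog_pairs: int = 0
    paralog_shared_frac: float = 0.5
    n_conditions: int = 1
    samples_per_condition: int = 1
    mean_fragments: float | Sequence[Sequence[float]] = 100.0
    dispersion: float = 0.0
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.duplicate_rate, self.fragmentation_rate, self.chimera_rate,
                     self.paralog_shared_frac):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.n_genes < 1 or self.n_conditions < 1 or self.samples_per_condition < 1:
            raise ValueError("n_genes, n_conditions and samples_per_condition must be >= 1")
        if 2 * self.paralog_pairs > self.n_genes:
            raise ValueError("not enough genes for the requested paralogue pairs")
        if self.read_length < 1 or self.dispersion < 0:
            raise ValueError("bad read_length or dispersion")

    def mean(self, gene: int, condition: int) -> float:
        if isinstance(self.mean_fragments, (int, float)):
            return float(self.mean_fragments)
        return float(self.mean_fragments[gene][condition])


@dataclass(frozen=True)
class Contig:
    """A contig as a tuple of gene-interval segments it carries."""

    name: str
    segments: tuple[tuple[str, int, int], ...]  # (gene, start, end), half-open

    @property
    def length(self) -> int:
        return max(end for _, _, end in self.segments)


@dataclass
class Scenario:
    fragments: list[FragmentRecord]
    truth: dict[str, str]
    design: ExperimentDesign
    contigs: dict[str, int] = field(default_factory=dict)  # name -> SAM header length


def _build_contigs(cfg: ScenarioConfig, rng: np.random.Generator) -> tuple[list[Contig], dict[str, str]]:
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    length = cfg.gene_length
    genes = [f"g{i}" for i in range(cfg.n_genes)]
    shared = int(round(cfg.paralog_shared_frac * length))
    paralog_partner: dict[int, int] = {}
    for p in range(cfg.paralog_pairs):
        paralog_partner[2 * p] = 2 * p + 1
        paralog_partner[2 * p + 1] = 2 * p

    def add(name: str, gene_label: str, segments: Iterable[tuple[str, int, int]]) -> None:
        contigs.append(Contig(name, tuple(segments)))
        truth[name] = gene_label

    for gi, gene in enumerate(genes):
        base_segments: list[tuple[str, int, int]] = [(gene, 0, length)]
        if gi in paralog_partner and shared > 0:
            partner = genes[paralog_partner[gi]]
            # the first `shared` bases are identical between the two genes
            base_segments.append((partner, 0, shared))
        if rng.random() < cfg.fragmentation_rate:
            # replace the full-length contig by two pieces around the midpoint
            half_ov = cfg.fragment_overlap // 2
            mid = length // 2
            cut_hi = min(length, mid + half_ov + cfg.fragment_overlap % 2)
            cut_lo = max(0, mid - half_ov)
            add(f"{gene}_p0", gene, _clip(base_segments, 0, cut_hi))
            add(f"{gene}_p1", gene, _clip(base_segments, cut_lo, length))
        else:
            for iso in range(cfg.isoforms_per_gene):
                add(f"{gene}_c{iso}", gene, base_segments)
            if rng.random() < cfg.duplicate_rate:
                add(f"{gene}_dup", gene, base_segments)
        if rng.random() < cfg.chimera_rate and cfg.n_genes > 1:
            other = genes[(gi + 1) % cfg.n_genes]
            add(f"chim_{gene}_{other}", CHIMERIC, [(gene, 0, length), (other, 0, length)])
    return contigs, truth


def _clip(
    segments: Sequence[tuple[str, int, int]], lo: int, hi: int
) -> list[tuple[str, int, int]]:
    """Restrict each gene segment to the contig window [lo, hi)."""
    out = []
    for gene, s, e in segments:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((gene, s2, e2))
    return out


def _draw_count(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate contigs, fragments and truth labels for one scenario.

    Fragments are random sub-intervals of their gene; each maps to every
    contig with a segment of that gene entirely containing it.  A fragment
    contained in no contig (e.g. one straddling a disjoint split point) is
    dropped, mirroring an unmapped read.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs, truth = _build_contigs(cfg, rng)
    if cfg.read_length > cfg.gene_length:
        raise ValueError("fragment longer than the genes it must fit in")

    by_gene: dict[str, list[Contig]] = {}
    for contig in contigs:
        for gene, _, _ in contig.segments:
            by_gene.setdefault(gene, []).append(contig)

    conditions = [f"cond{i}" for i in range(cfg.n_conditions)]
    samples = [
        f"{cond}_r{j}" for cond in conditions for j in range(cfg.samples_per_condition)
    ]
    design = ExperimentDesign(
        tuple(samples),
        {},
        {s: s.rsplit("_r", 1)[0] for s in samples},
    )

    fragments: list[FragmentRecord] = []
    for si, sample in enumerate(samples):
        cond_idx = si // cfg.samples_per_condition
        counter = 0
        for gi in range(cfg.n_genes):
            gene = f"g{gi}"
            n = _draw_count(cfg.mean(gi, cond_idx), cfg.dispersion, rng)
            span = cfg.gene_length - cfg.read_length + 1
            for _ in range(n):
                start = int(rng.integers(0, span))
                end = start + cfg.read_length
                hit = frozenset(
                    c.name
                    for c in by_gene.get(gene, [])
                    for g2, s2, e2 in c.segments
                    if g2 == gene and s2 <= start and end <= e2
                )
                counter += 1
                if hit:
                    fragments.append(
                        FragmentRecord(f"{sample}_f{counter:06d}", sample, hit)
                    )
    return Scenario(
        fragments,
        truth,
        design,
        {c.name: c.length for c in sorted(contigs, key=lambda c: c.name)},
    )


def emit_sam(
    fragments: Iterable[FragmentRecord],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a minimal single-end SAM: one record per (fragment, contig) mapping.

    Positions are unknown in the abstract-interval model, so POS is 1 with a
    placeholder 1M CIGAR (SAM parsers demote CIGAR-less mapped records to
    unmapped).  Round-trips through ``parse_alignments`` to the same fragment
    multiset.  All fragments must belong to one sample.
    """
    fragments = sorted(fragments, key=lambda f: f.fragment_id)
    samples = {f.sample_id for f in fragments}
    if len(samples) > 1:
        raise ValueError("emit one SAM per sample")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in sorted(contigs):
            fh.write(f"@SQ\tSN:{name}\tLN:{contigs[name]}\n")
        for frag in fragments:
            for contig in sorted(frag.contig_ids):
                fh.write(
                    f"{frag.fragment_id}\t0\t{contig}\t1\t0\t1M\t*\t0\t0\t*\t*\n"
                )


# ---------------------------------------------------------------------------
# Preset scenarios used by the test suite


def redundant_config(seed: int = 0) -> ScenarioConfig:
    """One gene represented by two identical contigs: they must always merge."""
    return ScenarioConfig(
        n_genes=1, isoforms_per_gene=2, mean_fragments=200.0, seed=seed
    )


def paralog_config(seed: int = 0) -> ScenarioConfig:
    """Two paralogues sharing 65% of their span with reciprocal differential expression.

    Shared-block fragments multi-map, pulling the pair below the distance
    threshold; the expression-ratio test detects the reciprocal change and
    keeps the genes apart, so the test-enabled run yields 2 clusters and the
    test-disabled run yields 1.
    """
    return ScenarioConfig(
        n_genes=2,
        paralog_pairs=1,
        paralog_shared_frac=0.65,
        n_conditions=2,
        samples_per_condition=1,
        mean_fragments=[[500.0, 50.0], [50.0, 500.0]],
        seed=seed,
    )


def disjoint_config(seed: int = 0) -> ScenarioConfig:
    """One gene split into two disjoint contigs: no shared reads, never merged."""
    return ScenarioConfig(
        n_genes=1,
        fragmentation_rate=1.0,
        fragment_overlap=0,
        mean_fragments=300.0,
        seed=seed,
    )
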