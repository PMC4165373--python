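"""Read multi-mapped alignments and the equivalence-class TSV dialect.

Input alignments are expected to come from report-all mapping (every
alignment of every read reported).  Only the read name, the paired/unmapped
flag bits and the reference name of each record are consulted; positions,
CIGAR strings and all other flags are ignored.  The counting unit throughout
is the *fragment*: a read pair contributes once, with the union of the
reference names hit by either mate; a single-end read is a fragment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "FragmentRecord",
    "ExperimentDesign",
    "EqClassFormatError",
    "parse_alignments",
    "read_eqclass_table",
    "write_eqclass_table",
]

#: trailing mate designators stripped from read names (``/1``, ``/2``, ``.1``, ``.2``)
_MATE_SUFFIX = re.compile(r"[/.][12]$")


class EqClassFormatError(ValueError):
    """Raised when an equivalence-class table line cannot be parsed."""


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment and the set of contigs it maps to."""

    fragment_id: str
    sample_id: str
    contig_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.contig_ids:
            raise ValueError(f"fragment {self.fragment_id!r}: empty contig set")


@dataclass(frozen=True)
class ExperimentDesign:
    """Samples, their alignment files and their condition-group labels.

    ``conditions`` preserves the order in which group labels first appear in
    ``samples``; replicate order within a condition is sample order.
    """

    samples: tuple[str, ...]
    files_per_sample: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    group_of_sample: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("design has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in design")
        for s in self.samples:
            if s not in self.group_of_sample:
                raise ValueError(f"sample {s!r} has no group label")
        if self.files_per_sample:
            for s in self.samples:
                if not self.files_per_sample.get(s):
                    raise ValueError(f"sample {s!r} has no alignment files")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of_sample[s], None)
        return tuple(seen)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def replicates(self, condition: str) -> tuple[str, ...]:
        """Sample ids belonging to ``condition``, in sample order."""
        return tuple(s for s in self.samples if self.group_of_sample[s] == condition)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    @classmethod
    def single_group(cls, samples: Sequence[str]) -> "ExperimentDesign":
        """Convenience: all samples in one condition, no files."""
        return cls(tuple(samples), {}, {s: "all" for s in samples})


def strip_mate_suffix(name: str) -> str:
    """Remove a trailing ``/1``-style mate designator from a read name."""
    return _MATE_SUFFIX.sub("", name)


def _validate_sam_references(path: str | Path) -> None:
    """Reject text-SAM records naming a contig absent from the header.

    htslib silently demotes such records to unmapped; we treat them as a
    format error instead.  Binary inputs (BAM/gzip) cannot encode an unknown
    reference, so they are skipped.
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == b"\x1f\x8b" or magic == b"BAM\x01":
        return
    refs: set[str] = set()
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t"):
                        if field.startswith("SN:"):
                            refs.add(field[3:])
                continue
            fields = line.split("\t", 4)
            if len(fields) > 2 and fields[2] not in ("*", "") and fields[2] not in refs:
                raise ValueError(
                    f"{path}:{lineno}: alignment references contig "
                    f"{fields[2]!r} absent from the header"
                )


def parse_alignments(
    files: Sequence[str | Path], sample_id: str
) -> Iterator[FragmentRecord]:
    """Parse SAM/BAM files of one sample into fragment records.

    Files may be unsorted and unindexed.  Mates are paired by read name via a
    name-keyed map, so memory is O(distinct fragments).  Unmapped records are
    skipped; every mapped record contributes its reference name regardless of
    secondary/supplementary status.  Records are yielded sorted by fragment id
    for determinism.

    Raises
    ------
    OSError
        if a file cannot be opened.
    ValueError
        if an alignment references a contig absent from the header (raised by
        the underlying SAM parser).
    """
    hits: dict[str, set[str]] = {}
    for path in files:
        _validate_sam_references(path)
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                name = strip_mate_suffix(aln.query_name)
                hits.setdefault(name, set()).add(aln.reference_name)
    for name in sorted(hits):
        yield FragmentRecord(name, sample_id, frozenset(hits[name]))


def read_eqclass_table(
    path: str | Path,
) -> Iterator[tuple[frozenset[str], str, int]]:
    """Read the equivalence-class TSV dialect.

    Each line holds three tab-separated fields: comma-joined contig ids, a
    sample id and a positive integer fragment count.  Round-trips with
    :func:`write_eqclass_table`.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise EqClassFormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            contig_field, sample_id, count_field = parts
            contigs = frozenset(c for c in contig_field.split(",") if c)
            if not contigs:
                raise EqClassFormatError(f"{path}:{lineno}: empty contig set")
            try:
                count = int(count_field)
            except ValueError:
                raise EqClassFormatError(f"{path}:{lineno}: bad count {count_field!r}") from None
            if count <= 0:
                raise EqClassFormatError(f"{path}:{lineno}: non-positive count {count}")
            yield contigs, sample_id, count


def write_eqclass_table(
    classes: Iterable[tuple[frozenset[str] | set[str], str, int]],
    path: str | Path,
) -> None:
    """Write equivalence classes as TSV, sorted by contig-set key then sample."""
    rows = sorted(
        (",".join(sorted(key)), sample, count) for key, sample, count in classes
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, sample, count in rows:
            fh.write(f"{key}\t{sample}\t{count}\n")
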