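"""RNA/DNA tag x UMI sequencing into per-replicate count tables.

Filters follow the primary-processing rules: tag or UMI reads with
unresolved bases (N) or off-design lengths are excluded, paired tag
reads must agree after reverse complement, each tag x UMI pair counts
once, only assigned tags are kept, and a tag needs both RNA and DNA in
the same replicate to enter the count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .assignment import TagAssignment
from .core import reverse_complement
from .io import iter_fastq


@dataclass
class FilterReport:
    """Per-filter record tallies; emitted + filtered == input (conservation)."""

    total: int = 0
    passed: int = 0
    unresolved_base: int = 0
    wrong_length: int = 0
    pair_mismatch: int = 0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "passed": self.passed,
            "unresolved_base": self.unresolved_base,
            "wrong_length": self.wrong_length,
            "pair_mismatch": self.pair_mismatch,
        }


def _check(seq: str, expected_length: int, report: FilterReport) -> bool:
    if len(seq) != expected_length:
        report.wrong_length += 1
        return False
    if "N" in seq:
        report.unresolved_base += 1
        return False
    return True


def parse_tag_umi_records(
    tag_umi_pairs: Iterable[tuple[str, str] | tuple[str, str, str]],
    tag_length: int,
    umi_length: int,
) -> tuple[list[tuple[str, str]], FilterReport]:
    """Filter raw (tag, umi) or (tag_fwd, tag_rev, umi) records.

    Three-tuples are consensus-merged: the reverse read must be the
    exact reverse complement of the forward read after passing the
    length filter. Returns surviving (tag, umi) records and tallies.
    """
    report = FilterReport()
    records: list[tuple[str, str]] = []
    for item in tag_umi_pairs:
        report.total += 1
        if len(item) == 3:
            tag_fwd, tag_rev, umi = item
            if not _check(tag_fwd, tag_length, report):
                continue
            if len(tag_rev) != tag_length:
                report.wrong_length += 1
                continue
            if reverse_complement(tag_rev) != tag_fwd:
                report.pair_mismatch += 1
                continue
            tag = tag_fwd
        else:
            tag, umi = item
            if not _check(tag, tag_length, report):
                continue
        if not _check(umi, umi_length, report):
            continue
        records.append((tag, umi))
        report.passed += 1
    return records, report


def parse_tag_umi_reads(
    tag_fastq: str,
    umi_fastq: str,
    tag_length: int,
    umi_length: int,
    tag_fastq_reverse: str | None = None,
) -> tuple[list[tuple[str, str]], FilterReport]:
    """FASTQ front end of :func:`parse_tag_umi_records`."""
    tags = (seq for _, seq in iter_fastq(tag_fastq))
    umis = (seq for _, seq in iter_fastq(umi_fastq))
    if tag_fastq_reverse is not None:
        revs = (seq for _, seq in iter_fastq(tag_fastq_reverse))
        stream: Iterator = zip(tags, revs, umis, strict=True)
    else:
        stream = zip(tags, umis, strict=True)
    return parse_tag_umi_records(stream, tag_length, umi_length)


def dedup_and_match(
    records: Iterable[tuple[str, str]],
    assignment: TagAssignment,
) -> tuple[dict[str, int], dict]:
    """Count distinct UMIs per assigned tag.

    Duplicate (tag, UMI) pairs collapse to one; tags absent from the
    assignment are dropped and tallied. Idempotent by construction.
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    n_unassigned = 0
    n_duplicate = 0
    for tag, umi in records:
        if tag not in assignment:
            n_unassigned += 1
            continue
        key = (tag, umi)
        if key in seen:
            n_duplicate += 1
            continue
        seen.add(key)
        counts[tag] = counts.get(tag, 0) + 1
    return counts, {"unassigned_records": n_unassigned, "duplicate_tag_umi": n_duplicate}


def join_rna_dna(
    rna_counts: dict[int, dict[str, int]],
    dna_counts: dict[int, dict[str, int]],
) -> tuple[pd.DataFrame, dict]:
    """Intersect RNA and DNA tag counts within each replicate.

    A (replicate, tag) row is emitted iff the tag was observed in both
    RNA and DNA of that replicate. Inputs are keyed by replicate label.
    """
    if set(rna_counts) != set(dna_counts):
        raise ValueError(
            f"replicate labels differ: RNA {sorted(rna_counts)} vs DNA {sorted(dna_counts)}"
        )
    rows = []
    report = {"rna_only_tags": 0, "dna_only_tags": 0}
    for rep in sorted(rna_counts):
        rna, dna = rna_counts[rep], dna_counts[rep]
        shared = rna.keys() & dna.keys()
        report["rna_only_tags"] += len(rna.keys() - shared)
        report["dna_only_tags"] += len(dna.keys() - shared)
        for tag in sorted(shared):
            rows.append((rep, tag, dna[tag], rna[tag]))
    table = pd.DataFrame(rows, columns=["replicate", "tag", "dna_count", "rna_count"])
    return table, report
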