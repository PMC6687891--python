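"""Tag-to-variant assignment ("subassembly") from reads covering the insert.

Reads carrying a tag label are aligned to the reference element with an
affine-gap global aligner; per-tag variants are called by a per-position
majority vote. A tag is assigned only when every element position is
covered by at least ``min_coverage`` reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import Align

from .core import (
    TargetElement,
    Variant,
    all_possible_deletions,
    all_possible_snvs,
    reverse_complement,
)

DISQUALIFY_REASONS = ("insertion", "multi_bp_deletion", "low_coverage", "ambiguous")


class UnalignableReadError(ValueError):
    """Raised when a read falls below the alignment identity floor."""


@dataclass(frozen=True)
class Difference:
    """One observed difference between read and reference.

    ``kind`` is ``snv`` (ref/alt single bases), ``deletion`` (alt empty,
    ref holds the deleted bases) or ``insertion`` (ref empty, alt holds
    the inserted bases; position is the reference offset the insertion
    precedes).
    """

    position: int
    ref: str
    alt: str
    kind: str

    def as_variant(self, element_id: str = "") -> Variant:
        if self.kind == "snv":
            return Variant(self.position, self.ref, self.alt, element_id)
        if self.kind == "deletion" and len(self.ref) == 1:
            return Variant(self.position, self.ref, "", element_id)
        raise ValueError(f"{self.kind} of length {len(self.ref) or len(self.alt)} is not a Variant")


@dataclass
class AlignmentResult:
    coverage: np.ndarray          # bool mask over element positions
    differences: list[Difference]
    score: float
    identity: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    # mismatch cheaper than a gap pair so substitutions are preferred;
    # end gaps are cheap (partial reads) but not free, so a terminal
    # substitution is still reported rather than clipped
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.9
    aligner.extend_gap_score = -1.0
    end_gap = -0.6
    try:  # Biopython >= 1.88 naming
        aligner.end_insertion_score = end_gap
        aligner.end_deletion_score = end_gap
    except AttributeError:
        aligner.target_end_gap_score = end_gap
        aligner.query_end_gap_score = end_gap
    return aligner


_ALIGNER = _make_aligner()


def _left_normalize(diff: Difference, reference: str) -> Difference:
    """Shift a 1-bp indel to its leftmost equivalent placement."""
    pos = diff.position
    if diff.kind == "deletion" and len(diff.ref) == 1:
        while pos > 0 and reference[pos - 1] == diff.ref:
            pos -= 1
        return Difference(pos, reference[pos], "", "deletion")
    if diff.kind == "insertion" and len(diff.alt) == 1:
        while pos > 0 and reference[pos - 1] == diff.alt:
            pos -= 1
        return Difference(pos, "", diff.alt, "insertion")
    return diff


def align_to_reference(
    read: str,
    element: TargetElement,
    band: int = 25,
    min_identity: float = 0.8,
) -> AlignmentResult:
    """Globally align ``read`` to the element and report differences.

    ``band`` bounds how much longer than the element a read may be;
    end gaps are free so partial reads yield partial coverage.
    Raises :class:`UnalignableReadError` below the identity floor.
    """
    ref = element.sequence
    if len(read) > len(ref) + band:
        raise ValueError(f"read length {len(read)} exceeds element length + band ({len(ref) + band})")
    alignment = _ALIGNER.align(ref, read)[0]
    blocks = alignment.aligned  # (target_ranges, query_ranges)
    t_ranges, q_ranges = blocks[0], blocks[1]
    if len(t_ranges) == 0:
        raise UnalignableReadError("no aligned block")

    differences: list[Difference] = []
    matches = 0
    for (ts, te), (qs, qe) in zip(t_ranges, q_ranges):
        for offset in range(te - ts):
            r, q = ref[ts + offset], read[qs + offset]
            if r == q:
                matches += 1
            else:
                differences.append(Difference(ts + offset, r, q, "snv"))
    # gaps between consecutive aligned blocks
    for (prev_t, prev_q), (next_t, next_q) in zip(
        zip(t_ranges[:-1], q_ranges[:-1]), zip(t_ranges[1:], q_ranges[1:])
    ):
        t_gap = next_t[0] - prev_t[1]
        q_gap = next_q[0] - prev_q[1]
        if t_gap > 0:
            differences.append(
                Difference(prev_t[1], ref[prev_t[1] : prev_t[1] + t_gap], "", "deletion")
            )
        if q_gap > 0:
            differences.append(
                Difference(next_t[0], "", read[prev_q[1] : prev_q[1] + q_gap], "insertion")
            )

    differences = sorted(
        (_left_normalize(d, ref) for d in differences), key=lambda d: (d.position, d.kind)
    )

    start, end = t_ranges[0][0], t_ranges[-1][1]
    coverage = np.zeros(len(ref), dtype=bool)
    coverage[start:end] = True
    identity = matches / len(read) if read else 0.0
    if identity < min_identity:
        raise UnalignableReadError(f"identity {identity:.3f} below floor {min_identity}")
    return AlignmentResult(coverage, differences, float(alignment.score), identity)


@dataclass
class TagCall:
    """Consensus call for one tag."""

    variants: tuple[Variant, ...] = ()
    n_supporting_reads: int = 0
    disqualified: str | None = None

    def __post_init__(self) -> None:
        if self.disqualified is not None and self.disqualified not in DISQUALIFY_REASONS:
            raise ValueError(f"unknown disqualification reason {self.disqualified!r}")
        if self.disqualified is None:
            positions = [v.position for v in self.variants]
            if len(set(positions)) != len(positions):
                raise ValueError("non-disqualified tag with overlapping variants")

    @property
    def is_wildtype(self) -> bool:
        return not self.variants and self.disqualified is None


@dataclass
class TagAssignment:
    """Map from tag sequence to its consensus call."""

    element_id: str
    calls: dict[str, TagCall] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, tag: str) -> bool:
        return tag in self.calls

    def __getitem__(self, tag: str) -> TagCall:
        return self.calls[tag]

    def good_tags(self) -> dict[str, TagCall]:
        """Tags usable downstream (not disqualified)."""
        return {t: c for t, c in self.calls.items() if c.disqualified is None}


def call_tag_variants(
    reads_by_tag: Mapping[str, Iterable[str]],
    element: TargetElement,
    min_coverage: int = 3,
    majority: float = 0.5,
    conflict_floor: float = 1 / 3,
    band: int = 25,
    min_identity: float = 0.8,
) -> TagAssignment:
    """Call per-tag variants by per-position majority vote.

    A tag is assigned only if every element position has read depth
    >= ``min_coverage``. A difference is called when supported by more
    than ``majority`` of its covering reads; support between
    ``conflict_floor`` and ``majority`` flags the tag ambiguous. Called
    insertions or >1 bp deletions disqualify the tag.
    """
    assignment = TagAssignment(element.element_id)
    length = len(element)
    for tag, reads in reads_by_tag.items():
        depth = np.zeros(length, dtype=np.int64)
        diff_counts: Counter[Difference] = Counter()
        n_reads = 0
        for read in reads:
            try:
                result = align_to_reference(read, element, band=band, min_identity=min_identity)
            except UnalignableReadError:
                continue
            n_reads += 1
            depth += result.coverage
            diff_counts.update(result.differences)
        if n_reads == 0 or depth.min() < min_coverage:
            assignment.calls[tag] = TagCall((), n_reads, "low_coverage")
            continue

        called: list[Difference] = []
        ambiguous = False
        for diff, support in diff_counts.items():
            pos = min(diff.position, length - 1)
            covering = depth[pos]
            frac = support / covering if covering else 0.0
            if frac > majority:
                called.append(diff)
            elif frac >= conflict_floor:
                ambiguous = True

        reason: str | None = None
        if any(d.kind == "insertion" for d in called):
            reason = "insertion"
        elif any(d.kind == "deletion" and len(d.ref) > 1 for d in called):
            reason = "multi_bp_deletion"
        else:
            variants = sorted(
                (d.as_variant(element.element_id) for d in called), key=lambda v: v.position
            )
            if len({v.position for v in variants}) != len(variants):
                reason = "ambiguous"
            elif ambiguous:
                reason = "ambiguous"
            else:
                assignment.calls[tag] = TagCall(tuple(variants), n_reads, None)
                continue
        if reason is None and ambiguous:
            reason = "ambiguous"
        assignment.calls[tag] = TagCall((), n_reads, reason or "ambiguous")
    return assignment


def assignment_stats(assignment: TagAssignment, element: TargetElement) -> dict:
    """Summary statistics of an assignment against its element."""
    if not assignment.calls:
        raise ValueError("empty assignment")
    good = assignment.good_tags()
    tags_per_variant: Counter[Variant] = Counter()
    n_variants_total = 0
    n_wildtype = 0
    for call in good.values():
        if call.is_wildtype:
            n_wildtype += 1
        for v in call.variants:
            tags_per_variant[v] += 1
        n_variants_total += len(call.variants)

    snvs = all_possible_snvs(element)
    dels = all_possible_deletions(element)
    snv_covered = sum(1 for v in snvs if tags_per_variant.get(v, 0) >= 1)
    del_covered = sum(1 for v in dels if tags_per_variant.get(v, 0) >= 1)
    return {
        "n_tags": len(assignment),
        "n_good_tags": len(good),
        "n_disqualified": len(assignment) - len(good),
        "snv_coverage": snv_covered / len(snvs),
        "deletion_coverage": del_covered / len(dels) if dels else float("nan"),
        "wildtype_fraction": n_wildtype / len(good) if good else float("nan"),
        "mean_variants_per_tag": n_variants_total / len(good) if good else float("nan"),
        "tags_per_variant": dict(tags_per_variant),
    }
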