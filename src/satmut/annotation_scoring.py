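"""Sequence-based scoring: deltaSVM from k-mer weights and PWM scanning.

deltaSVM follows the convention that the mean of all reference-allele
k-mer weights minus the mean of all alternative-allele k-mer weights is
reported (missing k-mers contribute zero); ``sign='alt-minus-ref'``
restores the original deltaSVM orientation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import TargetElement, Variant, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class UnsupportedVariantError(ValueError):
    pass


@dataclass
class KmerWeightTable:
    weights: dict[str, float]
    lookup_revcomp: bool = True  # fall back to the reverse complement before 0

    def __post_init__(self) -> None:
        ks = {len(k) for k in self.weights}
        if len(ks) != 1:
            raise ValueError(f"mixed k-mer lengths {sorted(ks)}")
        self.k = ks.pop()
        if self.k < 2:
            raise ValueError("k must be >= 2")
        bad = [k for k in self.weights if set(k) - set("ACGT")]
        if bad:
            raise ValueError(f"non-ACGT k-mers: {bad[:3]}")

    def lookup(self, kmer: str) -> float:
        if kmer in self.weights:
            return self.weights[kmer]
        if self.lookup_revcomp:
            return self.weights.get(reverse_complement(kmer), 0.0)
        return 0.0


def delta_svm_score(
    variant: Variant,
    element: TargetElement,
    table: KmerWeightTable,
    sign: str = "ref-minus-alt",
) -> float:
    """Mean ref-allele k-mer weight minus mean alt-allele k-mer weight.

    All k-mers overlapping the variant base are averaged (fewer exist
    near element edges); k-mers absent from the table count as zero.
    SNVs only.
    """
    if variant.is_deletion:
        raise UnsupportedVariantError("deltaSVM is defined for SNVs only")
    if sign not in ("ref-minus-alt", "alt-minus-ref"):
        raise ValueError(f"unknown sign convention {sign!r}")
    variant.check_against(element)
    k = table.k
    ref_seq = element.sequence
    alt_seq = variant.apply(ref_seq)
    lo = max(0, variant.position - k + 1)
    hi = min(len(ref_seq) - k, variant.position)
    if hi < lo:
        raise UnsupportedVariantError("no k-mer overlaps the variant position")
    ref_scores = [table.lookup(ref_seq[s : s + k]) for s in range(lo, hi + 1)]
    alt_scores = [table.lookup(alt_seq[s : s + k]) for s in range(lo, hi + 1)]
    score = float(np.mean(ref_scores) - np.mean(alt_scores))
    return score if sign == "ref-minus-alt" else -score


# ----------------------------------------------------------------------- PWMs

@dataclass
class PWM:
    """Log-odds position weight matrix (rows = positions, cols = ACGT)."""

    motif_id: str
    matrix: np.ndarray
    factor: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not self.factor:
            self.factor = self.motif_id

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def best_possible_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.8,
        factor: str = "",
    ) -> "PWM":
        """Log2-odds from a position frequency matrix, uniform background."""
        counts = np.asarray(counts, dtype=float)
        freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
        return cls(motif_id, np.log2(freqs / 0.25), factor=factor)

    def score(self, window: str) -> float:
        idx = [_BASE_INDEX[b] for b in window]
        return float(self.matrix[np.arange(len(self)), idx].sum())


def read_jaspar_pwms(path, pseudocount: float = 0.8) -> list[PWM]:
    """Parse a JASPAR-format PFM file into log-odds PWMs."""
    from Bio import motifs

    with open(path) as handle:
        parsed = motifs.parse(handle, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"]).T
        out.append(PWM.from_counts(m.matrix_id or m.name, counts, pseudocount, factor=m.name))
    return out


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    start: int
    end: int   # 0-based half-open on the element
    strand: str
    raw_score: float
    factor: str = ""

    @property
    def norm_score(self) -> float:
        return self.raw_score / (self.end - self.start)


def scan_pwm(
    element: TargetElement, pwm: PWM, threshold: float | None = None
) -> list[MotifMatch]:
    """Score every window on both strands; optional norm-score threshold.

    Reverse-strand windows are scored on the reverse complement and
    reported on forward coordinates. Output is ordered by (start,
    strand).
    """
    length, width = len(element), len(pwm)
    matches: list[MotifMatch] = []
    if width > length:
        return matches
    seq = element.sequence
    for start in range(length - width + 1):
        window = seq[start : start + width]
        for strand, oriented in (("+", window), ("-", reverse_complement(window))):
            raw = pwm.score(oriented)
            match = MotifMatch(pwm.motif_id, start, start + width, strand, raw, pwm.factor)
            if threshold is None or match.norm_score >= threshold:
                matches.append(match)
    return matches


def motif_percentile_thresholds(
    matches: list[MotifMatch], percentiles: list[float]
) -> dict[float, float]:
    """Linear-interpolation percentiles of pooled length-normalized scores."""
    if not matches:
        raise ValueError("empty match pool")
    scores = np.array([m.norm_score for m in matches])
    return {p: float(np.percentile(scores, p, method="linear")) for p in percentiles}


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def count_overlapping_motifs(
    position: int, matches: list[MotifMatch], merge_same_motif: bool = True
) -> int:
    """Number of motif matches overlapping a position.

    With ``merge_same_motif`` overlapping matches of one motif are
    combined and both strands collapse, so each motif contributes at
    most one count per merged interval.
    """
    if merge_same_motif:
        by_motif: dict[str, list[tuple[int, int]]] = {}
        for m in matches:
            by_motif.setdefault(m.motif_id, []).append((m.start, m.end))
        count = 0
        for intervals in by_motif.values():
            count += sum(1 for s, e in _merge_intervals(intervals) if s <= position < e)
        return count
    return sum(1 for m in matches if m.start <= position < m.end)


def pwm_delta(
    variant: Variant,
    element: TargetElement,
    pwm: PWM,
    gate_percentile: float = 0.8,
) -> tuple[float, bool]:
    """Best-window PWM score change of an SNV with the percentile gate.

    Ref and alt best scores are taken over all windows (both strands)
    overlapping the variant base; ``gated`` is True when either best
    exceeds ``gate_percentile * best_possible_score``.
    """
    if variant.is_deletion:
        raise UnsupportedVariantError("pwm_delta is defined for SNVs only")
    variant.check_against(element)
    width = len(pwm)
    lo = max(0, variant.position - width + 1)
    hi = min(len(element) - width, variant.position)
    if hi < lo:
        return float("nan"), False
    ref_seq = element.sequence
    alt_seq = variant.apply(ref_seq)
    best = {"ref": -np.inf, "alt": -np.inf}
    for name, seq in (("ref", ref_seq), ("alt", alt_seq)):
        for start in range(lo, hi + 1):
            window = seq[start : start + width]
            best[name] = max(best[name], pwm.score(window),
                             pwm.score(reverse_complement(window)))
    delta = best["alt"] - best["ref"]
    gated = max(best.values()) > gate_percentile * pwm.best_possible_score
    return float(delta), bool(gated)


def top_factors(matches: list[MotifMatch], top_n: int = 5) -> list[str]:
    """The top-N most frequent factors, plus all factors tied with the Nth."""
    counts = Counter(m.factor for m in matches)
    if len(counts) <= top_n:
        return sorted(counts, key=lambda f: (-counts[f], f))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ranked[top_n - 1][1]
    return [f for f, c in ranked if c >= cutoff]
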