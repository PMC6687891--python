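"""Synthetic saturation-mutagenesis MPRA experiments.

Generates a target element, an error-prone-PCR-like tagged library, and
per-replicate RNA/DNA tag x UMI sequencing, with known ground truth so
every downstream stage can be tested without external data.

The generative model for counts is the inverse of the effect regression:
``log2(RNA) = log2(DNA) + sum(variant effects on the tag) + noise``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assignment import TagAssignment, TagCall
from .core import TargetElement, Variant, reverse_complement

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_AT_PARTNER = {"A": "T", "T": "A"}

# mutation classes drawn by spectrum weight, per introduced change
_CLASSES = ("transition", "transversion_at", "transversion_other", "deletion", "insertion")


@dataclass
class SpectrumWeights:
    """Relative weights of mutation classes introduced by error-prone PCR.

    Transition-biased by default, with the common A<->T transversion,
    rare other transversions, 1-bp deletions at transversion-like rates
    and very rare insertions.
    """

    transition: float = 4.0
    transversion_at: float = 1.0
    transversion_other: float = 0.5
    deletion: float = 0.5
    insertion: float = 0.05

    def as_array(self) -> np.ndarray:
        w = np.array(
            [self.transition, self.transversion_at, self.transversion_other,
             self.deletion, self.insertion],
            dtype=float,
        )
        if (w < 0).any():
            raise ValueError("spectrum weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("spectrum weights sum to zero")
        return w


@dataclass
class SimulationConfig:
    element_id: str = "synthetic"
    element_length: int = 250
    gc_content: float = 0.45
    element_type: str = "promoter"

    mutation_rate: float = 0.008
    spectrum: SpectrumWeights = field(default_factory=SpectrumWeights)

    n_tags: int = 50_000
    tag_length: int = 15
    umi_length: int = 10
    n_replicates: int = 3
    wildtype_tag_fraction: float = 0.05

    dna_mean_log: float = 3.0        # natural-log mean of the log-normal tag abundance
    dna_dispersion: float = 1.0      # sdlog of the shared tag abundance
    dna_replicate_jitter: float = 0.3  # sdlog of per-replicate resampling around the tag mean
    rna_noise_sd: float = 0.3        # log2-scale multiplicative RNA noise
    rna_intercept_log2: float = 0.0

    n_footprints: int = 3
    footprint_width: int = 12
    activating_fraction: float = 0.3   # repressive effects outnumber activating
    effect_sd: float = 1.0             # scale of |log2 effect| inside footprints
    inert_fraction: float = 0.1        # in-footprint positions left inert

    read_duplicates: int = 1
    corrupt_fraction: float = 0.0
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (100 <= self.element_length <= 601):
            raise ValueError(f"element_length {self.element_length} outside [100, 601]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.tag_length not in (15, 20):
            raise ValueError("tag_length must be 15 or 20")
        for name in ("wildtype_tag_fraction", "inert_fraction", "activating_fraction",
                     "corrupt_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_footprints * self.footprint_width > self.element_length:
            raise ValueError("footprints do not fit into the element")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.corrupt_fraction >= 0.5:
            raise ValueError("corrupt_fraction must be < 0.5")


@dataclass
class SimulationTruth:
    """Planted ground truth: per-variant effects and per-tag haplotypes."""

    element: TargetElement | None = None
    footprints: list[tuple[int, int]] = field(default_factory=list)
    effects: dict[Variant, float] = field(default_factory=dict)
    haplotypes: dict[str, tuple[Variant, ...]] = field(default_factory=dict)
    dna_abundance: dict[str, float] = field(default_factory=dict)

    def tag_effect(self, tag: str) -> float:
        """Summed (additive, log2) planted effect of a tag's haplotype."""
        return sum(self.effects.get(v, 0.0) for v in self.haplotypes[tag])


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Sequence with an exact (rounded) GC base count at random positions."""
    n_gc = round(gc * length)
    bases = np.empty(length, dtype="<U1")
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    mask = np.zeros(length, dtype=bool)
    mask[gc_positions] = True
    bases[mask] = rng.choice(["G", "C"], size=n_gc)
    bases[~mask] = rng.choice(["A", "T"], size=length - n_gc)
    return "".join(bases)


def _place_footprints(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    width = config.footprint_width
    intervals: list[tuple[int, int]] = []
    for _ in range(config.n_footprints):
        for _attempt in range(1000):
            start = int(rng.integers(0, config.element_length - width + 1))
            if all(start + width <= s or start >= e for s, e in intervals):
                intervals.append((start, start + width))
                break
        else:
            raise RuntimeError("could not place non-overlapping footprints")
    return sorted(intervals)


def simulate_element(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TargetElement, SimulationTruth]:
    """Generate an element and plant per-variant effects in TFBS-like footprints.

    Effects exist for all 3L SNVs and L 1-bp deletions; they are zero
    outside footprints and at inert in-footprint positions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sequence = _random_sequence(config.element_length, config.gc_content, rng)
    element = TargetElement(config.element_id, sequence, config.element_type)
    footprints = _place_footprints(config, rng)

    in_footprint = np.zeros(config.element_length, dtype=bool)
    for start, end in footprints:
        in_footprint[start:end] = True
    active = in_footprint & (rng.random(config.element_length) >= config.inert_fraction)

    effects: dict[Variant, float] = {}
    for pos, ref in enumerate(sequence):
        alts = [a for a in "ACGT" if a != ref] + [""]
        for alt in alts:
            variant = Variant(pos, ref, alt, element.element_id)
            if active[pos]:
                sign = 1.0 if rng.random() < config.activating_fraction else -1.0
                magnitude = abs(rng.normal(0.0, config.effect_sd))
                effects[variant] = sign * magnitude
            else:
                effects[variant] = 0.0
    return element, SimulationTruth(element=element, footprints=footprints, effects=effects)


def _random_tags(n: int, length: int, rng: np.random.Generator) -> list[str]:
    tags: set[str] = set()
    for _attempt in range(50):
        need = n - len(tags)
        if need == 0:
            break
        draws = rng.integers(0, 4, size=(need, length))
        for row in draws:
            tags.add("".join(_BASES[row]))
    else:
        raise RuntimeError("tag collision retries exhausted")
    return sorted(tags)[:n] if len(tags) > n else sorted(tags)


def _left_normalize_deletion(pos: int, sequence: str) -> int:
    base = sequence[pos]
    while pos > 0 and sequence[pos - 1] == base:
        pos -= 1
    return pos


def mutagenize_library(
    element: TargetElement,
    config: SimulationConfig,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
) -> TagAssignment:
    """Attach random tags to mutagenized copies of the element.

    Per-tag mutation counts are Binomial(L, rate); mutation classes are
    drawn from the spectrum weights per change. Tags that receive an
    insertion are flagged disqualified (their substitutions are still
    recorded but never used downstream). Planted 1-bp deletions are
    left-normalized so generator and aligner coordinates agree.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    length = len(element)
    tags = _random_tags(config.n_tags, config.tag_length, rng)
    rng.shuffle(tags)

    n_wildtype = round(config.wildtype_tag_fraction * config.n_tags)
    weights = config.spectrum.as_array()

    assignment = TagAssignment(element.element_id)
    n_mutations = rng.binomial(length, config.mutation_rate, size=config.n_tags)
    n_mutations[:n_wildtype] = 0

    for tag, n_mut in zip(tags, n_mutations):
        variants: dict[int, Variant] = {}
        has_insertion = False
        if n_mut > 0:
            positions = rng.choice(length, size=n_mut, replace=False)
            for pos in positions:
                pos = int(pos)
                ref = element.sequence[pos]
                w = weights.copy()
                if ref not in _AT_PARTNER:
                    w[1] = 0.0
                w = w / w.sum()
                mclass = _CLASSES[rng.choice(len(_CLASSES), p=w)]
                if mclass == "insertion":
                    has_insertion = True
                    continue
                if mclass == "deletion":
                    pos = _left_normalize_deletion(pos, element.sequence)
                    if pos in variants:
                        continue
                    variant = Variant(pos, element.sequence[pos], "", element.element_id)
                elif mclass == "transition":
                    variant = Variant(pos, ref, _TRANSITION_PARTNER[ref], element.element_id)
                elif mclass == "transversion_at":
                    variant = Variant(pos, ref, _AT_PARTNER[ref], element.element_id)
                else:  # transversion_other
                    choices = [b for b in "ACGT" if b != ref
                               and b != _TRANSITION_PARTNER[ref] and b != _AT_PARTNER.get(ref)]
                    variant = Variant(pos, ref, choices[rng.integers(len(choices))],
                                      element.element_id)
                variants[pos] = variant
        ordered = tuple(sorted(variants.values(), key=lambda v: v.position))
        call = TagCall(ordered, 0, "insertion" if has_insertion else None)
        assignment.calls[tag] = call
        truth.haplotypes[tag] = ordered
    return assignment


@dataclass
class SimulatedCounts:
    """Exact molecule counts per (replicate, tag, source) plus record emission."""

    counts: pd.DataFrame  # columns: replicate, tag, dna_count, rna_count
    config: SimulationConfig

    def iter_records(self, rng: np.random.Generator | None = None):
        """Yield raw (source, replicate, tag, umi) records, one per read.

        Each molecule gets a distinct UMI within its (tag, replicate,
        source) group and is emitted ``read_duplicates`` times; corrupt
        extra records (N bases / wrong lengths) are interleaved so that
        their expected share of all records is ``corrupt_fraction``.
        """
        rng = np.random.default_rng(self.config.seed + 2) if rng is None else rng
        cfg = self.config
        corrupt_odds = cfg.corrupt_fraction / (1.0 - cfg.corrupt_fraction)
        for row in self.counts.itertuples(index=False):
            for source, count in (("DNA", row.dna_count), ("RNA", row.rna_count)):
                count = int(round(count))
                umis = _distinct_umis(count, cfg.umi_length, rng)
                for umi in umis:
                    for _ in range(cfg.read_duplicates):
                        yield (source, int(row.replicate), row.tag, umi)
                        if corrupt_odds and rng.random() < corrupt_odds:
                            yield _corrupt_record(source, int(row.replicate), row.tag, umi, rng)


def _distinct_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    umis: set[str] = set()
    while len(umis) < n:
        draws = rng.integers(0, 4, size=(n - len(umis), length))
        for row in draws:
            umis.add("".join(_BASES[row]))
    return sorted(umis)


def _corrupt_record(source, replicate, tag, umi, rng: np.random.Generator):
    """A record guaranteed to fail the N / length filters."""
    mode = rng.integers(3)
    if mode == 0:  # N in tag
        i = int(rng.integers(len(tag)))
        tag = tag[:i] + "N" + tag[i + 1 :]
    elif mode == 1:  # N in UMI
        i = int(rng.integers(len(umi)))
        umi = umi[:i] + "N" + umi[i + 1 :]
    else:  # wrong tag length
        tag = tag[:-1] if rng.random() < 0.5 else tag + "A"
    return (source, replicate, tag, umi)


def simulate_counts(
    assignment: TagAssignment,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedCounts:
    """Draw per-replicate DNA/RNA molecule counts for every tag.

    DNA abundance is log-normal per tag (shared mean, per-replicate
    jitter); RNA satisfies ``E[log2 RNA] = log2 DNA + effect + noise``.
    With ``round_counts=False`` counts stay exact floats so the
    noiseless pipeline identity holds to machine precision.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    tags = list(assignment.calls)
    n = len(tags)
    effect_sums = np.array([truth.tag_effect(t) for t in tags])

    shared = rng.lognormal(config.dna_mean_log, config.dna_dispersion, size=n)
    for tag, abundance in zip(tags, shared):
        truth.dna_abundance[tag] = float(abundance)

    frames = []
    for rep in range(1, config.n_replicates + 1):
        dna = shared * rng.lognormal(0.0, config.dna_replicate_jitter, size=n)
        if config.round_counts:
            dna = np.maximum(1, np.round(dna))
        noise = rng.normal(0.0, config.rna_noise_sd, size=n) if config.rna_noise_sd > 0 else 0.0
        rna = np.exp2(np.log2(dna) + config.rna_intercept_log2 + effect_sums + noise)
        if config.round_counts:
            rna = np.maximum(1, np.round(rna))
        frames.append(
            pd.DataFrame({"replicate": rep, "tag": tags, "dna_count": dna, "rna_count": rna})
        )
    counts = pd.concat(frames, ignore_index=True)
    return SimulatedCounts(counts=counts, config=config)


def simulate_subassembly_reads(
    element: TargetElement,
    assignment: TagAssignment,
    reads_per_tag: int = 3,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Error-free full-length insert reads per tag, for assignment testing.

    Variants are applied from the highest position down so deletion
    shifts cannot invalidate lower coordinates.
    """
    reads: dict[str, list[str]] = {}
    for tag, call in assignment.calls.items():
        seq = element.sequence
        for variant in sorted(call.variants, key=lambda v: -v.position):
            seq = variant.apply(seq)
        reads[tag] = [seq] * reads_per_tag
    return reads


def simulate_experiment(config: SimulationConfig):
    """Convenience: element + library + counts in one seeded call."""
    rng = np.random.default_rng(config.seed)
    element, truth = simulate_element(config, rng)
    assignment = mutagenize_library(element, config, truth, rng)
    counts = simulate_counts(assignment, truth, config, rng)
    return element, truth, assignment, counts
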