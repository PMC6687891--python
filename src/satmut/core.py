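"""Core domain types shared across the pipeline.

Coordinates are 0-based internally. Exported human-readable tables use
1-based positions and BED output is 0-based half-open; writers state their
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSITION = "transition"
TRANSVERSION = "transversion"
DELETION_1BP = "deletion_1bp"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TargetElement:
    """A cloned promoter/enhancer region under mutagenesis."""

    element_id: str
    sequence: str
    element_type: str = "promoter"
    coordinate_origin: int = 0

    def __post_init__(self) -> None:
        if set(self.sequence) - DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"element {self.element_id}: non-ACGT characters {bad}")
        if self.element_type not in ("promoter", "enhancer"):
            raise ValueError(f"element_type must be promoter/enhancer, got {self.element_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass(frozen=True, order=True)
class Variant:
    """A single-base substitution or 1-bp deletion on an element.

    ``alt == ""`` encodes a 1-bp deletion. Position is a 0-based offset
    into the element sequence.
    """

    position: int
    ref: str
    alt: str
    element_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or self.ref not in DNA_ALPHABET:
            raise ValueError(f"ref must be a single ACGT base, got {self.ref!r}")
        if self.alt and (len(self.alt) != 1 or self.alt not in DNA_ALPHABET):
            raise ValueError(f"alt must be empty (deletion) or one ACGT base, got {self.alt!r}")
        if self.alt == self.ref:
            raise ValueError(f"SNV with ref == alt at position {self.position}")
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""

    @property
    def vclass(self) -> str:
        if self.is_deletion:
            return DELETION_1BP
        same_ring = (self.ref in PURINES) == (self.alt in PURINES)
        return TRANSITION if same_ring else TRANSVERSION

    @property
    def token(self) -> str:
        """Compact ``pos:ref>alt`` token; deletions render alt as ``-``."""
        return f"{self.position}:{self.ref}>{self.alt or '-'}"

    @classmethod
    def from_token(cls, token: str, element_id: str = "") -> "Variant":
        try:
            pos_s, change = token.split(":", 1)
            ref, alt = change.split(">", 1)
        except ValueError as exc:
            raise ValueError(f"malformed variant token {token!r}") from exc
        if alt == "-":
            alt = ""
        return cls(position=int(pos_s), ref=ref, alt=alt, element_id=element_id)

    def check_against(self, element: TargetElement) -> None:
        if self.position >= len(element):
            raise ValueError(
                f"variant {self.token} outside element {element.element_id} (L={len(element)})"
            )
        if element.sequence[self.position] != self.ref:
            raise ValueError(
                f"variant {self.token}: element has {element.sequence[self.position]} "
                f"at position {self.position}, not {self.ref}"
            )

    def apply(self, sequence: str) -> str:
        """Return ``sequence`` with this variant applied."""
        if sequence[self.position] != self.ref:
            raise ValueError(f"reference mismatch applying {self.token}")
        return sequence[: self.position] + self.alt + sequence[self.position + 1 :]


def all_possible_snvs(element: TargetElement) -> list[Variant]:
    """The 3L possible single-nucleotide substitutions of an element."""
    out = []
    for pos, ref in enumerate(element.sequence):
        for alt in "ACGT":
            if alt != ref:
                out.append(Variant(pos, ref, alt, element.element_id))
    return out


def all_possible_deletions(element: TargetElement) -> list[Variant]:
    """The L possible 1-bp deletions of an element."""
    return [Variant(pos, ref, "", element.element_id) for pos, ref in enumerate(element.sequence)]


def variants_overlap(a: Variant, b: Variant) -> bool:
    return a.position == b.position
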