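"""Readers and writers for the pipeline's text formats.

Conventions: positions are 0-based internally; effects TSV and the
VCF-like export are 1-based; BED is 0-based half-open. Gzip input is
handled transparently by extension.
"""

from __future__ import annotations

import gzip
import json
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assignment import TagAssignment, TagCall
from .core import TargetElement, Variant


class FormatError(ValueError):
    """Malformed input; message names file, line and field."""


def open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta_element(path, element_type: str = "promoter") -> TargetElement:
    with open_text(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    record = records[0]
    return TargetElement(record.id, str(record.seq).upper(), element_type)


def write_fasta(path, element: TargetElement) -> None:
    with open_text(path, "wt") as handle:
        SeqIO.write([SeqRecord(Seq(element.sequence), id=element.element_id, description="")],
                    handle, "fasta")


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs; raises FormatError with record index."""
    with open_text(path) as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FormatError(f"{path}: malformed FASTQ at record {index}")
            yield header[1:].split()[0], seq.strip().upper()
            index += 1


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ------------------------------------------------------------- assignment TSV

_ASSIGNMENT_HEADER = ["tag", "variants", "n_reads", "disqualified"]


def write_assignment(path, assignment: TagAssignment) -> None:
    with open_text(path, "wt") as handle:
        handle.write("# tag assignment; variant tokens are 0-based pos:ref>alt, '-' = deletion\n")
        handle.write("\t".join(_ASSIGNMENT_HEADER) + "\n")
        for tag in sorted(assignment.calls):
            call = assignment.calls[tag]
            tokens = ",".join(v.token for v in call.variants) or "."
            handle.write(
                f"{tag}\t{tokens}\t{call.n_supporting_reads}\t{call.disqualified or '.'}\n"
            )


def read_assignment(path, element_id: str = "") -> TagAssignment:
    assignment = TagAssignment(element_id)
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields == _ASSIGNMENT_HEADER:
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, found {len(fields)}")
            tag, tokens, n_reads, disqualified = fields
            try:
                variants = tuple(
                    Variant.from_token(tok, element_id)
                    for tok in tokens.split(",") if tok and tok != "."
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if tag in assignment.calls:
                raise FormatError(f"{path}:{lineno}: duplicate tag {tag}")
            try:
                call = TagCall(
                    variants,
                    int(n_reads),
                    None if disqualified == "." else disqualified,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            assignment.calls[tag] = call
    return assignment


# ------------------------------------------------------------------ count TSV

_COUNT_COLUMNS = ["replicate", "tag", "dna_count", "rna_count"]


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=_COUNT_COLUMNS)


def read_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(_COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return table[_COUNT_COLUMNS]


# ---------------------------------------------------------------- effects TSV

_EFFECT_COLUMNS = [
    "element", "position", "ref", "alt", "log2_effect", "std_error",
    "p_value", "ci_low", "ci_high", "n_obs", "n_distinct_tags",
]


def write_effects(path, estimates: pd.DataFrame, element_id: str = "") -> None:
    """Effects table with 1-based positions; deletions write alt '-'."""
    out = estimates.copy()
    out["element"] = element_id or out.get("element", "")
    out["position"] = out["position"].astype(int) + 1
    out["alt"] = out["alt"].replace("", "-")
    extra = [c for c in ("label",) if c in out.columns]
    with open_text(path, "wt") as handle:
        handle.write("# effects table; positions are 1-based\n")
        out.to_csv(handle, sep="\t", index=False, columns=_EFFECT_COLUMNS + extra)


def read_effects(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"ref": str, "alt": str})
    missing = set(_EFFECT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    table["position"] = table["position"].astype(int) - 1
    table["alt"] = table["alt"].fillna("-").replace("-", "")
    table["variant"] = [
        Variant(int(p), r, a, e)
        for p, r, a, e in zip(table["position"], table["ref"], table["alt"], table["element"])
    ]
    return table


def write_effects_vcf(path, estimates: pd.DataFrame, element_id: str) -> None:
    """Minimal VCF-like export (1-based); deletions use the padded-base form."""
    with open_text(path, "wt") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=EFFECT,Number=1,Type=Float,Description="log2 effect">\n')
        handle.write('##INFO=<ID=SE,Number=1,Type=Float,Description="standard error">\n')
        handle.write('##INFO=<ID=PVALUE,Number=1,Type=Float,Description="coefficient p-value">\n')
        handle.write('##INFO=<ID=NTAGS,Number=1,Type=Integer,Description="tag observations">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in estimates.itertuples(index=False):
            info = (
                f"EFFECT={row.log2_effect:.6g};SE={row.std_error:.6g};"
                f"PVALUE={row.p_value:.6g};NTAGS={row.n_obs}"
            )
            if row.alt == "":
                # padded representation: previous base + deleted base -> previous base
                handle.write(
                    f"{element_id}\t{row.position}\t.\tN{row.ref}\tN\t.\t.\t{info}\n"
                )
            else:
                handle.write(
                    f"{element_id}\t{row.position + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\n"
                )


# ----------------------------------------------------------- k-mer / BED / JSON

def read_kmer_weights(path) -> dict[str, float]:
    weights: dict[str, float] = {}
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'kmer<TAB>weight'")
            try:
                weights[fields[0].upper()] = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad weight {fields[1]!r}") from exc
    if not weights:
        raise FormatError(f"{path}: empty k-mer table")
    lengths = {len(k) for k in weights}
    if len(lengths) != 1:
        raise FormatError(f"{path}: mixed k-mer lengths {sorted(lengths)}")
    return weights


def write_matches_bed(path, matches, element_id: str) -> None:
    """BED6 (0-based half-open), score = length-normalized match score."""
    with open_text(path, "wt") as handle:
        for m in matches:
            handle.write(
                f"{element_id}\t{m.start}\t{m.end}\t{m.motif_id}\t{m.norm_score:.4f}\t{m.strand}\n"
            )


def write_json(path, payload: dict) -> None:
    with open_text(path, "wt") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
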