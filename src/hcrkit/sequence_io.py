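"""Reading and normalizing target and transcriptome FASTA files.

A probe that spans a splice junction fails to detect the spliced mRNA, so
multi-exon targets must carry junction information. Two FASTA conventions
are accepted for the same gene:

``single_entry_N``
    one record in which exons are separated by one or more ``N`` characters;
``multi_entry_exons``
    one record per exon, in transcript order, in a single file.

Both normalize to the same :class:`TargetSequence`: exons concatenated with
exactly one ``N`` between consecutive exons, so downstream tiling excludes
junction-spanning windows simply by rejecting windows that contain ``N``.

Coordinates are 0-based half-open everywhere inside the library; user-facing
reports convert to 1-based inclusive and say so in their headers.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "TargetSequence",
    "TranscriptomeIndex",
    "InputError",
    "read_target",
    "write_target",
    "read_transcriptome",
]

_VALID = set("ACGTN")


class InputError(ValueError):
    """Malformed user input (bad FASTA, bad alphabet, wrong record count)."""


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fasta(path) -> list[tuple[str, str]]:
    with _open_maybe_gzip(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise InputError(f"{path}: empty FASTA file (no records)")
    return records


def _normalize(seq: str, record_id: str) -> str:
    """Uppercase, map U->T, reject anything outside {A,C,G,T,N}."""
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in _VALID:
            raise InputError(
                f"record {record_id!r}: invalid character {ch!r} at position "
                f"{pos + 1} (only A/C/G/T/U/N accepted)"
            )
    return out


@dataclass(frozen=True)
class TargetSequence:
    """A normalized target transcript with junction mask and exon provenance.

    ``sequence`` is over {A,C,G,T,N} with a single ``N`` marking each exon
    junction; ``exon_bounds`` are 0-based half-open intervals in the
    concatenated coordinate system, covering exactly the non-N positions.
    """

    gene_id: str
    sequence: str
    exon_bounds: tuple[tuple[int, int], ...]
    source_mode: str  # "single_entry_N" | "multi_entry_exons"

    def __post_init__(self):
        covered = []
        prev_end = -1
        for start, end in self.exon_bounds:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"exon bound ({start},{end}) out of range")
            if start <= prev_end:
                raise ValueError("exon bounds overlap or are unsorted")
            prev_end = end
            covered.extend(range(start, end))
        non_n = [i for i, c in enumerate(self.sequence) if c != "N"]
        if covered != non_n:
            raise ValueError("exon bounds do not tile the non-N positions")

    @property
    def junction_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.sequence) if c == "N")

    def equivalent_to(self, other: "TargetSequence") -> bool:
        """Field equality ignoring source_mode (junction-convention check)."""
        return (
            self.gene_id == other.gene_id
            and self.sequence == other.sequence
            and self.exon_bounds == other.exon_bounds
        )


def _gene_id_from_records(ids: list[str], mode: str) -> str:
    """Gene id for a target file: the record id, with per-exon suffixes
    (``_exon1`` etc.) stripped in multi-entry files when all records share
    the same stem — so both junction conventions name the same gene."""
    if mode != "multi_entry_exons" or len(ids) == 1:
        return ids[0]
    import re

    stems = {re.sub(r"[._-]?[Ee]xon\d+$", "", rid) for rid in ids}
    if len(stems) == 1:
        stem = stems.pop()
        if stem:
            return stem
    return ids[0]


def _exons_from_masked(seq: str) -> list[tuple[int, int]]:
    bounds = []
    start = None
    for i, c in enumerate(seq):
        if c != "N" and start is None:
            start = i
        elif c == "N" and start is not None:
            bounds.append((start, i))
            start = None
    if start is not None:
        bounds.append((start, len(seq)))
    return bounds


def read_target(path, mode: str = "auto") -> TargetSequence:
    """Read a target FASTA in either junction convention.

    Parameters
    ----------
    path
        FASTA file (optionally gzip-compressed).
    mode
        ``"single_entry_N"``, ``"multi_entry_exons"``, or ``"auto"``
        (= exons if the file has more than one record, else single).

    Returns
    -------
    TargetSequence
        The two conventions applied to the same gene yield identical
        ``sequence`` and ``exon_bounds``. Runs of one or more ``N`` in
        single-entry input are collapsed to a single masked junction.
    """
    records = _parse_fasta(path)
    if mode == "auto":
        mode = "multi_entry_exons" if len(records) > 1 else "single_entry_N"
    if mode not in ("single_entry_N", "multi_entry_exons"):
        raise ValueError(f"unknown junction mode {mode!r}")

    gene_id = _gene_id_from_records([rid for rid, _ in records], mode)
    if mode == "single_entry_N":
        if len(records) != 1:
            raise InputError(
                f"{path}: single_entry_N mode requires exactly one record, "
                f"found {len(records)}"
            )
        raw = _normalize(records[0][1], gene_id)
        # collapse N runs to one separator, strip terminal Ns
        collapsed = []
        for ch in raw:
            if ch == "N" and collapsed and collapsed[-1] == "N":
                continue
            collapsed.append(ch)
        seq = "".join(collapsed).strip("N")
        if not seq:
            raise InputError(f"{path}: record {gene_id!r} has no sequence")
        exons = [seq[s:e] for s, e in _exons_from_masked(seq)]
    else:
        exons = []
        for rec_id, rec_seq in records:
            norm = _normalize(rec_seq, rec_id)
            if not norm:
                raise InputError(f"{path}: empty exon record {rec_id!r}")
            if "N" in norm:
                raise InputError(
                    f"record {rec_id!r}: 'N' not allowed inside an exon record"
                )
            exons.append(norm)

    sequence = "N".join(exons)
    bounds = []
    pos = 0
    for ex in exons:
        bounds.append((pos, pos + len(ex)))
        pos += len(ex) + 1
    return TargetSequence(
        gene_id=gene_id,
        sequence=sequence,
        exon_bounds=tuple(bounds),
        source_mode=mode,
    )


def write_target(target: TargetSequence, path, mode: str) -> None:
    """Write a TargetSequence back out in either junction convention."""
    path = Path(path)
    with open(path, "w") as fh:
        if mode == "single_entry_N":
            fh.write(f">{target.gene_id}\n{target.sequence}\n")
        elif mode == "multi_entry_exons":
            for i, (s, e) in enumerate(target.exon_bounds, start=1):
                fh.write(f">{target.gene_id}_exon{i}\n{target.sequence[s:e]}\n")
        else:
            raise ValueError(f"unknown junction mode {mode!r}")


@dataclass
class TranscriptomeIndex:
    """k-mer seed index over a transcriptome FASTA.

    Stand-in backend for a BLAST nucleotide database: ``kmer_index`` maps
    every N-free k-mer to all (transcript_id, position) occurrences, which
    the off-target screen extends to maximal exact matches.
    """

    records: dict[str, str]
    k: int
    kmer_index: dict[str, list[tuple[str, int]]] = field(repr=False, default=None)

    def __post_init__(self):
        if self.kmer_index is None:
            index: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for tid, seq in self.records.items():
                for p in range(len(seq) - self.k + 1):
                    kmer = seq[p : p + self.k]
                    if "N" not in kmer:
                        index[kmer].append((tid, p))
            self.kmer_index = dict(index)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.kmer_index.get(kmer, [])

    def __len__(self) -> int:
        return len(self.records)


def read_transcriptome(path, k: int = 15) -> TranscriptomeIndex:
    """Read a transcriptome FASTA and build a k-mer seed index.

    Transcript ids are the FASTA header token before the first whitespace
    (matching BLAST database behavior). Requires 8 <= k <= 20; every record
    must be non-empty and at least k long.
    """
    if not (8 <= k <= 20):
        raise ValueError(f"seed length k={k} outside supported range [8, 20]")
    records: dict[str, str] = {}
    for rec_id, rec_seq in _parse_fasta(path):
        if rec_id in records:
            raise InputError(f"{path}: duplicate transcript id {rec_id!r}")
        norm = _normalize(rec_seq, rec_id)
        if not norm:
            raise InputError(f"{path}: empty record {rec_id!r}")
        if len(norm) < k:
            raise InputError(
                f"{path}: record {rec_id!r} shorter than seed length {k}"
            )
        records[rec_id] = norm
    return TranscriptomeIndex(records=records, k=k)
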