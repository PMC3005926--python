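"""Read collapsing and the abundance / adapter / length filters.

Raw small-RNA reads are collapsed to unique sequences with copy numbers
(the copy number of a unique read is the expression proxy carried through
the whole pipeline), then filtered: copy number >= 3 first, adapter
trimming second, 18-25 nt length window last — in that order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from mirfish.seqs import normalize


@dataclass(frozen=True)
class UniqueRead:
    sequence: str
    copy_number: int
    read_id: str

    @classmethod
    def make(cls, sequence: str, copy_number: int) -> "UniqueRead":
        rid = hashlib.sha1(sequence.encode()).hexdigest()[:12]
        return cls(sequence=sequence, copy_number=copy_number, read_id=rid)


def collapse(reads: Iterable[str]) -> list[UniqueRead]:
    """Collapse raw reads into unique sequences with copy numbers.

    Sequences are uppercased and U-normalized to DNA.  Output is ordered
    by descending copy number, then lexicographically, so the result is
    deterministic regardless of input order.  Copy numbers sum to the
    input read count.
    """
    counts: dict[str, int] = {}
    for read in reads:
        seq = normalize(read)
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [UniqueRead.make(seq, n) for seq, n in ordered]


def filter_copy_number(unique: list[UniqueRead], min_copies: int = 3) -> list[UniqueRead]:
    """Keep unique reads with copy_number >= min_copies (order preserved)."""
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    return [u for u in unique if u.copy_number >= min_copies]


def trim_adapter(unique: list[UniqueRead], adapter: str, min_overlap: int = 6) -> list[UniqueRead]:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    A match must cover at least ``min_overlap`` bases; reads with no such
    overlap pass through unchanged and reads trimmed to nothing are
    dropped.  Reads that become identical after trimming are merged (copy
    numbers summed).
    """
    adapter = normalize(adapter)
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    merged: dict[str, int] = {}
    for u in unique:
        seq = u.sequence
        trimmed = seq
        for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                trimmed = seq[:-k]
                break
        if trimmed:
            merged[trimmed] = merged.get(trimmed, 0) + u.copy_number
    ordered = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return [UniqueRead.make(seq, n) for seq, n in ordered]


def filter_length(unique: list[UniqueRead], min_len: int = 18, max_len: int = 25) -> list[UniqueRead]:
    """Keep reads with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [u for u in unique if min_len <= len(u.sequence) <= max_len]


# ---------------------------------------------------------------------------
# I/O


def load_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_collapsed(unique: list[UniqueRead], fasta_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write collapsed reads as ``>read_<id>_x<copy>`` FASTA plus optional TSV."""
    with open(fasta_path, "w") as fh:
        for u in unique:
            fh.write(f">read_{u.read_id}_x{u.copy_number}\n{u.sequence}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("sequence\tcopy_number\n")
            for u in unique:
                fh.write(f"{u.sequence}\t{u.copy_number}\n")
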