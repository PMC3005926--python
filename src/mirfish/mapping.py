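"""Perfect-match read mapping and the three exclusion filters.

A mappable read must be completely identical to a genomic locus — no
mismatch, no gap — on either strand.  Reads are then excluded when they
(a) fall in masked repeat regions (soft-masked lowercase or hard-masked
N, or an explicit interval list), (b) align to a coding-sequence decoy
set at more than 90% identity, or (c) map back to more than ten genomic
loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from mirfish.reads import UniqueRead
from mirfish.seqs import revcomp

_VALID = set("ACGT")


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int
    end: int
    strand: str
    read_id: str


@dataclass
class Genome:
    """Uppercase chromosome sequences plus a boolean mask per chromosome.

    Masked positions (True) mark repeat or ambiguous bases; a locus
    overlapping any masked base is never reported by the mapper.
    """

    seqs: dict[str, str]
    mask: dict[str, np.ndarray]

    @classmethod
    def from_dict(cls, raw: dict[str, str], masked_intervals: dict[str, list[tuple[int, int]]] | None = None) -> "Genome":
        seqs, mask = {}, {}
        for chrom, seq in raw.items():
            lowercase_or_n = np.array([(c.islower() or c in "Nn") for c in seq], dtype=bool)
            seqs[chrom] = seq.upper()
            mask[chrom] = lowercase_or_n
        g = cls(seqs=seqs, mask=mask)
        if masked_intervals:
            for chrom, ivs in masked_intervals.items():
                for s, e in ivs:
                    g.mask[chrom][s:e] = True
        return g

    @classmethod
    def from_fasta(cls, path: str | Path, masked_bed: str | Path | None = None) -> "Genome":
        raw = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        intervals: dict[str, list[tuple[int, int]]] = {}
        if masked_bed is not None:
            for line in Path(masked_bed).read_text().splitlines():
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e = line.split("\t")[:3]
                intervals.setdefault(chrom, []).append((int(s), int(e)))
        return cls.from_dict(raw, intervals or None)


class ExactMatchIndex:
    """k-mer seed index over the forward strand of every chromosome.

    Lookup of a read checks the forward strand directly and the reverse
    complement of the read against the forward strand (reporting strand
    '-'), so all occurrences on both strands are found.  A palindromic
    read therefore yields one locus per strand at the same interval.
    """

    def __init__(self, genome: Genome, k: int = 18):
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.seqs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if _VALID.issuperset(kmer):
                    self._seeds.setdefault(kmer, []).append((chrom, pos))

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self._seeds.get(query[: self.k], ()):
            if self.genome.seqs[chrom][pos : pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits


def build_index(genome: Genome, k: int = 18) -> ExactMatchIndex:
    return ExactMatchIndex(genome, k=k)


def map_exact(index: ExactMatchIndex, read: UniqueRead, exclude_masked: bool = True) -> list[GenomicLocus]:
    """All perfect-match loci of a read on both strands.

    Loci overlapping masked bases are excluded.  Reads containing
    characters outside ACGT are rejected with an error (they can never
    match an unmasked locus, and silently returning nothing would hide
    upstream processing bugs).
    """
    seq = read.sequence
    if not _VALID.issuperset(seq):
        raise ValueError(f"read {read.read_id} contains non-ACGT characters")
    if len(seq) < index.k:
        raise ValueError(f"read shorter than index k={index.k}")
    loci = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom, pos in index._forward_hits(query):
            if exclude_masked and index.genome.mask[chrom][pos : pos + len(seq)].any():
                continue
            loci.append(GenomicLocus(chrom, pos, pos + len(seq), strand, read.read_id))
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


def map_all(index: ExactMatchIndex, unique: list[UniqueRead]) -> dict[str, list[GenomicLocus]]:
    """Map every unique read; reads with zero loci are omitted."""
    out: dict[str, list[GenomicLocus]] = {}
    for u in unique:
        loci = map_exact(index, u)
        if loci:
            out[u.read_id] = loci
    return out


def filter_multimappers(read_to_loci: dict[str, list[GenomicLocus]], max_loci: int = 10) -> dict[str, list[GenomicLocus]]:
    """Drop reads mapping to more than ``max_loci`` loci (exactly 10 survives)."""
    return {rid: loci for rid, loci in read_to_loci.items() if len(loci) <= max_loci}


def best_decoy_identity(seq: str, decoys: list[str]) -> float:
    """Best ungapped identity of a read against a decoy set.

    Identity = matched bases / read length, maximized over every decoy
    and every alignment offset (including read overhangs past the decoy
    ends, handled by padding).
    """
    best = 0.0
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    for decoy in decoys:
        padded = "#" * (n - 1) + decoy.upper() + "#" * (n - 1)
        if len(padded) < n:
            continue
        windows = sliding_window_view(np.frombuffer(padded.encode(), dtype="S1"), n)
        matches = (windows == arr).sum(axis=1)
        best = max(best, float(matches.max()) / n)
    return best


def filter_refseq(unique: list[UniqueRead], decoys: list[str], min_identity: float = 0.90) -> list[UniqueRead]:
    """Discard reads with more than ``min_identity`` to any decoy sequence.

    The threshold is strict: a read survives at exactly 90% identity.
    With an empty decoy set the filter is the identity.
    """
    if not decoys:
        return list(unique)
    return [u for u in unique if best_decoy_identity(u.sequence, decoys) <= min_identity]


def write_bed6(read_to_loci: dict[str, list[GenomicLocus]], copies: dict[str, int], path: str | Path) -> None:
    """Emit loci as BED6 (name = read id, score = copy number)."""
    rows = [l for loci in read_to_loci.values() for l in loci]
    rows.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand))
    with open(path, "w") as fh:
        for l in rows:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.read_id}\t{copies.get(l.read_id, 0)}\t{l.strand}\n")
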