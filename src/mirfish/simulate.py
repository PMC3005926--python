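"""Synthetic genomes, read sets, catalogs and decoys with planted ground truth.

The generator emulates the structure of a whole-body small-RNA sequencing
experiment against a draft fish genome: ~140 nt hairpin precursors planted
on both strands (some grouped into genomic clusters within 10 kb), read
stacks concentrated on one or both precursor arms with configurable 5p:3p
dominance, isomiR end-variation biased to the 3' end, repeat elements
copied to many loci (so the multi-locus filter fires), coding-gene decoys
(so the protein-coding exclusion filter fires), and random noise reads
absent from the genome.

Every output is a deterministic function of the seed; the TruthTable
records where everything was planted and round-trips losslessly via JSON.

Hairpin construction: the 5' arm is sampled uniformly over ACGT, the 3'
arm is its reverse complement with Binomial(n, 0.1) point mutations
(realistic bulges), and the loop is 8-15 random nt.  This guarantees
foldable stems of >=18 base pairs without an external folding engine,
which is re-verified with the in-package folder at planting time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from mirfish.hairpin import fold, pairs_from_structure
from mirfish.seqs import revcomp

SPECIES_POOL = ("hsa", "mmu", "rno", "gga", "xtr", "dre", "ssc", "bta", "cfa", "tni")

#: default isomiR end-variation distribution over (5' shift, 3' shift);
#: most variation sits at the 3' end, as observed in deep small-RNA stacks
DEFAULT_ISOMIR_OFFSETS = {
    (0, 0): 0.50,
    (0, -1): 0.18,
    (0, 1): 0.12,
    (0, -2): 0.08,
    (0, 2): 0.05,
    (-1, 0): 0.04,
    (1, 0): 0.03,
}

#: arm-expression categories and their frequencies among vertebrate
#: pre-miRNAs (5p-only, 3p-only, 5p-dominant, 3p-dominant, equal)
ARM_RATIO_CHOICES = ((1, 0), (0, 1), (4, 1), (1, 4), (1, 1))
ARM_RATIO_FREQS = (0.433, 0.414, 0.067, 0.052, 0.034)


class PlacementError(RuntimeError):
    """Raised when an element cannot be placed after bounded retries."""


@dataclass
class PlantedMirna:
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    mature5p_interval: tuple[int, int] | None
    mature3p_interval: tuple[int, int] | None
    arm_ratio: tuple[float, float]  # (5p weight, 3p weight)
    isomir_offsets: dict[tuple[int, int], float]
    family: str
    n_species: int
    cluster: int | None = None
    #: ortholog arm annotation used when building the catalog arm table
    ortholog_arms: tuple[str, str] = ("major", "absent")

    def mature_interval(self, arm: str) -> tuple[int, int] | None:
        return self.mature5p_interval if arm == "5p" else self.mature3p_interval


@dataclass
class TruthTable:
    planted: list[PlantedMirna]
    repeats: list[dict]  # {"unit_interval": (s, e), "chrom": ..., "copies": [...]}
    decoys: list[dict]  # {"chrom": ..., "interval": (s, e)}
    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            d = asdict(o) if not isinstance(o, dict) else dict(o)
            return d

        payload = {
            "seed": self.seed,
            "chrom_lengths": self.chrom_lengths,
            "planted": [
                {**asdict(p), "isomir_offsets": [[list(k), v] for k, v in p.isomir_offsets.items()]}
                for p in self.planted
            ],
            "repeats": self.repeats,
            "decoys": self.decoys,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        raw = json.loads(text)
        planted = []
        for d in raw["planted"]:
            d = dict(d)
            d["isomir_offsets"] = {tuple(k): v for k, v in d.pop("isomir_offsets")}
            for key in ("precursor_interval", "mature5p_interval", "mature3p_interval", "arm_ratio", "ortholog_arms"):
                if d[key] is not None:
                    d[key] = tuple(d[key])
            planted.append(PlantedMirna(**d))
        return cls(
            planted=planted,
            repeats=[{**r, "unit_interval": tuple(r["unit_interval"]), "copies": [tuple(c) for c in r["copies"]]} for r in raw["repeats"]],
            decoys=[{**d, "interval": tuple(d["interval"])} for d in raw["decoys"]],
            seed=raw["seed"],
            chrom_lengths=dict(raw["chrom_lengths"]),
        )


# ---------------------------------------------------------------------------
# hairpin construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply exactly k point substitutions at distinct positions."""
    if k <= 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(k, len(chars)), replace=False):
        alternatives = [c for c in "ACGT" if c != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _build_hairpin(rng: np.random.Generator, mature_len: int, min_stem_pairs: int = 18,
                   max_tries: int = 30):
    """Construct (precursor_seq, mature5p span, mature3p span in sense coords).

    Retries until the in-package folder confirms a stem of at least
    ``min_stem_pairs`` base pairs.
    """
    for _ in range(max_tries):
        arm = int(rng.integers(50, 66))
        loop_len = int(rng.integers(8, 16))
        arm5 = _random_seq(rng, arm)
        n_mut = int(rng.binomial(arm, 0.1))
        arm3 = _mutate(rng, revcomp(arm5), n_mut)
        prec = arm5 + _random_seq(rng, loop_len) + arm3
        a = int(rng.integers(1, arm - mature_len))
        m5 = (a, a + mature_len)
        L = len(prec)
        m3 = (L - m5[1], L - m5[0])
        structure, _score = fold(prec)
        if len(pairs_from_structure(structure)) >= min_stem_pairs:
            return prec, m5, m3
    raise PlacementError("could not construct a foldable hairpin")


# ---------------------------------------------------------------------------
# genome generation


def _place(rng, occupied, forbidden_centers, length, chrom_len, min_gap, max_tries=2000):
    """Pick a start for an interval of ``length`` avoiding occupied regions.

    ``occupied`` is a list of (start, end); candidate must not come within
    ``min_gap`` of any interval in ``forbidden_centers`` and must not
    overlap anything in ``occupied`` (20 bp margin).
    """
    for _ in range(max_tries):
        start = int(rng.integers(0, max(1, chrom_len - length)))
        end = start + length
        if any(start < e + 20 and end > s - 20 for s, e in occupied):
            continue
        if any(start < e + min_gap and end > s - min_gap for s, e in forbidden_centers):
            continue
        return start
    return None


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    n_mirna: int,
    n_clusters: int,
    n_repeats: int,
    n_decoys: int,
    seed: int,
    cluster_size: int = 3,
    mature_len: int = 22,
    repeat_copies: int = 15,
    mirna_isolation: int = 12_000,
):
    """Generate a random genome with planted miRNA hairpins, repeats and decoys.

    Returns ``(genome, truth)`` where ``genome`` maps chromosome name to
    sequence.  ``n_clusters`` clusters of ``cluster_size`` members each are
    carved out of the ``n_mirna`` budget; members of one cluster are
    pairwise chainable within 10 kb while all other planted elements keep
    at least ``mirna_isolation`` bp of clearance so no accidental cluster
    forms.  Repeat units are copied to ``repeat_copies`` loci (>10, so the
    multi-locus filter fires) and decoy coding sequences are >=200 nt.
    """
    if n_clusters * cluster_size > n_mirna:
        raise ValueError("cluster members exceed the miRNA budget")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_arrays = {c: list(_random_seq(rng, chrom_len)) for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    mirna_regions: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    planted: list[PlantedMirna] = []
    fam_counter = 900

    def _new_plant(chrom, start, prec, m5, m3, cluster_id):
        nonlocal fam_counter
        fam_counter += 1
        strand = "+" if rng.random() < 0.5 else "-"
        L = len(prec)
        seq = prec if strand == "+" else revcomp(prec)
        for i, ch in enumerate(seq):
            chrom_arrays[chrom][start + i] = ch
        if strand == "+":
            g5 = (start + m5[0], start + m5[1])
            g3 = (start + m3[0], start + m3[1])
        else:
            g5 = (start + L - m5[1], start + L - m5[0])
            g3 = (start + L - m3[1], start + L - m3[0])
        cat_idx = int(rng.choice(len(ARM_RATIO_CHOICES), p=np.array(ARM_RATIO_FREQS) / sum(ARM_RATIO_FREQS)))
        ratio = ARM_RATIO_CHOICES[cat_idx]
        n_species = 0 if rng.random() < 0.2 else int(rng.integers(1, len(SPECIES_POOL) - 1))
        w5, w3 = ratio
        ortho = ("major" if w5 else "absent", "major" if w3 else "absent")
        if w5 and w3 and w5 != w3:
            ortho = ("major", "minor") if w5 > w3 else ("minor", "major")
        plant = PlantedMirna(
            chrom=chrom,
            strand=strand,
            precursor_interval=(start, start + L),
            mature5p_interval=g5 if w5 > 0 else None,
            mature3p_interval=g3 if w3 > 0 else None,
            arm_ratio=(float(w5), float(w3)),
            isomir_offsets=dict(DEFAULT_ISOMIR_OFFSETS),
            family=str(fam_counter),
            n_species=n_species,
            cluster=cluster_id,
            ortholog_arms=ortho,
        )
        planted.append(plant)
        occupied[chrom].append((start, start + L))
        mirna_regions[chrom].append((start, start + L))

    # clustered miRNAs: each cluster is one placed block of members with
    # 500-2500 bp end-to-start gaps (well within the 10 kb chaining window)
    for cid in range(n_clusters):
        members = []
        for _ in range(cluster_size):
            members.append(_build_hairpin(rng, mature_len))
        gaps = [int(rng.integers(500, 2500)) for _ in range(cluster_size - 1)]
        block_len = sum(len(m[0]) for m in members) + sum(gaps)
        chrom = chrom_names[int(rng.integers(0, n_chrom))]
        start = _place(rng, occupied[chrom], mirna_regions[chrom], block_len, chrom_len, mirna_isolation)
        if start is None:
            raise PlacementError(f"could not place miRNA cluster {cid}")
        pos = start
        for m_idx, (prec, m5, m3) in enumerate(members):
            _new_plant(chrom, pos, prec, m5, m3, cid)
            pos += len(prec) + (gaps[m_idx] if m_idx < len(gaps) else 0)

    # isolated miRNAs
    for _ in range(n_mirna - n_clusters * cluster_size):
        prec, m5, m3 = _build_hairpin(rng, mature_len)
        chrom = chrom_names[int(rng.integers(0, n_chrom))]
        start = _place(rng, occupied[chrom], mirna_regions[chrom], len(prec), chrom_len, mirna_isolation)
        if start is None:
            raise PlacementError("could not place isolated miRNA")
        _new_plant(chrom, start, prec, m5, m3, None)

    # repeat elements copied to many loci (escaping any masking, as
    # high-frequency elements in draft assemblies do)
    repeats = []
    for r in range(n_repeats):
        unit_len = int(rng.integers(200, 400))
        unit = _random_seq(rng, unit_len)
        copies = []
        unit_interval = None
        unit_chrom = None
        for c in range(repeat_copies):
            chrom = chrom_names[int(rng.integers(0, n_chrom))]
            start = _place(rng, occupied[chrom], [], unit_len, chrom_len, 0)
            if start is None:
                raise PlacementError(f"could not place repeat {r} copy {c}")
            for i, ch in enumerate(unit):
                chrom_arrays[chrom][start + i] = ch
            occupied[chrom].append((start, start + unit_len))
            copies.append((chrom, start, start + unit_len))
            if unit_interval is None:
                unit_interval, unit_chrom = (start, start + unit_len), chrom
        repeats.append({"chrom": unit_chrom, "unit_interval": unit_interval, "copies": copies})

    # protein-coding decoys (>=200 nt random ORF-free sequence is enough
    # for an identity filter that only sees 18-25 nt reads)
    decoys = []
    for d in range(n_decoys):
        dec_len = int(rng.integers(250, 600))
        dec = _random_seq(rng, dec_len)
        chrom = chrom_names[int(rng.integers(0, n_chrom))]
        start = _place(rng, occupied[chrom], [], dec_len, chrom_len, 0)
        if start is None:
            raise PlacementError(f"could not place decoy {d}")
        for i, ch in enumerate(dec):
            chrom_arrays[chrom][start + i] = ch
        occupied[chrom].append((start, start + dec_len))
        decoys.append({"chrom": chrom, "interval": (start, start + dec_len)})

    genome = {c: "".join(arr) for c, arr in chrom_arrays.items()}
    truth = TruthTable(
        planted=planted,
        repeats=repeats,
        decoys=decoys,
        seed=seed,
        chrom_lengths={c: chrom_len for c in chrom_names},
    )
    return genome, truth


def decoy_sequences(genome: dict[str, str], truth: TruthTable) -> list[str]:
    """The planted coding-decoy sequences, as a RefSeq-style decoy set."""
    return [genome[d["chrom"]][d["interval"][0] : d["interval"][1]] for d in truth.decoys]


# ---------------------------------------------------------------------------
# read generation


def _mature_read(genome, plant: PlantedMirna, arm: str, offset: tuple[int, int]) -> str:
    """The isomiR sequence for an arm and a (5' shift, 3' shift) pair.

    Shifts are in sense orientation: the 5' shift moves the sense start,
    the 3' shift moves the sense end (positive = longer at that end is
    ``+1`` on the 3' shift, ``-1`` on the 5' shift).
    """
    s, e = plant.mature_interval(arm)
    d5, d3 = offset
    chrom_seq = genome[plant.chrom]
    if plant.strand == "+":
        seq = chrom_seq[s + d5 : e + d3]
    else:
        seq = revcomp(chrom_seq[s - d3 : e - d5])
    return seq.upper()


def generate_reads(
    genome: dict[str, str],
    truth: TruthTable,
    depth_per_mirna: int = 600,
    noise_reads: int = 200,
    adapter: str = "CGCCTTGGCCGTACAGCAG",
    seed: int = 0,
    read_length: int = 35,
    repeat_read_depth: int = 30,
    decoy_read_depth: int = 30,
) -> list[str]:
    """Emit raw reads: mature-derived stacks, repeat/decoy reads and noise.

    Each mature-derived read is ``(isomiR sequence + adapter)`` truncated
    to the platform read length.  Per-arm totals follow each plant's
    ``arm_ratio`` via binomial sampling; isomiR offsets are multinomial
    over the plant's offset distribution.  Noise reads are random
    sequences verified absent from the genome (either strand).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if depth_per_mirna < 1:
        raise ValueError("depth_per_mirna must be >= 1")
    rng = np.random.default_rng(seed)
    reads: list[str] = []

    def emit(seq: str, count: int):
        read = (seq + adapter)[:read_length]
        reads.extend([read] * count)

    for plant in truth.planted:
        w5, w3 = plant.arm_ratio
        total = depth_per_mirna
        n5 = int(rng.binomial(total, w5 / (w5 + w3))) if (w5 + w3) > 0 else 0
        arm_counts = {"5p": n5, "3p": total - n5}
        offsets = list(plant.isomir_offsets.items())
        probs = np.array([p for _, p in offsets])
        probs = probs / probs.sum()
        for arm, n_arm in arm_counts.items():
            if n_arm == 0 or plant.mature_interval(arm) is None:
                continue
            counts = rng.multinomial(n_arm, probs)
            for (off, _), cnt in zip(offsets, counts):
                if cnt:
                    emit(_mature_read(genome, plant, arm, off), int(cnt))

    for rep in truth.repeats:
        chrom, (s, e) = rep["chrom"], rep["unit_interval"]
        mid = (s + e) // 2
        emit(genome[chrom][mid : mid + 22].upper(), repeat_read_depth)

    for dec in truth.decoys:
        chrom, (s, e) = dec["chrom"], dec["interval"]
        mid = (s + e) // 2
        emit(genome[chrom][mid : mid + 20].upper(), decoy_read_depth)

    emitted = 0
    uppercase = {c: s.upper() for c, s in genome.items()}
    while emitted < noise_reads:
        seq = _random_seq(rng, int(rng.integers(18, 25)))
        rc = revcomp(seq)
        if any(seq in g or rc in g for g in uppercase.values()):
            continue
        cnt = min(int(rng.integers(1, 6)), noise_reads - emitted)
        emit(seq, cnt)
        emitted += cnt
    return reads


def write_fastq(reads: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# catalog generation


def generate_catalog(
    truth: TruthTable,
    genome: dict[str, str],
    species_codes: tuple[str, ...] = SPECIES_POOL,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Build a miRBase-style mature catalog plus a precursor arm table.

    For each planted family with ``n_species >= 1``, one catalog entry per
    species (``<sp>-miR-<family>``) is emitted for every arm whose
    ortholog annotation is not "absent"; each entry's sequence differs
    from the planted mature by at most two substitutions, so homolog
    matching at edit distance <= 2 must succeed.  Returns
    ``(mature_entries, arm_table)`` where ``mature_entries`` is a list of
    (id, sequence) and ``arm_table`` rows carry per-precursor arm status.
    """
    rng = np.random.default_rng(truth.seed + 104729)
    mature_entries: list[tuple[str, str]] = []
    arm_table: list[dict] = []
    for plant in truth.planted:
        if plant.n_species < 1:
            continue
        if plant.n_species > len(species_codes):
            raise ValueError(f"family {plant.family}: n_species exceeds species pool")
        arms_present = [
            arm
            for arm, status in zip(("5p", "3p"), plant.ortholog_arms)
            if status != "absent"
        ]
        for sp in species_codes[: plant.n_species]:
            for arm in arms_present:
                interval = plant.mature_interval(arm)
                if interval is None:
                    # ortholog encodes an arm the planted gene does not
                    # express; derive its sequence from the genome anyway
                    interval = _implied_interval(plant, arm)
                s, e = interval
                seq = genome[plant.chrom][s:e].upper()
                if plant.strand == "-":
                    seq = revcomp(seq)
                seq = _mutate(rng, seq, int(rng.integers(0, 3)))
                suffix = f"-{arm}" if len(arms_present) > 1 else ""
                mature_entries.append((f"{sp}-miR-{plant.family}{suffix}", seq))
            arm_table.append(
                {
                    "precursor_id": f"{sp}-mir-{plant.family}",
                    "arm_5p_status": plant.ortholog_arms[0],
                    "arm_3p_status": plant.ortholog_arms[1],
                }
            )
    return mature_entries, arm_table


def _implied_interval(plant: PlantedMirna, arm: str) -> tuple[int, int]:
    """Mirror the expressed mature interval across the precursor midpoint."""
    other = plant.mature3p_interval if arm == "5p" else plant.mature5p_interval
    ps, pe = plant.precursor_interval
    s, e = other
    return (ps + (pe - e), pe - (s - ps))


def write_catalog_fasta(entries: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
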