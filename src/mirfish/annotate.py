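"""Homolog/novel annotation against a known-miRNA catalog.

A discovered pre-miRNA is a homolog (Mh) when any of its isomiRs lies
within two nucleotide variations — edit distance, so length variants
count — of a catalog mature miRNA; otherwise it is novel (Mn).  Catalog
identifiers follow the miRBase dialect ``<species>-miR-<name>`` from
which the family name and the per-family conservation level (number of
species encoding the family) are derived.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import edlib
from Bio import SeqIO

from mirfish.classify import PreMirna
from mirfish.seqs import normalize

_ID_RE = re.compile(r"^(?P<species>[a-z]{3,4})-(?P<tag>mir|miR|let)-(?P<rest>.+)$")


@dataclass(frozen=True)
class CatalogEntry:
    id: str
    species: str
    family: str
    sequence: str


@dataclass
class FamilyRecord:
    family: str
    conservation_level: int  # number of catalog species encoding the family
    expression_level: int  # copy number of the family's most abundant isomiR


@dataclass
class Annotation:
    premirna_id: str
    set_label: str  # "Mh" or "Mn"
    ortholog_id: str | None
    family: str | None
    conservation_level: int


def family_of(catalog_id: str) -> str:
    """Family name of a miRBase-style identifier.

    The species prefix, star marker, arm suffixes (-5p/-3p) and trailing
    numeric locus suffixes (-1, -2) are stripped; lettered paralog
    suffixes are part of the family (let-7b != let-7a).
    """
    m = _ID_RE.match(catalog_id)
    if not m:
        raise ValueError(f"unrecognized catalog identifier: {catalog_id!r}")
    tag = "mir" if m.group("tag") in ("mir", "miR") else "let"
    rest = m.group("rest").rstrip("*")
    rest = re.sub(r"-[35]p$", "", rest, flags=re.IGNORECASE)
    rest = re.sub(r"(-\d+)+$", "", rest)
    return f"{tag}-{rest}"


def load_catalog(source) -> list[CatalogEntry]:
    """Load a mature-miRNA catalog from FASTA (path) or (id, seq) pairs."""
    if isinstance(source, (str, Path)):
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
    else:
        pairs = list(source)
    entries = []
    for cid, seq in pairs:
        m = _ID_RE.match(cid)
        if not m:
            raise ValueError(f"unrecognized catalog identifier: {cid!r}")
        entries.append(CatalogEntry(id=cid, species=m.group("species"), family=family_of(cid), sequence=normalize(seq)))
    return entries


def match_known(mature_seq: str, catalog: list[CatalogEntry], max_variations: int = 2) -> CatalogEntry | None:
    """Best catalog hit within ``max_variations`` edit distance, or None.

    Distance counts substitutions and indels.  Ties break by lower
    distance, then lexicographic catalog id.
    """
    query = normalize(mature_seq)
    best: tuple[int, str, CatalogEntry] | None = None
    for entry in catalog:
        d = edlib.align(query, entry.sequence, mode="NW", task="distance", k=max_variations)["editDistance"]
        if d < 0:  # beyond k
            continue
        key = (d, entry.id)
        if best is None or key < (best[0], best[1]):
            best = (d, entry.id, entry)
    return best[2] if best else None


def conservation_level(family: str, catalog: list[CatalogEntry]) -> int:
    """Number of distinct species with at least one catalog entry of a family."""
    return len({e.species for e in catalog if e.family == family})


def annotate(premirnas: list[PreMirna], catalog: list[CatalogEntry], max_variations: int = 2) -> list[Annotation]:
    """Partition pre-miRNAs into Mh/Mn and assign Mh ids, families, conservation.

    Ids are assigned per set in genomic order (Mh1..MhN, Mn1..MnM) and
    written back onto each PreMirna.
    """
    annotations = []
    mh_counter = mn_counter = 0
    for pre in premirnas:
        hit: CatalogEntry | None = None
        best_key: tuple[int, str] | None = None
        for iso in pre.isomirs_5p + pre.isomirs_3p + pre.isomirs_loop:
            h = match_known(iso.sequence, catalog, max_variations=max_variations)
            if h is None:
                continue
            d = edlib.align(normalize(iso.sequence), h.sequence, mode="NW", task="distance")["editDistance"]
            if best_key is None or (d, h.id) < best_key:
                best_key, hit = (d, h.id), h
        if hit is not None:
            mh_counter += 1
            pre.id = f"Mh{mh_counter}"
            fam = hit.family
            annotations.append(
                Annotation(pre.id, "Mh", hit.id, fam, conservation_level(fam, catalog))
            )
        else:
            mn_counter += 1
            pre.id = f"Mn{mn_counter}"
            annotations.append(Annotation(pre.id, "Mn", None, None, 0))
    return annotations


def build_family_records(premirnas: list[PreMirna], annotations: list[Annotation]) -> list[FamilyRecord]:
    """Per-family conservation and expression (max isomiR copy) for the Mh set."""
    by_family: dict[str, FamilyRecord] = {}
    for pre, ann in zip(premirnas, annotations):
        if ann.set_label != "Mh":
            continue
        top = max(
            (i.copy_number for i in pre.isomirs_5p + pre.isomirs_3p + pre.isomirs_loop),
            default=0,
        )
        rec = by_family.get(ann.family)
        if rec is None:
            by_family[ann.family] = FamilyRecord(ann.family, ann.conservation_level, top)
        else:
            rec.expression_level = max(rec.expression_level, top)
    return sorted(by_family.values(), key=lambda r: r.family)
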