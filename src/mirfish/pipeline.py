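"""End-to-end pipeline orchestration, summary statistics and reporting.

Stages run in a fixed order: collapse -> copy-number filter -> adapter
trim -> length filter -> exact mapping -> exclusion filters (decoy
identity, multi-locus) -> precursor extraction -> folding -> features ->
SVM classification -> pre-miRNA assembly -> catalog annotation ->
characterization.  Every stage logs its in/out counts; the summary
mirrors the bookkeeping of a discovery run (mappable reads / unique
reads / loci, per-set pre-miRNA, isomiR and read counts, and the derived
percentages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from mirfish import annotate as ann
from mirfish import characterize as char
from mirfish import classify as cls
from mirfish import hairpin as hp
from mirfish import mapping as mp
from mirfish import reads as rd
from mirfish import simulate as sim
from mirfish.mapping import Genome, GenomicLocus

log = logging.getLogger("mirfish")


@dataclass
class PipelineConfig:
    """Every pipeline threshold, with the method's defaults."""

    min_copies: int = 3
    adapter: str = "CGCCTTGGCCGTACAGCAG"
    min_adapter_overlap: int = 6
    min_len: int = 18
    max_len: int = 25
    index_k: int = 18
    max_loci: int = 10
    refseq_min_identity: float = 0.90
    flank: int = 60
    alpha: float = 0.05
    max_variations: int = 2
    cluster_window: int = 10_000
    dominance_ratio: float = 2.0
    svm_C: float = 10.0
    svm_gamma: str | float = "scale"
    n_training_negatives: int = 300
    seed: int = 0


@dataclass
class PipelineSummary:
    n_mappable_reads: int = 0
    n_mappable_unique_reads: int = 0
    n_mappable_loci: int = 0
    n_premirna: dict = field(default_factory=lambda: {"Mh": 0, "Mn": 0})
    n_isomir: dict = field(default_factory=lambda: {"Mh": 0, "Mn": 0})
    n_reads: dict = field(default_factory=lambda: {"Mh": 0, "Mn": 0})
    pct_mirna_reads: float = 0.0
    pct_premirna_with_isomirs: float = 0.0
    pct_clustered_premirna: float = 0.0
    n_clusters: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round-half-up (so 0.25 -> 0.3 at one decimal), as tables print it."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator/denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def summary_percentages(
    reads_mh: int,
    reads_mn: int,
    n_mappable_reads: int,
    n_premirna_with_isomirs: int,
    n_premirna: int,
    n_clustered_premirna: int,
) -> dict[str, float]:
    """The three headline percentages of a discovery run."""
    return {
        "pct_mirna_reads": percentage(reads_mh + reads_mn, n_mappable_reads),
        "pct_premirna_with_isomirs": percentage(n_premirna_with_isomirs, n_premirna),
        "pct_clustered_premirna": percentage(n_clustered_premirna, n_premirna),
    }


# ---------------------------------------------------------------------------
# training data


def build_training_set(
    genome: Genome,
    truth: sim.TruthTable,
    n_negatives: int = 300,
    jitter: int = 2,
    flank: int = 60,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrices for SVM training from planted ground truth.

    Positives: windows around every planted mature (both arms where
    present), augmented with small positional jitters so each planted
    gene yields several examples.  Negatives: random genomic windows of
    mature length kept clear of planted precursors.
    """
    rng = np.random.default_rng(seed)
    n_arms = sum(
        1 for p in truth.planted for arm in ("5p", "3p") if p.mature_interval(arm) is not None
    )
    if n_arms == 0:
        raise ValueError("truth table plants no mature arms to train on")
    # widen the jitter range when few genes are planted, so at least ~60
    # genuinely positive windows exist (shifted matures stay inside the stem)
    jitter = max(jitter, min(10, (60 // n_arms) // 2 + 1))
    pos_rows = []
    for plant in truth.planted:
        for arm in ("5p", "3p"):
            iv = plant.mature_interval(arm)
            if iv is None:
                continue
            for shift in range(-jitter, jitter + 1):
                locus = GenomicLocus(plant.chrom, iv[0] + shift, iv[1] + shift, plant.strand, "train")
                cand = hp.extract_precursor(genome.seqs, locus, flank=flank)
                hp.fold_candidate(cand)
                pos_rows.append(hp.compute_features(cand))
    forbidden = {}
    for plant in truth.planted:
        forbidden.setdefault(plant.chrom, []).append(plant.precursor_interval)
    chroms = sorted(genome.seqs)
    neg_rows = []
    attempts = 0
    while len(neg_rows) < n_negatives and attempts < n_negatives * 50:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = len(genome.seqs[chrom])
        mlen = int(rng.integers(18, 26))
        start = int(rng.integers(flank, L - flank - mlen))
        if any(start < e + 200 and start + mlen > s - 200 for s, e in forbidden.get(chrom, [])):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        locus = GenomicLocus(chrom, start, start + mlen, strand, "train")
        cand = hp.extract_precursor(genome.seqs, locus, flank=flank)
        hp.fold_candidate(cand)
        neg_rows.append(hp.compute_features(cand))
    if len(neg_rows) < n_negatives:
        raise RuntimeError("could not sample enough negative training windows")
    return np.array(pos_rows), np.array(neg_rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    summary: PipelineSummary
    premirnas: list[cls.PreMirna]
    annotations: list[ann.Annotation]
    clusters: list[char.MirnaCluster]
    family_records: list[ann.FamilyRecord]
    unique_reads: list[rd.UniqueRead]
    read_to_loci: dict[str, list[GenomicLocus]]
    positives: list[cls.ClassifiedCandidate]
    model: cls.SvmModel | None


def run_pipeline(
    raw_reads: list[str],
    genome: Genome,
    decoys: list[str],
    catalog: list[ann.CatalogEntry],
    model: cls.SvmModel | None = None,
    truth: sim.TruthTable | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on in-memory inputs.

    When no trained model is given, one is trained from the synthetic
    truth table (planted hairpin windows as positives, random genomic
    windows as negatives); exactly one of ``model`` / ``truth`` must be
    provided.
    """
    cfg = config or PipelineConfig()
    if model is None:
        if truth is None:
            raise ValueError("either a trained model or a truth table is required")
        pos, neg = build_training_set(
            genome, truth, n_negatives=cfg.n_training_negatives, flank=cfg.flank, seed=cfg.seed
        )
        model = cls.train(pos, neg, C=cfg.svm_C, gamma=cfg.svm_gamma, seed=cfg.seed)
        log.info("trained SVM: held-out accuracy %.3f", model.heldout_accuracy)

    unique = rd.collapse(raw_reads)
    log.info("collapse: %d raw -> %d unique", len(raw_reads), len(unique))
    unique = rd.filter_copy_number(unique, cfg.min_copies)
    log.info("copy filter (>=%d): %d unique", cfg.min_copies, len(unique))
    unique = rd.trim_adapter(unique, cfg.adapter, cfg.min_adapter_overlap)
    log.info("adapter trim: %d unique", len(unique))
    unique = rd.filter_length(unique, cfg.min_len, cfg.max_len)
    log.info("length filter [%d, %d]: %d unique", cfg.min_len, cfg.max_len, len(unique))
    n_ambiguous = sum(1 for u in unique if not set(u.sequence) <= set("ACGT"))
    if n_ambiguous:
        log.info("dropping %d unique reads with ambiguous bases", n_ambiguous)
        unique = [u for u in unique if set(u.sequence) <= set("ACGT")]

    index = mp.build_index(genome, k=cfg.index_k)
    read_to_loci = mp.map_all(index, unique)
    mapped = [u for u in unique if u.read_id in read_to_loci]
    log.info("perfect-match mapping: %d of %d unique reads mappable", len(mapped), len(unique))
    mapped = mp.filter_refseq(mapped, decoys, cfg.refseq_min_identity)
    log.info("decoy identity filter (> %.0f%%): %d unique", cfg.refseq_min_identity * 100, len(mapped))
    kept_ids = {u.read_id for u in mapped}
    read_to_loci = {rid: loci for rid, loci in read_to_loci.items() if rid in kept_ids}
    read_to_loci = mp.filter_multimappers(read_to_loci, cfg.max_loci)
    mapped_ids = set(read_to_loci)
    unique = [u for u in mapped if u.read_id in mapped_ids]
    copies = {u.read_id: u.copy_number for u in unique}
    n_loci = sum(len(l) for l in read_to_loci.values())
    log.info("mapping: %d mappable unique reads, %d loci", len(unique), n_loci)

    summary = PipelineSummary(
        n_mappable_reads=sum(copies.values()),
        n_mappable_unique_reads=len(unique),
        n_mappable_loci=n_loci,
    )

    classified: list[cls.ClassifiedCandidate] = []
    for u in unique:
        for locus in read_to_loci[u.read_id]:
            cand = hp.extract_precursor(genome.seqs, locus, flank=cfg.flank)
            hp.fold_candidate(cand)
            cand.features = hp.compute_features(cand)
            classified.append(cls.classify(model, cand, u.copy_number, alpha=cfg.alpha))
    positives = [c for c in classified if c.positive]
    log.info("classification: %d candidates, %d positive", len(classified), len(positives))

    premirnas = cls.assemble(positives, genome_seqs=genome.seqs)
    annotations = ann.annotate(premirnas, catalog, max_variations=cfg.max_variations)
    clusters = char.detect_clusters(premirnas, window=cfg.cluster_window)
    families = ann.build_family_records(premirnas, annotations)
    log.info("assembly: %d pre-miRNAs, %d clusters, %d Mh families",
             len(premirnas), len(clusters), len(families))

    reads_in: dict[str, set[str]] = {"Mh": set(), "Mn": set()}
    for pre, a in zip(premirnas, annotations):
        s = a.set_label
        summary.n_premirna[s] += 1
        summary.n_isomir[s] += pre.n_isomirs
        for iso in pre.isomirs_5p + pre.isomirs_3p + pre.isomirs_loop:
            reads_in[s].add(iso.read_id)
    # a multi-locus read hitting both sets is attributed to Mh only,
    # so the per-set read counts stay disjoint and sum to <= mappable
    reads_in["Mn"] -= reads_in["Mh"]
    for s in ("Mh", "Mn"):
        summary.n_reads[s] = sum(copies[rid] for rid in reads_in[s])
    n_pre = len(premirnas)
    if summary.n_mappable_reads > 0 and n_pre > 0:
        clustered_ids = {m.id for c in clusters for m in c.members}
        pct = summary_percentages(
            summary.n_reads["Mh"],
            summary.n_reads["Mn"],
            summary.n_mappable_reads,
            sum(1 for p in premirnas if p.n_isomirs >= 2),
            n_pre,
            len(clustered_ids),
        )
        summary.pct_mirna_reads = pct["pct_mirna_reads"]
        summary.pct_premirna_with_isomirs = pct["pct_premirna_with_isomirs"]
        summary.pct_clustered_premirna = pct["pct_clustered_premirna"]
    summary.n_clusters = len(clusters)

    return PipelineResult(
        summary=summary,
        premirnas=premirnas,
        annotations=annotations,
        clusters=clusters,
        family_records=families,
        unique_reads=unique,
        read_to_loci=read_to_loci,
        positives=positives,
        model=model,
    )


def run_synthetic(
    n_mirna: int = 20,
    n_clusters: int = 1,
    cluster_size: int = 3,
    n_chrom: int = 2,
    chrom_len: int = 300_000,
    n_repeats: int = 1,
    n_decoys: int = 2,
    depth_per_mirna: int = 600,
    noise_reads: int = 200,
    seed: int = 0,
    config: PipelineConfig | None = None,
):
    """Generate a synthetic dataset and run the pipeline on it.

    Returns ``(result, genome, truth)``.  Defaults describe the standard
    desk-scale study conditions: 20 planted miRNAs (one 3-member
    cluster), 600 reads per gene, one multi-locus repeat family and two
    coding decoys.
    """
    cfg = config or PipelineConfig(seed=seed)
    raw_genome, truth = sim.generate_genome(
        n_chrom, chrom_len, n_mirna, n_clusters, n_repeats, n_decoys,
        seed=seed, cluster_size=cluster_size,
    )
    reads = sim.generate_reads(
        raw_genome, truth, depth_per_mirna=depth_per_mirna,
        noise_reads=noise_reads, adapter=cfg.adapter, seed=seed + 1,
    )
    genome = Genome.from_dict(raw_genome)
    decoys = sim.decoy_sequences(raw_genome, truth)
    catalog = ann.load_catalog(sim.generate_catalog(truth, raw_genome)[0])
    result = run_pipeline(reads, genome, decoys, catalog, truth=truth, config=cfg)
    return result, raw_genome, truth


# ---------------------------------------------------------------------------
# evaluation against planted truth


def evaluate_against_truth(premirnas: list[cls.PreMirna], truth: sim.TruthTable) -> dict:
    """Recall/precision of assembled pre-miRNAs against planted hairpins.

    Matching is by interval overlap on the same chromosome, ignoring
    strand: a hairpin is nearly its own reverse complement, so a planted
    gene whose mirrored arm window is mutation-free is also detected as
    an overlapping opposite-strand hairpin — a duplicate call of a real
    gene, not a spurious discovery.  For the recall numerator the
    matched pre-miRNA on the planted strand is preferred when both
    exist.
    """
    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    recovered = 0
    matches: dict[int, cls.PreMirna] = {}
    for idx, plant in enumerate(truth.planted):
        hits = [
            pre
            for pre in premirnas
            if pre.chrom == plant.chrom and overlaps(pre.precursor_interval, plant.precursor_interval)
        ]
        if hits:
            recovered += 1
            same_strand = [p for p in hits if p.strand == plant.strand]
            matches[idx] = (same_strand or hits)[0]
    true_pos = sum(
        1
        for pre in premirnas
        if any(
            pre.chrom == p.chrom and overlaps(pre.precursor_interval, p.precursor_interval)
            for p in truth.planted
        )
    )
    n_planted = len(truth.planted)
    n_pred = len(premirnas)
    return {
        "recall": recovered / n_planted if n_planted else 0.0,
        "precision": true_pos / n_pred if n_pred else 0.0,
        "n_planted": n_planted,
        "n_predicted": n_pred,
        "matches": matches,
    }


def expected_arm_category(plant: sim.PlantedMirna, dominance_ratio: float = 2.0) -> str:
    """Arm category implied by a plant's 5p:3p weights."""
    w5, w3 = plant.arm_ratio
    if w3 == 0:
        return "5P_only"
    if w5 == 0:
        return "3P_only"
    ratio = max(w5, w3) / min(w5, w3)
    if ratio >= dominance_ratio:
        return "5P_dominant" if w5 > w3 else "3P_dominant"
    return "equal"
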