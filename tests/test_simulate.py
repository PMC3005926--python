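"""Ground-truth properties of the synthetic genome/read/catalog generator."""

import numpy as np
import pytest

from mirfish import simulate as sim
from mirfish.hairpin import fold, pairs_from_structure
from mirfish.seqs import revcomp


def naive_scan(genome: dict[str, str], query: str) -> list[tuple[str, int, str]]:
    """Brute-force all perfect-match loci of query on both strands."""
    hits = []
    rc = revcomp(query)
    for chrom, seq in genome.items():
        seq = seq.upper()
        for probe, strand in ((query, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append((chrom, start, strand))
                start = seq.find(probe, start + 1)
    return hits


def test_generation_is_deterministic():
    a = sim.generate_genome(1, 50_000, 3, 0, 0, 0, seed=7)
    b = sim.generate_genome(1, 50_000, 3, 0, 0, 0, seed=7)
    assert a[0] == b[0]
    assert a[1].to_json() == b[1].to_json()
    reads_a = sim.generate_reads(a[0], a[1], 50, 20, "CGCCTT", seed=7)
    reads_b = sim.generate_reads(b[0], b[1], 50, 20, "CGCCTT", seed=7)
    assert reads_a == reads_b


def test_planted_matures_found_at_truth_intervals_by_naive_scan():
    genome, truth = sim.generate_genome(1, 50_000, 3, 0, 0, 0, seed=7)
    for plant in truth.planted:
        for arm in ("5p", "3p"):
            iv = plant.mature_interval(arm)
            if iv is None:
                continue
            sense = genome[plant.chrom][iv[0] : iv[1]]
            if plant.strand == "-":
                sense = revcomp(sense)
            hits = naive_scan(genome, sense)
            assert (plant.chrom, iv[0], plant.strand) in hits


def test_precursor_invariants():
    genome, truth = sim.generate_genome(2, 100_000, 10, 0, 0, 0, seed=3)
    for plant in truth.planted:
        s, e = plant.precursor_interval
        assert 100 <= e - s <= 160
        for arm in ("5p", "3p"):
            iv = plant.mature_interval(arm)
            if iv is None:
                continue
            assert 18 <= iv[1] - iv[0] <= 25
            assert s <= iv[0] and iv[1] <= e
        prec = genome[plant.chrom][s:e]
        if plant.strand == "-":
            prec = revcomp(prec)
        structure, _ = fold(prec)
        assert len(pairs_from_structure(structure)) >= 18


def test_clustered_plants_chainable_within_10kb():
    _, truth = sim.generate_genome(1, 100_000, 6, 1, 0, 0, seed=1, cluster_size=6)
    assert len(truth.planted) == 6
    assert all(p.cluster == 0 for p in truth.planted)
    intervals = sorted(p.precursor_interval for p in truth.planted)
    gaps = [intervals[i + 1][0] - intervals[i][1] for i in range(5)]
    assert all(g <= 10_000 for g in gaps)


def test_repeat_kmer_maps_to_all_copies_by_naive_scan():
    genome, truth = sim.generate_genome(1, 50_000, 0, 0, 1, 0, seed=2, repeat_copies=15)
    rep = truth.repeats[0]
    s, e = rep["unit_interval"]
    mid = (s + e) // 2
    kmer = genome[rep["chrom"]][mid : mid + 22]
    assert len(naive_scan(genome, kmer)) >= 15
    assert len(rep["copies"]) == 15


def test_arm_ratio_respected_at_depth():
    genome, truth = sim.generate_genome(1, 60_000, 1, 0, 0, 0, seed=9)
    plant = truth.planted[0]
    assert plant.mature5p_interval and plant.mature3p_interval  # seed 9 plants both arms
    plant.arm_ratio = (3.0, 1.0)
    depth = 4000
    reads = sim.generate_reads(genome, truth, depth_per_mirna=depth, noise_reads=0,
                               adapter="CGCCTTGG", seed=5)
    m5 = plant.mature5p_interval
    core5 = genome[plant.chrom][m5[0] + 3 : m5[1] - 3]
    if plant.strand == "-":
        core5 = revcomp(core5)
    n5 = sum(1 for r in reads if core5 in r)
    p_hat = n5 / depth
    sigma = np.sqrt(0.75 * 0.25 / depth)
    assert abs(p_hat - 0.75) <= 3 * sigma


def test_degenerate_arm_ratio_yields_single_arm_reads():
    genome, truth = sim.generate_genome(1, 60_000, 1, 0, 0, 0, seed=11)
    plant = truth.planted[0]
    plant.arm_ratio = (1.0, 0.0)
    assert plant.mature5p_interval is not None  # seed 11 plants a 5p mature
    reads = sim.generate_reads(genome, truth, depth_per_mirna=100, noise_reads=0,
                               adapter="CGCCTTGG", seed=1)
    assert len(reads) == 100
    m5 = plant.mature5p_interval
    core = genome[plant.chrom][m5[0] + 2 : m5[1] - 2]
    if plant.strand == "-":
        core = revcomp(core)
    assert all(core in r for r in reads)


def test_isomir_structure_matches_offset_distribution():
    """Six configured isomiR offsets at depth 600 give six unique sequences,
    with end-variation concentrated at the 3' end."""
    genome, truth = sim.generate_genome(1, 60_000, 1, 0, 0, 0, seed=13)
    plant = truth.planted[0]
    plant.arm_ratio = (1.0, 0.0)
    assert plant.mature5p_interval is not None  # seed 13 plants a 5p mature
    plant.isomir_offsets = {
        (0, 0): 0.5, (0, -1): 0.15, (0, 1): 0.12,
        (0, -2): 0.1, (0, 2): 0.08, (-1, 0): 0.05,
    }
    reads = sim.generate_reads(genome, truth, depth_per_mirna=600, noise_reads=0,
                               adapter="CGCCTTGGCCGTACAGCAG", seed=2)
    from mirfish.reads import collapse, trim_adapter
    unique = trim_adapter(collapse(reads), "CGCCTTGGCCGTACAGCAG")
    assert len(unique) == 6
    assert sum(u.copy_number for u in unique) == 600
    starts = {u.sequence[:3] for u in unique}
    assert len(starts) == 2  # one 5'-shifted variant, five sharing the 5' end


def test_noise_reads_absent_from_genome():
    genome, truth = sim.generate_genome(1, 40_000, 0, 0, 0, 0, seed=4)
    reads = sim.generate_reads(genome, truth, depth_per_mirna=1, noise_reads=30,
                               adapter="CGCCTTGGCCGTACAGCAG", seed=4)
    assert len(reads) == 30
    for r in reads:
        insert = r[:18]  # leading part before any adapter is genuine noise
        assert not naive_scan(genome, insert)


def test_truth_table_roundtrip_lossless():
    _, truth = sim.generate_genome(2, 60_000, 5, 1, 1, 1, seed=6, cluster_size=2)
    again = sim.TruthTable.from_json(truth.to_json())
    assert again.to_json() == truth.to_json()
    assert again.planted[0].isomir_offsets == truth.planted[0].isomir_offsets


def test_catalog_entries_follow_n_species():
    genome, truth = sim.generate_genome(1, 200_000, 8, 0, 0, 0, seed=8)
    entries, arm_table = sim.generate_catalog(truth, genome)
    names = [e[0] for e in entries]
    for plant in truth.planted:
        matching = [n for n in names if f"-miR-{plant.family}" in n]
        arms_present = sum(1 for s in plant.ortholog_arms if s != "absent")
        assert len(matching) == plant.n_species * arms_present
        if plant.n_species == 0:
            assert not matching


def test_catalog_matures_within_two_substitutions():
    genome, truth = sim.generate_genome(1, 200_000, 6, 0, 0, 0, seed=10)
    entries, _ = sim.generate_catalog(truth, genome)
    by_family = {}
    for name, seq in entries:
        fam = name.split("-miR-")[1].split("-")[0]
        by_family.setdefault(fam, []).append(seq)
    for plant in truth.planted:
        if plant.n_species == 0 or plant.family not in by_family:
            continue
        planted_seqs = []
        for arm in ("5p", "3p"):
            iv = plant.mature_interval(arm)
            if iv is None:
                continue
            s = genome[plant.chrom][iv[0] : iv[1]]
            planted_seqs.append(revcomp(s) if plant.strand == "-" else s)
        for cat_seq in by_family[plant.family]:
            dists = [
                sum(a != b for a, b in zip(cat_seq, ps))
                for ps in planted_seqs
                if len(ps) == len(cat_seq)
            ]
            if dists:
                assert min(dists) <= 2


def test_placement_failure_raises_named_error():
    with pytest.raises(sim.PlacementError):
        sim.generate_genome(1, 2_000, 10, 0, 0, 0, seed=1)
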