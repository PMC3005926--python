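"""Clusters, arm-selection profiles, difference classes, quartile analysis."""

import numpy as np
import pytest

from mirfish.annotate import FamilyRecord
from mirfish.characterize import (
    ArmProfile,
    arm_profile,
    classify_difference,
    conservation_expression,
    detect_clusters,
)
from mirfish.classify import IsomiR, PreMirna


def _pre(chrom, start, end, strand="+", c5=0, c3=0, ident=""):
    pre = PreMirna(chrom=chrom, strand=strand, precursor_interval=(start, end), id=ident or f"p{start}")
    if c5:
        pre.isomirs_5p.append(IsomiR("A" * 22, c5, 0.01))
    if c3:
        pre.isomirs_3p.append(IsomiR("C" * 22, c3, 0.01))
    return pre


# ---------------------------------------------------------------------------
# clusters


def test_six_members_spaced_one_kb_form_one_cluster():
    pres = [_pre("chr1", i * 1140, i * 1140 + 140) for i in range(6)]
    clusters = detect_clusters(pres)
    assert len(clusters) == 1 and clusters[0].size == 6


def test_cluster_gap_boundary_inclusive_at_10kb():
    near = [_pre("c", 0, 140), _pre("c", 10_140, 10_280)]  # gap exactly 10,000
    far = [_pre("c", 0, 140), _pre("c", 10_141, 10_281)]  # gap 10,001
    assert len(detect_clusters(near)) == 1
    assert detect_clusters(far) == []


def test_singletons_discarded_and_strand_agnostic():
    pres = [_pre("c", 0, 140, "+"), _pre("c", 5_000, 5_140, "-"), _pre("c", 80_000, 80_140)]
    clusters = detect_clusters(pres)
    assert len(clusters) == 1
    assert clusters[0].size == 2
    assert {m.strand for m in clusters[0].members} == {"+", "-"}


def test_cluster_chaining_matches_all_pairs_oracle(rng):
    def oracle(pres, window=10_000):
        """Connected components of the interval-gap graph, O(n^2)."""
        n = len(pres)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = pres[i], pres[j]
                if a.chrom != b.chrom:
                    continue
                gap = max(a.precursor_interval[0], b.precursor_interval[0]) - min(
                    a.precursor_interval[1], b.precursor_interval[1]
                )
                if gap <= window:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), set()).add(pres[i].id)
        return {frozenset(c) for c in comps.values() if len(c) > 1}

    for trial in range(10):
        pres = [
            _pre(f"chr{int(rng.integers(1, 3))}", s, s + 140, ident=f"t{trial}_{k}")
            for k, s in enumerate(sorted(rng.integers(0, 150_000, size=12)))
        ]
        got = {frozenset(m.id for m in c.members) for c in detect_clusters(pres)}
        assert got == oracle(pres)


def test_detect_clusters_order_invariant(rng):
    pres = [_pre("c", s, s + 140, ident=f"x{k}") for k, s in enumerate([0, 3000, 30_000, 31_000, 90_000])]
    base = [frozenset(m.id for m in c.members) for c in detect_clusters(pres)]
    for _ in range(5):
        perm = [pres[i] for i in rng.permutation(len(pres))]
        assert [frozenset(m.id for m in c.members) for c in detect_clusters(perm)] == base


def test_cluster_member_bookkeeping(pipeline_run):
    result, _, _ = pipeline_run
    clustered = {m.id for c in result.clusters for m in c.members}
    assert sum(c.size for c in result.clusters) == len(clustered)
    assert all(c.size >= 2 for c in result.clusters)


# ---------------------------------------------------------------------------
# arm profiles and difference classes


@pytest.mark.parametrize(
    ("c5", "c3", "category"),
    [
        (100, 0, "5P_only"),
        (0, 77, "3P_only"),
        (300, 100, "5P_dominant"),
        (100, 300, "3P_dominant"),
        (120, 100, "equal"),
        (100, 199, "equal"),
        (100, 200, "3P_dominant"),  # ratio exactly 2.0 is dominant
    ],
)
def test_arm_profile_categories(c5, c3, category):
    assert arm_profile(_pre("c", 0, 140, c5=c5, c3=c3)).category == category


def test_arm_categories_partition_pipeline_premirnas(pipeline_run):
    result, _, _ = pipeline_run
    cats = [arm_profile(p).category for p in result.premirnas]
    valid = {"5P_only", "3P_only", "5P_dominant", "3P_dominant", "equal"}
    assert set(cats) <= valid
    assert len(cats) == len(result.premirnas)


@pytest.mark.parametrize(
    ("c5", "c3", "ortho", "klass"),
    [
        (50, 30, ("major", "absent"), "1"),  # both arms vs single-arm ortholog
        (0, 80, ("major", "minor"), "2"),  # single arm vs both-arm ortholog
        (80, 0, ("absent", "major"), "3"),  # opposite arms
        (0, 80, ("absent", "major"), "concordant"),
        (50, 30, ("major", "minor"), "concordant"),
    ],
)
def test_difference_classes(c5, c3, ortho, klass):
    prof = arm_profile(_pre("c", 0, 140, c5=c5, c3=c3))
    assert classify_difference(prof, ortho).klass == klass


def test_difference_class_symmetric_under_arm_swap(rng):
    statuses = ["major", "minor", "absent"]
    for _ in range(50):
        c5, c3 = int(rng.integers(0, 3)) * 40, int(rng.integers(0, 3)) * 40
        ortho = (statuses[int(rng.integers(0, 3))], statuses[int(rng.integers(0, 3))])
        a = classify_difference(ArmProfile("x", c5, c3), ortho)
        b = classify_difference(ArmProfile("x", c3, c5), (ortho[1], ortho[0]))
        assert a.klass == b.klass


# ---------------------------------------------------------------------------
# conservation vs expression


def _families(rng, n, mean_log, sd=0.5, cons=1, tag=""):
    vals = 10 ** rng.normal(mean_log, sd, size=n)
    return [
        FamilyRecord(f"mir-{tag}{i}", cons, max(3, int(v)))
        for i, v in enumerate(vals)
    ]


def test_quartile_split_sizes_remainder_to_earlier():
    fams = [FamilyRecord(f"mir-{i:03d}", i, 10 + i) for i in range(10)]
    report = conservation_expression(fams)
    assert [q["n"] for q in report.quartiles] == [3, 3, 2, 2]


def test_quartile_medians_monotone_under_planted_gradient(rng):
    fams = []
    for level, mean in ((1, 1.0), (3, 2.0), (5, 3.0), (8, 4.0)):
        fams += _families(rng, 12, mean, cons=level, tag=f"c{level}_")
    report = conservation_expression(fams)
    medians = [q["median"] for q in report.quartiles]
    assert medians == sorted(medians)
    assert all(t["p"] < 0.05 for t in report.tests)


def test_null_type_one_error_near_nominal(rng):
    rejections = 0
    n_trials = 60
    for _ in range(n_trials):
        fams = _families(rng, 40, 2.0, cons=1)
        for i, f in enumerate(fams):  # spread conservation, same expression law
            f.conservation_level = 1 + i % 8
            f.family = f"mir-{i}"
        p = conservation_expression(fams).tests[0]["p"]
        rejections += p < 0.05
    assert rejections / n_trials <= 0.15


def test_power_to_detect_two_log_unit_shift(rng):
    detected = 0
    for _ in range(50):
        low = _families(rng, 25, 1.0, cons=1, tag="lo")
        high = _families(rng, 25, 3.0, cons=9, tag="hi")
        report = conservation_expression(low + high)
        detected += report.tests[1]["p"] < 0.05  # the Q2|Q3 boundary splits the groups
    assert detected >= 49


def test_too_few_families_rejected():
    with pytest.raises(ValueError):
        conservation_expression([FamilyRecord("mir-1", 1, 10)] * 7)
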