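"""Downstream characterization of discovered pre-miRNAs.

Three analyses: genomic cluster detection (precursors within 10,000 bp
chained into clusters), arm-selection profiling (5P only / 3P only / 5P
dominant / 3P dominant / equal abundance, plus the three cross-species
difference classes against ortholog arm annotations), and the
conservation-versus-expression quartile analysis (families split into
four quarters by ascending conservation level; Welch t-tests on
log10 expression between adjacent quarters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mirfish.annotate import FamilyRecord
from mirfish.classify import PreMirna

ARM_CATEGORIES = ("5P_only", "3P_only", "5P_dominant", "3P_dominant", "equal")


@dataclass
class MirnaCluster:
    members: list[PreMirna]
    chrom: str
    span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ArmProfile:
    category: str
    copies_5p: int
    copies_3p: int


@dataclass
class DifferenceClass:
    klass: str  # "1", "2", "3" or "concordant"
    candidate_arms: tuple[bool, bool]  # (5p expressed, 3p expressed)
    ortholog_arms: tuple[str, str]  # status in {major, minor, absent}


def detect_clusters(premirnas: list[PreMirna], window: int = 10_000) -> list[MirnaCluster]:
    """Chain precursors within ``window`` bp into maximal clusters.

    Single-linkage per chromosome, strand-agnostic: precursors sorted by
    start are joined when the end-to-start gap to the previous chain
    member is <= window (a gap of exactly 10,000 bp still joins).
    Singletons are discarded.  Input order does not matter.
    """
    clusters: list[MirnaCluster] = []
    by_chrom: dict[str, list[PreMirna]] = {}
    for p in premirnas:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda p: p.precursor_interval)
        chain: list[PreMirna] = []
        chain_end = -math.inf
        for p in members:
            s, e = p.precursor_interval
            if chain and s - chain_end <= window:
                chain.append(p)
                chain_end = max(chain_end, e)
            else:
                if len(chain) >= 2:
                    clusters.append(_finish(chain, chrom))
                chain, chain_end = [p], e
        if len(chain) >= 2:
            clusters.append(_finish(chain, chrom))
    return clusters


def _finish(chain: list[PreMirna], chrom: str) -> MirnaCluster:
    span = (min(p.precursor_interval[0] for p in chain), max(p.precursor_interval[1] for p in chain))
    return MirnaCluster(members=list(chain), chrom=chrom, span=span)


def arm_profile(premirna: PreMirna, dominance_ratio: float = 2.0) -> ArmProfile:
    """Classify a pre-miRNA by where its mature reads come from.

    Zero reads on one arm gives the "only" categories; otherwise the
    majority arm is "dominant" when the copy ratio reaches
    ``dominance_ratio``, else the arms are of "equal" abundance.
    """
    c5, c3 = premirna.copies_5p, premirna.copies_3p
    if c5 == 0 and c3 == 0:
        category = "equal"  # degenerate: only loop-spanning reads
    elif c3 == 0:
        category = "5P_only"
    elif c5 == 0:
        category = "3P_only"
    else:
        ratio = max(c5, c3) / min(c5, c3)
        if ratio >= dominance_ratio:
            category = "5P_dominant" if c5 > c3 else "3P_dominant"
        else:
            category = "equal"
    return ArmProfile(category=category, copies_5p=c5, copies_3p=c3)


def classify_difference(candidate: ArmProfile, ortholog_arms: tuple[str, str]) -> DifferenceClass:
    """Compare candidate arm usage with its ortholog's annotated arms.

    Class 1: candidate expresses both arms, ortholog annotates one.
    Class 2: candidate expresses one arm, ortholog annotates both.
    Class 3: candidate expresses one arm, ortholog annotates only the
    opposite arm.  Anything else (same arm sets) is concordant.
    """
    cand = (candidate.copies_5p > 0, candidate.copies_3p > 0)
    orth = tuple(status != "absent" for status in ortholog_arms)
    n_cand, n_orth = sum(cand), sum(orth)
    if n_cand == 2 and n_orth == 1:
        klass = "1"
    elif n_cand == 1 and n_orth == 2:
        klass = "2"
    elif n_cand == 1 and n_orth == 1 and cand != orth:
        klass = "3"
    else:
        klass = "concordant"
    return DifferenceClass(klass=klass, candidate_arms=cand, ortholog_arms=tuple(ortholog_arms))


@dataclass
class QuartileReport:
    quartiles: list[dict]  # per-quarter: n, median, q1, q3, lo, hi, mean (log10 units)
    tests: list[dict]  # adjacent pairs: pair, t, p


def conservation_expression(families: list[FamilyRecord], n_quarters: int = 4) -> QuartileReport:
    """Quartile analysis of log10 expression versus conservation level.

    Families are sorted by ascending conservation level (family name as
    deterministic tiebreak) and split into ``n_quarters`` contiguous
    groups, any remainder going to the earlier groups.  Each adjacent
    pair of groups is compared with a Welch two-sample t-test on log10
    expression levels.
    """
    if len(families) < 2 * n_quarters:
        raise ValueError(f"need at least {2 * n_quarters} families")
    ordered = sorted(families, key=lambda r: (r.conservation_level, r.family))
    values = np.log10([max(r.expression_level, 1) for r in ordered])
    n = len(ordered)
    base, rem = divmod(n, n_quarters)
    sizes = [base + (1 if i < rem else 0) for i in range(n_quarters)]
    groups: list[np.ndarray] = []
    pos = 0
    for s in sizes:
        groups.append(values[pos : pos + s])
        pos += s

    quartiles = []
    for i, g in enumerate(groups):
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        iqr = q3 - q1
        lo = float(g[g >= q1 - 1.5 * iqr].min())
        hi = float(g[g <= q3 + 1.5 * iqr].max())
        quartiles.append(
            {"quarter": f"Q{i + 1}", "n": len(g), "median": float(med), "q1": float(q1),
             "q3": float(q3), "lo": lo, "hi": hi, "mean": float(g.mean())}
        )
    tests = []
    for i in range(n_quarters - 1):
        t, p = stats.ttest_ind(groups[i], groups[i + 1], equal_var=False)
        tests.append({"pair": f"Q{i + 1}Q{i + 2}", "t": float(t), "p": float(p)})
    return QuartileReport(quartiles=quartiles, tests=tests)
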