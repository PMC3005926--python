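"""SVM classification of hairpin candidates and pre-miRNA assembly.

An RBF-kernel support vector machine separates genuine pre-miRNA
hairpins from background genomic windows on the ten hairpin features.
Instead of the raw decision score, each candidate is reported with an
empirical p-value: the probability that a held-out negative example
scores at least as high — i.e. the probability that the candidate would
have been called positive by mistake.  Candidates with p < alpha
(default 0.05) are positive hits; overlapping positive hits on one
strand are merged into a pre-miRNA record carrying per-arm isomiR
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mirfish.hairpin import _PAIR_W, CandidatePrecursor, _encode, mature_anchored_loop
from mirfish.seqs import revcomp


@dataclass
class SvmModel:
    pipeline: Pipeline
    calibration_scores: np.ndarray  # sorted decision scores of held-out negatives
    heldout_accuracy: float
    version: str = "mirfish-svm-1"


@dataclass
class ClassifiedCandidate:
    candidate: CandidatePrecursor
    decision_score: float
    p_value: float
    positive: bool
    copy_number: int


@dataclass
class IsomiR:
    sequence: str
    copy_number: int
    p_value: float
    read_id: str = ""


@dataclass
class PreMirna:
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    isomirs_5p: list[IsomiR] = field(default_factory=list)
    isomirs_3p: list[IsomiR] = field(default_factory=list)
    isomirs_loop: list[IsomiR] = field(default_factory=list)  # loop-spanning, excluded from arm stats
    id: str = ""
    loop_span: tuple[int, int] | None = None  # sense coords in representative precursor

    @property
    def n_isomirs(self) -> int:
        return len(self.isomirs_5p) + len(self.isomirs_3p) + len(self.isomirs_loop)

    @property
    def copies_5p(self) -> int:
        return sum(i.copy_number for i in self.isomirs_5p)

    @property
    def copies_3p(self) -> int:
        return sum(i.copy_number for i in self.isomirs_3p)

    @property
    def total_copies(self) -> int:
        return self.copies_5p + self.copies_3p + sum(i.copy_number for i in self.isomirs_loop)


def train(
    positive_features: np.ndarray,
    negative_features: np.ndarray,
    C: float = 10.0,
    gamma: str | float = "scale",
    seed: int = 0,
    calibration_fraction: float = 0.5,
    min_per_class: int = 50,
) -> SvmModel:
    """Train the RBF SVM and build the negative calibration table.

    Half of each class (by default) is held out; held-out accuracy is
    reported and the decision scores of the held-out negatives form the
    empirical null distribution used for p-values.
    """
    pos = np.asarray(positive_features, dtype=float)
    neg = np.asarray(negative_features, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    if len(pos) < min_per_class or len(neg) < min_per_class:
        raise ValueError(f"need at least {min_per_class} examples per class")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=calibration_fraction, random_state=seed, stratify=y
    )
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed))]
    )
    pipe.fit(X_tr, y_tr)
    accuracy = float((pipe.predict(X_te) == y_te).mean())
    calib = np.sort(pipe.decision_function(X_te[y_te == 0]))
    return SvmModel(pipeline=pipe, calibration_scores=calib, heldout_accuracy=accuracy)


def empirical_p(model: SvmModel, score: float) -> float:
    """Add-one smoothed fraction of calibration negatives scoring >= score."""
    calib = model.calibration_scores
    n_ge = len(calib) - int(np.searchsorted(calib, score, side="left"))
    return (n_ge + 1) / (len(calib) + 1)


def classify(model: SvmModel, candidate: CandidatePrecursor, copy_number: int, alpha: float = 0.05) -> ClassifiedCandidate:
    """Score one folded/featurized candidate and attach its p-value."""
    if candidate.features is None:
        raise ValueError("candidate has no feature vector")
    score = float(model.pipeline.decision_function(candidate.features.reshape(1, -1))[0])
    p = empirical_p(model, score)
    return ClassifiedCandidate(
        candidate=candidate,
        decision_score=score,
        p_value=p,
        positive=p < alpha,
        copy_number=copy_number,
    )


def _complement_score(probe: str, segment: str, min_overlap: int = 8) -> float:
    """Best ungapped antiparallel pairing weight of probe against segment.

    Slides the probe along the reversed segment and sums the weighted
    pair table (GC=3, AU=2, GU=1) on each diagonal; the maximum over all
    shifts with at least ``min_overlap`` aligned bases is returned.
    """
    if len(segment) < min_overlap or len(probe) < min_overlap:
        return 0.0
    a = _encode(probe)
    b = _encode(segment)[::-1]
    m = _PAIR_W[np.ix_(a, b)]
    best = 0
    for off in range(-(len(a) - min_overlap), len(b) - min_overlap + 1):
        s = int(np.trace(m, offset=off))
        if s > best:
            best = s
    return float(best)


def assign_arm(
    genome_seqs: dict[str, str],
    locus,
    scan_flank: int = 150,
    probe_pad: int = 8,
    dominance: float = 1.2,
) -> str:
    """Which precursor arm a mature locus sits on: "5p", "3p" or "loop".

    The mature (padded by ``probe_pad`` nt of arm context) must pair with
    the opposite arm across the terminal loop, so the side of the mature
    holding its reverse-complement partner decides the arm: partner
    downstream in sense orientation -> the mature is the 5' arm.  The
    scan covers ``scan_flank`` nt each side — wider than the
    classification window, because the partner arm of a mature lying
    near the precursor edge can fall outside a 60 nt flank entirely.
    Near-equal evidence on both sides is flagged "loop".
    """
    chrom_seq = genome_seqs[locus.chrom]
    s0 = max(0, locus.start - scan_flank)
    e0 = min(len(chrom_seq), locus.end + scan_flank)
    window = chrom_seq[s0:e0].upper()
    if locus.strand == "-":
        window = revcomp(window)
        m0 = e0 - locus.end
    else:
        m0 = locus.start - s0
    m1 = m0 + (locus.end - locus.start)
    p0, p1 = max(0, m0 - probe_pad), min(len(window), m1 + probe_pad)
    probe = window[p0:p1]
    score_up = _complement_score(probe, window[:p0])
    score_down = _complement_score(probe, window[p1:])
    if score_down > dominance * score_up:
        return "5p"
    if score_up > dominance * score_down:
        return "3p"
    return "loop"


def assemble(positives: list[ClassifiedCandidate], genome_seqs: dict[str, str] | None = None) -> list[PreMirna]:
    """Merge strand-wise overlapping positive candidates into pre-miRNAs.

    Each positive candidate contributes one isomiR (its unique read, copy
    number and p-value).  Arm assignment prefers the complementarity
    scan of :func:`assign_arm` when genome sequences are available (the
    partner arm of an edge-proximal mature can lie outside the candidate
    window, where structure-based rules are blind); without a genome it
    falls back to the mature midpoint relative to the terminal loop of
    the most abundant member's folded precursor.  Ambiguous isomiRs are
    flagged loop-spanning and excluded from arm statistics.  The result
    is independent of input order.
    """
    by_group: dict[tuple[str, str], list[ClassifiedCandidate]] = {}
    for c in positives:
        key = (c.candidate.locus.chrom, c.candidate.locus.strand)
        by_group.setdefault(key, []).append(c)

    out: list[PreMirna] = []
    for (chrom, strand), members in sorted(by_group.items()):
        members.sort(key=lambda c: (c.candidate.precursor_interval, c.candidate.locus.start, c.candidate.mature_seq))
        groups: list[list[ClassifiedCandidate]] = []
        cur: list[ClassifiedCandidate] = []
        cur_end = None
        for c in members:
            s, e = c.candidate.precursor_interval
            if cur and s < cur_end:
                cur.append(c)
                cur_end = max(cur_end, e)
            else:
                if cur:
                    groups.append(cur)
                cur, cur_end = [c], e
        if cur:
            groups.append(cur)

        for grp in groups:
            span = (min(c.candidate.precursor_interval[0] for c in grp),
                    max(c.candidate.precursor_interval[1] for c in grp))
            rep = min(grp, key=lambda c: (-c.copy_number, c.p_value, c.candidate.locus.start, c.candidate.mature_seq))
            loop = None
            if rep.candidate.structure:
                m0 = rep.candidate.mature_offset
                m1 = m0 + (rep.candidate.locus.end - rep.candidate.locus.start)
                loop = mature_anchored_loop(rep.candidate.structure, m0, m1)
            pre = PreMirna(chrom=chrom, strand=strand, precursor_interval=span)
            if loop is not None:
                rep_iv = rep.candidate.precursor_interval
                # loop span in genome-anchored sense coords of the merged span
                if strand == "+":
                    loop_genome = (rep_iv[0] + loop[0], rep_iv[0] + loop[1])
                else:
                    loop_genome = (rep_iv[1] - loop[1], rep_iv[1] - loop[0])
                pre.loop_span = loop
            for c in grp:
                iso = IsomiR(c.candidate.mature_seq, c.copy_number, c.p_value, c.candidate.locus.read_id)
                if genome_seqs is not None:
                    arm = assign_arm(genome_seqs, c.candidate.locus)
                elif loop is None:
                    arm = "loop"
                else:
                    mid = (c.candidate.locus.start + c.candidate.locus.end) / 2.0
                    if strand == "+":
                        before, after = mid < loop_genome[0], mid >= loop_genome[1]
                    else:
                        before, after = mid > loop_genome[1], mid <= loop_genome[0]
                    arm = "5p" if before else ("3p" if after else "loop")
                if arm == "5p":
                    pre.isomirs_5p.append(iso)
                elif arm == "3p":
                    pre.isomirs_3p.append(iso)
                else:
                    pre.isomirs_loop.append(iso)
            for stack in (pre.isomirs_5p, pre.isomirs_3p, pre.isomirs_loop):
                stack.sort(key=lambda i: (-i.copy_number, i.sequence))
            out.append(pre)
    out.sort(key=lambda p: (p.chrom, p.precursor_interval, p.strand))
    for i, p in enumerate(out):
        p.id = f"pre_{i + 1}"
    return out
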