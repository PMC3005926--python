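"""Candidate pre-miRNA extraction, hairpin folding and classification features.

Each mapped mature-miRNA locus is extended by a fixed flank (60 nt by
default) on both sides, giving a ~140 nt candidate precursor.  The
precursor is folded with a base-pair-maximization dynamic program
(Nussinov-style, weighted GC=3 > AU=2 > GU=1, minimum loop 3) and a
ten-dimensional feature vector summarizing the hairpin is computed for
the SVM classifier.

The folder reports an integer ``pairing_score`` (the maximized weighted
pair count), not a free energy; the backend is deliberately swappable
behind :func:`fold`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from mirfish.seqs import gc_fraction, revcomp

# base codes: A=0 C=1 G=2 T=3 N=4 (N never pairs)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# weighted pair table: GC=3, AU=2, GU=1
_PAIR_W = np.zeros((5, 5), dtype=np.int32)
_PAIR_W[2, 1] = _PAIR_W[1, 2] = 3
_PAIR_W[0, 3] = _PAIR_W[3, 0] = 2
_PAIR_W[2, 3] = _PAIR_W[3, 2] = 1

# Watson-Crick-only variant.  Note the full table is NOT invariant under
# reverse complement: a G-U wobble maps to A-C, which cannot pair.
_PAIR_W_WC = _PAIR_W.copy()
_PAIR_W_WC[2, 3] = _PAIR_W_WC[3, 2] = 0

MIN_LOOP = 3


@dataclass
class CandidatePrecursor:
    """A mature-miRNA candidate locus with its extended precursor window."""

    locus: "object"  # GenomicLocus; kept loose to avoid circular import
    precursor_seq: str
    precursor_interval: tuple[int, int]
    mature_offset: int  # 0-based offset of the mature within the precursor
    structure: str | None = None
    pairing_score: int | None = None
    features: np.ndarray | None = field(default=None, repr=False)

    @property
    def mature_seq(self) -> str:
        m = self.locus
        return self.precursor_seq[self.mature_offset : self.mature_offset + (m.end - m.start)]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character in sequence: {exc}") from None


@njit(cache=True)
def _nussinov_fill(codes, weights, minloop):  # pragma: no cover - numba kernel
    n = codes.size
    dp = np.zeros((n, n), dtype=np.int32)
    for d in range(minloop + 1, n):
        for i in range(n - d):
            j = i + d
            best = dp[i, j - 1]  # j unpaired
            cj = codes[j]
            for k in range(i, j - minloop):
                w = weights[codes[k], cj]
                if w > 0:
                    left = dp[i, k - 1] if k > i else 0
                    v = left + dp[k + 1, j - 1] + w
                    if v > best:
                        best = v
            dp[i, j] = best
    return dp


def _traceback(codes: np.ndarray, dp: np.ndarray, weights: np.ndarray = _PAIR_W) -> str:
    """Deterministic traceback: prefer pairing, leftmost pairing partner."""
    n = codes.size
    struct = ["."] * n
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = dp[i, j]
        cj = codes[j]
        paired = False
        for k in range(i, j - MIN_LOOP):
            w = weights[codes[k], cj]
            if w > 0:
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + w == target:
                    struct[k] = "("
                    struct[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return "".join(struct)


def fold(seq: str, max_n_fraction: float = 0.10, gu_wobble: bool = True) -> tuple[str, int]:
    """Fold a sequence into one optimal weighted-maximum-pairing structure.

    Returns ``(dot_bracket, pairing_score)``.  Raises ``ValueError`` for
    sequences whose N fraction exceeds ``max_n_fraction`` or that contain
    characters outside ACGTN.  With ``gu_wobble=False`` only
    Watson-Crick pairs score, making the score strictly invariant under
    reverse complement (wobble pairs break that symmetry).
    """
    s = seq.upper().replace("U", "T")
    if not s:
        return "", 0
    if s.count("N") / len(s) > max_n_fraction:
        raise ValueError(f"sequence has >{max_n_fraction:.0%} ambiguous bases")
    if len(s) <= MIN_LOOP + 1:
        return "." * len(s), 0
    weights = _PAIR_W if gu_wobble else _PAIR_W_WC
    codes = _encode(s)
    dp = _nussinov_fill(codes, weights, MIN_LOOP)
    return _traceback(codes, dp, weights), int(dp[0, len(s) - 1])


def pairs_from_structure(structure: str) -> list[tuple[int, int]]:
    """Base-pair list (i, j) with i < j from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced structure")
    return sorted(pairs)


def terminal_loop(structure: str) -> tuple[int, int] | None:
    """Half-open span of the terminal loop of the deepest-stem hairpin.

    A hairpin loop is the region enclosed by an innermost base pair (no
    pair nested inside it).  When several hairpins exist, the one whose
    closing pair sits under the most enclosing pairs (the longest stem)
    wins; ties break leftmost.  ``None`` when the structure has no pairs.
    """
    pairs = pairs_from_structure(structure)
    if not pairs:
        return None
    inner = [
        (i, j)
        for (i, j) in pairs
        if not any(i < a and b < j for (a, b) in pairs)
    ]
    best = max(inner, key=lambda p: (sum(1 for (a, b) in pairs if a < p[0] and b > p[1]), -p[0]))
    return best[0] + 1, best[1]


def mature_anchored_loop(structure: str, m_start: int, m_end: int) -> tuple[int, int] | None:
    """Terminal loop of the hairpin whose stem the mature participates in.

    Among innermost pairs, picks the one enclosed-by the most base pairs
    that touch the mature interval [m_start, m_end); this is robust when
    the folding window also contains unrelated flanking sequence whose
    spurious pairs can build a deeper but irrelevant hairpin.  Falls back
    to the globally deepest hairpin when no pair touches the mature.
    """
    pairs = pairs_from_structure(structure)
    if not pairs:
        return None
    inner = [(i, j) for (i, j) in pairs if not any(i < a and b < j for (a, b) in pairs)]

    def mature_depth(p):
        i, j = p
        return sum(
            1
            for (a, b) in pairs
            if a <= i and b >= j and (m_start <= a < m_end or m_start <= b < m_end)
        )

    best = max(inner, key=lambda p: (mature_depth(p), -p[0]))
    if mature_depth(best) == 0:
        return terminal_loop(structure)
    return best[0] + 1, best[1]


def extract_precursor(genome, locus, flank: int = 60) -> CandidatePrecursor:
    """Extend a mature locus by ``flank`` nt both sides and orient it in sense.

    ``genome`` is a mapping of chromosome name to sequence string.  For a
    minus-strand locus the window is reverse-complemented so the mature
    sequence appears in sense orientation; ``mature_offset`` is expressed
    in those sense coordinates.  Flanks are clipped at chromosome ends.
    """
    chrom_seq = genome[locus.chrom]
    ps = max(0, locus.start - flank)
    pe = min(len(chrom_seq), locus.end + flank)
    window = chrom_seq[ps:pe].upper()
    if locus.strand == "-":
        window = revcomp(window)
        offset = pe - locus.end
    else:
        offset = locus.start - ps
    return CandidatePrecursor(
        locus=locus,
        precursor_seq=window,
        precursor_interval=(ps, pe),
        mature_offset=offset,
    )


def fold_candidate(cand: CandidatePrecursor) -> CandidatePrecursor:
    cand.structure, cand.pairing_score = fold(cand.precursor_seq)
    return cand


FEATURE_NAMES = (
    "precursor_length",
    "precursor_gc",
    "pairing_score",
    "pairing_score_per_nt",
    "frac_precursor_paired",
    "frac_mature_paired",
    "terminal_loop_length",
    "longest_mature_bulge",
    "mature_gc",
    "mature_arm_position",
)


def compute_features(cand: CandidatePrecursor) -> np.ndarray:
    """Ten-dimensional hairpin feature vector for a folded candidate.

    Features (in order): precursor length; precursor GC fraction;
    pairing score; pairing score per nt; fraction of precursor bases
    paired; fraction of mature bases paired; terminal-loop length;
    longest unpaired run inside the mature; mature GC fraction; mature
    arm position in [-1, 1] (negative = 5' side of the terminal loop).
    """
    if cand.structure is None:
        raise ValueError("candidate must be folded before feature computation")
    seq, db = cand.precursor_seq, cand.structure
    n = len(seq)
    m_start = cand.mature_offset
    m_end = m_start + (cand.locus.end - cand.locus.start)
    mature_struct = db[m_start:m_end]
    mature_seq = seq[m_start:m_end]

    paired = sum(1 for c in db if c != ".")
    mature_paired = sum(1 for c in mature_struct if c != ".")
    loop = terminal_loop(db)
    if loop is None:
        loop_len = float(n)
        loop_mid = n / 2.0
    else:
        loop_len = float(loop[1] - loop[0])
        loop_mid = (loop[0] + loop[1]) / 2.0

    longest_bulge = max((len(r) for r in _dot_runs(mature_struct)), default=0)

    mature_mid = (m_start + m_end) / 2.0
    arm_pos = 0.0 if n == 0 else float(np.clip((mature_mid - loop_mid) / (n / 2.0), -1.0, 1.0))

    return np.array(
        [
            float(n),
            gc_fraction(seq),
            float(cand.pairing_score),
            cand.pairing_score / n if n else 0.0,
            paired / n if n else 0.0,
            mature_paired / len(mature_struct) if mature_struct else 0.0,
            loop_len,
            float(longest_bulge),
            gc_fraction(mature_seq),
            arm_pos,
        ]
    )


def _dot_runs(structure: str) -> list[str]:
    return [r for r in structure.replace("(", ")").split(")") if r]
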