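"""Tiny sequence helpers shared across the pipeline.

All internal sequences are DNA alphabet (U is normalized to T on input)
and all coordinates are 0-based half-open.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (lowercase marks masked bases)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")
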