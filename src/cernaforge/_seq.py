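"""Small nucleotide-sequence helpers shared across modules.

All internal sequence handling is DNA-alphabet uppercase; RNA input (U) is
normalized to T at the boundary so that U and T behave identically.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and map U->T. Other ambiguity codes are left as-is."""
    return seq.upper().replace("U", "T")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; normalize first for RNA input)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")
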