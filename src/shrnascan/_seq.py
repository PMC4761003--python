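"""Low-level nucleotide string helpers shared across modules.

All sequences are stored as uppercase DNA: RNA input is accepted anywhere and
normalized with U→T so published siRNA strands (written as RNA) work
unchanged.
"""

import re

# Full IUPAC complement, so reads with ambiguity codes survive orientation
# flips even though only N is given special meaning downstream.
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)

_IUPAC_RE = re.compile(r"^[ACGTUNRYSWKMBDHV]+$")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def validate_iupac(seq: str, what: str = "sequence") -> str:
    """Normalize and reject characters outside the IUPAC nucleotide alphabet."""
    norm = normalize(seq)
    if not norm:
        from .errors import EmptyInputError

        raise EmptyInputError(f"empty {what}")
    if not _IUPAC_RE.match(norm):
        bad = sorted(set(norm) - set("ACGTUNRYSWKMBDHV"))
        raise ValueError(f"{what} contains non-IUPAC characters: {bad}")
    return norm


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly RNA-spelled) nucleotide string."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]
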