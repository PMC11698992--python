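"""Shared sequence/number helpers.

DNA alphabet internally: U is mapped to T on input, lowercase to uppercase.
N is tolerated in genomes but never matches a motif position.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError

_ALLOWED = frozenset("ACGTN")
_U2T = str.maketrans("Uu", "Tt")
_RC = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and validate the A/C/G/T/N alphabet."""
    s = seq.translate(_U2T).upper()
    bad = set(s) - _ALLOWED
    if bad:
        raise ValidationError(
            f"illegal character(s) {sorted(bad)} in {context!r}; "
            "allowed: A/C/G/T/U/N (case-insensitive)"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a normalized DNA string."""
    return seq.translate(_RC)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet (T -> U), for display of rRNA-derived labels."""
    return seq.replace("T", "U")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as done for the reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
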