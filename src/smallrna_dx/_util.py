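"""Shared helpers: alphabet normalization, reverse complement, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to the internal DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence with U, miRNA-style."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, *, context: str = "sequence") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T: {sorted(bad)!r}"
        )


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Report columns use commercial half-up rounding rather than Python's
    banker's rounding so that e.g. 0.125 renders as 0.13 at 2 decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
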