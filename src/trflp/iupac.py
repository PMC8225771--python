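"""IUPAC degenerate nucleotide alphabet.

T-RFLP primers and reference amplicons routinely contain degenerate
positions (the forward tag used for formyltetrahydrofolate-synthetase
profiling carries eleven N's), so every sequence comparison in this
package is defined on base *sets* rather than on letters.  A code ``a``
is *compatible* with ``b`` when their base sets intersect, and is
*encompassed* by ``b`` when its set is a subset of ``b``'s.
"""

from __future__ import annotations

import itertools
from typing import Iterator

#: base set of every one-letter IUPAC nucleotide code (uppercase).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}
_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: complement of every IUPAC code, derived set-wise (e.g. R=AG -> Y=CT).
COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class SequenceError(ValueError):
    """Raised for sequences containing characters outside the IUPAC alphabet."""


def clean_sequence(raw: str, *, name: str = "sequence") -> str:
    """Normalise ``raw`` to an uppercase IUPAC string.

    Whitespace is stripped, lowercase letters are uppercased and RNA ``U``
    is mapped to ``T``.  Any other character is fatal; the error message
    points at the 1-based offending position.  Empty sequences are
    rejected.
    """
    s = "".join(raw.split()).upper().replace("U", "T")
    if not s:
        raise SequenceError(f"{name}: empty sequence")
    for pos, ch in enumerate(s, start=1):
        if ch not in IUPAC_SETS:
            raise SequenceError(
                f"{name}: invalid IUPAC character {ch!r} at position {pos}"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (involution: rc(rc(s)) == s)."""
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def compatible(a: str, b: str) -> bool:
    """True when the base sets of codes ``a`` and ``b`` intersect."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def encompasses(pattern_code: str, seq_code: str) -> bool:
    """True when every base represented by ``seq_code`` is allowed by
    ``pattern_code`` (subset semantics)."""
    return IUPAC_SETS[seq_code] <= IUPAC_SETS[pattern_code]


def n_ambiguous(seq: str) -> int:
    """Number of positions with a non-concrete (multi-base) code."""
    return sum(1 for c in seq if len(IUPAC_SETS[c]) > 1)


def disambiguations(seq: str) -> Iterator[str]:
    """Yield every concrete ACGT sequence represented by ``seq``.

    The number of variants is the product of the base-set sizes; callers
    are expected to bound ambiguity before expanding.
    """
    pools = [sorted(IUPAC_SETS[c]) for c in seq]
    for combo in itertools.product(*pools):
        yield "".join(combo)
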