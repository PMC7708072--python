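"""IUPAC degenerate nucleotide alphabet helpers.

The degenerate alphabet maps each code to the set of unambiguous bases it
stands for (R = A/G, Y = C/T, N = any, ...). These helpers are used both to
express hidden PAM recognition rules in the simulator and to emit consensus
strings from position profiles.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"

IUPAC_TO_BASES: dict[str, frozenset[str]] = {
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

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(pattern: str) -> bool:
    return len(pattern) > 0 and all(c in IUPAC_TO_BASES for c in pattern)


def matches(kmer: str, pattern: str) -> bool:
    """True if an unambiguous k-mer is compatible with an IUPAC pattern."""
    if len(kmer) != len(pattern):
        return False
    return all(b in IUPAC_TO_BASES[p] for b, p in zip(kmer, pattern))


def code_for(bases) -> str:
    """IUPAC code for a set of unambiguous bases."""
    key = frozenset(bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"not a set of nucleotides: {sorted(bases)!r}") from None


def all_kmers(k: int) -> list[str]:
    """All 4^k unambiguous k-mers in lexicographic (A<C<G<T) order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def pattern_mask(patterns, k: int) -> np.ndarray:
    """Boolean mask over the lexicographic 4^k k-mer universe.

    mask[i] is True when k-mer i matches at least one of the IUPAC patterns.
    """
    mask = np.zeros(4**k, dtype=bool)
    base_index = {b: i for i, b in enumerate(BASES)}
    for pattern in patterns:
        if len(pattern) != k:
            raise ValueError(f"pattern {pattern!r} has length {len(pattern)}, expected {k}")
        # positional digit sets in base-4; enumerate the cartesian product of
        # allowed digits instead of scanning all 4^k strings
        digit_sets = [sorted(base_index[b] for b in IUPAC_TO_BASES[c]) for c in pattern]
        for digits in itertools.product(*digit_sets):
            idx = 0
            for d in digits:
                idx = idx * 4 + d
            mask[idx] = True
    return mask


def n_matching(patterns, k: int) -> int:
    return int(pattern_mask(patterns, k).sum())
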