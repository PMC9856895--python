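"""Cytoplasmic polyadenylation element (CPE) censuses of 3'UTR sequences.

CPEs are U-rich elements in mRNA 3'UTRs bound by CPEB-family proteins.  Two
classes are distinguished: canonical A-containing sites (UUUUAU-like) and
noncanonical G-containing variants (UUUUGU-like).  Sequences are handled as
DNA (T for U) on the sense strand of the mRNA; the reverse complement is
never scanned.  Every occurrence is counted at its distinct start position,
so overlapping sites each contribute a hit.

:func:`apply_deletion` removes an interval from a sequence, mimicking 3'UTR
deletion alleles such as orb2^R; motifs spanning a breakpoint are destroyed
unless the junction happens to recreate a match, because the census is taken
on the joined sequence.

The default motif set is a plausible, fully user-configurable stand-in: the
exact motif strings behind published per-isoform CPE counts are defined in
the primary CPEB literature, not here, and should be supplied (e.g. via a
YAML file on the CLI) to reproduce any published census.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InputError

__all__ = [
    "CpeCensus",
    "DEFAULT_MOTIFS",
    "MotifHit",
    "MotifSet",
    "apply_deletion",
    "census",
    "scan_motifs",
]

# IUPAC degenerate DNA codes; N in a *sequence* never matches because the
# classes below are what patterns expand to — none includes N.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_SEQ_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MotifSet:
    """Canonical (A-containing) and noncanonical (G-containing) CPE patterns.

    Patterns are fixed-length strings over the DNA alphabet, optionally with
    IUPAC degeneracy codes.
    """

    canonical: tuple[str, ...]
    noncanonical: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.canonical or not self.noncanonical:
            raise InputError("both motif classes must be non-empty")
        for pat in self.all_patterns():
            if len(pat) < 4:
                raise InputError(f"pattern {pat!r} shorter than 4 nt")
            bad = set(pat.upper()) - set(_IUPAC)
            if bad:
                raise InputError(f"pattern {pat!r} has non-IUPAC symbols {bad}")

    def all_patterns(self) -> tuple[str, ...]:
        return tuple(self.canonical) + tuple(self.noncanonical)

    def class_of(self, pattern: str) -> str:
        return "canonical" if pattern in self.canonical else "noncanonical"


DEFAULT_MOTIFS = MotifSet(
    canonical=("TTTTAT", "TTTTAAT", "TTTTTAT"),
    noncanonical=("TTTTGT", "TTTTGAT", "TTTTTGT"),
)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based
    end: int  # exclusive
    pattern: str
    cpe_class: str


@dataclass(frozen=True)
class CpeCensus:
    seq_id: str
    n_canonical: int
    n_noncanonical: int
    hits: tuple[MotifHit, ...] = field(repr=False)

    @property
    def n_total(self) -> int:
        return self.n_canonical + self.n_noncanonical


def _clean_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise InputError(f"sequence contains non-DNA symbols {sorted(bad)}")
    return seq


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    body = "".join(_IUPAC[c] for c in pattern.upper())
    # Lookahead so overlapping occurrences are each reported.
    return re.compile(f"(?=({body}))")


def scan_motifs(
    sequence: str,
    motifs: MotifSet = DEFAULT_MOTIFS,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All motif occurrences on the sense strand, sorted by start position."""
    seq = _clean_sequence(sequence)
    hits: list[MotifHit] = []
    for pattern in motifs.all_patterns():
        cls = motifs.class_of(pattern)
        for m in _pattern_regex(pattern).finditer(seq):
            start = m.start()
            hits.append(
                MotifHit(seq_id, start, start + len(pattern), pattern, cls)
            )
    hits.sort(key=lambda h: (h.start, h.end, h.pattern))
    return hits


def census(
    sequence: str,
    motifs: MotifSet = DEFAULT_MOTIFS,
    seq_id: str = "seq",
) -> CpeCensus:
    """Per-sequence motif counts split into canonical / noncanonical classes."""
    hits = scan_motifs(sequence, motifs, seq_id=seq_id)
    n_canon = sum(1 for h in hits if h.cpe_class == "canonical")
    return CpeCensus(
        seq_id=seq_id,
        n_canonical=n_canon,
        n_noncanonical=len(hits) - n_canon,
        hits=tuple(hits),
    )


def apply_deletion(sequence: str, interval: tuple[int, int]) -> str:
    """Remove a 0-based half-open interval, joining the flanks.

    Motifs wholly inside the interval disappear; motifs spanning a breakpoint
    survive only if the junction recreates a match on the joined sequence.
    """
    start, end = interval
    if not (0 <= start <= end <= len(sequence)):
        raise InputError(
            f"deletion interval [{start}, {end}) out of bounds for length "
            f"{len(sequence)}"
        )
    return sequence[:start] + sequence[end:]
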