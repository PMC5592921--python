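"""Nucleotide alphabet handling, allele-pair parsing and candidate guide enumeration.

An allele-specific siRNA (ASP-siRNA) is a 19-nt guide (antisense) strand designed so
that the base complementary to a point mutation sits at one of the 19 guide positions.
Against the mutant mRNA the guide is fully complementary; against the wild-type allele
it carries exactly one mismatch at that position.  This module parses the mutant /
wild-type allele pair (FASTA, variant marked in lower case), and enumerates the up to
19 candidate guides that tile the variant.

Coordinate conventions
----------------------
* Target (sense mRNA) coordinates are 0-based half-open.
* Guide positions are 1-based, counted 5'->3' along the antisense strand; guide
  position 1 pairs with the 3'-most base of the 19-nt sense target window.
* The internal alphabet is RNA (A, C, G, U); DNA input is accepted, T -> U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "AlphabetError",
    "VariantError",
    "AllelePair",
    "SiRNACandidate",
    "normalize_sequence",
    "reverse_complement",
    "complement",
    "parse_allele_pair",
    "enumerate_candidates",
    "mismatch_class",
]

logger = logging.getLogger(__name__)

GUIDE_LEN = 19

RNA_ALPHABET = frozenset("ACGU")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_VALID_RAW = set("ACGTUacgtu")


class AlphabetError(ValueError):
    """A character outside the nucleotide alphabet was encountered."""


class VariantError(ValueError):
    """The allele pair does not define exactly one variant site."""


@dataclass(frozen=True)
class AllelePair:
    """A mutant / wild-type mRNA context pair differing at one nucleotide.

    Both sequences are sense-strand RNA of equal length; ``variant_offset`` is the
    0-based index of the single differing position.
    """

    mutant_seq: str
    wild_seq: str
    variant_offset: int
    mutant_nt: str
    wild_nt: str

    def __post_init__(self) -> None:
        if len(self.mutant_seq) != len(self.wild_seq):
            raise VariantError("mutant and wild sequences differ in length")
        if not (0 <= self.variant_offset < len(self.mutant_seq)):
            raise VariantError("variant_offset outside sequence")
        diffs = [
            i
            for i, (m, w) in enumerate(zip(self.mutant_seq, self.wild_seq))
            if m != w
        ]
        if diffs != [self.variant_offset]:
            raise VariantError(
                f"sequences must differ at exactly the variant offset; "
                f"differing positions: {diffs}"
            )
        if self.mutant_seq[self.variant_offset] != self.mutant_nt:
            raise VariantError("mutant_nt does not match sequence at variant_offset")
        if self.wild_seq[self.variant_offset] != self.wild_nt:
            raise VariantError("wild_nt does not match sequence at variant_offset")
        for seq in (self.mutant_seq, self.wild_seq):
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise AlphabetError(f"non-RNA characters after normalization: {bad}")


@dataclass(frozen=True)
class SiRNACandidate:
    """A 19-nt candidate guide with the variant-complementary base at a known position.

    ``guide`` is written 5'->3' on the antisense strand; ``variant_guide_pos`` is the
    1-based guide position pairing with the mutation; ``target_window`` is the 19-nt
    sense-strand window (0-based start ``target_window_start`` on the mutant mRNA).
    """

    guide: str
    variant_guide_pos: int
    target_window_start: int
    target_window: str

    def __post_init__(self) -> None:
        if len(self.guide) != GUIDE_LEN or len(self.target_window) != GUIDE_LEN:
            raise ValueError("guide and target window must be 19 nt")
        if not (1 <= self.variant_guide_pos <= GUIDE_LEN):
            raise ValueError("variant_guide_pos must be in 1..19")
        if self.guide != reverse_complement(self.target_window):
            raise ValueError("guide is not the reverse complement of its target window")


def normalize_sequence(raw: str) -> str:
    """Normalize a raw nucleotide string to uppercase RNA (T -> U).

    Whitespace is stripped.  Case information is *not* preserved here; callers that
    need the lowercase variant marker must inspect the raw string first (see
    :func:`parse_allele_pair`).

    Raises
    ------
    AlphabetError
        If any character is outside ``{A,C,G,T,U}`` (either case), naming the
        1-based offending position.
    """
    if not raw or not raw.strip():
        raise ValueError("empty sequence")
    stripped = "".join(raw.split())
    for i, ch in enumerate(stripped):
        if ch not in _VALID_RAW:
            raise AlphabetError(f"invalid nucleotide {ch!r} at position {i + 1}")
    return stripped.upper().replace("T", "U")


def complement(nt: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    try:
        return _COMPLEMENT[nt]
    except KeyError:
        raise AlphabetError(f"invalid nucleotide {nt!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return "".join(_COMPLEMENT[nt] for nt in reversed(seq))


def _lowercase_offsets(raw: str) -> list[int]:
    stripped = "".join(raw.split())
    return [i for i, ch in enumerate(stripped) if ch.islower()]


def parse_allele_pair(mutant_raw: str, wild_raw: str) -> AllelePair:
    """Build an :class:`AllelePair` from two raw sequence strings.

    The variant site is located from the single lowercase nucleotide in each
    sequence (webserver convention: "the nucleotide mutation in lower case").  When
    neither sequence carries a lowercase marker, the unique differing position is
    used instead; zero or more than one difference is an error.

    Parameters are the raw sequence strings (FASTA headers already removed); use
    :func:`asirna.io.read_allele_fasta` for file input.
    """
    mut_low = _lowercase_offsets(mutant_raw)
    wild_low = _lowercase_offsets(wild_raw)
    mutant = normalize_sequence(mutant_raw)
    wild = normalize_sequence(wild_raw)
    if len(mutant) != len(wild):
        raise VariantError("mutant and wild sequences differ in length")

    if len(mut_low) > 1 or len(wild_low) > 1:
        raise VariantError("ambiguous variant marker: more than one lowercase nucleotide")
    if mut_low or wild_low:
        if mut_low and wild_low and mut_low != wild_low:
            raise VariantError(
                f"lowercase variant markers disagree: {mut_low[0]} vs {wild_low[0]}"
            )
        offset = (mut_low or wild_low)[0]
        if mutant[offset] == wild[offset]:
            raise VariantError("no variant: alleles identical at the marked position")
    else:
        diffs = [i for i, (m, w) in enumerate(zip(mutant, wild)) if m != w]
        if not diffs:
            raise VariantError("no variant: sequences are identical")
        if len(diffs) > 1:
            raise VariantError(
                f"sequences differ at {len(diffs)} positions; exactly one expected"
            )
        offset = diffs[0]

    diffs = [i for i, (m, w) in enumerate(zip(mutant, wild)) if m != w]
    if diffs != [offset]:
        raise VariantError(
            f"sequences must differ only at the variant site {offset}; "
            f"differing positions: {diffs}"
        )
    return AllelePair(
        mutant_seq=mutant,
        wild_seq=wild,
        variant_offset=offset,
        mutant_nt=mutant[offset],
        wild_nt=wild[offset],
    )


def enumerate_candidates(pair: AllelePair) -> list[SiRNACandidate]:
    """Enumerate candidate guides placing the variant at each of guide positions 1..19.

    For guide position ``p`` the 19-nt sense window starts at
    ``variant_offset - (19 - p)``: guide position 1 (5') pairs with the 3'-most base
    of the window, so p = 19 puts the variant at the window's 5' end.  Windows that
    would extend past either end of the context are skipped with a warning.  Output
    is ordered by ``p`` ascending.
    """
    out: list[SiRNACandidate] = []
    n = len(pair.mutant_seq)
    for p in range(1, GUIDE_LEN + 1):
        start = pair.variant_offset - (GUIDE_LEN - p)
        if start < 0 or start + GUIDE_LEN > n:
            logger.warning(
                "candidate at guide position %d skipped: window [%d, %d) outside "
                "context of length %d",
                p, start, start + GUIDE_LEN, n,
            )
            continue
        window = pair.mutant_seq[start : start + GUIDE_LEN]
        out.append(
            SiRNACandidate(
                guide=reverse_complement(window),
                variant_guide_pos=p,
                target_window_start=start,
                target_window=window,
            )
        )
    return out


def mismatch_class(guide_nt: str, target_nt: str) -> str:
    """Classify a guide:target apposition.

    Returns one of ``match`` (Watson-Crick pair), ``pur:pur``, ``pyr:pyr``,
    ``pur:pyr`` or ``pyr:pur``; the class name orders guide base first.  G:U wobble
    is a mismatch here — the tolerance-matrix tier penalizes any non-Watson-Crick
    apposition.
    """
    for nt in (guide_nt, target_nt):
        if nt not in RNA_ALPHABET:
            raise AlphabetError(f"invalid nucleotide {nt!r}")
    if _COMPLEMENT[guide_nt] == target_nt:
        return "match"
    g = "pur" if guide_nt in PURINES else "pyr"
    t = "pur" if target_nt in PURINES else "pyr"
    return f"{g}:{t}"
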