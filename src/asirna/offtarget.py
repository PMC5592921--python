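"""Off-target discovery for siRNA guides against a target sequence set.

Two search modes mirror how RISC engages unintended transcripts:

* **seed search** — exact (zero-mismatch) matches of the guide seed region
  (hexamer, guide positions 2-7, or heptamer, positions 2-8) against target
  sites complementary to the seed.  Seed pairing in 3'UTRs is the dominant
  driver of off-target silencing, so no mismatches are allowed.
* **full-sequence search** — every 19-nt sense window whose complement differs
  from the guide by at most 3 mismatches (Hamming distance on the aligned
  duplex).

Targets are scanned on the sense strand of the supplied FASTA for sites
complementary to the guide; coordinates are reported 1-based inclusive.
Ambiguity codes (N, ...) never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence import GUIDE_LEN, reverse_complement

__all__ = [
    "OffTargetHit",
    "SEED_SLICES",
    "seed_of",
    "build_seed_index",
    "seed_offtargets",
    "full_offtargets",
    "map_guides",
]

logger = logging.getLogger(__name__)

#: guide-position slices (1-based, inclusive) of the two seed modes
SEED_SLICES = {"seed6": (2, 7), "seed7": (2, 8)}

MAX_MISMATCH_CEILING = 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True, order=True)
class OffTargetHit:
    """One matched site on a target record (1-based start, sense coordinates)."""

    sequence_id: str
    start: int
    mode: str
    mismatches: int
    site: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1 (1-based)")


def seed_of(guide: str, mode: str) -> str:
    """Seed region of a guide: positions 2-7 (seed6) or 2-8 (seed7), 1-based from 5'."""
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt")
    try:
        lo, hi = SEED_SLICES[mode]
    except KeyError:
        raise ValueError(f"unknown seed mode {mode!r}") from None
    return guide[lo - 1 : hi]


def _normalize_target(seq: str) -> str:
    return seq.upper().replace("T", "U")


def build_seed_index(
    targets: Mapping[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    """Index every k-mer of the target sense sequences to its occurrence list.

    ``targets`` maps record id -> sequence (use :func:`asirna.io.read_fasta`).
    Occurrences are (record id, 1-based start); k-mers containing characters
    outside A/C/G/U (after T->U) are skipped.  Records shorter than k contribute
    nothing.
    """
    if k not in (6, 7):
        raise ValueError("seed index k must be 6 or 7")
    if not targets:
        raise ValueError("empty target sequence set")
    index: dict[str, list[tuple[str, int]]] = {}
    for rec_id, seq in targets.items():
        s = _normalize_target(seq)
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= _CODE.keys():
                index.setdefault(kmer, []).append((rec_id, i + 1))
    return index


def seed_offtargets(
    guide: str, index: Mapping[str, list[tuple[str, int]]], mode: str
) -> list[OffTargetHit]:
    """Zero-mismatch seed off-targets: target occurrences of the seed's complement.

    A target site is hit when it is exactly Watson-Crick complementary to the
    guide seed, i.e. the reverse complement of the seed occurs on the sense
    strand.  Sorted by (sequence_id, start).
    """
    seed = seed_of(guide, mode)
    k = len(seed)
    if index and len(next(iter(index))) != k:
        raise ValueError(f"index k-mer length does not match mode {mode!r}")
    site = reverse_complement(seed)
    hits = [
        OffTargetHit(rec_id, start, mode, 0, site)
        for rec_id, start in index.get(site, [])
    ]
    return sorted(hits)


def _encode(seq: str) -> np.ndarray:
    """Map a target string to integer codes, -1 for ambiguity codes (never match)."""
    return np.array([_CODE.get(ch, -1) for ch in seq], dtype=np.int8)


def full_offtargets(
    guide: str,
    targets: Mapping[str, str],
    max_mismatch: int = MAX_MISMATCH_CEILING,
    allow_above_ceiling: bool = False,
) -> list[OffTargetHit]:
    """Full-sequence off-targets: 19-nt windows within Hamming distance of the guide.

    A window hits when the reverse complement of the guide matches the sense
    window with at most ``max_mismatch`` substitutions (equivalently, the guide
    matches the window's complement).  The ceiling of 3 mismatches can only be
    raised with ``allow_above_ceiling=True``, which warns.  Sorted by
    (sequence_id, start, mismatches).
    """
    if len(guide) != GUIDE_LEN:
        raise ValueError(f"guide must be {GUIDE_LEN} nt")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if max_mismatch > MAX_MISMATCH_CEILING:
        if not allow_above_ceiling:
            raise ValueError(
                f"max_mismatch {max_mismatch} above the ceiling of "
                f"{MAX_MISMATCH_CEILING}; pass allow_above_ceiling=True to override"
            )
        logger.warning(
            "max_mismatch %d above the usual ceiling of %d",
            max_mismatch, MAX_MISMATCH_CEILING,
        )
    if not targets:
        raise ValueError("empty target sequence set")

    # Hamming(guide, revcomp(window)) == Hamming(revcomp(guide), window): compare
    # the guide's reverse complement against every sense window with one
    # vectorized sliding comparison per record.
    rc = _encode(_normalize_target(reverse_complement(guide)))
    hits: list[OffTargetHit] = []
    for rec_id, seq in targets.items():
        s = _normalize_target(seq)
        if len(s) < GUIDE_LEN:
            continue
        codes = _encode(s)
        windows = np.lib.stride_tricks.sliding_window_view(codes, GUIDE_LEN)
        valid = (windows >= 0).all(axis=1)
        mm = (windows != rc).sum(axis=1)
        for i in np.flatnonzero(valid & (mm <= max_mismatch)):
            hits.append(
                OffTargetHit(
                    rec_id, int(i) + 1, "full", int(mm[i]),
                    s[int(i) : int(i) + GUIDE_LEN],
                )
            )
    return sorted(hits, key=lambda h: (h.sequence_id, h.start, h.mismatches))


def map_guides(
    guides: Mapping[str, str] | Sequence[str], gene_seq: str
) -> list[dict]:
    """Map guides to their exact target sites on a single gene sequence.

    For each guide, every exact reverse-complement match is reported with its
    1-based start on the sense strand; guides without a match are flagged
    ``unmapped``.  ``guides`` is a mapping id -> guide or a plain sequence of
    guides (ids are then g1, g2, ...).
    """
    if not guides:
        raise ValueError("empty guide table")
    if not gene_seq:
        raise ValueError("empty gene sequence")
    if not isinstance(guides, Mapping):
        guides = {f"g{i + 1}": g for i, g in enumerate(guides)}
    s = _normalize_target(gene_seq)
    rows: list[dict] = []
    for gid, guide in guides.items():
        site = _normalize_target(reverse_complement(guide))
        starts = []
        pos = s.find(site)
        while pos != -1:
            starts.append(pos + 1)
            pos = s.find(site, pos + 1)
        if starts:
            for st in starts:
                rows.append(
                    {"guide_id": gid, "guide": guide, "start": st, "mapped": True}
                )
        else:
            rows.append(
                {"guide_id": gid, "guide": guide, "start": None, "mapped": False}
            )
    return rows
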