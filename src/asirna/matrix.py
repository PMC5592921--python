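"""Position-specific mismatch tolerance matrix: wild-type allele efficacy (Eff_wild).

The guide of an allele-specific siRNA carries exactly one mismatch against the
wild-type allele, at the guide position complementary to the mutation.  This tier
predicts the efficacy retained against the wild-type allele as

    Eff_wild = Eff_mut * retention(position, guide_nt : target_nt)

with a retention factor in [0, 1] per (guide position 1-19, ordered mismatch pair).
The 12 mismatch pairs are all ordered guide:target appositions that are not
Watson-Crick.  A perfectly discriminating design has a high Eff_mut and a low
retention at its variant position; the difference Eff_mut - Eff_wild is the
discrimination score used to rank candidates.

The default matrix shipped here encodes qualitative rules from mismatch-tolerance
studies — purine:purine clashes are least tolerated, pyrimidine:pyrimidine most;
retention is minimal at the RISC cleavage site (guide positions 9-11, cleavage
opposite position 10) and maximal at the duplex termini (positions 1 and 19).  It
is a synthetic, documented default, not an empirically fitted matrix; supply a
measured matrix as a TSV for production designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sequence import (
    GUIDE_LEN,
    AllelePair,
    SiRNACandidate,
    complement,
    mismatch_class,
)

__all__ = [
    "MISMATCH_PAIRS",
    "MismatchMatrix",
    "load_matrix",
    "save_matrix",
    "default_matrix",
    "predict_eff_wild",
    "discrimination",
]

_BASES = "ACGU"

#: the 12 ordered non-Watson-Crick guide:target pairs
MISMATCH_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (g, t) for g in _BASES for t in _BASES if complement(g) != t
)

N_CELLS = GUIDE_LEN * len(MISMATCH_PAIRS)  # 19 x 12 = 228


@dataclass
class MismatchMatrix:
    """Retention factors for every (guide position, ordered mismatch pair) cell."""

    retention: dict[tuple[int, str, str], float]
    source: str = "unspecified"
    version: str = "1"

    def __post_init__(self) -> None:
        expected = {
            (pos, g, t)
            for pos in range(1, GUIDE_LEN + 1)
            for g, t in MISMATCH_PAIRS
        }
        keys = set(self.retention)
        if keys != expected:
            missing = expected - keys
            extra = keys - expected
            parts = []
            if missing:
                parts.append(f"{len(missing)} missing cells (e.g. {sorted(missing)[0]})")
            if extra:
                parts.append(f"{len(extra)} unexpected cells (e.g. {sorted(extra)[0]})")
            raise ValueError("malformed matrix: " + "; ".join(parts))
        for key, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention {r} outside [0, 1] at cell {key}")

    def __getitem__(self, key: tuple[int, str, str]) -> float:
        return self.retention[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "guide_nt": g, "target_nt": t, "retention": r}
            for (pos, g, t), r in sorted(self.retention.items())
        ]
        return pd.DataFrame(rows)

    def class_view(self) -> pd.DataFrame:
        """Mean retention per (position, clash class) — the collapsed rule view."""
        df = self.to_frame()
        df["clash"] = [
            mismatch_class(g, t) for g, t in zip(df["guide_nt"], df["target_nt"])
        ]
        return df.groupby(["position", "clash"])["retention"].mean().reset_index()


def load_matrix(path: str | Path) -> MismatchMatrix:
    """Read a matrix TSV (position, guide_nt, target_nt, retention; '#' comments).

    Rejects duplicate or missing cells, malformed rows and out-of-range values.
    """
    meta = {"source": str(path), "version": "1"}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                for key in ("source", "version"):
                    if stripped.startswith(f"{key}="):
                        meta[key] = stripped.split("=", 1)[1]
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "guide_nt", "target_nt", "retention"}
    if set(df.columns) < required:
        raise ValueError(
            f"matrix file missing columns: {sorted(required - set(df.columns))}"
        )
    retention: dict[tuple[int, str, str], float] = {}
    for row in df.itertuples(index=False):
        key = (int(row.position), str(row.guide_nt), str(row.target_nt))
        if key in retention:
            raise ValueError(f"duplicate matrix cell {key}")
        retention[key] = float(row.retention)
    return MismatchMatrix(retention, source=meta["source"], version=meta["version"])


def save_matrix(matrix: MismatchMatrix, path: str | Path) -> None:
    """Write the matrix TSV with metadata comments; load -> save round-trips losslessly."""
    with open(path, "w") as fh:
        fh.write(f"# source={matrix.source}\n")
        fh.write(f"# version={matrix.version}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


# class retention envelopes: (value at termini, value at the cleavage site);
# ordering pur:pur < mixed < pyr:pyr holds at both ends, so it holds everywhere
# along the linear interpolation between them
_CLASS_ENVELOPE = {
    "pur:pur": (0.50, 0.05),
    "pur:pyr": (0.65, 0.15),
    "pyr:pur": (0.65, 0.15),
    "pyr:pyr": (0.80, 0.30),
}

# small within-class offsets ranking pairs from least to most tolerated; gaps
# between class envelopes (>= 0.10) exceed the largest offset so the class
# ordering is never violated cell-by-cell
_PAIR_OFFSET = {
    ("G", "G"): 0.00, ("A", "G"): 0.01, ("G", "A"): 0.02, ("A", "A"): 0.03,
    ("C", "A"): 0.00, ("A", "C"): 0.01, ("U", "G"): 0.02, ("G", "U"): 0.03,
    ("C", "C"): 0.00, ("U", "C"): 0.01, ("C", "U"): 0.02, ("U", "U"): 0.03,
}


def _centrality(pos: int) -> float:
    """1.0 at the RISC cleavage region (positions 9-11), 0.0 at positions 1 and 19."""
    if 9 <= pos <= 11:
        return 1.0
    d = min(abs(pos - 9), abs(pos - 11))
    return 1.0 - d / 8.0


def default_matrix() -> MismatchMatrix:
    """Synthetic default matrix obeying the qualitative mismatch-tolerance rules.

    Cell-by-cell it satisfies: retention(pur:pur) <= retention(mixed) <=
    retention(pyr:pyr) at every position; positions 9-11 carry the minimum
    retention within each mismatch class and positions 1/19 the maximum.  Within
    a class, pairs get small fixed offsets (e.g. G:G least tolerated) so the
    ordered-pair structure is not degenerate.
    """
    retention: dict[tuple[int, str, str], float] = {}
    for pos in range(1, GUIDE_LEN + 1):
        c = _centrality(pos)
        for g, t in MISMATCH_PAIRS:
            hi, lo = _CLASS_ENVELOPE[mismatch_class(g, t)]
            retention[(pos, g, t)] = round(hi - (hi - lo) * c + _PAIR_OFFSET[(g, t)], 6)
    return MismatchMatrix(retention, source="builtin-qualitative-rules", version="1")


def predict_eff_wild(
    eff_mut: float,
    candidate: SiRNACandidate,
    pair: AllelePair,
    matrix: MismatchMatrix,
    mode: str = "multiplicative",
) -> float:
    """Wild-type-allele efficacy from the candidate's variant cell, clamped to [0,100].

    ``multiplicative`` (default): Eff_wild = Eff_mut x retention — the cell is a
    modifier relative to the matched duplex. ``absolute``: Eff_wild = 100 x
    retention — for matrices whose cells store absolute efficacies.

    The candidate guide must mismatch the wild-type allele at exactly one
    position (its variant position); zero or multiple mismatches are errors.
    """
    if mode not in ("multiplicative", "absolute"):
        raise ValueError(f"unknown matrix mode {mode!r}")
    start = candidate.target_window_start
    wild_window = pair.wild_seq[start : start + GUIDE_LEN]
    mismatches = [
        i
        for i in range(GUIDE_LEN)
        if complement(candidate.guide[i]) != wild_window[GUIDE_LEN - 1 - i]
    ]
    if not mismatches:
        raise ValueError("no mismatch against the wild-type allele at this window")
    if len(mismatches) > 1:
        raise ValueError(
            f"{len(mismatches)} mismatches against the wild-type allele; "
            "single-mismatch prediction only"
        )
    pos = mismatches[0] + 1
    if pos != candidate.variant_guide_pos:
        raise ValueError(
            f"mismatch at guide position {pos}, expected {candidate.variant_guide_pos}"
        )
    guide_nt = candidate.guide[pos - 1]
    target_nt = wild_window[GUIDE_LEN - pos]
    r = matrix[(pos, guide_nt, target_nt)]
    base = eff_mut if mode == "multiplicative" else 100.0
    return float(min(100.0, max(0.0, base * r)))


def discrimination(eff_mut: float, eff_wild: float) -> float:
    """Signed difference Eff_mut - Eff_wild; the candidate maximizing it is recommended."""
    return float(eff_mut) - float(eff_wild)
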